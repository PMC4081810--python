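"""Background niche divergence / conservatism testing.

Workflow: extract climate values at occurrence points from a raster stack,
prune correlated variables, delimit each lineage's available background
with a minimum convex polygon (MCP), sample random background points
inside each MCP, run a PCA on the pooled (z-scored) background climate,
project occurrences onto the same axes, and compare the observed
between-lineage difference on each axis against a resampling null built
from the background differences.  A larger-than-background observed
difference is *divergence*, a smaller-than-null difference is
*conservatism*, anything inside the null interval is *indistinguishable*.

Rasters are ESRI ASCII grids (plain-text ``.asc``), lon/lat WGS84 decimal
degrees, cell registration at cell centers, nearest-cell extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.prepared import prep

__all__ = [
    "Raster",
    "RasterStack",
    "OccurrenceSet",
    "NicheTestResult",
    "PcaAxes",
    "read_ascii_grid",
    "read_occurrences",
    "extract_climate",
    "filter_correlated",
    "minimum_convex_polygon",
    "sample_background",
    "pca_niche",
    "background_divergence_test",
]


# ---------------------------------------------------------------------------
# rasters


@dataclass(frozen=True)
class Raster:
    """A single gridded variable.  ``data`` is row 0 = northernmost row
    (ESRI ASCII convention); missing cells are NaN."""

    name: str
    data: np.ndarray
    xll: float
    yll: float
    cellsize: float

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing a point, or None if off-grid."""
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmin <= lon < xmax and ymin <= lat < ymax):
            return None
        col = int((lon - xmin) / self.cellsize)
        row = self.nrows - 1 - int((lat - ymin) / self.cellsize)
        return row, col

    def value_at(self, lon: float, lat: float) -> float:
        idx = self.cell_index(lon, lat)
        if idx is None:
            return float("nan")
        return float(self.data[idx])

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        out = np.where(np.isnan(self.data), nodata, self.data)
        header = (
            f"ncols {self.ncols}\nnrows {self.nrows}\n"
            f"xllcorner {self.xll}\nyllcorner {self.yll}\n"
            f"cellsize {self.cellsize}\nNODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path, name: str | None = None) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return Raster(
        name=name or path.stem,
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )


class RasterStack:
    """Named grids sharing extent, resolution and CRS."""

    def __init__(self, rasters: Sequence[Raster]):
        if not rasters:
            raise ValueError("empty raster stack")
        first = rasters[0]
        for r in rasters[1:]:
            same = (
                r.data.shape == first.data.shape
                and np.isclose(r.xll, first.xll)
                and np.isclose(r.yll, first.yll)
                and np.isclose(r.cellsize, first.cellsize)
            )
            if not same:
                raise ValueError(
                    f"raster {r.name!r} geometry differs from {first.name!r}"
                )
        self.rasters = {r.name: r for r in rasters}
        if len(self.rasters) != len(rasters):
            raise ValueError("duplicate raster names")

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return next(iter(self.rasters.values())).bounds

    def __getitem__(self, name: str) -> Raster:
        return self.rasters[name]

    def valid_mask(self) -> np.ndarray:
        """Cells with data in every variable."""
        masks = [~np.isnan(r.data) for r in self.rasters.values()]
        return np.logical_and.reduce(masks)

    @classmethod
    def from_directory(cls, directory: str | Path, pattern: str = "*.asc") -> "RasterStack":
        files = sorted(Path(directory).glob(pattern))
        if not files:
            raise FileNotFoundError(f"no {pattern} rasters in {directory}")
        return cls([read_ascii_grid(f) for f in files])


# ---------------------------------------------------------------------------
# occurrences and extraction


@dataclass(frozen=True)
class OccurrenceSet:
    """Occurrence points of one lineage with their extracted climate."""

    lineage: str
    points: np.ndarray          # (n, 2) lon/lat
    climate: pd.DataFrame       # n rows x variables
    n_dropped: int = 0          # rows dropped for nodata / off-grid


def read_occurrences(path: str | Path) -> dict[str, np.ndarray]:
    """Read an occurrence CSV with columns ``lineage, lon, lat``; returns
    lineage -> (n, 2) lon/lat array."""
    df = pd.read_csv(path)
    missing = {"lineage", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return {
        lin: grp[["lon", "lat"]].to_numpy(dtype=float)
        for lin, grp in df.groupby("lineage", sort=True)
    }


def extract_climate(
    points: np.ndarray, stack: RasterStack, lineage: str = ""
) -> OccurrenceSet:
    """Nearest-cell climate values at each point; rows with any missing
    variable are dropped (count recorded on the result)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rows = []
    kept_pts = []
    dropped = 0
    for lon, lat in pts:
        vals = [stack[name].value_at(lon, lat) for name in stack.names]
        if any(np.isnan(v) for v in vals):
            dropped += 1
            continue
        rows.append(vals)
        kept_pts.append((lon, lat))
    if not rows:
        raise ValueError("all points fall off-grid or on missing cells")
    if dropped:
        warnings.warn(
            f"dropped {dropped} occurrence point(s) with missing climate",
            stacklevel=2,
        )
    return OccurrenceSet(
        lineage=lineage,
        points=np.asarray(kept_pts),
        climate=pd.DataFrame(rows, columns=stack.names),
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# variable pruning


def filter_correlated(
    climate: pd.DataFrame,
    threshold: float = 0.80,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy pruning of correlated variables.

    Variables are visited in ``priority`` order (defaults to column order);
    each is kept only if its absolute Pearson correlation with every
    already-kept variable is <= threshold, otherwise it is dropped and the
    (kept, dropped, r) pair is reported.
    """
    if climate.shape[1] < 2:
        raise ValueError("need at least two variables")
    order = list(priority) if priority is not None else list(climate.columns)
    unknown = sorted(set(order) - set(climate.columns))
    if unknown:
        raise ValueError(f"priority names not in climate matrix: {unknown}")
    corr = climate[order].corr().abs()
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in order:
        clash = None
        for kv in kept:
            r = float(corr.loc[var, kv])
            if r > threshold:
                clash = (kv, var, r)
                break
        if clash is None:
            kept.append(var)
        else:
            dropped.append(clash)
    return kept, dropped


# ---------------------------------------------------------------------------
# background delimitation and sampling


def minimum_convex_polygon(points: np.ndarray) -> Polygon:
    """Convex hull of occurrence points; errors on degenerate input."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ValueError("minimum convex polygon needs >= 3 points")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("points are collinear or degenerate; no polygon")
    return hull


def sample_background(
    polygon: Polygon,
    stack: RasterStack,
    n: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Uniform rejection sampling of n climate rows inside the polygon,
    excluding nodata cells; reproducible by seed."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds
    prepared = prep(polygon)
    names = stack.names
    rows: list[list[float]] = []
    attempts = 0
    max_attempts = 100 * n
    batch = max(4 * n, 256)
    while len(rows) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} background points after {attempts} draws; "
                "polygon may not overlap valid cells"
            )
        xs = rng.uniform(minx, maxx, size=batch)
        ys = rng.uniform(miny, maxy, size=batch)
        attempts += batch
        for lon, lat in zip(xs, ys):
            if not prepared.contains(Point(lon, lat)):
                continue
            vals = [stack[name].value_at(lon, lat) for name in names]
            if any(np.isnan(v) for v in vals):
                continue
            rows.append(vals)
            if len(rows) == n:
                break
    return pd.DataFrame(rows, columns=names)


# ---------------------------------------------------------------------------
# PCA niche axes


@dataclass(frozen=True)
class PcaAxes:
    """PCA fitted on pooled z-scored background climate.

    Sign convention: the largest-magnitude element of each loading vector
    is positive.  ``transform`` projects any climate matrix (e.g. the
    occurrences) onto the same axes.
    """

    loadings: pd.DataFrame          # variables x axes
    variance_explained: np.ndarray  # percent, per axis
    center: pd.Series
    scale: pd.Series

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def transform(self, climate: pd.DataFrame) -> np.ndarray:
        z = (climate[self.loadings.index] - self.center) / self.scale
        return z.to_numpy() @ self.loadings.to_numpy()


def pca_niche(background: pd.DataFrame) -> PcaAxes:
    """PCA (correlation-matrix form) of the pooled background climate."""
    if background.shape[1] < 2 or background.shape[0] < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 rows")
    center = background.mean()
    scale = background.std(ddof=1)
    dead = scale.index[scale == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    z = ((background - center) / scale).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    # deterministic sign: largest-|.| element of each loading positive
    for a in range(loadings.shape[1]):
        col = loadings[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, a] = -col
    var = s**2 / (len(z) - 1)
    pct = 100.0 * var / var.sum()
    axes = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaAxes(
        loadings=pd.DataFrame(loadings, index=background.columns, columns=axes),
        variance_explained=pct,
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# the background divergence test


@dataclass(frozen=True)
class NicheTestResult:
    """Per-axis observed vs background divergence with a resampling null."""

    axes: tuple[str, ...]
    observed_diff: np.ndarray
    background_diff: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    verdict: tuple[str, ...]
    variance_explained: np.ndarray
    loadings: pd.DataFrame
    n_jack: int
    frac: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": list(self.axes),
                "variance_explained": self.variance_explained[: len(self.axes)],
                "observed": self.observed_diff,
                "background": self.background_diff,
                "null_lo": self.null_lo,
                "null_hi": self.null_hi,
                "verdict": list(self.verdict),
            }
        )


def background_divergence_test(
    occ_scores_a: np.ndarray,
    occ_scores_b: np.ndarray,
    bg_scores_a: np.ndarray,
    bg_scores_b: np.ndarray,
    axes: PcaAxes | None = None,
    n_axes: int | None = None,
    n_jack: int = 1000,
    frac: float = 0.75,
    seed: int | None = None,
    method: str = "jackknife",
) -> NicheTestResult:
    """Background test of niche divergence vs conservatism, per PCA axis.

    The observed statistic on each axis is |mean_A - mean_B| of occurrence
    scores; the null distribution resamples ceil(frac x n) background rows
    per lineage (without replacement for ``method="jackknife"``, with
    replacement for ``method="bootstrap"``) and recomputes the background
    divergence |mean difference| each replicate.  Verdicts: *divergence*
    when observed exceeds the upper bound of the middle-95% null interval,
    *conservatism* when below the lower bound, else *indistinguishable*.
    """
    import warnings as _warnings

    if n_jack < 100:
        _warnings.warn("n_jack < 100 gives a coarse null interval", stacklevel=2)
    if method not in {"jackknife", "bootstrap"}:
        raise ValueError("method must be 'jackknife' or 'bootstrap'")
    oa = np.atleast_2d(np.asarray(occ_scores_a, dtype=float))
    ob = np.atleast_2d(np.asarray(occ_scores_b, dtype=float))
    ba = np.atleast_2d(np.asarray(bg_scores_a, dtype=float))
    bb = np.atleast_2d(np.asarray(bg_scores_b, dtype=float))
    n_ax = n_axes or oa.shape[1]
    oa, ob, ba, bb = oa[:, :n_ax], ob[:, :n_ax], ba[:, :n_ax], bb[:, :n_ax]

    observed = np.abs(oa.mean(axis=0) - ob.mean(axis=0))
    background = np.abs(ba.mean(axis=0) - bb.mean(axis=0))

    rng = np.random.default_rng(seed)
    na, nb = len(ba), len(bb)
    ma, mb = int(np.ceil(frac * na)), int(np.ceil(frac * nb))
    null = np.empty((n_jack, n_ax))
    for r in range(n_jack):
        if method == "jackknife":
            ia = rng.choice(na, size=ma, replace=False)
            ib = rng.choice(nb, size=mb, replace=False)
        else:
            ia = rng.integers(0, na, size=ma)
            ib = rng.integers(0, nb, size=mb)
        null[r] = np.abs(ba[ia].mean(axis=0) - bb[ib].mean(axis=0))
    lo = np.percentile(null, 2.5, axis=0)
    hi = np.percentile(null, 97.5, axis=0)

    verdict = tuple(
        "divergence" if observed[a] > hi[a]
        else "conservatism" if observed[a] < lo[a]
        else "indistinguishable"
        for a in range(n_ax)
    )
    axis_names = tuple(f"PC{i + 1}" for i in range(n_ax))
    if axes is not None:
        var_expl = axes.variance_explained
        loadings = axes.loadings
    else:
        var_expl = np.full(n_ax, np.nan)
        loadings = pd.DataFrame()
    return NicheTestResult(
        axes=axis_names,
        observed_diff=observed,
        background_diff=background,
        null_lo=lo,
        null_hi=hi,
        verdict=verdict,
        variance_explained=var_expl,
        loadings=loadings,
        n_jack=n_jack,
        frac=frac,
    )
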