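"""Aligned-sequence I/O and basic sequence containers.

Reads pre-aligned FASTA (one file per locus), concatenates loci, collapses
samples into haplotypes, and computes pairwise distance matrices (raw
differences, p-distance, Jukes–Cantor).

Two site policies govern how alignment columns containing gaps, ``N`` or
IUPAC ambiguity codes are treated:

``complete_deletion``
    columns containing any non-ACGT symbol in *any* sample are removed once,
    up front (the default of most population-genetics tools);
``pairwise_deletion``
    every pairwise comparison uses only the sites where *both* members of
    the pair carry an unambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "SampleMeta",
    "HaplotypeTable",
    "DistanceMatrix",
    "AlignmentError",
    "read_alignment",
    "read_metadata",
    "concatenate",
    "collapse_haplotypes",
    "pairwise_distances",
]

#: bases that count as unambiguous, comparable sites
_VALID = frozenset("ACGT")
#: full accepted alphabet (IUPAC ambiguity + gap + N)
_ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")

SitePolicy = Literal["complete_deletion", "pairwise_deletion"]
DistanceKind = Literal["raw_differences", "p_distance", "jukes_cantor"]


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length sequences for one (or several
    concatenated) loci.

    Parameters
    ----------
    locus_name : str
        Name of the locus, or ``"+"``-joined names after concatenation.
    sample_ids : tuple of str
        Unique sample identifiers, order preserved from input.
    sequences : tuple of str
        Upper-case sequences, one per sample, all the same length.
    locus_bounds : tuple of (str, int, int)
        Half-open ``[start, end)`` column ranges of each constituent locus;
        a single-locus alignment has one entry spanning the whole length.
    """

    locus_name: str
    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    locus_bounds: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        L = len(self.sequences[0])
        if L == 0:
            raise AlignmentError("zero-length sequences")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"sequence for sample {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlignmentError(f"invalid symbols {sorted(bad)} in sample {sid!r}")
        if not self.locus_bounds:
            object.__setattr__(self, "locus_bounds", ((self.locus_name, 0, L),))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        """Alignment restricted to ``sample_ids`` (input order preserved)."""
        wanted = list(sample_ids)
        missing = sorted(set(wanted) - set(self.sample_ids))
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return Alignment(
            locus_name=self.locus_name,
            sample_ids=tuple(wanted),
            sequences=tuple(self.sequences[idx[s]] for s in wanted),
            locus_bounds=self.locus_bounds,
        )

    def filtered_matrix(self, site_policy: SitePolicy = "complete_deletion") -> np.ndarray:
        """Character matrix after applying the site policy.

        Under complete deletion, columns containing any non-ACGT symbol are
        dropped.  Under pairwise deletion the full matrix is returned;
        downstream pairwise comparisons mask sites per pair.
        """
        mat = self.matrix()
        if site_policy == "complete_deletion":
            ok = np.isin(mat, list(_VALID)).all(axis=0)
            return mat[:, ok]
        if site_policy == "pairwise_deletion":
            return mat
        raise ValueError(f"unknown site policy {site_policy!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: population label, sex and WGS84 coordinates."""

    sample_id: str
    population: str
    sex: str = "unknown"
    lon: float = float("nan")
    lat: float = float("nan")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata TSV with columns
    ``sample_id, population[, sex, lon, lat]``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    required = {"sample_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                population=row["population"],
                sex=str(row.get("sex", "unknown")),
                lon=float(row["lon"]) if "lon" in df.columns else float("nan"),
                lat=float(row["lat"]) if "lat" in df.columns else float("nan"),
            )
        )
    pops = {m.population for m in out}
    if any(not p for p in pops):
        raise ValueError("empty population label in metadata")
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metadata")
    return out


def check_metadata(aln: Alignment, meta: Sequence[SampleMeta]) -> dict[str, str]:
    """Map sample id -> population; error if any alignment sample lacks
    exactly one metadata row."""
    table = {m.sample_id: m.population for m in meta}
    missing = sorted(set(aln.sample_ids) - set(table))
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return {s: table[s] for s in aln.sample_ids}


def read_alignment(path: str | Path, locus_name: str) -> Alignment:
    """Read one locus from an aligned FASTA file.

    Sequences are upper-cased and surrounding whitespace stripped; the FASTA
    description after the first whitespace is ignored; ids are
    case-sensitive.  Unequal sequence lengths, duplicate ids and empty files
    raise :class:`AlignmentError` naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = [str(r.seq).strip().upper().replace("U", "T") for r in records]
    L = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != L:
            raise AlignmentError(
                f"{path}: sequence {rid!r} has length {len(s)}, expected {L} "
                f"(alignment must be pre-aligned)"
            )
    return Alignment(locus_name=locus_name, sample_ids=tuple(ids), sequences=tuple(seqs))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment to FASTA (plain text, 70-column wrap)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def concatenate(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate loci sharing an identical sample id set.

    Per-sample order follows the first alignment.  Locus boundaries are
    recorded for reporting.  A single alignment is returned unchanged.
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    if len(alignments) == 1:
        return alignments[0]
    first = alignments[0]
    base = set(first.sample_ids)
    for aln in alignments[1:]:
        if set(aln.sample_ids) != base:
            diff = sorted(base.symmetric_difference(aln.sample_ids))
            raise AlignmentError(
                f"sample id sets differ between loci {first.locus_name!r} and "
                f"{aln.locus_name!r}: {diff}"
            )
    order = first.sample_ids
    parts = [aln.subset(order) for aln in alignments]
    seqs = ["".join(p.sequences[i] for p in parts) for i in range(len(order))]
    bounds = []
    offset = 0
    for p in parts:
        bounds.append((p.locus_name, offset, offset + p.length))
        offset += p.length
    return Alignment(
        locus_name="+".join(p.locus_name for p in parts),
        sample_ids=order,
        sequences=tuple(seqs),
        locus_bounds=tuple(bounds),
    )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``haplotypes`` are filtered sequences (site policy already applied);
    ``counts`` is a (haplotypes x populations) integer matrix; ``assignment``
    maps each sample id to its haplotype row index.  Haplotypes are ordered
    by descending total count, ties broken lexicographically by sequence.
    """

    haplotypes: tuple[str, ...]
    populations: tuple[str, ...]
    counts: np.ndarray
    assignment: dict[str, int]

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def population_counts(self, population: str) -> np.ndarray:
        j = self.populations.index(population)
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=[f"H{i + 1}" for i in range(self.k)],
            columns=list(self.populations),
        )
        df.insert(0, "sequence", list(self.haplotypes))
        df.index.name = "haplotype"
        return df

    def write_tsv(self, path: str | Path, assignment_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t")
        if assignment_path is not None:
            rows = [
                {"sample_id": s, "haplotype": f"H{h + 1}"}
                for s, h in self.assignment.items()
            ]
            pd.DataFrame(rows).to_csv(assignment_path, sep="\t", index=False)


def collapse_haplotypes(
    aln: Alignment,
    meta: Sequence[SampleMeta],
    site_policy: SitePolicy = "complete_deletion",
) -> HaplotypeTable:
    """Collapse samples into distinct haplotypes, counted per population.

    Haplotype identity is exact string equality after applying the site
    policy (ambiguity codes are never expanded).  Column sums of the count
    matrix equal population sample sizes by construction.
    """
    pop_of = check_metadata(aln, meta)
    populations = tuple(dict.fromkeys(pop_of[s] for s in aln.sample_ids))
    if site_policy == "complete_deletion":
        mat = aln.filtered_matrix("complete_deletion")
        keys = ["".join(row) for row in mat]
    else:
        keys = list(aln.sequences)

    groups: dict[str, list[str]] = {}
    for sid, key in zip(aln.sample_ids, keys):
        groups.setdefault(key, []).append(sid)
    # deterministic ordering: descending total count, then lexicographic
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haplotypes = tuple(h for h, _ in ordered)
    counts = np.zeros((len(haplotypes), len(populations)), dtype=int)
    assignment: dict[str, int] = {}
    for i, (_, members) in enumerate(ordered):
        for sid in members:
            assignment[sid] = i
            counts[i, populations.index(pop_of[sid])] += 1
    return HaplotypeTable(
        haplotypes=haplotypes,
        populations=populations,
        counts=counts,
        assignment=assignment,
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over samples."""

    ids: tuple[str, ...]
    values: np.ndarray
    kind: DistanceKind

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(v < 0):
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _pair_counts(
    mat: np.ndarray, site_policy: SitePolicy
) -> tuple[np.ndarray, np.ndarray]:
    """(diffs, comparable) matrices of pairwise differing / comparable sites."""
    n = mat.shape[0]
    valid = np.isin(mat, list(_VALID))
    diffs = np.zeros((n, n), dtype=float)
    comp = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = int(both.sum())
            nd = int((mat[i, both] != mat[j, both]).sum())
            diffs[i, j] = diffs[j, i] = nd
            comp[i, j] = comp[j, i] = nc
    return diffs, comp


def pairwise_distances(
    aln: Alignment,
    kind: DistanceKind = "raw_differences",
    site_policy: SitePolicy = "complete_deletion",
) -> DistanceMatrix:
    """Pairwise distances among all samples of an alignment.

    ``raw_differences`` counts differing comparable sites; ``p_distance``
    divides by the number of comparable sites; ``jukes_cantor`` applies
    d = -(3/4) ln(1 - (4/3) p).  A proportion p >= 0.75 makes the JC
    distance undefined and raises ``ValueError``.
    """
    if aln.n < 2:
        raise AlignmentError("need at least two samples for distances")
    mat = aln.filtered_matrix(site_policy)
    if mat.shape[1] == 0:
        raise AlignmentError("no comparable sites left after site filtering")
    diffs, comp = _pair_counts(mat, site_policy)
    if kind == "raw_differences":
        values = diffs
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(comp > 0, diffs / np.maximum(comp, 1), np.nan)
        np.fill_diagonal(p, 0.0)
        if np.any(np.isnan(p)):
            raise AlignmentError("a sample pair shares no comparable sites")
        if kind == "p_distance":
            values = p
        elif kind == "jukes_cantor":
            if np.any(p >= 0.75):
                raise ValueError(
                    "Jukes-Cantor distance undefined for p >= 0.75 "
                    f"(max p = {p.max():.4f})"
                )
            values = -0.75 * np.log1p(-(4.0 / 3.0) * p)
            np.fill_diagonal(values, 0.0)
        else:
            raise ValueError(f"unknown distance kind {kind!r}")
    return DistanceMatrix(ids=aln.sample_ids, values=values, kind=kind)
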