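"""Synthetic-data generators with known truth for every analysis stage.

Sequence data come from coalescent simulations (msprime genealogies) with
finite-sites Jukes-Cantor mutations overlaid on a discrete genome, so the
simulated alignments exercise JC distances and haplotype collapsing
exactly as real data do.  Loci are simulated haploid with effective size N
(mtDNA-like, no ploidy scaling), matching the demography module's default
inheritance scalar.

Niche rasters are smoothed Gaussian random fields plus a directional
gradient; occurrences are drawn by weighting grid cells with a Gaussian
kernel around a lineage-specific environmental optimum.  Morphology
groups are plain Gaussian samples.

All generators are reproducible: the same seed yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import msprime
import numpy as np
from scipy import ndimage

from .niche import Raster, RasterStack, OccurrenceSet
from .seqio import Alignment, SampleMeta

__all__ = [
    "IMSimParams",
    "NicheSimParams",
    "simulate_im_sequences",
    "simulate_expansion_sample",
    "simulate_niche",
    "simulate_morphology",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IMSimParams:
    """Two-population isolation-with-migration model (haploid sizes).

    ``t_split`` is in generations; ``m_ab`` is the per-generation fraction
    of population A made up of migrants from B (and vice versa);
    ``growth`` optionally replaces the within-population constant size
    with a sudden expansion (theta0, theta1, tau) shared by both demes.
    """

    n_a: int = 10
    n_b: int = 15
    L: int = 1077
    mu: float = 1e-6
    N_a: float = 2000.0
    N_b: float = 1500.0
    N_anc: float = 5000.0
    t_split: float = 8000.0
    m_ab: float = 0.0
    m_ba: float = 0.0
    seed: int = 1
    pop_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if min(self.N_a, self.N_b, self.N_anc) <= 0 or self.mu < 0:
            raise ValueError("sizes must be positive and mu non-negative")
        if self.t_split < 0 or min(self.m_ab, self.m_ba) < 0:
            raise ValueError("t_split and migration rates must be non-negative")


def _ts_to_alignment(
    ts, sample_ids: Sequence[str], L: int, seed: int, locus_name: str
) -> Alignment:
    """Project a mutated tree sequence onto full-length sequences.

    Sites never hit by mutation take a random (seeded) reference base;
    mutated sites use the simulator's ancestral/derived states.
    """
    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=L)
    mat = np.tile(ref, (len(sample_ids), 1))
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = np.array(var.alleles, dtype="U1")
        mat[:, pos] = alleles[var.genotypes]
    seqs = tuple("".join(row) for row in mat)
    return Alignment(locus_name=locus_name, sample_ids=tuple(sample_ids), sequences=seqs)


def simulate_im_sequences(
    p: IMSimParams,
) -> tuple[Alignment, list[SampleMeta], dict]:
    """Simulate sequences under the two-population IM model.

    Returns the finite-sites JC alignment, per-sample metadata with
    population labels, and a truth record of the generating parameters.
    """
    name_a, name_b = p.pop_names
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=p.N_a)
    dem.add_population(name="B", initial_size=p.N_b)
    dem.add_population(name="ANC", initial_size=p.N_anc)
    if p.m_ab > 0:
        dem.set_migration_rate(source="A", dest="B", rate=p.m_ab)
    if p.m_ba > 0:
        dem.set_migration_rate(source="B", dest="A", rate=p.m_ba)
    dem.add_population_split(time=p.t_split, derived=["A", "B"], ancestral="ANC")
    ts = msprime.sim_ancestry(
        samples={"A": p.n_a, "B": p.n_b},
        demography=dem,
        sequence_length=p.L,
        ploidy=1,
        discrete_genome=True,
        random_seed=_msp_seed(p.seed, 0),
    )
    if p.mu > 0:
        ts = msprime.sim_mutations(
            ts,
            rate=p.mu,
            model=msprime.JC69(),
            random_seed=_msp_seed(p.seed, 1),
        )
    ids = [f"{name_a}{i + 1:02d}" for i in range(p.n_a)] + [
        f"{name_b}{i + 1:02d}" for i in range(p.n_b)
    ]
    aln = _ts_to_alignment(ts, ids, p.L, _msp_seed(p.seed, 2), "simlocus")
    meta = [
        SampleMeta(sample_id=s, population=name_a if i < p.n_a else name_b)
        for i, s in enumerate(ids)
    ]
    truth = {
        "n_a": p.n_a, "n_b": p.n_b, "L": p.L, "mu": p.mu,
        "N_a": p.N_a, "N_b": p.N_b, "N_anc": p.N_anc,
        "t_split": p.t_split, "m_ab": p.m_ab, "m_ba": p.m_ba,
        "theta_a": 2 * p.N_a * p.mu * p.L,
        "theta_b": 2 * p.N_b * p.mu * p.L,
        "seed": p.seed,
    }
    return aln, meta, truth


def _msp_seed(seed: int, stream: int) -> int:
    """Deterministic per-stream seed in msprime's accepted range."""
    ss = np.random.SeedSequence([int(seed), stream])
    return int(ss.generate_state(1)[0] % (2**31 - 2)) + 1


def simulate_expansion_sample(
    theta0: float,
    theta1: float,
    tau: float,
    n: int,
    L: int,
    seed: int,
    mu_site: float = 1e-7,
) -> Alignment:
    """Single-population coalescent sample with an instantaneous size
    change at mutational time tau before present.

    Scaled parameters follow the mismatch-model convention for a haploid
    locus: theta = 2 N u and tau = 2 u t with u = mu_site x L the
    per-locus per-generation rate.  theta1 is the size after (more
    recently than) the expansion, theta0 before it; theta1 = theta0
    reduces to the constant-size model.
    """
    if min(theta0, theta1) < 0 or tau < 0:
        raise ValueError("theta0, theta1, tau must be non-negative")
    u = mu_site * L
    n0 = max(theta1, 1e-4) / (2 * u)   # present size
    n1 = max(theta0, 1e-4) / (2 * u)   # ancient size
    t_change = tau / (2 * u)
    dem = msprime.Demography()
    dem.add_population(name="P", initial_size=n0)
    if t_change > 0:
        dem.add_population_parameters_change(
            time=t_change, population="P", initial_size=n1
        )
    ts = msprime.sim_ancestry(
        samples={"P": n},
        demography=dem,
        sequence_length=L,
        ploidy=1,
        discrete_genome=True,
        random_seed=_msp_seed(seed, 0),
    )
    ts = msprime.sim_mutations(
        ts, rate=mu_site, model=msprime.JC69(), random_seed=_msp_seed(seed, 1)
    )
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return _ts_to_alignment(ts, ids, L, _msp_seed(seed, 2), "expansion")


# ---------------------------------------------------------------------------
# niche simulation


@dataclass(frozen=True)
class NicheSimParams:
    """Synthetic rasters plus two lineages with Gaussian environmental
    niches.

    ``shift`` displaces lineage B's environmental optimum, in units of the
    background SD, on each variable (zero vector = identical niches).
    ``niche_sd`` is the niche breadth relative to the background SD.
    Defaults (200 occurrences per lineage over 1000 background points,
    four variables on an 80 x 80 grid) keep occurrence-mean noise inside
    the jackknife null width, the regime the background test assumes.
    """

    grid: int = 80
    n_vars: int = 4
    n_occ: int = 200
    niche_sd: float = 0.5
    shift: tuple[float, ...] = ()
    smooth: float = 6.0
    seed: int = 1

    def shift_vector(self) -> np.ndarray:
        v = np.zeros(self.n_vars)
        s = np.asarray(self.shift, dtype=float)
        v[: len(s)] = s[: self.n_vars]
        return v


def _random_field(rng: np.random.Generator, g: int, smooth: float) -> np.ndarray:
    """Smoothed white noise plus a random linear gradient, z-scored."""
    noise = ndimage.gaussian_filter(rng.standard_normal((g, g)), smooth)
    yy, xx = np.mgrid[0:g, 0:g] / (g - 1)
    angle = rng.uniform(0, 2 * np.pi)
    grad = np.cos(angle) * xx + np.sin(angle) * yy
    f = noise / noise.std() + 1.0 * (grad - grad.mean())
    return (f - f.mean()) / f.std()


def simulate_niche(
    p: NicheSimParams,
) -> tuple[RasterStack, OccurrenceSet, OccurrenceSet, dict]:
    """Generate a raster stack and two lineages' occurrences.

    Occurrences are drawn (with replacement over cells, jittered within
    the cell) with probability proportional to a Gaussian kernel around
    each lineage's optimum in environment space.  The truth record stores
    the per-variable optimum shift between lineages.
    """
    rng = np.random.default_rng(p.seed)
    g = p.grid
    fields = [_random_field(rng, g, p.smooth) for _ in range(p.n_vars)]
    rasters = [
        Raster(name=f"VAR{i + 1}", data=fields[i], xll=0.0, yll=0.0, cellsize=1.0 / g)
        for i in range(p.n_vars)
    ]
    stack = RasterStack(rasters)

    env = np.stack([f.ravel() for f in fields], axis=1)  # cells x vars
    shift = p.shift_vector()
    opt_a = np.zeros(p.n_vars)
    opt_b = shift  # background fields are z-scored, so units are SDs
    pts_by_lineage = {}
    for lineage, opt in (("A", opt_a), ("B", opt_b)):
        w = np.exp(-0.5 * np.sum(((env - opt) / p.niche_sd) ** 2, axis=1))
        w /= w.sum()
        cells = rng.choice(len(w), size=p.n_occ, replace=True, p=w)
        rows, cols = np.unravel_index(cells, (g, g))
        # points jittered inside their cell, in the unit-square grid frame
        lon = (cols + rng.uniform(0.25, 0.75, p.n_occ)) / g
        lat = (g - 1 - rows + rng.uniform(0.25, 0.75, p.n_occ)) / g
        pts_by_lineage[lineage] = np.column_stack([lon, lat])
    # extract climate through the same path real data take
    from .niche import extract_climate

    occ_a = extract_climate(pts_by_lineage["A"], stack, lineage="A")
    occ_b = extract_climate(pts_by_lineage["B"], stack, lineage="B")
    truth = {
        "shift": shift.tolist(),
        "niche_sd": p.niche_sd,
        "n_occ": p.n_occ,
        "grid": g,
        "n_vars": p.n_vars,
        "seed": p.seed,
    }
    return stack, occ_a, occ_b, truth


def simulate_morphology(
    means: Mapping[str, float] | Sequence[float],
    sds: Mapping[str, float] | Sequence[float],
    ns: Mapping[str, int] | Sequence[int],
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Gaussian measurement groups, e.g. one trait for two populations."""
    if isinstance(means, Mapping):
        keys = list(means)
        mu = [means[k] for k in keys]
        sd = [sds[k] for k in keys]
        n = [ns[k] for k in keys]
    else:
        mu, sd, n = list(means), list(sds), list(ns)
        keys = [f"group{i + 1}" for i in range(len(mu))]
    if not (len(mu) == len(sd) == len(n)):
        raise ValueError("means, sds and ns must have equal lengths")
    rng = np.random.default_rng(seed)
    return {
        k: rng.normal(m, s, size=int(cnt))
        for k, m, s, cnt in zip(keys, mu, sd, n)
    }
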