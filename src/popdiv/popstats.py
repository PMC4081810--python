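"""Diversity, differentiation and neutrality statistics.

Implements the classical sequence-based summaries for one or two
populations: Nei's gene (haplotype) diversity h and nucleotide diversity
pi with their sampling standard deviations, between-population distances
dxy and the net divergence da ("corrected for intra-population
polymorphism"), Tajima's D, Fu's Fs, a two-level AMOVA with a permutation
test on the Phi fixation index, and the Kruskal-Wallis rank test used for
morphological comparisons.

Undefined statistics (e.g. Tajima's D on a monomorphic alignment) are
returned as ``nan`` with an explicit ``defined`` flag, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .seqio import (
    Alignment,
    SampleMeta,
    DistanceMatrix,
    SitePolicy,
    check_metadata,
    collapse_haplotypes,
    _pair_counts,
)

__all__ = [
    "DiversityResult",
    "NeutralityResult",
    "AmovaResult",
    "BetweenPopDistance",
    "gene_diversity",
    "nucleotide_diversity",
    "population_diversity",
    "between_pop_distance",
    "tajimas_d",
    "fus_fs",
    "neutrality",
    "amova",
    "pairwise_phi_st",
    "kruskal_wallis",
]


# ---------------------------------------------------------------------------
# diversity


@dataclass(frozen=True)
class DiversityResult:
    population: str
    n: int
    k: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


def gene_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased gene diversity and its sampling SD.

    h = n (1 - sum p_i^2) / (n - 1), with the Nei (1987) variance
    V(h) = 2/(n(n-1)) { 2(n-2) [sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    p = c / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def _mean_pairwise(aln: Alignment, site_policy: SitePolicy) -> tuple[float, int, int]:
    """(mean pairwise differences, comparable length, S) after site policy.

    Under pairwise deletion the per-pair difference counts are rescaled to
    the mean comparable length so the statistic stays per-locus comparable.
    """
    mat = aln.filtered_matrix(site_policy)
    diffs, comp = _pair_counts(mat, site_policy)
    n = aln.n
    iu = np.triu_indices(n, 1)
    if site_policy == "complete_deletion":
        L = mat.shape[1]
        if L == 0:
            raise ValueError("no comparable sites after complete deletion")
        k_mean = float(diffs[iu].mean())
        # segregating sites: polymorphic columns of the filtered matrix
        S = int(np.sum([len(set(col)) > 1 for col in mat.T]))
    else:
        if np.any(comp[iu] == 0):
            raise ValueError("a pair shares no comparable sites")
        L = int(round(float(comp[iu].mean())))
        k_mean = float((diffs[iu] / comp[iu]).mean() * L)
        valid = np.isin(mat, list("ACGT"))
        S = 0
        for j in range(mat.shape[1]):
            col = mat[valid[:, j], j]
            if col.size > 1 and len(set(col)) > 1:
                S += 1
    return k_mean, L, S


def nucleotide_diversity(
    aln: Alignment, site_policy: SitePolicy = "complete_deletion"
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its sampling SD (Nei 1987).

    pi = sum_{i<j} d_ij / (C(n,2) L); the SD uses the total (stochastic +
    sampling) variance V(pi) = (n+1)/(3(n-1)L) pi + 2(n^2+n+3)/(9n(n-1)) pi^2.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    k_mean, L, _ = _mean_pairwise(aln, site_policy)
    n = aln.n
    pi = k_mean / L
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def population_diversity(
    aln: Alignment,
    meta: Sequence[SampleMeta],
    site_policy: SitePolicy = "complete_deletion",
    include_overall: bool = True,
) -> list[DiversityResult]:
    """Per-population (and pooled) haplotype and nucleotide diversity."""
    pop_of = check_metadata(aln, meta)
    pops = list(dict.fromkeys(pop_of.values()))
    groups = {p: [s for s in aln.sample_ids if pop_of[s] == p] for p in pops}
    if include_overall:
        groups["overall"] = list(aln.sample_ids)
    out = []
    for pop, ids in groups.items():
        sub = aln.subset(ids)
        sub_meta = [m for m in meta if m.sample_id in set(ids)]
        table = collapse_haplotypes(sub, sub_meta, site_policy)
        h, h_sd = gene_diversity(table.total_counts)
        pi, pi_sd = nucleotide_diversity(sub, site_policy)
        out.append(
            DiversityResult(
                population=pop, n=sub.n, k=table.k, h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd
            )
        )
    return out


# ---------------------------------------------------------------------------
# between-population distance


@dataclass(frozen=True)
class BetweenPopDistance:
    """Mean between-population per-site distance dxy and the net divergence
    da = dxy - (pi_X + pi_Y)/2.  Percent values are the per-site proportions
    scaled by 100."""

    pop_x: str
    pop_y: str
    dxy: float
    da: float

    @property
    def dxy_percent(self) -> float:
        return 100.0 * self.dxy

    @property
    def da_percent(self) -> float:
        return 100.0 * self.da


def between_pop_distance(
    aln: Alignment,
    meta: Sequence[SampleMeta],
    pop_x: str,
    pop_y: str,
    site_policy: SitePolicy = "complete_deletion",
) -> BetweenPopDistance:
    """dxy and da between two populations of one alignment."""
    pop_of = check_metadata(aln, meta)
    ids_x = [s for s in aln.sample_ids if pop_of[s] == pop_x]
    ids_y = [s for s in aln.sample_ids if pop_of[s] == pop_y]
    if not ids_x or not ids_y:
        raise ValueError(f"empty population among {pop_x!r}, {pop_y!r}")
    mat = aln.filtered_matrix(site_policy)
    diffs, comp = _pair_counts(mat, site_policy)
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    ix = [idx[s] for s in ids_x]
    iy = [idx[s] for s in ids_y]
    if site_policy == "complete_deletion":
        L = mat.shape[1]
        dxy = float(diffs[np.ix_(ix, iy)].mean()) / L
    else:
        sub_d = diffs[np.ix_(ix, iy)]
        sub_c = comp[np.ix_(ix, iy)]
        if np.any(sub_c == 0):
            raise ValueError("a between-population pair shares no comparable sites")
        dxy = float((sub_d / sub_c).mean())
    pi_x = (
        nucleotide_diversity(aln.subset(ids_x), site_policy)[0] if len(ids_x) > 1 else 0.0
    )
    pi_y = (
        nucleotide_diversity(aln.subset(ids_y), site_policy)[0] if len(ids_y) > 1 else 0.0
    )
    da = dxy - 0.5 * (pi_x + pi_y)
    return BetweenPopDistance(pop_x=pop_x, pop_y=pop_y, dxy=dxy, da=da)


# ---------------------------------------------------------------------------
# neutrality tests


@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    k: int
    theta_pi: float
    D: float
    Fs: float

    @property
    def d_defined(self) -> bool:
        return not np.isnan(self.D)

    @property
    def fs_defined(self) -> bool:
        return not np.isnan(self.Fs)


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(
    aln: Alignment, site_policy: SitePolicy = "complete_deletion"
) -> float:
    """Tajima's D; ``nan`` when S = 0 (undefined, not zero)."""
    if aln.n < 2:
        raise ValueError("Tajima's D needs n >= 2")
    k_mean, _, S = _mean_pairwise(aln, site_policy)
    if S == 0:
        return float("nan")
    c = _tajima_constants(aln.n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    return float((k_mean - S / c["a1"]) / np.sqrt(var))


@lru_cache(maxsize=None)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n, computed exactly then logged."""
    row = [1]
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k <= m - 1 else 0)
    out = []
    for v in row:
        if v == 0:
            out.append(float("-inf"))
        else:
            # exact integer -> log via int.bit_length-safe route
            out.append(_log_int(v))
    return tuple(out)


def _log_int(v: int) -> float:
    if v.bit_length() <= 900:
        return float(np.log(float(v)))
    shift = v.bit_length() - 900
    return float(np.log(float(v >> shift)) + shift * np.log(2.0))


def ewens_k_pmf_log(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = np.array(_log_stirling_first(n))
    ks = np.arange(n + 1)
    log_num = ls + ks * np.log(theta)
    log_den = float(np.sum(np.log(theta + np.arange(n))))  # rising factorial
    return log_num - log_den


def fus_fs(
    aln: Alignment, site_policy: SitePolicy = "complete_deletion"
) -> float:
    """Fu's Fs = logit of S' = P(K >= k_obs | theta = theta_pi).

    The allelic-configuration probability uses the Ewens sampling formula
    with unsigned Stirling numbers of the first kind, evaluated in log
    space.  ``nan`` when only one haplotype is observed or when S'
    degenerates to 0 or 1.
    """
    if aln.n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    mat = aln.filtered_matrix(site_policy)
    if site_policy == "complete_deletion":
        k_obs = len({"".join(r) for r in mat})
    else:
        k_obs = len(set(aln.sequences))
    if k_obs <= 1:
        return float("nan")
    theta, _, _ = _mean_pairwise(aln, site_policy)
    if theta <= 0:
        return float("nan")
    logp = ewens_k_pmf_log(aln.n, theta)
    log_sp = float(logsumexp(logp[k_obs:]))
    log_1m_sp = float(logsumexp(logp[:k_obs]))
    if not np.isfinite(log_sp) or not np.isfinite(log_1m_sp):
        return float("nan")
    return float(log_sp - log_1m_sp)


def neutrality(
    aln: Alignment, site_policy: SitePolicy = "complete_deletion"
) -> NeutralityResult:
    """Tajima's D and Fu's Fs plus the quantities they are built from."""
    k_mean, _, S = _mean_pairwise(aln, site_policy)
    mat = aln.filtered_matrix(site_policy)
    k_hap = len({"".join(r) for r in mat}) if site_policy == "complete_deletion" else len(
        set(aln.sequences)
    )
    return NeutralityResult(
        n=aln.n,
        S=S,
        k=k_hap,
        theta_pi=k_mean,
        D=tajimas_d(aln, site_policy),
        Fs=fus_fs(aln, site_policy),
    )


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    p: float
    n_perm: int

    @property
    def sigma_total(self) -> float:
        return self.sigma_among + self.sigma_within

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among groups", "within groups"],
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "variance": [self.sigma_among, self.sigma_within],
            }
        )


def _amova_phi(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, float]:
    """(phi, sigma_a, sigma_w, ss_a, ss_w) for one labelling."""
    n = d2.shape[0]
    groups = np.unique(labels)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    sizes = []
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        ng = len(idx)
        sizes.append(ng)
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, n - g
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    ms_a = ss_among / df_a
    sizes = np.asarray(sizes, dtype=float)
    n_eff = (n - float(np.sum(sizes**2)) / n) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_eff
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else 0.0
    return phi, sigma_a, sigma_w, ss_among, ss_within


def amova(
    dist: DistanceMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    n_perm: int = 16000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA with a permutation test on Phi.

    The supplied (model) distances enter the Excoffier sums of squares
    directly as squared Euclidean distances, the convention of the standard
    molecular-variance implementations.  Permutations shuffle individual
    assignments among groups; the p-value uses the add-one estimator
    p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1).
    """
    if isinstance(grouping, Mapping):
        labels = np.array([grouping[s] for s in dist.ids])
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != len(dist.ids):
            raise ValueError("grouping length does not match distance ids")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two groups")
    if np.any(counts == 0):
        raise ValueError("empty group")
    d2 = dist.values
    phi, sa, sw, ssa, ssw = _amova_phi(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        phi_p, *_ = _amova_phi(d2, perm)
        if phi_p >= phi:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return AmovaResult(
        sigma_among=sa,
        sigma_within=sw,
        phi=phi,
        df_among=len(groups) - 1,
        df_within=len(labels) - len(groups),
        ss_among=ssa,
        ss_within=ssw,
        p=p,
        n_perm=n_perm,
    )


def pairwise_phi_st(
    dist: DistanceMatrix, grouping: Mapping[str, str] | Sequence[str]
) -> float:
    """Phi_ST between two populations (no permutation), identical to the
    two-group AMOVA Phi on the same matrix."""
    if isinstance(grouping, Mapping):
        labels = np.array([grouping[s] for s in dist.ids])
    else:
        labels = np.asarray(list(grouping))
    phi, *_ = _amova_phi(dist.values, labels)
    return phi


# ---------------------------------------------------------------------------
# morphology


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical values across groups give H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
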