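"""Historical demography from mismatch distributions, plus demographic
unit conversions.

The mismatch distribution is the histogram of pairwise nucleotide
differences.  Under the sudden-expansion model a population of scaled size
theta0 grows instantaneously to theta1 at time tau before present, with
time measured in mutational units (tau = 2 u t for a per-locus mutation
rate u and t generations).  The expected distribution of pairwise
differences has the closed form

    F_j = Fhat_j(theta1) P[Gamma(j+1) <= tau (1 + 1/theta1)]
        + exp(-tau (1 + 1/theta1)) sum_{i=0}^{j} tau^i/i! Fhat_{j-i}(theta0)

where Fhat_j(theta) = theta^j / (1+theta)^{j+1} is the stationary
geometric distribution.  The fit minimizes the sum of squared deviations
(SSD) between observed and expected *frequencies*, and a parametric
bootstrap (coalescent simulation under the fitted expansion) gives the
SSD goodness-of-fit p-value: expansion is not rejected when p > 0.05.

Unit conversions cover the life-history generation time
T = a + s/(1-s) and the rescaling of mutation-scaled
isolation-with-migration (IM) parameters to demographic units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaln

from .seqio import Alignment, SitePolicy, _pair_counts

__all__ = [
    "MismatchHistogram",
    "MismatchFit",
    "DemogScaling",
    "ImaConversion",
    "mismatch_histogram",
    "expected_mismatch",
    "fit_sudden_expansion",
    "ssd_bootstrap",
    "generation_time",
    "convert_ima",
]


# ---------------------------------------------------------------------------
# histogram


@dataclass(frozen=True)
class MismatchHistogram:
    """Frequencies of pairwise difference counts j = 0..max."""

    counts: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.sum() != self.n_pairs:
            raise ValueError("histogram counts do not sum to the number of pairs")
        object.__setattr__(self, "counts", c)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_pairs

    @property
    def mean(self) -> float:
        j = np.arange(len(self.counts))
        return float((j * self.frequencies).sum())


def mismatch_histogram(
    aln: Alignment, site_policy: SitePolicy = "complete_deletion"
) -> MismatchHistogram:
    """Histogram of raw pairwise differences among all samples."""
    if aln.n < 2:
        raise ValueError("mismatch histogram needs n >= 2")
    mat = aln.filtered_matrix(site_policy)
    diffs, comp = _pair_counts(mat, site_policy)
    iu = np.triu_indices(aln.n, 1)
    d = diffs[iu].astype(int)
    counts = np.bincount(d)
    return MismatchHistogram(counts=counts, n_pairs=len(d))


# ---------------------------------------------------------------------------
# expected distribution and SSD fit


def _stationary(j: np.ndarray, theta: float) -> np.ndarray:
    """Fhat_j(theta) = theta^j / (1+theta)^(j+1), with the theta -> 0 limit
    of a point mass at j = 0."""
    j = np.asarray(j)
    if theta <= 1e-12:
        return (j == 0).astype(float)
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(
    jmax: int, tau: float, theta0: float, theta1: float
) -> np.ndarray:
    """Expected pairwise-difference probabilities F_j, j = 0..jmax, under
    the sudden-expansion model (exact two-epoch closed form)."""
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("parameters must be non-negative")
    j = np.arange(jmax + 1)
    if theta1 <= 1e-12:
        # recent size ~0: every pair coalesces immediately unless tau ~ 0
        if tau <= 1e-12:
            return _stationary(j, theta0)
        return (j == 0).astype(float)
    rate = 1.0 + 1.0 / theta1
    recent = _stationary(j, theta1) * gammainc(j + 1, tau * rate)
    # ancient epoch: exp(-tau*rate) * sum_i tau^i/i! * Fhat_{j-i}(theta0)
    f0 = _stationary(j, theta0)
    if tau <= 0:
        anc = f0
        pref = 1.0
    else:
        pois = np.exp(-tau + j * np.log(tau) - gammaln(j + 1))
        anc = np.convolve(pois, f0)[: jmax + 1]
        pref = np.exp(-tau / theta1)
    return recent + pref * anc


def expected_mismatch_full(
    tau: float, theta0: float, theta1: float, tol: float = 1e-12, jcap: int = 100000
) -> np.ndarray:
    """Expected distribution extended until the upper tail mass is below
    ``tol`` (used for normalization checks and model-based sampling)."""
    jmax = 32
    while jmax < jcap:
        f = expected_mismatch(jmax, tau, theta0, theta1)
        if 1.0 - f.sum() < tol or f[-1] < tol:
            return f
        jmax *= 2
    return expected_mismatch(jcap, tau, theta0, theta1)


def ssd(observed: np.ndarray, expected: np.ndarray) -> float:
    """Sum of squared deviations between two frequency vectors over the
    observed difference classes."""
    obs = np.asarray(observed, dtype=float)
    exp_ = np.asarray(expected, dtype=float)[: len(obs)]
    if len(exp_) < len(obs):
        exp_ = np.pad(exp_, (0, len(obs) - len(exp_)))
    return float(np.sum((obs - exp_) ** 2))


@dataclass(frozen=True)
class MismatchFit:
    """Least-squares sudden-expansion fit to a mismatch distribution."""

    tau: float
    theta0: float
    theta1: float
    SSD: float
    n: int
    boundary: bool = False
    p_ssd: float | None = None
    n_boot: int = 0

    @property
    def flagged_contraction(self) -> bool:
        """True when theta1 < theta0 (fitted change is a contraction)."""
        return self.theta1 < self.theta0


def fit_sudden_expansion(
    hist: MismatchHistogram,
    n: int,
    theta1_max: float = 5000.0,
) -> MismatchFit:
    """Fit (tau, theta0, theta1) by bounded nonlinear least squares on
    normalized frequencies.

    Initialization is method-of-moments (the histogram mean estimates
    tau + theta0 when theta1 is large) refined from a small multi-start
    grid; SSD = sum_j (obs_j - exp_j)^2 over the observed classes.
    """
    f_obs = hist.frequencies
    jmax = len(f_obs) - 1
    if jmax == 0:
        # degenerate: all pairs identical
        return MismatchFit(tau=0.0, theta0=0.0, theta1=0.0, SSD=0.0, n=n, boundary=True)

    m = hist.mean
    bounds = [(0.0, max(4.0 * (jmax + 1), 10.0)), (0.0, 100.0), (0.0, theta1_max)]

    def objective(x: np.ndarray) -> float:
        tau, th0, th1 = (
            min(max(v, lo), hi) for v, (lo, hi) in zip(x, bounds)
        )
        return ssd(f_obs, expected_mismatch(jmax, tau, th0, th1))

    starts = [
        [max(m, 1e-3), 0.1, min(100.0, theta1_max)],
        [max(0.5 * m, 1e-3), 1.0, min(100.0, theta1_max)],
        [max(1.5 * m, 1e-3), 0.1, min(1000.0, theta1_max)],
        [max(m, 1e-3), 0.01, theta1_max],
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish from the best basin
    res = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-14},
    )
    if res.fun < best.fun:
        best = res
    clipped = np.array(
        [min(max(v, lo), hi) for v, (lo, hi) in zip(best.x, bounds)]
    )
    best_x = clipped
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("sudden-expansion fit failed to converge")
    tau, th0, th1 = best_x
    boundary = bool(tau <= 1e-9 or th1 <= 1e-9)
    return MismatchFit(
        tau=float(tau), theta0=float(th0), theta1=float(th1),
        SSD=float(best.fun), n=n, boundary=boundary,
    )


def ssd_bootstrap(
    fit: MismatchFit,
    n: int,
    L: int,
    n_boot: int = 1000,
    seed: int | None = None,
    site_policy: SitePolicy = "complete_deletion",
) -> MismatchFit:
    """Parametric bootstrap p-value for the SSD goodness-of-fit statistic.

    Coalescent samples are simulated under the fitted expansion, each is
    refit with the same optimizer settings, and
    p = (1 + #{SSD* >= SSD_obs}) / (n_boot + 1).  Large p (> 0.05) means
    the sudden-expansion model is not rejected.
    """
    import warnings

    from .synth import simulate_expansion_sample

    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value", stacklevel=2)
    if fit.SSD == 0.0:
        return MismatchFit(
            tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1, SSD=fit.SSD,
            n=fit.n, boundary=fit.boundary, p_ssd=1.0, n_boot=n_boot,
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        aln = simulate_expansion_sample(
            theta0=fit.theta0, theta1=fit.theta1, tau=fit.tau,
            n=n, L=L, seed=rep_seed,
        )
        hist = mismatch_histogram(aln, site_policy)
        rep_fit = fit_sudden_expansion(hist, n)
        if rep_fit.SSD >= fit.SSD:
            exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    return MismatchFit(
        tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1, SSD=fit.SSD,
        n=fit.n, boundary=fit.boundary, p_ssd=p, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# unit conversions


def generation_time(a: float, s: float) -> float:
    """Generation time T = a + s/(1-s) in years, from age at maturity ``a``
    (years) and adult annual survival ``s``."""
    if not 0.0 <= s < 1.0:
        raise ValueError("survival must satisfy 0 <= s < 1")
    if a <= 0:
        raise ValueError("age at maturity must be positive")
    return a + s / (1.0 - s)


@dataclass(frozen=True)
class DemogScaling:
    """Life-history and mutation-rate inputs for demographic conversions.

    ``rates`` are per-site per-*year* substitution rates by locus and
    ``lengths`` the locus lengths in bp.
    """

    a: float
    s: float
    rates: Mapping[str, float]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.rates) != set(self.lengths):
            raise ValueError("rates and lengths must cover the same loci")
        if not self.rates:
            raise ValueError("at least one locus required")

    @property
    def T(self) -> float:
        return generation_time(self.a, self.s)

    def locus_rate_per_year(self, aggregation: str = "arithmetic") -> float:
        """Per-locus per-year mutation rate U, aggregated across loci
        (arithmetic mean default; geometric optional)."""
        per_locus = np.array(
            [self.rates[k] * self.lengths[k] for k in sorted(self.rates)]
        )
        if aggregation == "arithmetic":
            return float(per_locus.mean())
        if aggregation == "geometric":
            return float(np.exp(np.log(per_locus).mean()))
        raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass(frozen=True)
class ImaConversion:
    """Mutation-scaled IM parameters and their demographic conversions.

    Model scale: population sizes q = 4 N u_gen, time B = t u_year,
    migration m (rate per mutation).  Conversions: t_years = B / U,
    N = q / (4 u_gen x inheritance_scalar), Nm = (q/4) m.
    """

    q_a: float
    q_1: float
    q_2: float
    B: float
    m_12: float
    m_21: float
    N_a: float
    N_1: float
    N_2: float
    t_years: float
    Nm_12: float
    Nm_21: float
    aggregation: str
    inheritance_scalar: float
    U_per_year: float
    u_per_generation: float


def convert_ima(
    q_a: float,
    q_1: float,
    q_2: float,
    B: float,
    m_12: float,
    m_21: float,
    scaling: DemogScaling,
    aggregation: str = "arithmetic",
    inheritance_scalar: float = 1.0,
) -> ImaConversion:
    """Convert mutation-scaled IM estimates to demographic units.

    All conversions are linear in the input parameter: t_years = B / U
    with the per-locus per-year rate U aggregated across loci;
    N = q / (4 U T scalar) with T the generation time; Nm = (q/4) m.
    The aggregation used is recorded in the output.
    """
    if B < 0 or min(q_a, q_1, q_2) < 0 or min(m_12, m_21) < 0:
        raise ValueError("IM parameters must be non-negative")
    U = scaling.locus_rate_per_year(aggregation)
    u_gen = U * scaling.T
    return ImaConversion(
        q_a=q_a, q_1=q_1, q_2=q_2, B=B, m_12=m_12, m_21=m_21,
        N_a=q_a / (4.0 * u_gen * inheritance_scalar),
        N_1=q_1 / (4.0 * u_gen * inheritance_scalar),
        N_2=q_2 / (4.0 * u_gen * inheritance_scalar),
        t_years=B / U,
        Nm_12=(q_1 / 4.0) * m_12,
        Nm_21=(q_2 / 4.0) * m_21,
        aggregation=aggregation,
        inheritance_scalar=inheritance_scalar,
        U_per_year=U,
        u_per_generation=u_gen,
    )
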