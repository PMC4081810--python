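"""Diversity, neutrality, AMOVA and rank-test statistics against
independent oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popdiv.popstats import (
    amova,
    between_pop_distance,
    fus_fs,
    gene_diversity,
    kruskal_wallis,
    neutrality,
    nucleotide_diversity,
    pairwise_phi_st,
    tajimas_d,
)
from popdiv.seqio import Alignment, DistanceMatrix, SampleMeta

from conftest import make_alignment


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately independent of the implementation)


def brute_tajima_d(seqs: list[str]) -> float:
    """Tajima's D via per-site pair counting and directly summed constants."""
    n = len(seqs)
    L = len(seqs[0])
    # mean pairwise differences, accumulated site by site
    total = 0
    for site in range(L):
        col = [s[site] for s in seqs]
        for a, b in itertools.combinations(col, 2):
            total += a != b
    k_mean = total / math.comb(n, 2)
    S = sum(len({s[site] for s in seqs}) > 1 for site in range(L))
    if S == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_mean - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_fus_fs(seqs: list[str]) -> float:
    """Fu's Fs via exact-rational Ewens summation over K >= k_obs."""
    n = len(seqs)
    k_obs = len(set(seqs))
    if k_obs == 1:
        return float("nan")
    total = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(x != y for x, y in zip(a, b))
    theta = Fraction(total, math.comb(n, 2))
    if theta == 0:
        return float("nan")
    # unsigned Stirling numbers of the first kind, exact integers
    stirling = {(0, 0): 1}
    for m in range(1, n + 1):
        for k in range(0, m + 1):
            stirling[(m, k)] = stirling.get((m - 1, k - 1), 0) + (m - 1) * stirling.get(
                (m - 1, k), 0
            )
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    probs = [Fraction(stirling[(n, k)]) * theta**k / rising for k in range(n + 1)]
    s_prime = sum(probs[k_obs:])
    if s_prime in (0, 1):
        return float("nan")
    return math.log(float(s_prime)) - math.log(float(1 - s_prime))


def random_small_alignments(seed: int, count: int) -> list[list[str]]:
    """Alignments with n <= 6 and few variable sites (S <= 5)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < count:
        n = int(rng.integers(4, 7))
        n_var = int(rng.integers(1, 6))
        L = 20
        base = rng.choice(list("ACGT"), L)
        seqs = np.tile(base, (n, 1))
        cols = rng.choice(L, n_var, replace=False)
        for c in cols:
            alt = rng.choice([b for b in "ACGT" if b != base[c]])
            carriers = rng.choice(n, int(rng.integers(1, n)), replace=False)
            seqs[carriers, c] = alt
        joined = ["".join(r) for r in seqs]
        S = sum(len({s[i] for s in joined}) > 1 for i in range(L))
        if 1 <= S <= 5:
            out.append(joined)
    return out


# ---------------------------------------------------------------------------
# diversity


class TestGeneDiversity:
    def test_two_equal_haplotypes(self):
        h, sd = gene_diversity([2, 2])
        assert h == pytest.approx(4 / 3 * 0.5)
        assert sd > 0

    def test_single_haplotype_zero(self):
        h, sd = gene_diversity([5])
        assert h == 0
        assert sd == 0

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            gene_diversity([1])

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=8)
    )
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_bounds(self, counts):
        if sum(counts) < 2:
            return
        h, sd = gene_diversity(counts)
        assert 0 <= h <= 1 + 1e-12
        assert sd >= 0


class TestNucleotideDiversity:
    def test_single_pair_hand_count(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])
        pi, _ = nucleotide_diversity(aln)
        assert pi == pytest.approx(0.1)

    def test_identical_zero(self):
        pi, sd = nucleotide_diversity(make_alignment(["ACGT"] * 3))
        assert pi == 0
        assert sd == 0

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(make_alignment(["NN", "NN"]))


class TestBetweenPopDistance:
    def test_hand_computation_no_within_polymorphism(self):
        aln = Alignment("t", ("x", "y"), ("AAAA", "AAAT"))
        meta = [SampleMeta("x", "A"), SampleMeta("y", "B")]
        d = between_pop_distance(aln, meta, "A", "B")
        assert d.dxy == pytest.approx(0.25)
        assert d.da == pytest.approx(0.25)
        assert d.da_percent == pytest.approx(25.0)

    def test_random_split_of_one_population_gives_near_zero_da(self, rng):
        """Splitting one panmictic sample into two groups: the net
        divergence is a small fraction of dxy (zero in expectation)."""
        bases = np.array(list("ACGT"))
        base = rng.choice(bases, 200)
        seqs = []
        for _ in range(20):
            s = base.copy()
            sites = rng.choice(200, 8, replace=False)
            s[sites] = rng.choice(bases, 8)
            seqs.append("".join(s))
        aln = make_alignment(seqs)
        meta = [
            SampleMeta(sid, "A" if i < 10 else "B")
            for i, sid in enumerate(aln.sample_ids)
        ]
        d = between_pop_distance(aln, meta, "A", "B")
        assert abs(d.da) < 0.15 * d.dxy
        assert d.da <= d.dxy

    def test_da_never_exceeds_dxy_random(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seqs = ["".join(rng.choice(bases, 30)) for _ in range(6)]
            aln = make_alignment(seqs)
            meta = [
                SampleMeta(s, "A" if i < 3 else "B")
                for i, s in enumerate(aln.sample_ids)
            ]
            d = between_pop_distance(aln, meta, "A", "B")
            assert d.da <= d.dxy + 1e-12

    def test_empty_population_errors(self, toy_alignment, toy_meta):
        with pytest.raises(ValueError):
            between_pop_distance(toy_alignment, toy_meta, "north", "missing")


# ---------------------------------------------------------------------------
# neutrality


class TestNeutralityOracles:
    def test_tajimas_d_matches_bruteforce(self):
        for seqs in random_small_alignments(seed=11, count=25):
            assert tajimas_d(make_alignment(seqs)) == pytest.approx(
                brute_tajima_d(seqs), abs=1e-10
            )

    def test_fus_fs_matches_exact_rational_summation(self):
        for seqs in random_small_alignments(seed=13, count=25):
            got = fus_fs(make_alignment(seqs))
            want = brute_fus_fs(seqs)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-8)

    def test_monomorphic_undefined(self):
        res = neutrality(make_alignment(["ACGT"] * 5))
        assert res.S == 0
        assert math.isnan(res.D)
        assert math.isnan(res.Fs)

    def test_single_haplotype_fs_undefined(self):
        assert math.isnan(fus_fs(make_alignment(["ACGT"] * 4)))

    def test_fs_explicit_small_case(self):
        """n=4, k=2: S' summed explicitly over K in {2,3,4}."""
        seqs = ["AAAA", "AAAA", "AAAT", "AAAT"]
        # theta_pi = (4 pairs differing once... ) compute directly:
        # pairs: (1,2)=0 (1,3)=1 (1,4)=1 (2,3)=1 (2,4)=1 (3,4)=0 -> 4/6
        theta = Fraction(4, 6)
        stirling = {(4, 1): 6, (4, 2): 11, (4, 3): 6, (4, 4): 1}
        rising = theta * (theta + 1) * (theta + 2) * (theta + 3)
        probs = {
            k: Fraction(v) * theta**k / rising for k, v in
            ((1, 6), (2, 11), (3, 6), (4, 1))
        }
        s_prime = probs[2] + probs[3] + probs[4]
        expected = math.log(float(s_prime) / float(1 - s_prime))
        assert fus_fs(make_alignment(seqs)) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# AMOVA


def toy_distance_matrix() -> DistanceMatrix:
    ids = ("x1", "x2", "y1", "y2")
    d = np.array(
        [
            [0, 2, 10, 10],
            [2, 0, 10, 10],
            [10, 10, 0, 4],
            [10, 10, 4, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(ids=ids, values=d, kind="raw_differences")


class TestAmova:
    def test_hand_computed_decomposition(self):
        """4-sample toy: SS_total=11.5, SS_within=3, sigma_a=3.5, phi=0.7."""
        res = amova(
            toy_distance_matrix(),
            {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"},
            n_perm=99,
            seed=0,
        )
        assert res.ss_within == pytest.approx(3.0)
        assert res.ss_among == pytest.approx(8.5)
        assert res.sigma_within == pytest.approx(1.5)
        assert res.sigma_among == pytest.approx(3.5)
        assert res.phi == pytest.approx(0.7)
        assert res.df_among == 1
        assert res.df_within == 2

    def test_phi_equals_pairwise_phi_st(self):
        dm = toy_distance_matrix()
        labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        res = amova(dm, labels, n_perm=49, seed=1)
        assert pairwise_phi_st(dm, labels) == pytest.approx(res.phi)

    def test_panmictic_split_gives_small_phi_uniform_p(self, rng):
        n = 16
        pts = rng.normal(size=(n, 3))
        d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        dm = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(n)), values=d, kind="raw_differences"
        )
        ps = []
        for seed in range(20):
            labels = ["A"] * (n // 2) + ["B"] * (n // 2)
            rng.shuffle(labels)
            res = amova(dm, labels, n_perm=199, seed=seed)
            ps.append(res.p)
        # p-values roughly uniform: mean near 0.5, not clustered at 0
        assert 0.25 < np.mean(ps) < 0.75

    def test_permutation_p_reproducible_and_bounded(self):
        dm = toy_distance_matrix()
        labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        r1 = amova(dm, labels, n_perm=500, seed=7)
        r2 = amova(dm, labels, n_perm=500, seed=7)
        assert r1.p == r2.p
        assert 1 / 501 <= r1.p <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            amova(toy_distance_matrix(), {"x1": "X", "x2": "X", "y1": "X", "y2": "X"})


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_rank_sum_formula_and_exact_permutation(self):
        """{1,2,3} vs {4,5,6}: H = 3.857..., exact permutation p = 0.1."""
        H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        # no ties: H = 12/(n(n+1)) sum R_g^2/n_g - 3(n+1)
        expected_h = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert H == pytest.approx(expected_h)
        # exhaustive label permutations
        vals = [1, 2, 3, 4, 5, 6]
        hs = []
        for combo in itertools.combinations(range(6), 3):
            g1 = [vals[i] for i in combo]
            g2 = [vals[i] for i in range(6) if i not in combo]
            hs.append(kruskal_wallis([g1, g2])[0])
        exact_p = np.mean([h >= H - 1e-12 for h in hs])
        assert exact_p == pytest.approx(0.1)

    def test_identical_groups(self):
        H, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert H == 0
        assert p == 1

    def test_tie_correction_applied(self):
        H_tied, _ = kruskal_wallis([[1, 1, 2], [3, 3, 4]])
        assert H_tied > 0

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
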