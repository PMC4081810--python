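"""Raster handling, MCP backgrounds, niche PCA and the background
divergence test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from popdiv.niche import (
    Raster,
    RasterStack,
    background_divergence_test,
    extract_climate,
    filter_correlated,
    minimum_convex_polygon,
    pca_niche,
    read_ascii_grid,
    sample_background,
)


def flat_raster(name="flat", value=1.0, g=10):
    return Raster(name=name, data=np.full((g, g), value), xll=0.0, yll=0.0,
                  cellsize=0.1)


def gradient_raster(name="grad", g=10):
    # value = column index: closed-form in lon
    data = np.tile(np.arange(g, dtype=float), (g, 1))
    return Raster(name=name, data=data, xll=0.0, yll=0.0, cellsize=0.1)


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path, rng):
        data = rng.normal(size=(6, 8))
        data[0, 0] = np.nan
        r = Raster("x", data, xll=-10.0, yll=5.0, cellsize=0.25)
        r.write_ascii(tmp_path / "x.asc")
        back = read_ascii_grid(tmp_path / "x.asc")
        assert back.data.shape == (6, 8)
        assert np.isnan(back.data[0, 0])
        assert np.allclose(back.data[1:], data[1:], atol=1e-5)
        assert back.xll == -10.0 and back.cellsize == 0.25

    def test_header_validation(self, tmp_path):
        (tmp_path / "bad.asc").write_text("ncols 2\n1 2\n")
        with pytest.raises(ValueError, match="nrows"):
            read_ascii_grid(tmp_path / "bad.asc")

    def test_stack_requires_identical_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            RasterStack([flat_raster("a"), flat_raster("b", g=12)])


class TestExtractClimate:
    def test_cell_center_value(self):
        stack = RasterStack([gradient_raster()])
        # column 3 spans lon [0.3, 0.4); its center is 0.35
        occ = extract_climate(np.array([[0.35, 0.55]]), stack)
        assert occ.climate.iloc[0, 0] == 3.0

    def test_constant_raster_gives_constant_column(self):
        stack = RasterStack([flat_raster(value=7.5)])
        occ = extract_climate(np.array([[0.15, 0.15], [0.85, 0.85]]), stack)
        assert (occ.climate["flat"] == 7.5).all()

    def test_gradient_closed_form(self, rng):
        stack = RasterStack([gradient_raster()])
        pts = rng.uniform(0.01, 0.99, size=(20, 2))
        occ = extract_climate(pts, stack)
        expected = np.floor(pts[: len(occ.climate), 0] / 0.1)
        assert np.allclose(occ.climate["grad"].to_numpy(), expected)

    def test_all_points_off_grid_error(self):
        stack = RasterStack([flat_raster()])
        with pytest.raises(ValueError, match="off-grid"):
            extract_climate(np.array([[5.0, 5.0]]), stack)

    def test_nodata_rows_dropped_with_count(self):
        data = np.full((10, 10), 2.0)
        data[:, 5:] = np.nan
        stack = RasterStack([Raster("m", data, 0.0, 0.0, 0.1)])
        with pytest.warns(UserWarning, match="dropped 1"):
            occ = extract_climate(np.array([[0.25, 0.5], [0.75, 0.5]]), stack)
        assert occ.n_dropped == 1
        assert len(occ.climate) == 1


class TestFilterCorrelated:
    def test_uncorrelated_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        kept, dropped = filter_correlated(df, 0.8)
        assert kept == list("abcd")
        assert dropped == []

    def test_duplicate_column_pruned_by_priority(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"v1": x, "v2": x + 1e-9 * rng.normal(size=300),
                           "v3": rng.normal(size=300)})
        kept, dropped = filter_correlated(df, 0.8, priority=["v2", "v1", "v3"])
        assert kept == ["v2", "v3"]
        assert dropped[0][0] == "v2" and dropped[0][1] == "v1"
        assert dropped[0][2] > 0.99

    def test_threshold_boundary_is_strict(self):
        # |r| must exceed the threshold to trigger a drop
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        df = pd.DataFrame({"x": x, "y": y})
        r = abs(df.corr().iloc[0, 1])
        kept, _ = filter_correlated(df, threshold=max(r, 0.8))
        assert kept == ["x", "y"]


class TestMinimumConvexPolygon:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        poly = minimum_convex_polygon(pts)
        assert poly.area == pytest.approx(1.0)

    def test_interior_point_ignored(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        poly = minimum_convex_polygon(pts)
        assert poly.area == pytest.approx(1.0)
        assert len(poly.exterior.coords) == 5  # closed ring of 4 vertices

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            minimum_convex_polygon(np.array([[0, 0], [1, 1], [2, 2]]))

    def test_matches_bruteforce_hull(self, rng):
        """Hull area equals the max-area polygon over all point subsets."""
        pts = rng.uniform(size=(10, 2))
        poly = minimum_convex_polygon(pts)
        # brute force: the hull is the triangle-decomposable polygon that
        # contains all points; check containment + vertices are input points
        for p in pts:
            assert poly.buffer(1e-9).contains(Point(p))
        vertices = np.array(poly.exterior.coords)[:-1]
        for v in vertices:
            assert np.min(np.abs(pts - v).sum(axis=1)) < 1e-12
        # no smaller subset polygon contains all the points
        best = 0.0
        for combo in itertools.combinations(range(10), 3):
            tri = Polygon(pts[list(combo)])
            if all(tri.buffer(1e-9).contains(Point(p)) for p in pts):
                best = max(best, tri.area)
        assert poly.area >= best - 1e-12


class TestSampleBackground:
    def test_flat_raster_identical_rows(self):
        stack = RasterStack([flat_raster(value=3.0)])
        poly = Polygon([(0.1, 0.1), (0.9, 0.1), (0.9, 0.9), (0.1, 0.9)])
        bg = sample_background(poly, stack, n=50, seed=1)
        assert len(bg) == 50
        assert (bg["flat"] == 3.0).all()

    def test_seed_reproducible(self):
        stack = RasterStack([gradient_raster()])
        poly = Polygon([(0.1, 0.1), (0.9, 0.1), (0.5, 0.9)])
        a = sample_background(poly, stack, n=40, seed=9)
        b = sample_background(poly, stack, n=40, seed=9)
        assert a.equals(b)

    def test_half_masked_raster_only_valid_half_sampled(self):
        data = np.full((10, 10), 1.0)
        data[:, :5] = np.nan  # west half missing
        stack = RasterStack([Raster("m", data, 0.0, 0.0, 0.1)])
        poly = Polygon([(0.05, 0.05), (0.95, 0.05), (0.95, 0.95), (0.05, 0.95)])
        bg = sample_background(poly, stack, n=30, seed=2)
        assert (bg["m"] == 1.0).all()

    def test_no_valid_area_errors(self):
        data = np.full((10, 10), np.nan)
        stack = RasterStack([Raster("m", data, 0.0, 0.0, 0.1)])
        poly = Polygon([(0.1, 0.1), (0.9, 0.1), (0.5, 0.9)])
        with pytest.raises(RuntimeError):
            sample_background(poly, stack, n=10, seed=3)


class TestPcaNiche:
    def test_perfectly_correlated_pair_single_axis(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": 2 * x + 5})
        axes = pca_niche(df)
        assert axes.variance_explained[0] == pytest.approx(100.0)

    def test_isotropic_cloud_equal_shares(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        axes = pca_niche(df)
        assert np.all(axes.variance_explained < 30)
        assert np.all(axes.variance_explained > 20)

    def test_zero_variance_variable_named(self, rng):
        df = pd.DataFrame({"ok": rng.normal(size=10), "dead": np.ones(10)})
        with pytest.raises(ValueError, match="dead"):
            pca_niche(df)

    def test_scores_zero_mean_orthogonal_loadings(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5)),
                          columns=list("abcde"))
        axes = pca_niche(df)
        scores = axes.transform(df)
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-9)
        gram = axes.loadings.to_numpy().T @ axes.loadings.to_numpy()
        assert np.allclose(gram, np.eye(5), atol=1e-9)

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        l1 = pca_niche(df).loadings.to_numpy()
        # identical call is exactly reproducible; a copied frame may differ
        # at the last bit through BLAS memory alignment
        assert np.array_equal(l1, pca_niche(df).loadings.to_numpy())
        l2 = pca_niche(df.copy()).loadings.to_numpy()
        assert np.allclose(l1, l2, atol=1e-12)
        for col in l1.T:
            assert col[np.argmax(np.abs(col))] > 0


class TestBackgroundDivergenceTest:
    def test_zero_observed_with_positive_background_is_conservatism(self, rng):
        bg_a = rng.normal(0, 1, size=(400, 2))
        bg_b = rng.normal(3, 1, size=(400, 2))  # strong background divergence
        occ = np.zeros((50, 2))
        res = background_divergence_test(occ, occ, bg_a, bg_b, n_jack=300, seed=1)
        assert res.verdict[0] == "conservatism"
        assert res.observed_diff[0] == 0.0
        assert res.background_diff[0] > res.null_lo[0] * 0.5

    def test_large_observed_is_divergence(self, rng):
        bg = rng.normal(0, 1, size=(400, 1))
        occ_a = rng.normal(-3, 0.2, size=(60, 1))
        occ_b = rng.normal(3, 0.2, size=(60, 1))
        res = background_divergence_test(occ_a, occ_b, bg, bg.copy(),
                                         n_jack=300, seed=2)
        assert res.verdict[0] == "divergence"

    def test_seeded_reproducibility(self, rng):
        bg_a = rng.normal(size=(300, 3))
        bg_b = rng.normal(size=(300, 3))
        occ_a = rng.normal(size=(40, 3))
        occ_b = rng.normal(size=(40, 3))
        r1 = background_divergence_test(occ_a, occ_b, bg_a, bg_b, n_jack=200, seed=5)
        r2 = background_divergence_test(occ_a, occ_b, bg_a, bg_b, n_jack=200, seed=5)
        assert np.array_equal(r1.null_lo, r2.null_lo)
        assert r1.verdict == r2.verdict

    def test_null_interval_shrinks_with_background_size(self, rng):
        widths = []
        for n in (200, 1000, 5000):
            bg_a = rng.normal(0, 1, size=(n, 1))
            bg_b = rng.normal(0, 1, size=(n, 1))
            occ = rng.normal(0, 1, size=(30, 1))
            res = background_divergence_test(occ, occ, bg_a, bg_b,
                                             n_jack=400, seed=n)
            widths.append(res.null_hi[0] - res.null_lo[0])
        assert widths[0] > widths[1] > widths[2]

    def test_bootstrap_method_accepted(self, rng):
        bg = rng.normal(size=(200, 2))
        occ = rng.normal(size=(30, 2))
        res = background_divergence_test(occ, occ, bg, bg.copy(), n_jack=150,
                                         seed=3, method="bootstrap")
        assert len(res.verdict) == 2
        with pytest.raises(ValueError):
            background_divergence_test(occ, occ, bg, bg, method="sampling")
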