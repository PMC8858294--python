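"""Depth, bagplot, Spearman, linear fits and PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from prolylkin.stats import (
    PairedObservations,
    bagplot_outliers,
    halfspace_depth,
    linear_fit_ci,
    pca_scores,
    spearman,
)
from prolylkin.stats import _depth_region, _exact_p_no_ties, _spearman_d_distribution


def brute_force_depth(point, cloud, n_angles=3600):
    """Independent oracle: minimize the halfplane count over a dense angular
    grid augmented with the critical directions (normals of point-to-point
    vectors), where the count function actually changes value."""
    diff = np.asarray(cloud) - np.asarray(point)
    nonzero = diff[np.hypot(diff[:, 0], diff[:, 1]) > 1e-12]
    crit = np.arctan2(nonzero[:, 1], nonzero[:, 0]) + np.pi / 2
    angles = np.concatenate(
        [np.linspace(0, 2 * np.pi, n_angles, endpoint=False)]
        + [crit + d for d in (-1e-7, 0.0, 1e-7, np.pi - 1e-7, np.pi, np.pi + 1e-7)]
    )
    best = len(cloud)
    for th in angles:
        u = np.array([np.cos(th), np.sin(th)])
        best = min(best, int(np.sum(diff @ u >= -1e-12)))
    return best


class TestHalfspaceDepth:
    def test_centre_of_symmetric_cross(self):
        cloud = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        assert halfspace_depth([0.0, 0.0], cloud) == 2

    def test_hull_vertex_has_depth_one(self):
        cloud = np.array([[0, 0], [4, 0], [0, 4], [1, 1]], dtype=float)
        assert halfspace_depth([4.0, 0.0], cloud) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_angular_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cloud = rng.normal(size=(12, 2))
        for p in cloud:
            assert halfspace_depth(p, cloud) == brute_force_depth(p, cloud)

    def test_collinear_cloud_no_crash(self):
        cloud = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert halfspace_depth([2.0, 2.0], cloud) == 3

    def test_depth_region_consistent_with_pointwise_depth(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(11, 2))
        for k in (1, 2, 3):
            poly = _depth_region(pts, k)
            for _ in range(120):
                z = rng.uniform(-2.5, 2.5, 2)
                def cross2(u, v):
                    return u[0] * v[1] - u[1] * v[0]

                inside = False
                if len(poly) >= 3:
                    c = poly.mean(axis=0)
                    inside = all(
                        cross2(poly[(i + 1) % len(poly)] - poly[i], z - poly[i])
                        * cross2(poly[(i + 1) % len(poly)] - poly[i], c - poly[i])
                        >= -1e-7
                        for i in range(len(poly))
                    )
                assert inside == (halfspace_depth(z, pts) >= k)


class TestBagplot:
    def test_gross_outlier_flagged_alone(self):
        """A compact lattice cluster plus one point tens of IQR-scales away
        flags exactly that point."""
        grid = np.array(
            [(i, j) for i in range(4) for j in range(3)][:11], dtype=float
        )
        x = np.append(grid[:, 0], 30.0)
        y = np.append(grid[:, 1], -30.0)
        labels = tuple(f"p{i}" for i in range(12))
        res = bagplot_outliers(PairedObservations(labels, x, y))
        assert res.outlier_labels == ("p11",)

    def test_gross_outlier_always_caught_in_random_clusters(self):
        """Across random tight clusters the distant point is never missed."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            th = rng.uniform(0, 2 * np.pi, 11)
            r = np.sqrt(rng.uniform(0, 1, 11))
            x = np.append(r * np.cos(th), 30.0)
            y = np.append(r * np.sin(th), -30.0)
            labels = tuple(f"p{i}" for i in range(12))
            res = bagplot_outliers(PairedObservations(labels, x, y))
            assert "p11" in res.outlier_labels

    def test_round_clouds_flag_only_extreme_points_and_rarely(self):
        """On plain Gaussian clouds flags are rare and confined to points in
        the far tail of the standardized radius distribution."""
        total = 0
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            pts = rng.normal(size=(40, 2))
            res = bagplot_outliers(
                PairedObservations(tuple(map(str, range(40))), pts[:, 0], pts[:, 1])
            )
            total += len(res.outlier_labels)
            z = (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1)
            radii = np.hypot(z[:, 0], z[:, 1])
            for label in res.outlier_labels:
                assert radii[int(label)] > 2.0
        assert total <= 15  # on average well below one flag per cloud

    def test_requires_five_points(self):
        obs = PairedObservations(("a", "b", "c", "d"), np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError, match="n >= 5"):
            bagplot_outliers(obs)

    def test_flags_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 15)
        y = 2 * x + rng.normal(0, 0.5, 15)
        x[0], y[0] = 8.0, -8.0
        labels = tuple(map(str, range(15)))
        base = bagplot_outliers(PairedObservations(labels, x, y), standardize=False)
        scaled = bagplot_outliers(
            PairedObservations(labels, 1000.0 * x + 7.0, 0.01 * y - 3.0),
            standardize=False,
        )
        standardized = bagplot_outliers(PairedObservations(labels, x, y), standardize=True)
        assert base.outlier_labels == scaled.outlier_labels == standardized.outlier_labels

    def test_variant_table_outliers(self, variant_table):
        """The binding/activity table reproduces the published outlier
        pattern: W4E alone for the K_D-K_D comparison, Y3A alone for the
        K_D-activity comparison."""
        kd = PairedObservations.from_frame(variant_table, "kd_fkbp_uM", "kd_dif_uM")
        assert bagplot_outliers(kd).outlier_labels == ("W4E",)
        act = PairedObservations.from_frame(
            variant_table, "kd_dif_uM", "activity_dif_per_uM_s"
        )
        assert bagplot_outliers(act).outlier_labels == ("Y3A",)


class TestSpearman:
    def test_perfect_monotone(self):
        obs = PairedObservations(
            tuple("abcdef"), np.arange(6.0), np.exp(np.arange(6.0))
        )
        res = spearman(obs)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2.0 / math.factorial(6))

    def test_exact_distribution_matches_enumeration(self):
        """The DP null distribution of D equals full enumeration for n <= 7."""
        for n in (4, 5, 6, 7):
            dist = _spearman_d_distribution(n)
            counts = np.zeros_like(dist)
            base = np.arange(n)
            for perm in itertools.permutations(range(n)):
                counts[int(np.sum((base - np.array(perm)) ** 2))] += 1
            np.testing.assert_array_equal(dist, counts)
            assert dist.sum() == math.factorial(n)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        x, y = rng.normal(size=n), rng.normal(size=n)
        from scipy.stats import rankdata

        rx, ry = rankdata(x).astype(int), rankdata(y).astype(int)
        p_dp = _exact_p_no_ties(rx, ry)
        rho_obs = spearmanr(x, y).statistic
        count = sum(
            1
            for perm in itertools.permutations(range(n))
            if abs(spearmanr(x, y[list(perm)]).statistic) >= abs(rho_obs) - 1e-12
        )
        assert p_dp == pytest.approx(count / math.factorial(n), abs=1e-12)

    def test_midrank_ties_match_scipy_rho(self):
        obs = PairedObservations(
            tuple("abcdefg"),
            np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0]),
            np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0]),
        )
        res = spearman(obs)
        assert res.rho == pytest.approx(spearmanr(obs.x, obs.y).statistic)
        assert res.p_method == "exact"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        labels = tuple(map(str, range(8)))
        a = spearman(PairedObservations(labels, x, y))
        b = spearman(PairedObservations(labels, np.exp(x), y**3))
        assert a.rho == pytest.approx(b.rho)
        assert a.p_value == pytest.approx(b.p_value)

    def test_constant_input_raises(self):
        obs = PairedObservations(tuple("abcde"), np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            spearman(obs)

    def test_exclusions_and_missing_values_dropped(self, variant_table):
        obs = PairedObservations.from_frame(
            variant_table, "kd_dif_uM", "activity_dif_per_uM_s"
        )
        res = spearman(obs, exclude=("Y3A",))
        # R2A (missing K_D) and G14M/A15L (missing activity) drop out
        assert res.n_used == 8
        assert res.excluded_labels == ("Y3A",)

    def test_too_few_pairs_raise(self):
        obs = PairedObservations(tuple("abc"), np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError, match=">= 4"):
            spearman(obs)


class TestLinearFit:
    def test_exact_line(self):
        obs = PairedObservations(
            tuple("abcde"), np.arange(5.0), 2.0 * np.arange(5.0) + 1.0
        )
        fit = linear_fit_ci(obs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        mean, lo, hi = fit.band(np.array([0.0, 2.0, 10.0]))
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-8)

    def test_duplicated_x_still_fits(self):
        obs = PairedObservations(
            tuple("abcd"), np.array([1.0, 1.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0, 5.0])
        )
        fit = linear_fit_ci(obs)
        assert np.isfinite(fit.slope)
        _, lo, hi = fit.band(np.array([1.5]))
        assert hi[0] > lo[0]

    def test_through_origin(self):
        obs = PairedObservations(
            tuple("abcd"), np.arange(1.0, 5.0), 3.0 * np.arange(1.0, 5.0)
        )
        fit = linear_fit_ci(obs, through_origin=True)
        assert fit.slope == pytest.approx(3.0)
        assert np.isnan(fit.intercept)

    def test_rank_deficient_raises(self):
        obs = PairedObservations(tuple("abcd"), np.ones(4), np.arange(4.0))
        with pytest.raises(ValueError, match="rank-deficient"):
            linear_fit_ci(obs)

    def test_confidence_band_coverage(self):
        """The 95% slope interval covers the true slope in roughly 95% of
        simulated replicates."""
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(7)
        n, true_slope = 12, 3.0
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.uniform(0, 5, n)
            y = true_slope * x + 1.0 + rng.normal(0, 1.0, n)
            fit = linear_fit_ci(PairedObservations(tuple(map(str, range(n))), x, y))
            tcrit = t_dist.ppf(0.975, n - 2)
            if abs(fit.slope - true_slope) <= tcrit * fit.slope_se:
                hits += 1
        assert 0.92 <= hits / reps <= 0.98


class TestPCA:
    def test_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"a": x, "b": 3.0 * x + 2.0})
        res = pca_scores(table)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthogonal_noise_splits_variance(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        res = pca_scores(table)
        assert res.explained_variance_ratio[0] < 0.6

    def test_duplicate_rows_get_identical_scores(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(6, 3))
        table = pd.DataFrame(np.vstack([base, base[0]]), columns=list("abc"))
        res = pca_scores(table)
        np.testing.assert_allclose(
            res.scores.iloc[0].to_numpy(), res.scores.iloc[-1].to_numpy(), atol=1e-10
        )

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = pca_scores(table)
        for comp in res.loadings.columns:
            col = res.loadings[comp].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_incomplete_rows_dropped_and_limits_enforced(self):
        table = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError):
            pca_scores(table, n_components=2)
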