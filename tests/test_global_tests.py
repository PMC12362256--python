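import numpy as np
import pandas as pd
import pytest

from catmicro import (
    OutcomeSpec,
    build_design,
    euclidean,
    gower_center,
    max_over_metrics,
    mirkat_null_fit,
    mirkat_q,
    partial_r2,
    pcoa,
    permanova_pvalue,
    permanova_r2,
)
from catmicro.distances import DistanceMatrix, bray_curtis, jaccard, unifrac_weighted
from catmicro.global_tests import GowerMatrix


def classical_anova_r2(y, labels):
    """Independent one-way ANOVA oracle: 1 - SSW/SST from group means."""
    y = np.asarray(y, dtype=float)
    sst = np.sum((y - y.mean()) ** 2)
    ssw = sum(
        np.sum((y[labels == g] - y[labels == g].mean()) ** 2) for g in np.unique(labels)
    )
    return 1 - ssw / sst


class TestGower:
    def test_zero_distance_gives_zero_g(self):
        g = gower_center(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        np.testing.assert_allclose(g.values, 0)

    def test_two_sample_closed_form(self):
        d = 3.0
        g = gower_center(DistanceMatrix(["a", "b"], np.array([[0, d], [d, 0]])))
        expected = np.array([[d**2 / 4, -(d**2) / 4], [-(d**2) / 4, d**2 / 4]])
        np.testing.assert_allclose(g.values, expected)
        assert np.trace(g.values) == pytest.approx(d**2 / 2)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(7, 3))
        g = gower_center(euclidean(x))
        np.testing.assert_allclose(g.values.sum(axis=0), 0, atol=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            gower_center(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestDesign:
    def test_binary_groups_reference_coded(self):
        x = build_design(np.array(["A", "A", "B", "B"]))
        np.testing.assert_allclose(x, [[1, 0], [1, 0], [1, 1], [1, 1]])

    def test_three_level_factor(self):
        x = build_design(np.array(["a", "b", "c", "a"]))
        assert x.shape == (4, 3)

    def test_duplicate_covariate_dropped_with_warning(self):
        cov = pd.DataFrame({"u1": [1.0, 2, 3, 4], "u2": [2.0, 4, 6, 8]})
        with pytest.warns(UserWarning, match="dependent"):
            x = build_design(np.array([0, 0, 1, 1]), covariates=cov)
        assert x.shape[1] == 3  # intercept, u1, outcome

    def test_constant_grouping_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_design(np.array(["A", "A", "A"]))


class TestPermanovaR2:
    def test_perfect_separation(self):
        d = euclidean(np.array([0.0, 0.0, 1.0, 1.0]))
        g = gower_center(d)
        x = build_design(np.array(["A", "A", "B", "B"]))
        assert permanova_r2(g, x).r2 == pytest.approx(1.0)

    def test_hand_worked_anova(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        g = gower_center(euclidean(y))
        dec = permanova_r2(g, build_design(np.array(["A", "A", "B", "B"])))
        assert dec.ss_total == pytest.approx(5.0)
        assert dec.ss_among == pytest.approx(4.0)
        assert dec.r2 == pytest.approx(0.8)

    def test_intercept_only_model_explains_nothing(self):
        rng = np.random.default_rng(1)
        g = gower_center(euclidean(rng.normal(size=10)))
        dec = permanova_r2(g, np.ones((10, 1)))
        assert dec.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_classical_anova_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(6, 15)
            y = rng.normal(size=n)
            labels = rng.integers(0, 3, size=n)
            if len(np.unique(labels)) < 2:
                continue
            g = gower_center(euclidean(y))
            r2 = permanova_r2(g, build_design(labels.astype(str))).r2
            assert r2 == pytest.approx(classical_anova_r2(y, labels), abs=1e-10)

    @pytest.mark.parametrize("metric", [bray_curtis, jaccard])
    def test_decomposition_identity(self, metric):
        rng = np.random.default_rng(3)
        from catmicro import CountTable

        counts = rng.poisson(2, size=(8, 5))
        counts[:, 0] += 1  # keep sample totals positive but supports varied
        t = CountTable([f"s{i}" for i in range(8)], [f"f{j}" for j in range(5)], counts)
        g = gower_center(metric(t))
        dec = permanova_r2(g, build_design(rng.integers(0, 2, 8)))
        assert dec.ss_among + dec.ss_residual == pytest.approx(dec.ss_total, abs=1e-8)


class TestPartialR2:
    def test_reduced_intercept_equals_full_r2(self):
        rng = np.random.default_rng(2)
        g = gower_center(euclidean(rng.normal(size=8)))
        x = build_design(rng.integers(0, 2, 8))
        assert partial_r2(g, x, np.ones((8, 1))) == pytest.approx(
            permanova_r2(g, x).r2
        )

    def test_full_equals_reduced_gives_zero(self):
        rng = np.random.default_rng(2)
        g = gower_center(euclidean(rng.normal(size=8)))
        x = build_design(rng.integers(0, 2, 8))
        assert partial_r2(g, x, x) == pytest.approx(0.0, abs=1e-12)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        g = gower_center(euclidean(rng.normal(size=8)))
        x1 = build_design(rng.integers(0, 2, 8))
        x2 = build_design(rng.normal(size=8))
        with pytest.raises(ValueError, match="nested"):
            partial_r2(g, x1, x2)


class TestPermanovaPvalue:
    def test_single_group_rejected(self):
        d = euclidean(np.arange(6.0))
        with pytest.raises(ValueError):
            permanova_pvalue(d, np.array(["A"] * 6), n_perm=9)

    def test_strong_separation_attains_minimum(self):
        d = euclidean(np.array([0.0, 0.01, 0.02, 5.0, 5.01, 5.02]))
        res = permanova_pvalue(
            d, np.array(["A", "A", "A", "B", "B", "B"]), n_perm=99, rng=0
        )
        # only label swaps preserving the partition can tie the observed F
        assert res["p_value"] <= (1 + 9) / 100

    def test_type_i_error_calibration(self):
        """Rejection rate at alpha=0.05 within the binomial band when the
        outcome is independent of the distances."""
        rng = np.random.default_rng(12)
        n_datasets, rejections = 200, 0
        for _ in range(n_datasets):
            y = rng.normal(size=12)
            labels = np.repeat([0, 1], 6)
            res = permanova_pvalue(euclidean(y), labels, n_perm=99, rng=rng)
            rejections += res["p_value"] < 0.05
        rate = rejections / n_datasets
        se = np.sqrt(0.05 * 0.95 / n_datasets)
        assert abs(rate - 0.05) < 3 * se


class TestMirkat:
    def test_continuous_null_fit_no_covariates(self):
        y = OutcomeSpec("continuous", np.array([1.0, 2.0, 3.0, 6.0]))
        r, phi = mirkat_null_fit(y)
        np.testing.assert_allclose(r, y.values - y.values.mean(), atol=1e-12)
        assert phi == pytest.approx(np.sum(r**2) / 3)

    def test_binary_null_fit_no_covariates(self):
        y = OutcomeSpec("binary", np.array([1.0, 0.0, 1.0, 1.0]))
        r, phi = mirkat_null_fit(y)
        np.testing.assert_allclose(r, y.values - 0.75, atol=1e-8)
        assert phi == 1.0

    def test_martingale_residuals_sum_to_zero(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(1.0, size=12)
        y = OutcomeSpec("survival", times, event=np.ones(12, dtype=int))
        r, phi = mirkat_null_fit(y)
        assert phi == 1.0
        assert np.sum(r) == pytest.approx(0.0, abs=1e-8)

    def test_cox_null_fit_with_covariates_runs(self):
        rng = np.random.default_rng(5)
        n = 30
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        times = rng.exponential(1.0, size=n)
        event = (rng.random(n) < 0.8).astype(int)
        y = OutcomeSpec("survival", times, event=event, covariates=cov)
        r, _ = mirkat_null_fit(y)
        assert len(r) == n and np.all(np.isfinite(r))

    def test_quadratic_form_brute_force(self):
        """q matches an explicit elementwise expansion of r'Gr."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            r = rng.normal(size=n)
            g = gower_center(euclidean(rng.normal(size=n))).values
            phi = float(rng.uniform(0.5, 2.0))
            expected = sum(
                r[i] * g[i, j] * r[j] for i in range(n) for j in range(n)
            ) / (2 * phi)
            assert mirkat_q(r, phi, g).q == pytest.approx(expected, abs=1e-10)

    def test_r2_kernel_homogeneity_and_scale_invariance(self):
        rng = np.random.default_rng(10)
        r = rng.normal(size=6)
        d = euclidean(rng.normal(size=6))
        g = gower_center(d)
        score = mirkat_q(r, 1.0, g)
        doubled = mirkat_q(2 * r, 1.0, g)
        assert doubled.r2_kernel == pytest.approx(score.r2_kernel)
        assert doubled.q == pytest.approx(4 * score.q)
        # scaling all distances by c leaves r2_kernel unchanged
        g_scaled = gower_center(DistanceMatrix(d.sample_ids, 3.0 * d.values))
        assert mirkat_q(r, 1.0, g_scaled).r2_kernel == pytest.approx(score.r2_kernel)

    def test_zero_residuals_give_zero_q(self):
        g = gower_center(euclidean(np.arange(4.0)))
        score = mirkat_q(np.zeros(4), 1.0, g)
        assert score.q == 0.0


class TestMaxOverMetrics:
    def test_basic(self):
        assert max_over_metrics([0.1]) == 0.1
        assert max_over_metrics([0.1, 0.3, 0.2]) == 0.3
        assert max_over_metrics([0.2, 0.2]) == 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_over_metrics([])


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 2))
        g = gower_center(euclidean(pts))
        res = pcoa(g, k=2)
        d_rec = np.linalg.norm(
            res.coordinates[:, None, :] - res.coordinates[None, :, :], axis=2
        )
        d_orig = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.testing.assert_allclose(d_rec, d_orig, atol=1e-8)

    def test_two_samples_half_distance(self):
        g = gower_center(DistanceMatrix(["a", "b"], np.array([[0, 4.0], [4.0, 0]])))
        res = pcoa(g, k=1)
        np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), [2.0, 2.0])

    def test_zero_distances_zero_coordinates(self):
        g = GowerMatrix(np.zeros((3, 3)))
        res = pcoa(g, k=2)
        assert np.allclose(res.coordinates, 0)

    def test_k_bounds(self):
        g = GowerMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pcoa(g, k=0)
        with pytest.raises(ValueError):
            pcoa(g, k=3)
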