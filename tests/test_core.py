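import itertools
import math

import numpy as np
import pytest

from mra.core import (allometry_coefficients, allometry_ratio_spectrum,
                      pca_ratio_spectrum, shape_decompose, shape_pca,
                      size_shape_scatter, variance_explained)
from mra.synthetic import GroupSpec, SyntheticConfig, simulate_measurements

from conftest import make_table


def _isometric_config(p=6, n=80, seed=0, sigma_size=0.1, sigma_noise=0.02):
    chars = [f"v{k}" for k in range(p)]
    return SyntheticConfig(chars, [GroupSpec("g", n, np.zeros(p))],
                           sigma_size, np.zeros(p), sigma_noise, seed=seed)


class TestShapeDecompose:
    def test_hand_computed_two_variable_specimen(self):
        t = make_table([[100.0, 400.0]], ["a", "b"])
        st = shape_decompose(t)
        assert st.isosize.iloc[0] == pytest.approx(math.log(200), abs=1e-12)
        assert st.shape.iloc[0].to_numpy() == pytest.approx(
            [-0.6931471805599453, 0.6931471805599453], abs=1e-12)

    def test_equal_measurements_give_zero_shape(self):
        st = shape_decompose(make_table([[250.0] * 5], list("abcde")))
        assert np.allclose(st.shape.to_numpy(), 0.0)

    def test_doubling_shifts_isosize_not_shape(self):
        vals = np.array([[100.0, 150.0, 320.0]])
        st1 = shape_decompose(make_table(vals, ["a", "b", "c"]))
        st2 = shape_decompose(make_table(2 * vals, ["a", "b", "c"]))
        assert st2.isosize.iloc[0] - st1.isosize.iloc[0] == pytest.approx(
            math.log(2), abs=1e-12)
        assert np.abs(st2.shape.to_numpy() - st1.shape.to_numpy()).max() < 1e-9

    def test_rows_sum_to_zero(self, demo_table):
        _, table, _ = demo_table
        from mra.measurement_data import impute_missing
        table, _ = impute_missing(table, seed=0)
        st = shape_decompose(table)
        assert np.abs(st.shape.sum(axis=1)).max() < 1e-9

    def test_missing_cells_direct_to_imputation(self):
        t = make_table([[100.0, np.nan], [1.0, 2.0]], ["a", "b"])
        with pytest.raises(ValueError, match="impute"):
            shape_decompose(t)


class TestShapePCA:
    def test_proportional_specimens_have_no_shape_variance(self):
        base = np.array([100.0, 150.0, 320.0, 80.0])
        vals = np.vstack([c * base for c in (1.0, 1.3, 0.8, 2.0)])
        res = shape_pca(shape_decompose(make_table(vals, list("abcd"))))
        assert np.all(res.eigenvalues < 1e-18)

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(2)
        p = 6
        direction = np.array([3.0, -1.0, -1.0, 2.0, -2.0, -1.0])
        direction /= np.linalg.norm(direction)
        scores = rng.normal(0, 0.2, 200)
        shape = np.outer(scores, direction) + rng.normal(0, 1e-4, (200, p))
        shape -= shape.mean(axis=1, keepdims=True)
        vals = np.exp(6.0 + shape)
        res = shape_pca(shape_decompose(make_table(vals, list("abcdef"))))
        assert res.variance_fraction[0] > 0.99
        angle = math.degrees(math.acos(
            min(1.0, abs(res.loadings.iloc[0] @ direction))))
        assert angle < 1.0

    def test_loadings_orthogonal_to_ones_and_scores_consistent(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        res = shape_pca(st)
        ones = np.ones(len(st.columns))
        assert np.abs(res.loadings.to_numpy() @ ones).max() < 1e-9
        recomputed = st.shape.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recomputed - res.scores.to_numpy()).max() < 1e-9

    def test_trace_conservation(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        res = shape_pca(st)
        total = np.trace(np.cov(st.shape.to_numpy(), rowvar=False, ddof=1))
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-9)

    def test_brute_force_oracle_small_cases(self):
        # independent oracle: explicitly project the log data onto an
        # orthonormal basis of the sum-zero subspace and eigendecompose there
        rng = np.random.default_rng(7)
        for p, n in [(3, 5), (4, 6), (2, 4)]:
            vals = np.exp(rng.normal(6, 0.2, (n, p)))
            st = shape_decompose(make_table(
                vals, [f"v{k}" for k in range(p)],
                ids=[f"s{i}" for i in range(n)]))
            res = shape_pca(st)
            # Helmert-style basis of the hyperplane orthogonal to ones
            basis = np.linalg.svd(np.eye(p) - np.ones((p, p)) / p)[0][:, :p - 1]
            proj = st.shape.to_numpy() @ basis
            C = np.atleast_2d(np.cov(proj, rowvar=False, ddof=1))
            evals = np.sort(np.linalg.eigvalsh(C))[::-1]
            assert np.abs(res.eigenvalues - evals).max() < 1e-8

    def test_too_few_specimens(self):
        t = make_table([[1.0, 2.0], [2.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="3 specimens"):
            shape_pca(shape_decompose(t))


class TestVarianceExplained:
    def test_full_rank_sums_to_one(self, planted_table):
        _, table, _ = planted_table
        res = shape_pca(shape_decompose(table))
        p = len(table.columns)
        assert variance_explained(res, p - 1) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_k(self, planted_table):
        _, table, _ = planted_table
        res = shape_pca(shape_decompose(table))
        with pytest.raises(ValueError):
            variance_explained(res, 0)
        with pytest.raises(ValueError):
            variance_explained(res, len(table.columns))


class TestAllometry:
    def test_isometric_null_has_small_coefficients(self):
        table, _ = simulate_measurements(_isometric_config(n=300, seed=4))
        st = shape_decompose(table)
        b = allometry_coefficients(st)
        # slope SE under the generator: sigma_noise/(sqrt(n)*sigma_size)
        se = 0.02 / (math.sqrt(300) * 0.1)
        assert np.abs(b.to_numpy()).max() < 3 * se * 2  # small-sample slack

    def test_planted_allometry_recovered(self):
        p = 6
        a = 0.2 * np.sin(2 * np.pi * np.arange(p) / p)
        a -= a.mean()
        cfg = SyntheticConfig([f"v{k}" for k in range(p)],
                              [GroupSpec("g", 400, np.zeros(p))],
                              0.12, a, 0.02, seed=8)
        table, _ = simulate_measurements(cfg)
        st = shape_decompose(table)
        b = allometry_coefficients(st).to_numpy()
        # slope SE under the generator: sigma_noise*sqrt(1-1/p)/(sqrt(n)*sigma_size)
        se = 0.02 * math.sqrt(1 - 1 / p) / (math.sqrt(400) * 0.12)
        assert np.abs(b - a).max() < 5 * se

    def test_sum_zero_and_permutation_invariance(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        b = allometry_coefficients(st)
        assert abs(b.sum()) < 1e-9
        perm = np.random.default_rng(0).permutation(table.n_specimens)
        shuffled = make_table(table.values.to_numpy()[perm], table.columns,
                              groups=table.group.to_numpy()[perm],
                              ids=[table.specimen_ids[i] for i in perm])
        b2 = allometry_coefficients(shape_decompose(shuffled))
        assert np.abs(b.to_numpy() - b2.to_numpy()).max() < 1e-12

    def test_zero_size_variance_errors(self):
        vals = np.vstack([[100.0, 200.0, 400.0],
                          [200.0, 100.0, 400.0],
                          [400.0, 200.0, 100.0]])
        st = shape_decompose(make_table(vals, ["a", "b", "c"]))
        with pytest.raises(ValueError, match="variance"):
            allometry_coefficients(st)


class TestRatioSpectra:
    def test_single_bootstrap_collapses_ci(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        res = shape_pca(st)
        sp = pca_ratio_spectrum(res, 1, st, n_boot=1, seed=5)
        assert np.abs(sp.ci_high.to_numpy() - sp.ci_low.to_numpy()).max() < 1e-12

    def test_planted_contrast_occupies_extremes(self, planted_table):
        cfg, table, truth = planted_table
        st = shape_decompose(table)
        res = shape_pca(st)
        sp = pca_ratio_spectrum(res, 1, st, n_boot=50, seed=5)
        extremes = {sp.ordering[0], sp.ordering[-1]}
        assert extremes == set(truth.pairs[("g1", "g2")].best_pair)

    def test_isometric_allometry_cis_cover_zero(self):
        table, _ = simulate_measurements(_isometric_config(n=200, seed=12))
        st = shape_decompose(table)
        sp = allometry_ratio_spectrum(st, n_boot=200, level=0.99, seed=3)
        assert ((sp.ci_low.to_numpy() <= 0) & (sp.ci_high.to_numpy() >= 0)).all()

    def test_same_seed_same_cis(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        res = shape_pca(st)
        sp1 = pca_ratio_spectrum(res, 1, st, n_boot=30, seed=9)
        sp2 = pca_ratio_spectrum(res, 1, st, n_boot=30, seed=9)
        assert (sp1.ci_low == sp2.ci_low).all() and (sp1.ci_high == sp2.ci_high).all()

    def test_ordering_is_permutation(self, planted_table):
        _, table, _ = planted_table
        st = shape_decompose(table)
        sp = allometry_ratio_spectrum(st, n_boot=10, seed=2)
        assert sorted(sp.ordering) == sorted(st.columns)


class TestSizeShapeScatter:
    def test_isometric_correlation_small(self):
        table, _ = simulate_measurements(_isometric_config(n=400, seed=21))
        st = shape_decompose(table)
        res = shape_pca(st)
        _, r = size_shape_scatter(res, st, 1)
        assert abs(r) < 3 / math.sqrt(400)

    def test_planted_allometry_detected(self):
        p = 6
        a = np.zeros(p)
        a[0], a[1] = 0.4, -0.4
        cfg = SyntheticConfig([f"v{k}" for k in range(p)],
                              [GroupSpec("g", 300, np.zeros(p))],
                              0.12, a, 0.01, seed=3)
        table, _ = simulate_measurements(cfg)
        st = shape_decompose(table)
        res = shape_pca(st)
        _, r = size_shape_scatter(res, st, 1)
        assert abs(r) > 0.5

    def test_constant_isosize_reports_undefined(self):
        vals = np.vstack([[100.0, 200.0, 400.0],
                          [200.0, 100.0, 400.0],
                          [400.0, 200.0, 100.0]])
        st = shape_decompose(make_table(vals, ["a", "b", "c"]))
        res = shape_pca(st)
        _, r = size_shape_scatter(res, st, 1)
        assert r is None


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.5, 3.7])
    def test_single_specimen_rescaling(self, c):
        rng = np.random.default_rng(6)
        vals = np.exp(rng.normal(6, 0.1, (20, 5)))
        scaled = vals.copy()
        scaled[4] *= c
        st1 = shape_decompose(make_table(vals, list("abcde")))
        st2 = shape_decompose(make_table(scaled, list("abcde")))
        assert np.abs(st1.shape.to_numpy() - st2.shape.to_numpy()).max() < 1e-9
        assert st2.isosize.iloc[4] - st1.isosize.iloc[4] == pytest.approx(
            math.log(c), abs=1e-12)
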