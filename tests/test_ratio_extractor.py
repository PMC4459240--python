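import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mra.ratio_extractor import (GroupComparison, delta, extract_best_ratios,
                                 isosize_distance, ratio_ranges,
                                 standard_distance, table2_report)
from mra.synthetic import planted_contrast_config, simulate_measurements

from conftest import make_table


def brute_force_best_pair(table, comparison):
    """Independent exhaustive re-scan with an independently coded D."""
    cols = table.columns
    L = np.log(table.values.to_numpy(dtype=float))
    idx = {sid: i for i, sid in enumerate(table.specimen_ids)}
    i1 = [idx[s] for s in comparison.members_1]
    i2 = [idx[s] for s in comparison.members_2]
    best, best_d = None, -1.0
    for a, b in itertools.combinations(range(len(cols)), 2):
        r1 = L[i1, a] - L[i1, b]
        r2 = L[i2, a] - L[i2, b]
        ss = np.sum((r1 - r1.mean()) ** 2) + np.sum((r2 - r2.mean()) ** 2)
        sd = math.sqrt(ss / (len(r1) + len(r2) - 2))
        if sd == 0:
            continue
        d = abs(r1.mean() - r2.mean()) / sd
        if d > best_d:
            best, best_d = frozenset((cols[a], cols[b])), d
    return best, best_d


def two_column_table(logratios_1, logratios_2):
    """Two-character table whose log-ratio a/b takes the given values."""
    vals, groups = [], []
    for lr in logratios_1:
        vals.append([100.0 * math.exp(lr), 100.0])
        groups.append("g1")
    for lr in logratios_2:
        vals.append([100.0 * math.exp(lr), 100.0])
        groups.append("g2")
    return make_table(np.array(vals), ["a", "b"], groups=groups)


class TestStandardDistance:
    def test_hand_computed_value(self):
        # log-ratios {0.9, 1.0, 1.1} vs {1.9, 2.0, 2.1}: means 1 and 2,
        # pooled SD sqrt(0.04/4) = 0.1 -> D = 10
        t = two_column_table([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        comp = GroupComparison.from_table(t, "g1", "g2")
        d = standard_distance(np.array([1.0, -1.0]), t, comp)
        assert d == pytest.approx(10.0, abs=1e-9)

    def test_identical_means_give_zero(self):
        t = two_column_table([0.9, 1.0, 1.1], [1.1, 1.0, 0.9])
        comp = GroupComparison.from_table(t, "g1", "g2")
        assert standard_distance(np.array([1.0, -1.0]), t, comp) == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [-2.0, 0.5, 17.0])
    def test_homogeneous_in_direction(self, c, planted_table):
        _, table, _ = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        v = np.zeros(len(table.columns))
        v[0], v[1] = 1.0, -1.0
        assert standard_distance(c * v, table, comp) == pytest.approx(
            standard_distance(v, table, comp), rel=1e-12)

    def test_degenerate_direction_errors(self):
        t = two_column_table([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        comp = GroupComparison.from_table(t, "g1", "g2")
        with pytest.raises(ValueError, match="degenerate"):
            standard_distance(np.array([1.0, -1.0]), t, comp)

    def test_size_shift_invariance(self, planted_table):
        # adding a common factor to one specimen cannot move any log-ratio
        _, table, _ = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        v = np.zeros(len(table.columns))
        v[2], v[5] = 1.0, -1.0
        d0 = standard_distance(v, table, comp)
        scaled = table.copy()
        scaled.values.iloc[10] *= math.e  # +1 on every log-measurement
        d1 = standard_distance(v, scaled, comp)
        assert abs(d0 - d1) < 1e-9


class TestDelta:
    def test_zero_when_isosize_identical(self):
        t = two_column_table([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        # equalize isosize: scale each specimen to geometric mean 100
        gm = np.exp(np.log(t.values.to_numpy()).mean(axis=1))
        t.values.iloc[:, :] = t.values.to_numpy() * (100.0 / gm)[:, None]
        comp = GroupComparison.from_table(t, "g1", "g2")
        assert delta(np.array([1.0, -1.0]), comp, t) == pytest.approx(0.0, abs=1e-9)

    def test_matches_analytic_construction(self):
        # two groups with a planted log-ratio contrast and a size offset:
        # delta must match the ratio of the two analytic standard distances
        cfg = planted_contrast_config(p=8, n_per_group=250, target_D=4.0,
                                      sigma_size=0.1, sigma_noise=0.02,
                                      size_offset_2=0.08, seed=17)
        table, truth = simulate_measurements(cfg)
        comp = GroupComparison.from_table(table, "g1", "g2")
        v = np.zeros(8)
        v[0], v[1] = 1.0, -1.0
        est = delta(v, comp, table)
        pt = truth.pairs[("g1", "g2")]
        assert pt.delta == pytest.approx(pt.D_size / pt.D)
        # Monte-Carlo error at n=500: ~ 0.1 * analytic value
        assert est == pytest.approx(pt.delta, rel=0.25)

    def test_zero_ratio_distance_errors(self):
        t = two_column_table([0.9, 1.0, 1.1], [1.1, 1.0, 0.9])
        comp = GroupComparison.from_table(t, "g1", "g2")
        with pytest.raises(ValueError, match="undefined"):
            delta(np.array([1.0, -1.0]), comp, t)


class TestExtractBestRatios:
    def test_first_ratio_matches_brute_force(self, planted_table, demo_table):
        from mra.measurement_data import drop_variables, impute_missing
        _, t1, _ = planted_table
        _, t2raw, _ = demo_table
        t2, _ = impute_missing(drop_variables(t2raw, ["gst.b"]), seed=0)
        cases = [
            (t1, GroupComparison.from_table(t1, "g1", "g2")),
            (t2, GroupComparison.from_table(t2, "calandrae", "quinarius")),
            (t2, GroupComparison.from_table(t2, ["calandrae", "cornis"],
                                            ["caryedophagus", "quinarius"])),
        ]
        for table, comp in cases:
            res = extract_best_ratios(table, comp)
            oracle_pair, oracle_d = brute_force_best_pair(table, comp)
            got = frozenset((res.ratios[0].numerator, res.ratios[0].denominator))
            assert got == oracle_pair
            assert res.ratios[0].D == pytest.approx(oracle_d, rel=1e-9)

    def test_planted_pair_found_with_correct_orientation(self, planted_table):
        cfg, table, truth = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        res = extract_best_ratios(table, comp)
        first = res.ratios[0]
        assert {first.numerator, first.denominator} == set(
            truth.pairs[("g1", "g2")].best_pair)
        # orientation: pooled geometric-mean ratio >= 1
        pooled = (table.values[first.numerator]
                  / table.values[first.denominator])
        assert np.exp(np.log(pooled).mean()) >= 1.0

    def test_null_groups_low_separation(self):
        rng = np.random.default_rng(13)
        vals = np.exp(rng.normal(6, 0.1, (60, 5)))
        t = make_table(vals, list("abcde"),
                       groups=["g1"] * 30 + ["g2"] * 30)
        res = extract_best_ratios(t, GroupComparison.from_table(t, "g1", "g2"))
        assert res.low_separation
        assert all(r.D < 1.5 for r in res.ratios)

    def test_second_ratio_is_complementary_not_second_marginal(self, planted_table):
        _, table, _ = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        res = extract_best_ratios(table, comp, n_ratios=2)
        assert len(res.ratios) == 2
        # invariant required: ratio 1 maximizes marginal D (not D1 >= D2)
        _, oracle_d = brute_force_best_pair(table, comp)
        assert res.ratios[0].D == pytest.approx(oracle_d, rel=1e-9)

    def test_too_many_ratios_errors(self):
        t = two_column_table([0.9, 1.0, 1.1], [1.9, 2.0, 2.1])
        comp = GroupComparison.from_table(t, "g1", "g2")
        with pytest.raises(ValueError, match="n_ratios"):
            extract_best_ratios(t, comp, n_ratios=2)

    def test_groups_must_be_disjoint_and_large_enough(self):
        with pytest.raises(ValueError):
            GroupComparison("x", "y", ["a", "b", "c"], ["c", "d", "e"])
        with pytest.raises(ValueError):
            GroupComparison("x", "y", ["a", "b"], ["c", "d", "e"])


class TestRatioRanges:
    def test_single_specimen_range_collapses(self):
        t = make_table([[150.0, 100.0]], ["a", "b"], groups=["g"])
        assert ratio_ranges(t, "g", "a", "b") == (1.5, 1.5)

    def test_imputed_specimen_excluded_from_range_not_from_D(self, demo_table):
        from mra.measurement_data import drop_variables, impute_missing
        _, raw, _ = demo_table
        table, log = impute_missing(drop_variables(raw, ["gst.b"]), seed=1)
        assert log.n_imputed_cells > 0
        comp = GroupComparison.from_table(table, "calandrae", "quinarius")
        res = extract_best_ratios(table, comp)
        num, den = res.ratios[0].numerator, res.ratios[0].denominator
        # independent range over non-imputed calandrae specimens
        ok = (table.group.eq("calandrae")
              & ~table.imputed_mask[num] & ~table.imputed_mask[den])
        expect = table.values.loc[ok, num] / table.values.loc[ok, den]
        assert ratio_ranges(table, "calandrae", num, den) == (
            pytest.approx(expect.min()), pytest.approx(expect.max()))
        # D however uses every specimen (imputed included)
        v = np.zeros(len(table.columns))
        v[table.columns.index(num)] = 1.0
        v[table.columns.index(den)] = -1.0
        assert res.ratios[0].D == pytest.approx(
            standard_distance(v, table, comp), rel=1e-12)

    def test_no_qualifying_specimen_errors(self):
        t = make_table([[150.0, np.nan]], ["a", "b"], groups=["g"])
        with pytest.raises(ValueError, match="no specimen"):
            ratio_ranges(t, "g", "a", "b")


class TestTable2Report:
    def test_report_deterministic(self, planted_table):
        _, table, _ = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        r1 = table2_report(table, [comp]).to_csv(sep="\t")
        r2 = table2_report(table, [comp]).to_csv(sep="\t")
        assert r1 == r2

    def test_identical_groups_no_star(self):
        vals = np.exp(np.random.default_rng(3).normal(6, 0.1, (8, 3)))
        t = make_table(np.vstack([vals, vals]), ["a", "b", "c"],
                       groups=["g1"] * 8 + ["g2"] * 8,
                       ids=[f"s{i}" for i in range(16)])
        rep = table2_report(t, [GroupComparison.from_table(t, "g1", "g2")])
        assert (rep["range_1"] == rep["range_2"]).all()
        assert not rep["ratio"].str.startswith("*").any()

    def test_separated_groups_starred(self, planted_table):
        _, table, _ = planted_table
        comp = GroupComparison.from_table(table, "g1", "g2")
        rep = table2_report(table, [comp])
        assert rep["ratio"].iloc[0].startswith("*")
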