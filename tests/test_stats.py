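import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from damsleep.stats import (
    ContingencyTable,
    fisher_exact,
    sidak_adjust,
    significance_stars,
    stratified_2x2,
    three_way_rm_anova,
    tukey_hsd,
    two_way_anova,
)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = hypergeom.pmf(k, n, r1, c1)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [(((20, 9), (28, 2)), 0.021), (((24, 12), (43, 3)), 0.003)],
    )
    def test_rhythmicity_tables(self, table, expected):
        res = fisher_exact(table)
        assert round(res.p_value, 3) == expected

    def test_symmetric_table_gives_one(self):
        assert fisher_exact(((1, 1), (1, 1))).p_value == 1.0

    def test_zero_margin_flagged(self):
        res = fisher_exact(((0, 0), (3, 4)))
        assert res.p_value == 1.0 and res.degenerate

    @given(st.tuples(st.integers(0, 15), st.integers(0, 15),
                     st.integers(0, 15), st.integers(0, 15)))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        res = fisher_exact(((a, b), (c, d)))
        assert res.p_value == pytest.approx(
            fisher_enumeration_oracle(a, b, c, d), abs=1e-9
        )

    @given(st.tuples(st.integers(0, 12), st.integers(1, 12),
                     st.integers(1, 12), st.integers(0, 12)))
    def test_invariant_to_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact(((a, b), (c, d))).p_value
        p2 = fisher_exact(((d, c), (b, a))).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestStratified2x2:
    def test_pooling_identical_strata_strengthens_evidence(self):
        t = ContingencyTable(20, 9, 28, 2)
        single = fisher_exact(t).p_value
        pooled = stratified_2x2([t, t])["p_value"]
        assert pooled < single

    def test_exact_null_association_gives_zero_statistic(self):
        res = stratified_2x2([ContingencyTable(10, 10, 10, 10)])
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["common_odds_ratio"] == pytest.approx(1.0)

    def test_single_stratum_equals_score_test_formula(self):
        a, b, c, d = 20, 9, 28, 2
        res = stratified_2x2([ContingencyTable(a, b, c, d)])
        n = a + b + c + d
        e_a = (a + b) * (a + c) / n
        var_a = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
        assert res["statistic"] == pytest.approx((a - e_a) ** 2 / var_a)

    def test_degenerate_stratum_skipped(self):
        res = stratified_2x2(
            [ContingencyTable(20, 9, 28, 2), ContingencyTable(5, 0, 7, 0)]
        )
        assert res["n_strata_used"] == 1

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            stratified_2x2([ContingencyTable(5, 0, 7, 0)])


class TestTwoWayAnova:
    def test_balanced_textbook_dataset_by_hand(self):
        # cells (genotype x age): means 1.5 / 3.5 / 5.5 / 7.5, n=2 each
        values = [1, 2, 3, 4, 5, 6, 7, 8]
        genotype = ["g1"] * 4 + ["g2"] * 4
        age = ["a1", "a1", "a2", "a2"] * 2
        tab = two_way_anova(values, genotype, age)
        assert tab.loc["genotype", "sum_sq"] == pytest.approx(32.0)
        assert tab.loc["age", "sum_sq"] == pytest.approx(8.0)
        assert tab.loc["genotype:age", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["residual", "sum_sq"] == pytest.approx(2.0)
        assert tab.loc["genotype", "df"] == 1
        assert tab.loc["residual", "df"] == 4
        assert tab.loc["genotype", "F"] == pytest.approx(64.0)

    def test_equal_shift_leaves_interaction_unchanged(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 40)
        genotype = np.repeat(["g1", "g2"], 20)
        age = np.tile(np.repeat(["a1", "a2"], 10), 2)
        t1 = two_way_anova(values, genotype, age)
        shifted = values + np.where(genotype == "g2", 5.0, 0.0)
        t2 = two_way_anova(shifted, genotype, age)
        assert t1.loc["genotype:age", "sum_sq"] == pytest.approx(
            t2.loc["genotype:age", "sum_sq"]
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            two_way_anova([1, 2, 3], ["g1", "g1", "g2"], ["a1", "a1", "a1"])

    def test_null_calibration(self):
        """Type-I error of the genotype effect near the nominal 5%."""
        rng = np.random.default_rng(123)
        genotype = np.repeat(["g1", "g2"], 8)
        age = np.tile(np.repeat(["a1", "a2"], 4), 2)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            tab = two_way_anova(rng.normal(0, 1, 16), genotype, age)
            rejections += tab.loc["genotype", "p"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_tukey_pairs_cover_all_cells(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 40)
        genotype = np.repeat(["g1", "g2"], 20)
        age = np.tile(np.repeat(["a1", "a2"], 10), 2)
        out = tukey_hsd(values, genotype, age)
        assert len(out) == 6  # C(4, 2) cell pairs
        assert ((out["p_adj"] >= 0) & (out["p_adj"] <= 1)).all()


class TestRepeatedMeasuresAnova:
    def _design(self, n_per=8, seed=0, phase_delta=0.0):
        rng = np.random.default_rng(seed)
        rows = {"values": [], "genotype": [], "age": [], "phase": [], "fly": []}
        i = 0
        for g in ("g1", "g2"):
            for a in ("a1", "a2"):
                for _ in range(n_per):
                    base = rng.normal(0, 1)
                    for ph, delta in (("day", 0.0), ("night", phase_delta)):
                        rows["values"].append(base + delta + rng.normal(0, 0.5))
                        rows["genotype"].append(g)
                        rows["age"].append(a)
                        rows["phase"].append(ph)
                        rows["fly"].append(f"f{i}")
                    i += 1
        return rows

    def test_identical_phases_give_zero_phase_ss(self):
        d = self._design(seed=4)
        # copy each fly's day value into its night slot
        values = list(d["values"])
        for i in range(0, len(values), 2):
            values[i + 1] = values[i]
        tab = three_way_rm_anova(values, d["genotype"], d["age"],
                                 d["phase"], d["fly"])
        assert tab.loc["phase", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_injected_phase_effect_detected(self):
        d = self._design(seed=5, phase_delta=2.0)
        tab = three_way_rm_anova(d["values"], d["genotype"], d["age"],
                                 d["phase"], d["fly"])
        assert tab.loc["phase", "p"] < 1e-6
        # the effect was injected equally in all groups
        assert tab.loc["phase:genotype", "p"] > 0.01

    def test_between_effects_collapse_to_two_way_on_fly_means(self):
        d = self._design(seed=6)
        tab = three_way_rm_anova(d["values"], d["genotype"], d["age"],
                                 d["phase"], d["fly"])
        means, genotype, age = [], [], []
        for i in range(0, len(d["values"]), 2):
            means.append((d["values"][i] + d["values"][i + 1]) / 2)
            genotype.append(d["genotype"][i])
            age.append(d["age"][i])
        two = two_way_anova(means, genotype, age)
        assert tab.loc["genotype", "F"] == pytest.approx(two.loc["genotype", "F"])
        assert tab.loc["genotype", "p"] == pytest.approx(two.loc["genotype", "p"])

    def test_dfs_partition_total(self):
        d = self._design(n_per=5, seed=7)
        tab = three_way_rm_anova(d["values"], d["genotype"], d["age"],
                                 d["phase"], d["fly"])
        n_obs = len(d["values"])
        assert tab["df"].sum() == n_obs - 1

    def test_fly_missing_one_phase_dropped(self):
        d = self._design(seed=8)
        with pytest.warns(UserWarning, match="missing one phase"):
            three_way_rm_anova(
                d["values"][:-1], d["genotype"][:-1], d["age"][:-1],
                d["phase"][:-1], d["fly"][:-1],
            )


class TestSidak:
    def test_single_comparison_is_identity(self):
        assert sidak_adjust([0.3], m=1)[0] == pytest.approx(0.3)

    def test_zero_stays_zero(self):
        assert sidak_adjust([0.0], m=10)[0] == 0.0

    def test_closed_form(self):
        assert sidak_adjust([0.05], m=2)[0] == pytest.approx(0.0975)

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 20))
    def test_monotone_in_p_and_m(self, p1, p2, m):
        lo, hi = sorted((p1, p2))
        a = sidak_adjust([lo, hi], m=m)
        assert a[0] <= a[1]
        assert sidak_adjust([lo], m=m)[0] <= sidak_adjust([lo], m=m + 1)[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.2])


def test_significance_stars_thresholds():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
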