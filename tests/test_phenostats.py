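"""Blocked two-way ANOVA, one-way ANOVA, SED, and Dunnett comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timeclust import (InputError, dunnett_test, generate_phenotypes, one_way_anova,
                       phenotype_anova, sed, two_way_anova_blocked)


def brute_force_two_way_ss(y, a, b):
    """Hand decomposition for a balanced two-factor layout with replication."""
    y = np.asarray(y, float)
    frame = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = y.mean()
    ss_a = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in frame.groupby("a"))
    ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in frame.groupby("b"))
    cell = frame.groupby(["a", "b"])["y"].transform("mean")
    ss_resid = ((y - cell) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_ab = ss_total - ss_a - ss_b - ss_resid
    return ss_a, ss_b, ss_ab, ss_resid, ss_total


class TestTwoWayAnova:
    def _toy(self, rng, n_rep=3):
        rows = []
        for a in ("ctrl", "trt"):
            for b in (1.0, 2.0):
                for _ in range(n_rep):
                    rows.append({"a": a, "b": b,
                                 "y": rng.normal(2.0 * (a == "trt") + 0.5 * b, 1.0)})
        return pd.DataFrame(rows)

    def test_balanced_2x2_matches_brute_force_decomposition(self, rng):
        d = self._toy(rng)
        res = two_way_anova_blocked(d["y"], d["a"], d["b"])
        ss_a, ss_b, ss_ab, ss_res, ss_tot = brute_force_two_way_ss(d["y"], d["a"], d["b"])
        assert res.table.loc["treatment", "sum_sq"] == pytest.approx(ss_a, abs=1e-10)
        assert res.table.loc["time", "sum_sq"] == pytest.approx(ss_b, abs=1e-10)
        assert res.table.loc["treatment x time", "sum_sq"] == pytest.approx(ss_ab, abs=1e-10)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-10)

    def test_sums_of_squares_are_additive(self, rng):
        pheno = generate_phenotypes(seed=8)
        res = two_way_anova_blocked(pheno["carcass_kg"], pheno["treatment"],
                                    pheno["day"], pheno["batch"])
        total = ((pheno["carcass_kg"] - pheno["carcass_kg"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)

    def test_blocking_absorbs_a_constant_batch_shift(self):
        pheno = generate_phenotypes(seed=9)
        res0 = two_way_anova_blocked(pheno["carcass_kg"], pheno["treatment"],
                                     pheno["day"], pheno["batch"])
        shifted = pheno["carcass_kg"] + 50.0 * (pheno["batch"] == 2)
        res1 = two_way_anova_blocked(shifted, pheno["treatment"],
                                     pheno["day"], pheno["batch"])
        for term in ("treatment", "time", "treatment x time"):
            assert res1.table.loc[term, "F"] == pytest.approx(
                res0.table.loc[term, "F"], rel=1e-8)

    def test_null_treatment_p_roughly_uniform(self):
        """With no planted treatment effect, treatment p-values should not
        pile up near zero."""
        ps = []
        for seed in range(60):
            pheno = generate_phenotypes(
                seed=seed, treatment_effects={"control": 0, "ba": 0, "gh": 0},
                group_sizes={1.0: 4, 27.0: 4})
            res = two_way_anova_blocked(pheno["carcass_kg"], pheno["treatment"],
                                        pheno["day"], pheno["batch"])
            ps.append(res.table.loc["treatment", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_cell_is_an_error(self):
        d = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": ["x", "x", "y", "y"],
                          "b": [1, 2, 1, 1]})
        with pytest.raises(InputError, match="cells"):
            two_way_anova_blocked(d["y"], d["a"], d["b"])


class TestOneWayAnova:
    def test_two_group_f_equals_squared_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 10)
        res = one_way_anova(np.r_[x, y], ["a"] * 8 + ["b"] * 10)
        t = stats.ttest_ind(x, y, equal_var=True)
        assert res.table.loc["group", "F"] == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.table.loc["group", "p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_three_group_toy_matches_manual_calculation(self):
        y = np.array([1.0, 2, 3, 6, 7, 8, 11, 12, 13])
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = one_way_anova(y, g)
        # group means 2,7,12; grand 7; SSB = 3*(25+0+25) = 150; SSW = 6
        assert res.table.loc["group", "sum_sq"] == pytest.approx(150.0)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(6.0)
        assert res.mse == pytest.approx(1.0)

    def test_single_group_is_an_error(self):
        with pytest.raises(InputError):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestSed:
    def test_closed_form_and_edge_cases(self):
        assert sed(2.0, 10, 10) == pytest.approx(0.6325, abs=5e-5)
        assert sed(0.0, 5, 7) == 0.0
        assert sed(3.1, 4, 9) == sed(3.1, 9, 4)

    def test_invalid_arguments(self):
        with pytest.raises(InputError):
            sed(-1.0, 5, 5)
        with pytest.raises(InputError):
            sed(1.0, 0, 5)


class TestDunnett:
    def test_matches_independent_implementation(self, rng):
        groups = {"control": rng.normal(0, 1, 10), "ba": rng.normal(0.9, 1, 10),
                  "gh": rng.normal(0.3, 1, 15)}
        mine = dunnett_test(groups, "control", seed=1, n_mc=200_000)
        ref = stats.dunnett(groups["ba"], groups["gh"], control=groups["control"])
        got = mine.comparisons.set_index("treatment")["p_adjusted"]
        assert got["ba"] == pytest.approx(ref.pvalue[0], abs=0.01)
        assert got["gh"] == pytest.approx(ref.pvalue[1], abs=0.01)

    def test_adjusted_p_never_below_unadjusted_pairwise_p(self, rng):
        for _ in range(20):
            groups = {g: rng.normal(rng.uniform(-1, 1), 1, rng.integers(5, 12))
                      for g in ("control", "ba", "gh")}
            res = dunnett_test(groups, "control", seed=2, n_mc=20_000)
            for _, row in res.comparisons.iterrows():
                # pairwise t on the pooled-MSE statistic
                p_raw = 2 * stats.t.sf(abs(row["t"]), res.df_resid)
                assert row["p_adjusted"] >= p_raw - 0.01

    def test_extreme_shift_is_significant(self, rng):
        groups = {"control": rng.normal(0, 1, 10), "ba": rng.normal(10, 1, 10),
                  "gh": rng.normal(0, 1, 10)}
        res = dunnett_test(groups, "control", seed=3)
        assert res.comparisons.set_index("treatment").loc["ba", "p_adjusted"] < 0.001

    def test_familywise_error_under_null_at_most_alpha(self):
        rng = np.random.default_rng(404)
        n_sim, rejections = 300, 0
        for i in range(n_sim):
            groups = {"control": rng.normal(0, 1, 10), "ba": rng.normal(0, 1, 10),
                      "gh": rng.normal(0, 1, 15)}
            res = dunnett_test(groups, "control", alpha=0.05, seed=i, n_mc=20_000)
            rejections += bool(res.comparisons["significant"].any())
        fwer = rejections / n_sim
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_missing_control_label_is_an_error(self, rng):
        with pytest.raises(InputError, match="control"):
            dunnett_test({"a": rng.normal(size=5), "b": rng.normal(size=5)}, "control")


class TestPhenotypeAnova:
    def test_auto_gate_skips_dunnett_under_interaction(self):
        pheno = generate_phenotypes(seed=5, treatment_effects={"control": 0,
                                                               "ba": 40, "gh": 0})
        res = phenotype_anova(pheno, "carcass_kg", dunnett="auto", seed=0)
        assert res["interaction_p"] < 0.05
        assert res["dunnett"] is None
        res2 = phenotype_anova(pheno, "carcass_kg", dunnett="always", seed=0)
        assert res2["dunnett"] is not None
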