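"""Two-stage regression engine: design matrix, OLS oracle agreement,
stepwise elimination, and the two filters."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timeclust import (InputError, RegressionConfig, build_design, fit_probe,
                       fit_probes, r2_filter, significant_probes, stepwise_select)
from timeclust.regression import build_design_matrix


def ols_oracle(y, A):
    """Independent least-squares + global F oracle via the normal equations."""
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    n, p = A.shape
    f = ((tss - rss) / (p - 1)) / (rss / (n - p))
    return beta, 1 - rss / tss, stats.f.sf(f, p - 1, n - p)


@pytest.fixture(scope="module")
def two_arm_design():
    return build_design({1.0: 3, 3.0: 3, 7.0: 3, 13.0: 3, 27.0: 4},
                        treatments=("control", "ba"))


class TestDesignMatrix:
    def test_degree2_two_groups_has_six_named_columns(self, two_arm_design):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        assert list(X.columns) == ["intercept", "t", "t2", "ba", "ba_x_t", "ba_x_t2"]

    def test_control_rows_zero_in_group_terms(self, two_arm_design):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        ctrl = [s for s in X.index if s.startswith("control")]
        assert (X.loc[ctrl, ["ba", "ba_x_t", "ba_x_t2"]].to_numpy() == 0).all()

    def test_degree4_full_rank_against_independent_rank_oracle(self, two_arm_design):
        import sympy
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=4))
        assert sympy.Matrix(X.to_numpy().tolist()).rank() == X.shape[1]

    def test_excess_degree_and_extra_arm_rejected(self, two_arm_design, small_design):
        with pytest.raises(InputError, match="degree"):
            build_design_matrix(two_arm_design, RegressionConfig(degree=5))
        with pytest.raises(InputError, match="arms"):
            build_design_matrix(small_design, RegressionConfig(contrast="ba"))


class TestFitProbe:
    def test_matches_normal_equations_oracle_on_random_instances(self, two_arm_design, rng):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        A = X.to_numpy()
        for _ in range(200):
            y = rng.normal(size=A.shape[0]) + A @ rng.normal(size=A.shape[1])
            fit = fit_probe(y, X)
            beta, r2, p = ols_oracle(y, A)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, rtol=1e-8)
            assert fit.r_squared == pytest.approx(r2, rel=1e-8)
            assert fit.global_p == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_vectorized_fit_agrees_with_per_probe_fit(self, two_arm_design, rng):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        Y = pd.DataFrame(rng.normal(size=(20, X.shape[0])),
                         index=[f"p{i}" for i in range(20)], columns=X.index)
        bulk = fit_probes(Y, X)
        for probe in Y.index[::5]:
            single = fit_probe(Y.loc[probe].to_numpy(), X)
            assert bulk.loc[probe, "global_p"] == pytest.approx(single.global_p, rel=1e-10)
            assert bulk.loc[probe, "r_squared"] == pytest.approx(single.r_squared, rel=1e-10)

    def test_constant_response_gives_r2_zero_p_one(self, two_arm_design):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        fit = fit_probe(np.full(X.shape[0], 7.0), X)
        assert fit.r_squared == 0.0
        assert fit.global_p == 1.0

    def test_exact_linear_response_gives_r2_one(self, two_arm_design, rng):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        y = X.to_numpy() @ rng.normal(size=X.shape[1])
        fit = fit_probe(y, X)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_response_rejected(self, two_arm_design):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        y = np.zeros(X.shape[0])
        y[0] = np.nan
        with pytest.raises(InputError, match="non-finite"):
            fit_probe(y, X)


class TestStepwise:
    def _fit(self, y, X):
        return fit_probe(y, X)

    def test_alpha_one_retains_full_model(self, two_arm_design, rng):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        y = rng.normal(size=X.shape[0])
        red = stepwise_select(self._fit(y, X), y, X, alpha_step=1.0)
        assert set(red.selected_terms) == set(X.columns)

    def test_alpha_zero_reduces_to_intercept(self, two_arm_design, rng):
        X = build_design_matrix(two_arm_design, RegressionConfig(degree=2))
        y = rng.normal(size=X.shape[0])
        red = stepwise_select(self._fit(y, X), y, X, alpha_step=1e-300)
        assert red.selected_terms == ("intercept",)

    def test_strong_interaction_retained_in_nearly_all_simulations(self):
        """A planted group-by-time slope 10x the noise must survive backward
        elimination essentially always."""
        design = build_design({d: 10 for d in (1.0, 3.0, 7.0, 13.0, 27.0)},
                              treatments=("control", "ba"))
        X = build_design_matrix(design, RegressionConfig(degree=2))
        A = X.to_numpy()
        slope = A[:, X.columns.get_loc("ba_x_t")]
        rng = np.random.default_rng(77)
        kept = 0
        n_sim = 500
        for _ in range(n_sim):
            y = 10.0 * slope + rng.normal(size=A.shape[0])
            red = stepwise_select(fit_probe(y, X), y, X, alpha_step=0.05)
            kept += "ba_x_t" in red.selected_terms
        assert kept / n_sim >= 0.99


class TestFilters:
    def test_significance_boundary_is_strict(self):
        fits = pd.DataFrame({"global_p": [0.049, 0.051, 0.05]},
                            index=["a", "b", "c"])
        assert list(significant_probes(fits, 0.05)) == ["a"]

    def test_empty_fit_table_gives_empty_sets(self):
        empty = pd.DataFrame(columns=["global_p", "r_squared"])
        assert len(significant_probes(empty, 0.05)) == 0
        assert len(r2_filter(empty, 0.5)) == 0

    def test_r2_boundary_inclusive_and_antitone_in_threshold(self, rng):
        fits = pd.DataFrame({"r_squared": np.r_[0.50, 0.49, rng.uniform(0, 1, 50)]})
        kept = r2_filter(fits, 0.5)
        assert 0 in kept and 1 not in kept
        assert set(r2_filter(fits, 0.5)) <= set(r2_filter(fits, 0.2))

    def test_fdr_mode_is_more_conservative_under_nulls(self, rng):
        p = np.r_[1e-8, rng.uniform(0.2, 1, 99)]
        fits = pd.DataFrame({"global_p": p})
        raw = significant_probes(fits, 0.05)
        fdr = significant_probes(fits, 0.05, p_adjust="fdr_bh")
        assert set(fdr) <= set(raw)
        assert 0 in fdr
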