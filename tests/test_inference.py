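"""Model selection arithmetic, quantile/dispersion/energy tests, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearhr import inference as inf
from bearhr.errors import InferenceError, ParameterError, SingularDesignError

from helpers import make_sex_table


class TestFitLM:
    def test_t_is_estimate_over_se_and_centered_residuals(self):
        tab = make_sex_table(0)
        fit = inf.fit_lm(tab, inf.ModelSpec("Sex", ("sex",)))
        assert np.allclose(fit.tvalues, fit.params / fit.bse)
        assert fit.resid.sum() == pytest.approx(0.0, abs=1e-9)
        assert fit.K == 3  # intercept + sex + residual variance

    def test_constant_response(self):
        tab = make_sex_table(1, sd=0.0, effect=0.0)
        fit = inf.fit_lm(tab, inf.ModelSpec("Sex", ("sex",)))
        assert fit.params["sex_M"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_ci_coverage_of_true_sex_effect(self):
        hits = 0
        for s in range(100):
            fit = inf.fit_lm(make_sex_table(s), inf.ModelSpec("Sex", ("sex",)))
            b, se = fit.params["sex_M"], fit.bse["sex_M"]
            hits += (b - 1.96 * se) <= 0.65 <= (b + 1.96 * se)
        assert hits >= 93

    def test_singular_design_raises(self):
        tab = make_sex_table(2)
        tab["mass_kg"] = 100.0  # log_mass constant -> aliased with intercept
        with pytest.raises(SingularDesignError):
            inf.fit_lm(tab, inf.ModelSpec("M", ("sex", "log_mass")))

    def test_interaction_requires_mains(self):
        with pytest.raises(ParameterError):
            inf.ModelSpec("bad", ("sex", "sex:log_mass"))


class TestAICc:
    def test_weights_from_printed_delta_column(self):
        w = inf.aicc_weights([0.0, 1.18, 2.06, 7.88, 8.16])
        assert np.allclose(w, [0.51, 0.28, 0.18, 0.01, 0.01], atol=0.005)
        assert w.sum() == pytest.approx(1.0)

    def test_identical_models_split_weight(self):
        tab = make_sex_table(3)
        specs = [inf.ModelSpec("a", ("sex",)), inf.ModelSpec("b", ("sex",))]
        sel, _ = inf.aicc_table(tab, specs)
        assert np.allclose(sel["dAICc"], 0.0)
        assert np.allclose(sel["weight"], 0.5)

    def test_selection_table_invariants(self):
        tab = make_sex_table(4)
        tab["mass_kg"] = np.exp(np.random.default_rng(4).normal(4.9, 0.25, len(tab)))
        sel, fits = inf.aicc_table(tab, inf.candidate_models())
        assert sel["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert sel["dAICc"].iloc[0] == 0.0
        assert sel["weight"].iloc[0] == sel["weight"].max()
        assert (sel["evidence_ratio"] >= 1.0 - 1e-12).all()
        assert sel["n_used"].nunique() == 1  # common-sample rule
        # AICc column consistent with the fit objects
        for _, row in sel.iterrows():
            assert fits[row["model"]].aicc == pytest.approx(row["AICc"])

    @given(st.lists(st.floats(0, 50), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weight_properties(self, deltas):
        deltas = np.asarray(deltas) - min(deltas)
        w = inf.aicc_weights(deltas)
        assert w.sum() == pytest.approx(1.0)
        assert w[int(np.argmin(deltas))] == pytest.approx(w.max())


class TestModelAverage:
    def test_single_model_identity(self):
        tab = make_sex_table(5)
        sel, fits = inf.aicc_table(tab, [inf.ModelSpec("a", ("sex",)),
                                         inf.ModelSpec("null", ())])
        avg = inf.model_average(sel, {"a": fits["a"]})
        assert avg.loc["sex_M", "estimate"] == pytest.approx(fits["a"].params["sex_M"])
        assert avg.loc["sex_M", "unconditional_se"] == pytest.approx(fits["a"].bse["sex_M"])

    def test_two_equal_weight_models_closed_form(self):
        # estimates b±d with common SE s -> unconditional SE sqrt(s^2 + d^2)
        sel = pd.DataFrame({"model": ["m1", "m2"], "weight": [0.5, 0.5]})

        class Stub:
            def __init__(self, b, s):
                self.params = pd.Series({"x": b})
                self.bse = pd.Series({"x": s})

        b, d, s = 1.0, 0.3, 0.2
        avg = inf.model_average(sel, {"m1": Stub(b + d, s), "m2": Stub(b - d, s)})
        assert avg.loc["x", "estimate"] == pytest.approx(b)
        assert avg.loc["x", "unconditional_se"] == pytest.approx(math.sqrt(s**2 + d**2))

    def test_absent_term_absent(self):
        tab = make_sex_table(6)
        sel, fits = inf.aicc_table(tab, [inf.ModelSpec("a", ("sex",)),
                                         inf.ModelSpec("null", ())])
        avg = inf.model_average(sel, fits)
        assert "log_mass" not in avg.index


class TestBacktransform:
    def test_natural_and_log10(self):
        r, _ = inf.backtransform_ratio(0.65)
        assert round(r, 2) == 1.92
        r10, _ = inf.backtransform_ratio(0.295, base=10)
        assert round(r10, 2) == 1.97
        r0, (lo, hi) = inf.backtransform_ratio(0.0, 0.1)
        assert r0 == 1.0 and lo < 1.0 < hi

    def test_ci_formula(self):
        r, (lo, hi) = inf.backtransform_ratio(0.65, 0.20)
        assert lo == pytest.approx(math.exp(0.65 - 1.96 * 0.20))
        assert hi == pytest.approx(math.exp(0.65 + 1.96 * 0.20))


def _brute_force_quantile(x, tau):
    """Lowest data value minimising the check loss (independent oracle)."""
    x = np.asarray(x, float)
    losses = [
        (np.sum(np.where(x - c >= 0, tau * (x - c), (tau - 1) * (x - c))), c)
        for c in np.sort(x)
    ]
    best = min(l for l, _ in losses)
    return min(c for l, c in losses if abs(l - best) < 1e-9)


class TestQuantileFits:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beta_equals_group_quantile_difference(self, seed):
        tab = make_sex_table(seed)
        fits = inf.quantile_fits(tab, n_boot=50, seed=seed)
        xf = tab.loc[tab.sex == "F", "log_mcp"].to_numpy()
        xm = tab.loc[tab.sex == "M", "log_mcp"].to_numpy()
        for tau, res in fits.items():
            expect = _brute_force_quantile(xm, tau) - _brute_force_quantile(xf, tau)
            assert res["beta"] == pytest.approx(expect, abs=1e-9)
            assert res["ratio"] == pytest.approx(math.exp(res["beta"]))
            assert res["ci_low"] <= res["beta"] <= res["ci_high"]

    def test_cross_check_against_statsmodels_quantreg(self):
        # group sizes chosen so n*tau is never an integer (unique minimiser)
        import statsmodels.api as sm

        tab = make_sex_table(7, n_m=47, n_f=23)
        fits = inf.quantile_fits(tab, n_boot=10, seed=0)
        x = sm.add_constant((tab["sex"] == "M").astype(float))
        for tau, res in fits.items():
            qr = sm.QuantReg(tab["log_mcp"], x).fit(q=tau)
            assert res["beta"] == pytest.approx(qr.params.iloc[1], abs=1e-4)

    def test_tau_validation(self):
        with pytest.raises(ParameterError):
            inf.quantile_fits(make_sex_table(8), taus=(1.5,), n_boot=10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_check_loss_quantile_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 40))
        tau = float(rng.uniform(0.05, 0.95))
        assert inf.check_loss_quantile(x, tau) == pytest.approx(
            _brute_force_quantile(x, tau), abs=1e-12
        )


class TestDispersion:
    def test_location_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        chi2, df, p, iqrs = inf.dispersion_test([a, a + 5.0])
        assert chi2 < 1e-3  # rank-based: shift-invariant up to tie handling
        assert p > 0.99
        assert df == 1
        assert iqrs[0] == pytest.approx(iqrs[1])

    def test_tenfold_spread_detected(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 200), rng.normal(0, 10, 200)
        chi2, df, p, _ = inf.dispersion_test([a, b])
        assert p < 0.001

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        assert inf.dispersion_test(groups)[1] == 2


class TestEnergy:
    def test_tiny_case_brute_force(self):
        # x=(0,0), y=(1,1): cross pairs all |0-1|=1, within pairs all 0
        assert inf.energy_stat([0.0, 0.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_identical_samples(self):
        x = np.arange(10.0)
        e, p = inf.energy_perm_test(x, x.copy(), n_perm=99, seed=0)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert p > 0.5

    def test_location_scale_invariance_of_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        _, p1 = inf.energy_perm_test(x, y, n_perm=199, seed=7)
        _, p2 = inf.energy_perm_test(3.0 * x - 10.0, 3.0 * y - 10.0, n_perm=199, seed=7)
        assert p1 == p2

    def test_p_floor(self):
        x, y = np.zeros(5), np.ones(5) * 100
        _, p = inf.energy_perm_test(x, y, n_perm=99, seed=1)
        assert p >= 1.0 / 100.0


class TestDiagnostics:
    def test_gross_outlier_has_max_cooks(self):
        tab = make_sex_table(9)
        tab.loc[tab.index[0], "log_mcp"] += 15.0
        fit = inf.fit_lm(tab, inf.ModelSpec("Sex", ("sex",)))
        rep = inf.diagnostics(fit, tab)
        assert tab.loc[tab.index[int(np.argmax(fit.cooks_d))], "animal_id"] == "B000"
        assert "B000" in rep["influential_ids"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clean_data_flags_few_and_sign_stable(self, seed):
        tab = make_sex_table(seed)
        fit = inf.fit_lm(tab, inf.ModelSpec("Sex", ("sex",)))
        rep = inf.diagnostics(fit, tab)
        # 4/n flags a handful of points even on clean Gaussian data
        assert len(rep["influential_ids"]) <= 0.12 * len(tab)
        if "sex_coef_without_influential" in rep:
            assert rep["sex_coef_without_influential"]["sign_agrees"]


class TestRobustness:
    def test_hc3_close_to_classical_when_homoscedastic(self):
        tab = make_sex_table(10, n_m=120, n_f=80, sd=0.5)
        rep = inf.robustness_refits(tab)
        assert rep["ols_hc3"]["se"] == pytest.approx(rep["ols_classical_se"], rel=0.15)

    def test_gamma_log_sign_agreement(self):
        agree = 0
        for s in range(100):
            rep = inf.robustness_refits(make_sex_table(s))
            agree += rep["signs_agree"]
        assert agree >= 95

    def test_single_sex_raises(self):
        tab = make_sex_table(11, n_m=0, n_f=20)
        with pytest.raises(InferenceError):
            inf.robustness_refits(tab)
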