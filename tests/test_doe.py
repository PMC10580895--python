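"""Response-surface machinery: coding, model matrices, OLS statistics
against independent oracles, FDR adjustment, term selection, and the
grid-search optimizer."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import fermkin as fk
from fermkin import (
    DesignTable,
    Factor,
    RangeWarning,
    Term,
    TermSpec,
    ValidationError,
    build_design_matrix,
    code_levels,
    datasets,
    fdr_adjust,
    fit_ols,
    logworth,
    optimize_surface,
    select_terms,
)
from oracles import bh_stepup_brute


class TestCoding:
    def test_anchor_points(self):
        ph = Factor("X1", 5, 7)
        temp = Factor("X2", 25, 35)
        agit = Factor("X4", 150, 250)
        assert code_levels(6, ph) == 0.0
        assert code_levels(35, temp) == 1.0
        assert code_levels(175, agit) == -0.5

    def test_out_of_range_warns(self):
        with pytest.warns(RangeWarning):
            code_levels(8, Factor("X1", 5, 7))

    def test_degenerate_factor_rejected(self):
        with pytest.raises(ValidationError):
            Factor("X1", 5, 5)

    @settings(derandomize=True, max_examples=50)
    @given(
        low=st.floats(-100, 100),
        width=st.floats(0.1, 100),
        x=st.floats(-50, 50),
    )
    def test_code_decode_round_trip(self, low, width, x):
        f = Factor("F", low, low + width)
        level = low + (x + 50) / 100 * width
        assert f.decode(f.code(level)) == pytest.approx(level, rel=1e-12, abs=1e-12)


class TestTermSpec:
    def test_interaction_order_is_canonical(self):
        assert Term.parse("X2*X4") == Term.parse("X4*X2")
        assert Term.parse("X4^2") == Term.parse("X4*X4")

    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            TermSpec(["X1", "X4*X2", "X2*X4"])

    def test_full_quadratic_size(self, ref_factors):
        spec = TermSpec.full_quadratic(ref_factors)
        assert len(spec) == 1 + 5 + 10 + 5


class TestDesignMatrix:
    def test_center_and_corner_rows(self, ref_factors):
        levels = np.array(
            [
                [f.center for f in ref_factors],
                [f.high for f in ref_factors],
            ]
        )
        dt = DesignTable(
            run_ids=[1, 2], levels=levels, response=[1.0, 2.0], factors=ref_factors
        )
        spec = TermSpec.full_quadratic(ref_factors)
        X = build_design_matrix(dt, spec).to_numpy()
        # all-center run: 1 for the intercept, 0 elsewhere
        assert X[0, 0] == 1.0 and np.all(X[0, 1:] == 0.0)
        # all-high corner: every column is 1
        assert np.all(X[1] == 1.0)

    def test_reference_peak_run_codes_to_temperature_axis(self, ref_design):
        """The best run (pH 6, 35 C, 5.5 g, 200 rpm, 7 d) is center on every
        factor except temperature at its high level."""
        spec = TermSpec(["Intercept", "X1", "X2", "X3", "X4", "X5"])
        X = build_design_matrix(ref_design, spec)
        row = X.loc[5].to_numpy()
        np.testing.assert_allclose(row, [1, 0, 1, 0, 0, 0])

    def test_unknown_factor_rejected(self, ref_design):
        with pytest.raises(ValidationError):
            build_design_matrix(ref_design, TermSpec(["X9"]))


class TestFitOLS:
    def test_exact_linear_surface(self, ref_factors, ref_design):
        spec = TermSpec(["Intercept", "X2"])
        X = build_design_matrix(ref_design, spec)
        y = 3.0 + 2.0 * X["X2"].to_numpy()
        fit = fit_ols(X, y, terms=spec, factors=ref_factors)
        assert fit.params[1] == pytest.approx(2.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_matches_pseudoinverse_and_statsmodels(self):
        """Estimates, SEs, t/p values, CIs and RMSE must match both the
        pseudoinverse solution and statsmodels on random well-conditioned
        problems."""
        rng = np.random.default_rng(101)
        for _ in range(20):
            n, p = 30, 5
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            labels = ["Intercept"] + [f"X{j}" for j in range(1, p)]
            fit = fit_ols(pd.DataFrame(X, columns=labels), y)
            np.testing.assert_allclose(fit.params, np.linalg.pinv(X) @ y, rtol=1e-9)
            ref = sm.OLS(y, X).fit()
            np.testing.assert_allclose(fit.params, ref.params, rtol=1e-9)
            np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-9)
            np.testing.assert_allclose(fit.tvalues, ref.tvalues, rtol=1e-9)
            np.testing.assert_allclose(fit.pvalues, ref.pvalues, rtol=1e-8, atol=1e-12)
            ci = ref.conf_int(0.05)
            np.testing.assert_allclose(fit.ci_lower, ci[:, 0], rtol=1e-9)
            np.testing.assert_allclose(fit.ci_upper, ci[:, 1], rtol=1e-9)
            np.testing.assert_allclose(fit.rmse, np.sqrt(ref.mse_resid), rtol=1e-9)
            np.testing.assert_allclose(fit.f_model, ref.fvalue, rtol=1e-9)

    def test_internal_consistency_identities(self, ref_design):
        """F = t^2 per single-df effect, CI = estimate +/- t_crit*SE,
        rmse^2 * df = SSE, and SS_model + SS_error = SS_total."""
        from scipy import stats

        spec = datasets.term_variants()["text_variant"]
        y = ref_design.response
        fit = fit_ols(build_design_matrix(ref_design, spec), y, terms=spec)
        t_by_label = dict(zip(fit.terms.labels(), fit.tvalues))
        for _, row in fit.anova.iterrows():
            label = row["term"] if row["term"] != "X4^2" else "X4^2"
            assert row["f_ratio"] == pytest.approx(t_by_label[label] ** 2, rel=1e-6)
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        np.testing.assert_allclose(fit.ci_lower, fit.params - tcrit * fit.bse, rtol=1e-12)
        np.testing.assert_allclose(fit.ci_upper, fit.params + tcrit * fit.bse, rtol=1e-12)
        sse = fit.rmse**2 * fit.df_resid
        sst = np.sum((y - y.mean()) ** 2)
        ss_model = np.sum((fit.fitted - y.mean()) ** 2)
        assert ss_model + sse == pytest.approx(sst, rel=1e-8)

    def test_refit_on_fitted_values_is_exact(self, ref_design):
        spec = datasets.term_variants()["text_variant"]
        X = build_design_matrix(ref_design, spec)
        fit = fit_ols(X, ref_design.response, terms=spec)
        refit = fit_ols(X, fit.fitted, terms=spec)
        assert refit.rmse == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(refit.params, fit.params, rtol=1e-9, atol=1e-12)

    def test_rank_deficiency_names_aliased_terms(self):
        X = pd.DataFrame({"Intercept": np.ones(10), "X1": np.arange(10.0)})
        X["X2"] = 2.0 * X["X1"]
        with pytest.raises(fk.SingularFitError, match="X2"):
            fit_ols(X, np.arange(10.0))


class TestLogWorth:
    @pytest.mark.parametrize(
        "p,expected", [(0.00919, 2.037), (0.02009, 1.697), (1.0, 0.0)]
    )
    def test_transform(self, p, expected):
        assert round(logworth(p), 3) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001])
    def test_domain(self, p):
        with pytest.raises(fk.DomainError):
            logworth(p)


class TestFDRAdjust:
    def test_edge_cases(self):
        assert fdr_adjust([]).size == 0
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.uniform(1e-6, 1.0, rng.integers(2, 15))
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup_brute(p), rtol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_never_decreases_and_preserves_order(self, ps):
        p = np.array(ps)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _null_design(ref_factors, seed):
    ref = datasets.load_reference_design()
    rng = np.random.default_rng(seed)
    y = np.maximum(rng.normal(5.0, 0.852, len(ref)), 1e-6)
    return DesignTable(
        run_ids=ref.run_ids, levels=ref.levels, response=y, factors=ref_factors
    )


NINE_TERMS = TermSpec(
    ["Intercept", "X1", "X2", "X3", "X4", "X5", "X2*X4", "X3*X5", "X4^2", "X5^2"]
)


class TestSelectTerms:
    def test_alpha_one_keeps_everything(self, ref_design):
        assert select_terms(ref_design, NINE_TERMS, alpha_stay=1.0) == NINE_TERMS

    def test_null_response_retains_few_terms(self, ref_factors):
        """Pure-noise responses: backward elimination at alpha 0.05 keeps
        on average no more than 1.5 spurious non-intercept terms."""
        kept = []
        for seed in range(200):
            dt = _null_design(ref_factors, seed)
            spec = select_terms(dt, NINE_TERMS, alpha_stay=0.05)
            kept.append(sum(1 for t in spec if t.kind != "intercept"))
        assert np.mean(kept) <= 1.5

    def test_true_terms_recovered_at_low_noise(self, ref_factors):
        """Responses built from three active terms: the selection contains
        all three in at least 95% of seeded replicates."""
        ref = datasets.load_reference_design()
        active = {"X2": 1.0, "X2*X4": 1.2, "X4^2": -1.5}
        truth = {Term.parse(k) for k in active}
        hits = 0
        for seed in range(200):
            dt = fk.simulate_design(
                ref_factors,
                {"Intercept": 5.0, **active},
                sigma=0.2,
                seed=seed,
                layout=ref.levels,
            )
            spec = select_terms(dt, NINE_TERMS, alpha_stay=0.05)
            if truth <= set(spec.terms):
                hits += 1
        assert hits / 200 >= 0.95

    def test_full_model_on_reference_design_is_estimable(self, ref_design):
        """The complete 21-term quadratic model leaves one residual df on
        the 22 printed runs and must still be a legal starting point."""
        spec = select_terms(ref_design, datasets.initial_terms(), alpha_stay=1.0)
        assert len(spec) == 21


class TestOptimizeSurface:
    def test_concave_bowl_peaks_at_center(self, ref_factors, ref_design):
        spec = TermSpec(["Intercept"] + [f"{f.name}^2" for f in ref_factors])
        X = build_design_matrix(ref_design, spec)
        y = 10.0 - X.iloc[:, 1:].sum(axis=1).to_numpy()
        fit = fit_ols(X, np.maximum(y, 1e-6), terms=spec, factors=ref_factors)
        settings_, pred = optimize_surface(fit, ref_factors, grid_points_per_factor=5)
        for f in ref_factors:
            assert settings_[f.name] == pytest.approx(f.center)
        assert pred == pytest.approx(10.0, abs=1e-6)

    def test_linear_surface_peaks_at_high_level(self, ref_factors, ref_design):
        spec = TermSpec(["Intercept", "X2"])
        X = build_design_matrix(ref_design, spec)
        y = 5.0 + 2.0 * X["X2"].to_numpy()
        fit = fit_ols(X, y, terms=spec, factors=ref_factors)
        settings_, _ = optimize_surface(fit, ref_factors, grid_points_per_factor=5)
        assert settings_["X2"] == pytest.approx(35.0)

    def test_matches_brute_force_grid(self, ref_factors, ref_design):
        rng = np.random.default_rng(17)
        spec = NINE_TERMS
        X = build_design_matrix(ref_design, spec)
        y = np.maximum(X.to_numpy() @ rng.normal(size=len(spec)) + 6.0, 1e-6)
        fit = fit_ols(X, y, terms=spec, factors=ref_factors)
        settings_, pred = optimize_surface(fit, ref_factors, grid_points_per_factor=5)
        # exhaustive evaluation over the same grid
        axes = [np.linspace(-1, 1, 5)] * 5
        best = -np.inf
        for combo in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 5):
            coded = {f.name: np.array([c]) for f, c in zip(ref_factors, combo)}
            val = fit.predict(coded)[0]
            if val > best:
                best = val
        assert pred == pytest.approx(best, rel=1e-12)
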