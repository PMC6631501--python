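"""Second-order fitting, prediction, coefficient transforms and ANOVA."""

import numpy as np
import pytest
import statsmodels.api as sm

import rsmann as rm
from rsmann.quadratic import SingularFitError, quadratic_design_matrix, term_names


def test_fit_matches_statsmodels_oracle(ccrd_data, fitted_model):
    """The in-package OLS agrees with an independent OLS implementation."""
    X = quadratic_design_matrix(ccrd_data.design.coded)
    ref = sm.OLS(ccrd_data.response, X).fit()
    np.testing.assert_allclose(fitted_model.beta_coded, ref.params, rtol=1e-8)
    aov = rm.anova(fitted_model, ccrd_data)
    assert aov.summary["r_squared"] == pytest.approx(ref.rsquared, rel=1e-10)
    assert aov.summary["adj_r_squared"] == pytest.approx(ref.rsquared_adj, rel=1e-10)


def test_actual_space_coefficients_match_direct_actual_fit(ccrd_data, fitted_model):
    """Fitting in coded units then transforming coefficients reproduces a
    direct actual-unit fit (the transform is exact)."""
    X = quadratic_design_matrix(ccrd_data.design.actual)
    direct, *_ = np.linalg.lstsq(X, ccrd_data.response, rcond=None)
    np.testing.assert_allclose(fitted_model.beta_actual, direct, rtol=1e-6, atol=1e-9)


def test_coefficient_round_trip_through_actual_space(fitted_model, factors):
    rebuilt = rm.QuadraticModel.from_actual_coefs(factors, fitted_model.beta_actual)
    np.testing.assert_allclose(rebuilt.beta_coded, fitted_model.beta_coded, atol=1e-8)


def test_prediction_same_in_coded_and_actual_space(fitted_model, rng):
    z = rng.uniform(-2, 2, size=(20, 4))
    actual = np.array([f.to_actual(z[:, j]) for j, f in enumerate(fitted_model.factors)]).T
    np.testing.assert_allclose(
        fitted_model.predict(z, space="coded"),
        fitted_model.predict(actual, space="actual"),
        rtol=1e-10,
    )
    # all-zero coded point is the coded intercept
    assert fitted_model.predict(np.zeros(4), space="coded") == pytest.approx(
        fitted_model.beta_coded[0]
    )


def test_noise_free_quadratic_recovered_to_machine_precision(factors, rng):
    truth = rng.normal(scale=0.5, size=15)
    model = rm.QuadraticModel(factors=factors, beta_coded=truth)
    design = rm.build_ccrd(factors, n_center=3)
    mu = model.predict(design.actual)
    shift = 1.0 - mu.min()  # keep responses positive; only moves the intercept
    data = rm.ExperimentTable(design=design, response=mu + shift)
    refit = rm.fit_quadratic(data)
    expected = truth.copy()
    expected[0] += shift
    np.testing.assert_allclose(refit.beta_coded, expected, atol=1e-9)


def test_rank_deficient_design_names_collinear_columns(factors):
    design = rm.build_ccrd(factors, n_center=3)
    frame = design.frame.copy()
    # collapse the power column to a constant: X4 terms become collinear
    frame["X4_coded"] = 0.0
    frame["X4_actual"] = 120.0
    degenerate = rm.DesignTable(factors=factors, frame=frame)
    data = rm.ExperimentTable(design=degenerate, response=np.ones(design.n_runs))
    with pytest.raises(SingularFitError, match="X4"):
        rm.fit_quadratic(data)


def test_published_predictions_reproduced(ccrd_data, validation_data, fitted_model):
    """Model predictions at every printed run agree with the published
    fitted-surface column to the printed 2-decimal precision."""
    for tbl in (ccrd_data, validation_data):
        pred = fitted_model.predict(tbl.design.actual)
        np.testing.assert_allclose(
            pred, tbl.extra["rsm_pred"].to_numpy(), atol=0.05
        )


class TestAnova:
    def test_additivity_invariants(self, fitted_anova):
        t = fitted_anova.table
        assert t.loc["Model", "ss"] + t.loc["Residual", "ss"] == pytest.approx(
            t.loc["Cor Total", "ss"]
        )
        assert t.loc["Lack of Fit", "ss"] + t.loc["Pure Error", "ss"] == pytest.approx(
            t.loc["Residual", "ss"]
        )
        assert fitted_anova.summary["press"] >= t.loc["Residual", "ss"]

    def test_press_equals_brute_force_leave_one_out(self, ccrd_data, fitted_anova):
        """Hat-matrix PRESS equals refit-and-predict leave-one-out."""
        z = ccrd_data.design.coded
        y = ccrd_data.response
        X = quadratic_design_matrix(z)
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        assert fitted_anova.summary["press"] == pytest.approx(press, rel=1e-8)

    def test_partial_ss_equals_term_deletion_refit(self, ccrd_data, fitted_model, fitted_anova):
        """The closed-form partial SS is the extra sum of squares from
        deleting that single term and refitting (independent oracle)."""
        z = ccrd_data.design.coded
        y = ccrd_data.response
        X = quadratic_design_matrix(z)
        full_sse = float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
        names = term_names(ccrd_data.factors)
        for j in [1, 4, 7, 11, 14]:
            keep = [c for c in range(X.shape[1]) if c != j]
            beta_r, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
            sse_r = float(((y - X[:, keep] @ beta_r) ** 2).sum())
            assert fitted_anova.table.loc[names[j], "ss"] == pytest.approx(
                sse_r - full_sse, rel=1e-7
            )

    def test_partial_ss_invariant_to_run_order(self, ccrd_data, fitted_model, fitted_anova):
        order = np.random.default_rng(5).permutation(ccrd_data.design.n_runs)
        frame = ccrd_data.design.frame.iloc[order].reset_index(drop=True)
        shuffled = rm.ExperimentTable(
            design=rm.DesignTable(factors=ccrd_data.factors, frame=frame),
            response=ccrd_data.response[order],
        )
        aov = rm.anova(rm.fit_quadratic(shuffled), shuffled)
        np.testing.assert_allclose(
            aov.table["ss"].to_numpy(), fitted_anova.table["ss"].to_numpy(), rtol=1e-8
        )

    def test_noise_free_fit_has_zero_residual(self, factors):
        syn = rm.generate_synthetic(rm.SyntheticSpec(noise_sd=0.0))
        aov = rm.anova(rm.fit_quadratic(syn), syn)
        assert aov.table.loc["Residual", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert aov.summary["r_squared"] == pytest.approx(1.0)

    def test_no_replicates_marks_lack_of_fit_unavailable(self, factors, rng):
        design = rm.build_ccrd(factors, n_center=1)
        data = rm.ExperimentTable(
            design=design, response=rng.uniform(10, 40, design.n_runs)
        )
        aov = rm.anova(rm.fit_quadratic(data), data)
        assert aov.table.loc["Pure Error", "df"] == 0
        assert np.isnan(aov.table.loc["Lack of Fit", "F"])


class TestSurfaceGrid:
    def test_corner_consistency_with_predict(self, fitted_model):
        grid = rm.evaluate_surface_grid(fitted_model, ("X1", "X2"), resolution=2)
        assert len(grid) == 4
        for _, row in grid.iterrows():
            z = np.array([row["X1_coded"], row["X2_coded"], 0.0, 0.0])
            assert row["predicted"] == pytest.approx(
                fitted_model.predict(z, space="coded")
            )

    def test_fixed_settings_units_equivalent(self, fitted_model):
        g1 = rm.evaluate_surface_grid(
            fitted_model, ("X2", "X3"), fixed={"X1": 50.0, "X4": 120.0},
            resolution=11, fixed_space="actual",
        )
        g2 = rm.evaluate_surface_grid(
            fitted_model, ("X2", "X3"), fixed={"X1": 0.0, "X4": 0.0},
            resolution=11, fixed_space="coded",
        )
        np.testing.assert_allclose(g1["predicted"], g2["predicted"], rtol=1e-12)

    def test_grid_maximum_in_reported_window(self, fitted_model):
        """At center temperature and power, the highest predicted yield sits
        at 65-75% ethanol and 30-50 mL/g, the study's reported sweet spot."""
        grid = rm.evaluate_surface_grid(
            fitted_model, ("X2", "X3"), fixed={"X1": 50.0, "X4": 120.0},
            resolution=81,
        )
        top = grid.loc[grid["predicted"].idxmax()]
        assert 65.0 <= top["X2_actual"] <= 75.0
        assert 30.0 <= top["X3_actual"] <= 50.0
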