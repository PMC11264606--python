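import numpy as np
import pytest
from sklearn.base import clone

from prefscore.crosswalk import (
    EQ5D_TO_PROPR,
    PROPR_TO_EQ5D,
    BetaCrosswalkRegressor,
    CrosswalkModel,
    CrosswalkRegressor,
    apply_crosswalk,
    evaluate_map,
    evaluate_predictions,
    fit_beta_binomial_map,
    fit_ols_map,
    published_model,
    to_unit_interval,
)
from prefscore.exceptions import DegenerateFitError, ValidationError
from prefscore.synthetic import bivariate_moment_sample


@pytest.fixture(scope="module")
def study_moment_sample():
    # source PROPr, target EQ-5D-5L with the published baseline moments
    propr, eq5d = bivariate_moment_sample(50_000, 0.539, 0.249, 0.855, 0.195, 0.69, seed=21)
    return propr, eq5d


class TestOLSFit:
    def test_moment_matched_fit_matches_closed_form(self, study_moment_sample):
        propr, eq5d = study_moment_sample
        model = fit_ols_map(propr, eq5d, direction=PROPR_TO_EQ5D)
        slope = 0.69 * 0.195 / 0.249
        intercept = 0.855 - slope * 0.539
        assert model.slope == pytest.approx(slope, abs=1e-9)
        assert model.intercept == pytest.approx(intercept, abs=1e-9)
        # published constants were estimated on the real data; same ballpark
        assert model.slope == pytest.approx(0.543, abs=0.005)
        assert model.intercept == pytest.approx(0.563, abs=0.005)

    def test_identity_target(self, rng):
        x = rng.normal(size=100)
        model = fit_ols_map(x, x)
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_predicted_sd_is_slope_times_source_sd(self, rng):
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(scale=0.3, size=500)
        model = fit_ols_map(x, y)
        assert model.predicted_sd == pytest.approx(abs(model.slope) * x.std(ddof=1), rel=1e-10)

    def test_constant_source_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_ols_map(np.full(10, 0.5), np.arange(10.0))

    def test_estimator_clones_and_refits(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.1, size=50)
        est = CrosswalkRegressor(direction="custom").fit(x, y)
        reclone = clone(est).fit(x, y)
        assert reclone.slope_ == pytest.approx(est.slope_)
        assert est.predict(x).shape == (50,)


class TestPublishedModels:
    def test_slopes_and_clamps(self):
        fwd = published_model(PROPR_TO_EQ5D)
        back = published_model(EQ5D_TO_PROPR)
        assert fwd.slope == 0.543 and back.slope == 0.885
        assert (fwd.clamp_lower, fwd.clamp_upper) == (-0.573, 1.0)
        assert (back.clamp_lower, back.clamp_upper) == (-0.022, 1.0)

    def test_unknown_direction_raises(self):
        with pytest.raises(ValidationError):
            published_model("sideways")

    def test_slope_product_consistent_with_shared_correlation(self):
        # b_fwd * b_back = r^2 when both fits share one correlation
        prod = published_model(PROPR_TO_EQ5D).slope * published_model(EQ5D_TO_PROPR).slope
        assert prod == pytest.approx(0.69**2, abs=0.01)

    def test_ceiling_propr_clamps_to_one(self):
        model = published_model(PROPR_TO_EQ5D)
        predicted, equated, clamped = apply_crosswalk(model, np.array([0.954]), return_stages=True)
        assert predicted[0] == pytest.approx(1.081, abs=1e-3)
        assert equated[0] == pytest.approx(1.182, abs=1e-3)
        assert clamped[0] == 1.0

    def test_serialization_round_trip(self):
        model = published_model(EQ5D_TO_PROPR)
        assert CrosswalkModel.from_json(model.to_json()) == model


class TestApplyCrosswalk:
    def test_order_is_predict_equate_clamp(self, study_moment_sample):
        propr, eq5d = study_moment_sample
        model = fit_ols_map(propr, eq5d, clamp_bounds=(-0.573, 1.0))
        _, equated, clamped = apply_crosswalk(model, propr, return_stages=True)
        # pre-clamp equated scores carry exactly the target moments on the fit sample
        assert equated.mean() == pytest.approx(model.target_mean, rel=1e-10)
        assert equated.std(ddof=1) == pytest.approx(model.target_sd, rel=1e-10)
        assert clamped.min() >= -0.573 and clamped.max() <= 1.0

    def test_monotone_for_positive_slope(self):
        model = published_model(PROPR_TO_EQ5D)
        x = np.linspace(-0.022, 0.954, 200)
        out = apply_crosswalk(model, x)
        assert np.all(np.diff(out) >= -1e-12)

    def test_identity_equating(self, rng):
        x = rng.normal(size=200)
        predicted = 0.2 + 0.5 * x
        model = CrosswalkModel(
            direction="custom", intercept=0.2, slope=0.5,
            target_mean=float(predicted.mean()), target_sd=float(predicted.std(ddof=1)),
            predicted_sd=float(predicted.std(ddof=1)), clamp_lower=-10, clamp_upper=10,
        )
        assert apply_crosswalk(model, x) == pytest.approx(predicted, abs=1e-12)


class TestUnitInterval:
    def test_extremes_and_midpoint(self):
        scaled, tr = to_unit_interval(np.array([2.0, 4.0, 6.0]))
        assert scaled.tolist() == [0.0, 0.5, 1.0]

    def test_round_trip_identity(self, rng):
        x = rng.normal(size=100)
        scaled, tr = to_unit_interval(x)
        assert tr.inverse(scaled) == pytest.approx(x, abs=1e-12)

    def test_zero_range_raises(self):
        with pytest.raises(DegenerateFitError):
            to_unit_interval(np.full(5, 3.3))


class TestBetaFamilyMap:
    def test_parameter_recovery_within_two_ses(self):
        """Simulation-based check: refitting data drawn from the fitted family."""
        rng = np.random.default_rng(99)
        n, a, b, phi = 5000, 0.3, 0.8, 20.0
        x = rng.normal(size=n)
        mu = 1 / (1 + np.exp(-(a + b * x)))
        u = rng.beta(mu * phi, (1 - mu) * phi)
        # rescale to an arbitrary original scale; fit against the known range
        # so the logit-scale parameters stay identified
        from prefscore.crosswalk import UnitIntervalTransform
        tr = UnitIntervalTransform(minimum=-0.5, range_=1.5)
        y = tr.inverse(u)
        fit = fit_beta_binomial_map(x, y, mode="beta", transform=tr)
        assert abs(fit.params_["intercept"] - a) < 2 * fit.bse_["intercept"]
        assert abs(fit.params_["slope"] - b) < 2 * fit.bse_["slope"]

    def test_flat_relationship_gives_near_zero_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.beta(5, 5, size=2000)
        fit = fit_beta_binomial_map(x, y, mode="beta")
        assert abs(fit.params_["slope"]) < 3 * fit.bse_["slope"]

    def test_beta_binomial_mode_agrees_with_continuous(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=1500)
        mu = 1 / (1 + np.exp(-(0.2 + 0.7 * x)))
        y = rng.beta(mu * 15, (1 - mu) * 15)
        cont = fit_beta_binomial_map(x, y, mode="beta")
        disc = fit_beta_binomial_map(x, y, mode="beta-binomial", trials=100)
        assert disc.params_["slope"] == pytest.approx(cont.params_["slope"], abs=0.1)

    def test_predictions_return_to_original_scale(self, study_moment_sample):
        propr, eq5d = study_moment_sample
        fit = BetaCrosswalkRegressor(mode="beta").fit(propr[:5000], eq5d[:5000])
        pred = fit.predict(propr[:5000])
        assert eq5d[:5000].min() - 1e-9 <= pred.min() and pred.max() <= eq5d[:5000].max() + 1e-9


class TestEvaluation:
    def test_perfect_linear_map(self, rng):
        x = rng.normal(size=300)
        y = 1.0 + 2.0 * x
        model = fit_ols_map(x, y, clamp_bounds=(y.min() - 1, y.max() + 1))
        ev = evaluate_map(model, x, y)
        assert ev.adj_r2 == pytest.approx(1.0, abs=1e-10)
        assert ev.pearson_r == pytest.approx(1.0, abs=1e-10)
        assert ev.icc_random == pytest.approx(1.0, abs=1e-10)
        assert ev.nmae == pytest.approx(0.0, abs=1e-10)

    def test_five_row_worked_example(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mapped = np.array([1.5, 1.5, 3.0, 4.0, 4.5])
        ev = evaluate_predictions(obs, mapped)
        # hand computation of the components
        r_hand = np.corrcoef(obs, mapped)[0, 1]
        assert ev.pearson_r == pytest.approx(r_hand, abs=1e-12)
        assert ev.nmae == pytest.approx(np.mean(np.abs(obs - mapped)) / obs.std(ddof=1), abs=1e-12)
        assert ev.equated_mean == pytest.approx(mapped.mean())

    def test_moment_matched_cohort_beta_nmae_close_to_ols(self, study_moment_sample):
        propr, eq5d = study_moment_sample
        propr, eq5d = propr[:10_000], eq5d[:10_000]
        model = fit_ols_map(propr, eq5d)
        ols_ev = evaluate_map(model, propr, eq5d)
        beta = fit_beta_binomial_map(propr, eq5d, mode="beta")
        beta_ev = evaluate_predictions(eq5d, beta.predict(propr), n_params=3)
        assert beta_ev.nmae == pytest.approx(ols_ev.nmae, abs=0.1)
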