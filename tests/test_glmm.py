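"""Mixed-model engine: families, Laplace fits, prediction, variance explained, effect sizes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from concussion_profiles.glmm import (
    ConditionalEffect,
    ConvergenceError,
    EffectSize,
    ModelSpec,
    _make_family,
    classify_magnitude,
    cohens_d,
    contrast_between,
    fit_glmm,
    pearson_effect,
    predict_conditional,
    variance_explained,
    wald_term_test,
)


# ---------------------------------------------------------------------------
# family derivatives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "family,k,extra",
    [
        ("bernoulli", None, np.array([])),
        ("binomial_k", 6, np.array([])),
        ("poisson", None, np.array([])),
        ("nb2", None, np.array([np.log(1.7)])),
        ("zinb", None, np.array([np.log(1.7), -1.2])),
    ],
)
def test_family_derivatives_match_finite_differences(family, k, extra):
    fam = _make_family(family, k)
    rng = np.random.default_rng(0)
    eta = rng.normal(0.5, 1.0, 40)
    if family == "bernoulli":
        y = rng.integers(0, 2, 40).astype(float)
    elif family == "binomial_k":
        y = rng.integers(0, 7, 40).astype(float)
    else:
        y = rng.poisson(np.exp(np.clip(eta, None, 3)), 40).astype(float)
        y[:10] = 0  # make sure the zero branch is exercised
    h = 1e-6
    d1_num = (fam.loglik(y, eta + h, extra) - fam.loglik(y, eta - h, extra)) / (2 * h)
    h2 = 1e-4  # larger step: second differences amplify rounding error
    d2_num = (
        fam.loglik(y, eta + h2, extra)
        - 2 * fam.loglik(y, eta, extra)
        + fam.loglik(y, eta - h2, extra)
    ) / h2**2
    np.testing.assert_allclose(fam.d1(y, eta, extra), d1_num, rtol=1e-5, atol=1e-5)
    np.testing.assert_allclose(fam.d2(y, eta, extra), d2_num, rtol=1e-3, atol=1e-3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_bernoulli_intercept_recovers_logit_proportion():
    y = np.r_[np.ones(30), np.zeros(70)]
    fit = fit_glmm(ModelSpec("y", "bernoulli"), pd.DataFrame({"y": y}))
    assert fit.coef.iloc[0] == pytest.approx(np.log(30 / 70), abs=1e-6)
    assert fit.converged


def test_zinb_matches_statsmodels_zero_inflated_oracle():
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

    rng = np.random.default_rng(1)
    n = 600
    x = rng.normal(size=n)
    mu = np.exp(1.2 + 0.4 * x)
    theta, pi = 2.0, 0.25
    y = np.where(
        rng.random(n) < pi, 0, rng.negative_binomial(theta, theta / (theta + mu))
    )
    fit = fit_glmm(ModelSpec("y", "zinb", terms=["x"]), pd.DataFrame({"y": y, "x": x}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oracle = ZeroInflatedNegativeBinomialP(
            y, sm.add_constant(x), exog_infl=np.ones((n, 1)), p=2
        ).fit(disp=0, maxiter=300)
    np.testing.assert_allclose(fit.coef.to_numpy(), oracle.params[1:3], atol=1e-3)
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-3)
    assert fit.zi_prob == pytest.approx(expit(oracle.params[0]), abs=1e-3)


def test_random_intercept_vanishes_on_exchangeable_data():
    rng = np.random.default_rng(2)
    n = 600
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    df = pd.DataFrame({"y": y, "x": x, "grp": [f"g{i % 8}" for i in range(n)]})
    plain = fit_glmm(ModelSpec("y", "poisson", terms=["x"]), df)
    mixed = fit_glmm(ModelSpec("y", "poisson", terms=["x"], groups=["grp"]), df)
    # the ML variance estimate stays slightly positive on a finite sample
    # (glmmTMB gives the identical estimate), so the GLM collapse is approximate
    np.testing.assert_allclose(mixed.coef.to_numpy(), plain.coef.to_numpy(), atol=2e-3)
    assert mixed.variance_components["grp"] < 0.01


def test_zinb_nests_poisson_in_the_limit():
    rng = np.random.default_rng(3)
    n = 800
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    df = pd.DataFrame({"y": y, "x": x})
    fit = fit_glmm(ModelSpec("y", "zinb", terms=["x"]), df)
    assert fit.zi_prob < 0.02  # no structural zeros in the data
    np.testing.assert_allclose(fit.coef.to_numpy(), [1.0, 0.5], atol=0.1)


def test_single_level_group_dropped_with_warning():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {"y": rng.poisson(3.0, 100).astype(float), "grp": ["only"] * 100}
    )
    with pytest.warns(UserWarning, match="dropped"):
        fit = fit_glmm(ModelSpec("y", "poisson", groups=["grp"]), df)
    assert fit.variance_components == {}


def test_loglik_is_recomputable_at_reported_parameters():
    rng = np.random.default_rng(5)
    y = rng.negative_binomial(2.0, 2.0 / 7.0, 300).astype(float)
    df = pd.DataFrame({"y": y})
    fit = fit_glmm(ModelSpec("y", "nb2"), df)
    fam = _make_family("nb2", None)
    eta = np.full(300, fit.coef.iloc[0])
    ll = fam.loglik(y, eta, np.array([np.log(fit.theta)])).sum()
    assert ll == pytest.approx(fit.loglik, abs=1e-6)


def test_constant_response_is_an_explicit_error():
    df = pd.DataFrame({"y": np.ones(50)})
    with pytest.raises(ValueError, match="constant"):
        fit_glmm(ModelSpec("y", "bernoulli"), df)


# ---------------------------------------------------------------------------
# prediction and contrasts
# ---------------------------------------------------------------------------


def test_intercept_only_prediction_equals_sample_proportion():
    y = np.r_[np.ones(42), np.zeros(58)]
    fit = fit_glmm(ModelSpec("y", "bernoulli"), pd.DataFrame({"y": y}))
    eff = predict_conditional(fit, pd.DataFrame({"dummy": [0.0]}))
    assert eff.estimate[0] == pytest.approx(0.42, abs=1e-6)
    assert eff.lower[0] <= eff.estimate[0] <= eff.upper[0]


def test_ci_width_shrinks_with_sample_size():
    widths = []
    for n in (100, 10000):
        rng = np.random.default_rng(6)
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        fit = fit_glmm(
            ModelSpec("y", "poisson", terms=["x"]), pd.DataFrame({"y": y, "x": x})
        )
        eff = predict_conditional(fit, pd.DataFrame({"x": [0.0]}))
        widths.append(eff.upper[0] - eff.lower[0])
    assert widths[1] < widths[0] / 5


def test_prediction_monotone_in_linear_predictor():
    rng = np.random.default_rng(7)
    x = rng.normal(size=400)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    fit = fit_glmm(ModelSpec("y", "poisson", terms=["x"]), pd.DataFrame({"y": y, "x": x}))
    grid = pd.DataFrame({"x": np.linspace(-2, 2, 20)})
    eff = predict_conditional(fit, grid)
    assert np.all(np.diff(eff.eta) > 0) and np.all(np.diff(eff.estimate) > 0)


def test_contrast_and_term_test_roundtrip():
    rng = np.random.default_rng(8)
    n = 500
    sex = rng.choice(["female", "male"], n)
    y = rng.poisson(np.exp(1.0 + 0.4 * (sex == "male")))
    df = pd.DataFrame({"y": y, "sex": sex})
    fit = fit_glmm(ModelSpec("y", "poisson", terms=["sex"]), df)
    grid = pd.DataFrame({"sex": ["male", "female"]})
    c = contrast_between(fit, grid, 0, 1)
    assert c["eta_diff"] == pytest.approx(0.4, abs=0.15)
    assert c["p"] < 0.001
    wald = wald_term_test(fit, "sex")
    assert wald["df"] == 1 and wald["p"] < 0.001
    with pytest.raises(ValueError, match="not in model"):
        wald_term_test(fit, "age")


def test_conditional_effect_bounds_validated():
    with pytest.raises(ValueError):
        ConditionalEffect(
            grid=pd.DataFrame({"x": [0]}),
            estimate=np.array([1.0]),
            lower=np.array([2.0]),
            upper=np.array([3.0]),
            eta=np.array([0.0]),
            eta_se=np.array([0.1]),
        )


# ---------------------------------------------------------------------------
# variance explained and effect sizes
# ---------------------------------------------------------------------------


def test_variance_explained_null_and_nested_models():
    rng = np.random.default_rng(9)
    n = 800
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.8 + 0.6 * x))
    df = pd.DataFrame({"y": y, "x": x})
    null = fit_glmm(ModelSpec("y", "poisson"), df)
    ve_null = variance_explained(null, df)
    assert ve_null["marginal_r2"] == pytest.approx(0.0, abs=1e-10)
    with_x = fit_glmm(ModelSpec("y", "poisson", terms=["x"]), df)
    ve_x = variance_explained(with_x, df)
    assert ve_x["marginal_r2"] > ve_null["marginal_r2"]
    assert ve_x["marginal_r2"] <= ve_x["conditional_r2"] <= 1.0


def test_variance_explained_collapses_without_group_variance():
    rng = np.random.default_rng(10)
    n = 800
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.8 + 0.6 * x))
    df = pd.DataFrame({"y": y, "x": x, "grp": [f"g{i % 6}" for i in range(n)]})
    fit = fit_glmm(ModelSpec("y", "poisson", terms=["x"], groups=["grp"]), df)
    ve = variance_explained(fit, df)
    assert ve["conditional_r2"] == pytest.approx(ve["marginal_r2"], abs=0.01)
    assert ve["random_share_of_explained"] < 0.02


def test_variance_explained_requires_convergence():
    fit = fit_glmm(
        ModelSpec("y", "poisson"), pd.DataFrame({"y": np.random.default_rng(0).poisson(3, 50)})
    )
    object.__setattr__(fit, "converged", False)
    with pytest.raises(ConvergenceError):
        variance_explained(fit, pd.DataFrame({"y": [1]}))


class TestEffectSizes:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "nominal"), (0.16, "nominal"), (0.2, "small"), (0.5, "medium"),
         (0.79, "medium"), (0.8, "large"), (-0.6, "medium")],
    )
    def test_cohens_d_bands(self, value, expected):
        assert cohens_d(value, 1.0).magnitude == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.3, "nominal"), (0.7, "small"), (0.85, "medium"), (0.95, "large")],
    )
    def test_pearson_bands(self, value, expected):
        assert classify_magnitude(pearson_effect(value)) == expected

    def test_guards(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0)
        with pytest.raises(ValueError):
            EffectSize("pearson_r", 1.2)
        with pytest.raises(ValueError):
            EffectSize("eta_squared", 0.1)

    def test_d_scales_with_dispersion(self):
        assert cohens_d(4.0, 25.0).value == pytest.approx(0.16)
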