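import warnings

import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.special import expit

from pencure import (
    BaselineHazard,
    CureModelParams,
    FitOptions,
    FitResult,
    conditional_survival,
    cure_probability,
    e_step,
    fit_full_model,
    generate_cohort,
    incidence_probability,
    m_step_incidence,
    m_step_latency,
    population_survival,
    recode_cause_specific,
)
from pencure.synthetic import CovariateSpec, SyntheticTruth


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def test_incidence_probability_values():
    assert incidence_probability([], [0.0]) == pytest.approx(0.5)
    # intercept-only incidence at -0.37: susceptibility and cure fraction
    assert incidence_probability([], [-0.37]) == pytest.approx(0.4086, abs=1e-4)
    assert cure_probability([], [-0.37]) == pytest.approx(0.5914, abs=1e-4)
    # intercept -0.34 plus one indicator at -1.14
    assert incidence_probability([1.0], [-0.34, -1.14]) == pytest.approx(
        expit(-1.48), abs=1e-12
    )
    assert cure_probability([], [-0.75]) == pytest.approx(0.6792, abs=1e-4)


def test_incidence_cure_conservation(rng):
    theta = rng.normal(0, 1, 4)
    for _ in range(10):
        x = rng.normal(0, 2, 3)
        assert incidence_probability(x, theta) + cure_probability(x, theta) == 1.0


def test_incidence_dimension_mismatch():
    with pytest.raises(ValueError):
        incidence_probability([1.0, 2.0], [0.1])


def test_conditional_survival_breslow_arithmetic():
    base = BaselineHazard([1.0, 2.0], [1 / 3, 1 / 2])
    params = CureModelParams([0.0, 0.0], [0.0], base)
    assert conditional_survival(0.0, [0.0], params) == 1.0
    assert conditional_survival(1.5, [0.0], params) == pytest.approx(
        np.exp(-1 / 3), abs=1e-4
    )
    # zero-tail: beyond the last event time survival is 0
    assert conditional_survival(2.5, [0.0], params) == 0.0
    with pytest.raises(ValueError):
        conditional_survival(-1.0, [0.0], params)


def test_population_survival_mixture_arithmetic():
    base = BaselineHazard([1.0], [np.log(2.0)])  # S0(1) = 0.5
    theta = [np.log(0.4 / 0.6)]  # pi = 0.4
    params = CureModelParams(theta, [], base)
    assert population_survival(0.0, [], params) == pytest.approx(1.0)
    assert population_survival(1.0, [], params) == pytest.approx(0.8)
    # plateau equals the cure probability
    assert population_survival(99.0, [], params) == pytest.approx(
        cure_probability([], theta)
    )


def test_population_survival_nonincreasing(rng):
    base = BaselineHazard([1.0, 2.0, 4.0], [0.2, 0.3, 0.6])
    params = CureModelParams([0.3, 0.5], [0.7], base, ["x0"])
    x = [1.0]
    grid = np.linspace(0, 5, 60)
    vals = [population_survival(t, x, params) for t in grid]
    assert np.all(np.diff(vals) <= 1e-12)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def test_e_step_weight_algebra(cohort_factory):
    base = BaselineHazard([2.0], [0.5])
    params = CureModelParams([0.0], [], base)  # pi = 0.5
    cohort = cohort_factory([2.0, 1.0, 3.0], [1, 0, 0])
    state = e_step(cohort, params)
    assert state.weights[0] == 1.0                     # event
    assert state.weights[1] == pytest.approx(0.5)      # censored before any event
    assert state.weights[2] == 0.0                     # censored beyond the tail
    assert np.all((state.weights >= 0) & (state.weights <= 1))


# ---------------------------------------------------------------------------
# M-step oracles
# ---------------------------------------------------------------------------

def test_m_step_incidence_symmetry(cohort_factory):
    cohort = cohort_factory([1, 2, 3, 4], [1, 0, 1, 0])
    theta = m_step_incidence(cohort, [0.5, 0.5, 0.5, 0.5])
    assert theta[0] == pytest.approx(0.0, abs=1e-8)


def test_m_step_incidence_separation_capped(cohort_factory):
    cohort = cohort_factory([1, 2, 3], [1, 1, 1])
    with pytest.warns(RuntimeWarning, match="separation"):
        theta = m_step_incidence(cohort, [1.0, 1.0, 1.0])
    assert abs(theta[0]) == pytest.approx(50.0)


def test_m_step_incidence_matches_direct_maximizer(small_weighted_fixture):
    """Weighted logistic Newton vs an independent simplex maximizer."""
    cohort, w = small_weighted_fixture
    theta = m_step_incidence(cohort, w)
    Xd = np.hstack([np.ones((cohort.n, 1)), cohort.X])

    def negll(c):
        eta = Xd @ c
        return -np.sum(w * eta - np.logaddexp(0.0, eta))

    res = minimize(negll, np.zeros(3), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    np.testing.assert_allclose(theta, res.x, atol=1e-3)


def test_m_step_latency_breslow_hand_example(cohort_factory):
    # beta forced to zero: no covariates; increments d_k / |risk set|
    cohort = cohort_factory([1.0, 2.0, 3.0], [1, 1, 0])
    beta, base = m_step_latency(cohort, [1.0, 1.0, 1.0])
    assert beta.size == 0
    np.testing.assert_allclose(base.times, [1.0, 2.0])
    np.testing.assert_allclose(base.increments, [1 / 3, 1 / 2])


def test_m_step_latency_matches_lifelines_unit_weights(small_weighted_fixture):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    cohort, _ = small_weighted_fixture
    beta, _ = m_step_latency(cohort, np.ones(cohort.n))
    df = pd.DataFrame(cohort.X, columns=["x0", "x1"])
    df["T"] = cohort.time
    df["E"] = (cohort.cause >= 1).astype(int)
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-4)


def test_m_step_latency_scalar_score_root(cohort_factory):
    """Single covariate MLE vs a 1-d root of the directly-enumerated score."""
    times = [1.0, 2.0, 3.0, 4.0]
    events = [1, 1, 0, 1]
    x = np.array([1.0, 0.0, 1.0, 0.0])
    cohort = cohort_factory(times, events, x[:, None])
    beta, _ = m_step_latency(cohort, np.ones(4))

    def score(b):
        # risk sets at event times 1, 2, 4 (descending time order)
        s = 0.0
        for i, t in enumerate(times):
            if not events[i]:
                continue
            risk = [j for j in range(4) if times[j] >= t]
            num = sum(x[j] * np.exp(b * x[j]) for j in risk)
            den = sum(np.exp(b * x[j]) for j in risk)
            s += x[i] - num / den
        return s

    root = brentq(score, -10, 10, xtol=1e-12)
    assert beta[0] == pytest.approx(root, abs=1e-6)


def test_m_step_latency_requires_events(cohort_factory):
    with pytest.raises(ValueError):
        m_step_latency(cohort_factory([1, 2], [0, 0]), [0.5, 0.5])


def test_weight_bounds_enforced(cohort_factory):
    cohort = cohort_factory([1, 2], [1, 0])
    with pytest.raises(ValueError):
        m_step_incidence(cohort, [1.5, 0.2])
    with pytest.raises(ValueError):
        m_step_latency(cohort, [-0.1, 0.5])


# ---------------------------------------------------------------------------
# full EM fit
# ---------------------------------------------------------------------------

def _one_cov_truth(n, seed):
    return SyntheticTruth(
        n=n, seed=seed,
        covariates=(CovariateSpec("x0", p=0.5),),
        theta_star=(0.5, 1.0), beta_relapse=(-0.8,), beta_death=None,
        relapse_shape=1.0, relapse_scale=8.0, censor_rate=0.01, horizon=200.0,
    )


def test_fit_recovers_simulated_truth():
    cohort, _ = generate_cohort(_one_cov_truth(1000, 7))
    fit = fit_full_model(cohort)
    assert fit.converged
    np.testing.assert_allclose(fit.params.theta, [0.5, 1.0], atol=0.15)
    np.testing.assert_allclose(fit.params.beta, [-0.8], atol=0.15)


def test_fit_loglik_monotone_trace():
    cohort, _ = generate_cohort(_one_cov_truth(150, 3))
    fit = fit_full_model(cohort)
    diffs = np.diff(fit.trace)
    assert np.all(diffs >= -1e-8)


def test_fit_reduces_to_cox_without_censoring(cohort_factory, rng):
    """Everyone susceptible (no censoring): latency equals a plain Cox fit."""
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    n = 40
    x = rng.normal(0, 1, n)
    times = rng.exponential(5, n) * np.exp(-0.5 * x) + 0.01
    cohort = cohort_factory(times, np.ones(n, dtype=int), x[:, None])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_full_model(cohort)
    df = pd.DataFrame({"x0": x, "T": times, "E": 1})
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.params.beta, cph.params_.to_numpy(), atol=1e-4)
    assert any("separation" in w for w in fit.warnings)


def test_fit_prunes_duplicate_columns(cohort_factory, rng):
    n = 60
    x = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(5, n) + 0.1
    causes = rng.integers(0, 2, n)
    causes[:5] = 1
    X = np.column_stack([x, x])  # identical columns
    with pytest.warns(RuntimeWarning, match="collinear"):
        fit = fit_full_model(cohort_factory(times, causes, X, cause_set={0, 1}))
    assert fit.params.beta[1] == 0.0  # pruned column re-embedded as 0


def test_fit_refuses_without_events(cohort_factory):
    with pytest.raises(ValueError):
        fit_full_model(cohort_factory([1, 2, 3], [0, 0, 0]))


def test_fit_result_json_round_trip():
    cohort, _ = generate_cohort(_one_cov_truth(120, 11))
    fit = fit_full_model(cohort)
    back = FitResult.from_json(fit.to_json())
    np.testing.assert_allclose(back.params.theta, fit.params.theta)
    np.testing.assert_allclose(back.params.beta, fit.params.beta)
    assert back.aic == pytest.approx(fit.aic)
    assert back.n == fit.n
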