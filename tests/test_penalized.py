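import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pencure import (
    FitOptions,
    PenaltySpec,
    fit_full_model,
    fit_penalized,
    generate_cohort,
    lasso_penalty,
    penalized_m_step,
    scad_derivative,
    scad_penalty,
    sparse_scenario,
    tune_lambda,
)
from pencure.cure_em import _weighted_logistic, _with_intercept


def test_lasso_penalty_values():
    assert lasso_penalty(0.0, 0.7) == 0.0
    assert lasso_penalty(-2.0, 0.5) == pytest.approx(1.0)
    assert lasso_penalty(3.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        lasso_penalty(1.0, -0.1)


def test_scad_derivative_branches():
    assert scad_derivative(0.3, 0.5, 3.7) == pytest.approx(0.5)      # b < lambda
    assert scad_derivative(3.0, 0.5, 3.7) == 0.0                     # b >= a*lambda
    assert scad_derivative(1.0, 0.5, 3.7) == pytest.approx(
        (3.7 * 0.5 - 1.0) / 2.7, abs=1e-4
    )
    # continuity at b = lambda
    assert scad_derivative(0.5, 0.5, 3.7) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        scad_derivative(1.0, 0.5, a=2.0)


@given(lam=st.floats(0.01, 2.0), a=st.floats(2.1, 8.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_scad_penalty_shape_properties(lam, a):
    """SCAD is continuous, nondecreasing, linear below lambda, flat past a*lambda."""
    b = np.linspace(0, 1.5 * a * lam, 400)
    p = scad_penalty(b, lam, a)
    assert np.all(np.diff(p) >= -1e-12)
    small = b <= lam
    np.testing.assert_allclose(p[small], lam * b[small], atol=1e-12)
    flat = b >= a * lam
    np.testing.assert_allclose(p[flat], (a + 1) * lam**2 / 2, atol=1e-12)
    # derivative is the slope of the penalty (finite differences)
    mid = (b[1:] + b[:-1]) / 2
    fd = np.diff(p) / np.diff(b)
    np.testing.assert_allclose(fd, scad_derivative(mid, lam, a), atol=1e-3)


def test_penalty_spec_validation():
    with pytest.raises(ValueError):
        PenaltySpec("ridge", 0.1)
    with pytest.raises(ValueError):
        PenaltySpec("scad", -0.1)
    with pytest.raises(ValueError):
        PenaltySpec("scad", 0.1, a=1.5)
    PenaltySpec("lasso", 0.0)  # lambda 0 allowed


def test_penalized_m_step_lambda_zero_is_unpenalized(small_weighted_fixture):
    cohort, w = small_weighted_fixture
    current = np.array([0.1, -0.2, 0.3])
    pen = penalized_m_step("incidence", cohort, w, PenaltySpec("lasso", 0.0), current)
    unpen, _, _ = _weighted_logistic(_with_intercept(cohort.X), w, init=current)
    np.testing.assert_allclose(pen, unpen, atol=1e-10)


def test_penalized_m_step_saturation(small_weighted_fixture):
    cohort, w = small_weighted_fixture
    current = np.array([0.1, 0.4, -0.5])
    pen = penalized_m_step("incidence", cohort, w, PenaltySpec("lasso", 50.0), current)
    np.testing.assert_array_equal(pen[1:], 0.0)
    assert pen[0] != 0.0  # intercept survives


def test_penalized_m_step_matches_grid_oracle(cohort_factory, rng):
    """1-covariate LASSO logistic vs a brute-force grid on the same objective."""
    n = 20
    x = rng.integers(0, 2, n).astype(float)
    w = rng.uniform(0.1, 1.0, n)
    cohort = cohort_factory(np.arange(1, n + 1.0), (w > 0.5).astype(int),
                            x[:, None], cause_set={0, 1})
    lam = 0.2
    est = penalized_m_step("incidence", cohort, w, PenaltySpec("lasso", lam),
                           np.array([0.0, 0.5]))

    Xd = _with_intercept(cohort.X)

    def objective(a, b):
        eta = Xd @ np.array([a, b])
        return np.sum(w * eta - np.logaddexp(0, eta)) - n * lam * abs(b)

    grid_a = np.linspace(-3, 3, 601)
    grid_b = np.linspace(-3, 3, 601)
    # vectorized evaluation of the same objective over the grid
    eta = (grid_a[:, None, None] + x[None, None, :] * grid_b[None, :, None])
    ll = (w * eta - np.logaddexp(0, eta)).sum(axis=2)
    vals = ll - n * lam * np.abs(grid_b)[None, :]
    ia, ib = np.unravel_index(np.argmax(vals), vals.shape)
    assert est[0] == pytest.approx(grid_a[ia], abs=1e-2)
    assert est[1] == pytest.approx(grid_b[ib], abs=1e-2)
    # our estimate attains at least the best grid objective
    assert objective(est[0], est[1]) >= vals[ia, ib] - 1e-8


def test_penalized_objective_monotone_over_m_steps(small_weighted_fixture):
    cohort, w = small_weighted_fixture
    spec = PenaltySpec("scad", 0.1)
    Xd = _with_intercept(cohort.X)
    n = cohort.n

    def pen_obj(c):
        eta = Xd @ c
        return (np.sum(w * eta - np.logaddexp(0, eta))
                - n * np.sum(spec.penalty(np.abs(c[1:]))))

    current = np.array([0.05, 0.8, -0.9])
    objs = [pen_obj(current)]
    for _ in range(4):
        current = penalized_m_step("incidence", cohort, w, spec, current)
        objs.append(pen_obj(current))
    assert np.all(np.diff(objs) >= -1e-9)


def test_fit_penalized_lambda_zero_equals_full_model():
    cohort, _ = generate_cohort(sparse_scenario(n=300, seed=9))
    full = fit_full_model(cohort)
    pen = fit_penalized(cohort, PenaltySpec("scad", 0.0))
    np.testing.assert_allclose(pen.params.theta, full.params.theta, atol=1e-4)
    np.testing.assert_allclose(pen.params.beta, full.params.beta, atol=1e-4)


def test_shrinkage_near_monotone_along_path():
    cohort, _ = generate_cohort(sparse_scenario(n=400, seed=5))
    tun = tune_lambda(cohort, "lasso", criterion="bic",
                      options=FitOptions(tol=1e-5, max_iter=200))
    dfs = tun.table["df"].to_numpy()  # ascending lambda
    assert np.all(np.diff(dfs) <= 1)  # near-monotone decreasing nonzero count


def test_tuning_criterion_arithmetic():
    # AIC = -2 loglik + 2 df ; BIC = -2 loglik + ln(n) df
    loglik, df, n = -100.0, 5, 178
    assert -2 * loglik + 2 * df == pytest.approx(210.0)
    bic = -2 * loglik + np.log(n) * df
    assert bic == pytest.approx(225.91, abs=0.01)


def test_tune_lambda_table_consistency():
    cohort, _ = generate_cohort(sparse_scenario(n=300, seed=2))
    tun = tune_lambda(cohort, "scad", lambda_grid=[0.0, 0.05, 0.2],
                      criterion="bic", options=FitOptions(tol=1e-5, max_iter=200))
    tab = tun.table
    for _, row in tab.iterrows():
        fit = tun.fits[int(np.argmax(tun.lambdas == row["lambda"]))]
        assert row["aic"] == pytest.approx(-2 * fit.loglik + 2 * fit.df)
        assert row["bic"] == pytest.approx(-2 * fit.loglik + np.log(fit.n) * fit.df)
    sel = tun.selected_lambda["bic"]
    assert tab.loc[tab["lambda"] == sel, "bic"].iloc[0] == tab["bic"].min()


def test_tune_lambda_singleton_grid_and_ties():
    cohort, _ = generate_cohort(sparse_scenario(n=200, seed=4))
    tun = tune_lambda(cohort, "lasso", lambda_grid=[0.0], criterion="aic")
    assert tun.selected_lambda["aic"] == 0.0
    # duplicate criterion values: the larger lambda must win the tie
    big = tune_lambda(cohort, "lasso", lambda_grid=[5.0, 10.0], criterion="bic",
                      options=FitOptions(tol=1e-5, max_iter=100))
    vals = big.table["bic"].to_numpy()
    if vals[0] == vals[1]:
        assert big.selected_lambda["bic"] == 10.0


def test_tune_lambda_invalid_inputs():
    cohort, _ = generate_cohort(sparse_scenario(n=150, seed=1))
    with pytest.raises(ValueError):
        tune_lambda(cohort, "scad", lambda_grid=[], criterion="bic")
    with pytest.raises(ValueError):
        tune_lambda(cohort, "scad", lambda_grid=[0.1], criterion="hqc")
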