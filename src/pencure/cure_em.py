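"""Semi-parametric mixture cure model fitted by EM.

The population survival for a subject with covariates x is

    S_pop(t | x) = (1 - pi(x)) + pi(x) * S_u(t | x),

where pi(x) = expit(x'theta) is the logistic *incidence* probability of
being susceptible (uncured), and the *latency* S_u(t | x) =
S_0(t)^exp(x'beta) is a Cox proportional-hazards survival for the
susceptible, with a nonparametric Breslow baseline.  A zero-tail
constraint (S_u = 0 beyond the largest event time) identifies the cure
fraction.  Estimation alternates:

  E-step  posterior uncured weights w_i for censored subjects,
  M-step  weighted logistic regression for theta and a weighted Cox
          partial likelihood with Breslow baseline for beta,

both solved by Newton iterations with step-halving, optionally with a
penalty on the coefficients (see :mod:`pencure.penalized`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp  # noqa: F401  (expit used throughout)

from .cohort import CohortTable

__all__ = [
    "BaselineHazard",
    "CureModelParams",
    "EMState",
    "FitOptions",
    "FitResult",
    "incidence_probability",
    "cure_probability",
    "conditional_survival",
    "population_survival",
    "e_step",
    "m_step_incidence",
    "m_step_latency",
    "fit_full_model",
]

COEF_CAP = 50.0  # |coefficient| bound; hitting it flags separation
_EPS_LOG = 1e-300


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard: jumps at event times.

    ``tail_time`` is the largest event time; the conditional susceptible
    survival is truncated to zero beyond it (zero-tail constraint).
    """

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("baseline event times must be strictly increasing")
        if np.any(self.increments < 0):
            raise ValueError("baseline hazard increments must be nonnegative")

    @property
    def tail_time(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0

    def cumhaz(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        csum = np.concatenate([[0.0], np.cumsum(self.increments)])
        return csum[idx]

    def survival(self, t) -> np.ndarray:
        """Baseline survival exp(-H0(t)), zero beyond the last event time."""
        t = np.asarray(t, dtype=float)
        s = np.exp(-self.cumhaz(t))
        return np.where(t > self.tail_time, 0.0, s)

    def increment_at(self, t) -> np.ndarray:
        """Hazard mass at exact event times (0 elsewhere)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t)
        idx = np.clip(idx, 0, max(self.times.size - 1, 0))
        out = np.zeros(t.shape)
        if self.times.size:
            hit = self.times[idx] == t
            out[hit] = self.increments[idx[hit]]
        return out


@dataclass
class CureModelParams:
    """Fitted mixture cure parameters.

    theta: incidence coefficients with leading intercept (length p+1);
    beta: latency coefficients (length p, no intercept); baseline: the
    Breslow cumulative hazard of the latency component.
    """

    theta: np.ndarray
    beta: np.ndarray
    baseline: BaselineHazard
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta.ndim != 1 or self.beta.ndim != 1:
            raise ValueError("theta and beta must be vectors")
        if self.theta.size != self.beta.size + 1:
            raise ValueError("theta must have exactly one more entry (intercept) than beta")
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.beta))):
            raise ValueError("parameters must be finite")


@dataclass
class EMState:
    """Per-iteration EM snapshot: posterior uncured weights and log-likelihood."""

    weights: np.ndarray
    loglik: float
    iteration: int = 0


# ---------------------------------------------------------------------------
# elementary model quantities
# ---------------------------------------------------------------------------

def _with_intercept(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.hstack([np.ones((x.shape[0], 1)), x])


def incidence_probability(x, theta) -> np.ndarray | float:
    """P(susceptible | x) = expit(theta0 + x'theta_rest), overflow-safe."""
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim <= 1
    xd = _with_intercept(x)
    if xd.shape[1] != theta.size:
        raise ValueError(
            f"dimension mismatch: x gives {xd.shape[1]} columns with intercept, "
            f"theta has {theta.size}"
        )
    p = expit(xd @ theta)
    return float(p[0]) if scalar else p


def cure_probability(x, theta) -> np.ndarray | float:
    """P(cured | x) = 1 - incidence_probability(x, theta)."""
    p = incidence_probability(x, theta)
    return 1.0 - p


def conditional_survival(t, x, params: CureModelParams) -> np.ndarray | float:
    """Susceptible survival S_u(t|x) = S_0(t)^exp(x'beta), zero-tailed."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    eta = x @ params.beta
    h = params.baseline.cumhaz(t_arr)
    s = np.exp(-h * np.exp(np.clip(eta, -700, 700)))
    s = np.where(t_arr > params.baseline.tail_time, 0.0, s)
    return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s


def population_survival(t, x, params: CureModelParams) -> np.ndarray | float:
    """Mixture survival (1-pi) + pi * S_u(t|x); plateaus at the cure probability."""
    pi = incidence_probability(x, params.theta)
    su = conditional_survival(t, x, params)
    return (1.0 - pi) + pi * su


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def _estep_arrays(time, delta, X, theta, beta, baseline):
    """Posterior uncured weights and the observed-data log-likelihood."""
    eta_inc = _with_intercept(X) @ theta
    pi = expit(eta_inc)
    eta_lat = np.clip(X @ beta, -700, 700)
    h0 = baseline.cumhaz(time)
    su = np.exp(-h0 * np.exp(eta_lat))
    su = np.where(time > baseline.tail_time, 0.0, su)

    denom = (1.0 - pi) + pi * su
    w = np.where(delta == 1, 1.0, pi * su / np.clip(denom, _EPS_LOG, None))
    w = np.clip(w, 0.0, 1.0)

    inc = baseline.increment_at(time)
    ev = delta == 1
    ll_event = (
        np.log(np.clip(pi[ev], _EPS_LOG, None))
        + np.log(np.clip(inc[ev], _EPS_LOG, None))
        + eta_lat[ev]
        - h0[ev] * np.exp(eta_lat[ev])
    )
    ll_cens = np.log(np.clip(denom[~ev], _EPS_LOG, None))
    return w, float(ll_event.sum() + ll_cens.sum())


def e_step(cohort: CohortTable, params: CureModelParams, iteration: int = 0) -> EMState:
    """Posterior probability of being uncured for each subject.

    Subjects with the event have weight exactly 1; censored subjects get
    w = pi S_u / (1 - pi + pi S_u) evaluated at their follow-up time.
    """
    X = cohort.X
    if X.shape[1] + 1 != params.theta.size:
        raise ValueError("parameter dimensions do not match cohort covariates")
    delta = (cohort.cause >= 1).astype(int)
    w, ll = _estep_arrays(cohort.time, delta, X, params.theta, params.beta, params.baseline)
    return EMState(weights=w, loglik=ll, iteration=iteration)


# ---------------------------------------------------------------------------
# weighted logistic M-step (Newton with step-halving)
# ---------------------------------------------------------------------------

def _logistic_objective(coef, Xd, w, pen=None):
    eta = Xd @ coef
    ll = float(np.sum(w * eta - np.logaddexp(0.0, eta)))
    if pen is not None:
        ll -= pen(coef)
    return ll


_SEP_DETECT = 15.0  # |coefficient| beyond this (working scale) flags separation


def _resolve_separation(coef, obj, separation, cap, objective):
    """Push runaway coefficients to the declared cap when that does not
    hurt the objective (the likelihood is flat along a separated
    direction, so the finite 'estimate' is reported at the bound)."""
    runaway = np.abs(coef) >= _SEP_DETECT
    if not np.any(runaway):
        return coef, obj, separation
    cand = coef.copy()
    cand[runaway] = np.sign(coef[runaway]) * cap
    cand_obj = objective(cand)
    if cand_obj >= obj - 1e-9:
        return cand, cand_obj, True
    return coef, obj, True


def _weighted_logistic(Xd, w, init=None, pen_deriv=None, pen=None,
                       tol=1e-8, max_iter=200, cap=COEF_CAP):
    """Maximize sum_i w_i log p_i + (1-w_i) log(1-p_i) (optionally penalized).

    pen_deriv(coef) returns the LQA diagonal D (0 for unpenalized coords);
    pen(coef) the penalty value, used only for step-halving acceptance.
    Returns (coef, converged, separation_flag).
    """
    n, k = Xd.shape
    coef = np.zeros(k) if init is None else np.array(init, dtype=float)
    separation = False
    converged = False
    obj = _logistic_objective(coef, Xd, w, pen)
    for _ in range(max_iter):
        eta = Xd @ coef
        p = expit(eta)
        grad = Xd.T @ (w - p)
        wt = np.clip(p * (1.0 - p), 1e-12, None)
        hess = (Xd * wt[:, None]).T @ Xd
        if pen_deriv is not None:
            D = pen_deriv(coef)
            grad = grad - D * coef
            hess = hess + np.diag(D)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            hess = hess + 1e-8 * np.eye(k)
            step = np.linalg.solve(hess, grad)
        # trust-region style cap on the raw step
        smax = np.max(np.abs(step))
        if smax > 10.0:
            step = step * (10.0 / smax)
        # candidates are clipped to the coefficient box *before* the
        # acceptance check, so the objective never decreases even when
        # separation drives coefficients to the cap
        new = np.clip(coef + step, -cap, cap)
        new_obj = _logistic_objective(new, Xd, w, pen)
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 30:
            step *= 0.5
            new = np.clip(coef + step, -cap, cap)
            new_obj = _logistic_objective(new, Xd, w, pen)
            halvings += 1
        if new_obj < obj - 1e-12:
            new, new_obj = coef, obj  # no admissible improving step
        if np.any(np.abs(new) >= cap - 1e-9):
            separation = True
        delta = np.max(np.abs(new - coef))
        coef, obj = new, new_obj
        if np.max(np.abs(grad)) < tol or delta < 1e-12:
            converged = True
            break
        if separation and delta < 1e-6:
            break
    coef, obj, separation = _resolve_separation(
        coef, obj, separation, cap, lambda c: _logistic_objective(c, Xd, w, pen)
    )
    return coef, converged, separation


def m_step_incidence(cohort: CohortTable, weights, tol: float = 1e-8,
                     init=None) -> np.ndarray:
    """Weighted logistic maximization for the incidence coefficients theta.

    Separation (coefficients running away) is capped at |50| with a warning.
    """
    w = np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    Xd = _with_intercept(cohort.X)
    coef, _, separation = _weighted_logistic(Xd, w, init=init, tol=tol)
    if separation:
        warnings.warn("separation detected in incidence M-step; coefficients capped",
                      RuntimeWarning, stacklevel=2)
    return coef


# ---------------------------------------------------------------------------
# weighted Cox M-step (Breslow ties and baseline)
# ---------------------------------------------------------------------------

def _cox_prepare(time, delta, X, w):
    order = np.argsort(time, kind="stable")
    t, d, Xs, ws = time[order], delta[order], X[order], w[order]
    uniq, first = np.unique(t, return_index=True)
    group = np.searchsorted(uniq, t)
    return t, d, Xs, ws, uniq, first, group


def _cox_loglik_grad_hess(beta, t, d, Xs, ws, first, group, want_hess=True):
    n, p = Xs.shape
    eta = np.clip(Xs @ beta, -700, 700)
    we = ws * np.exp(eta)
    cs_we = np.cumsum(we[::-1])[::-1]
    cs_wex = np.cumsum((we[:, None] * Xs)[::-1], axis=0)[::-1]
    f = first[group]
    ev = d == 1
    wev = ws[ev]
    R = np.clip(cs_we[f[ev]], 1e-300, None)
    ll = float(np.sum(wev * (eta[ev] - np.log(R))))
    mean = cs_wex[f[ev]] / R[:, None]
    grad = (wev[:, None] * (Xs[ev] - mean)).sum(axis=0)
    if not want_hess:
        return ll, grad, None
    P = (we[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))
    cs_P = np.cumsum(P[::-1], axis=0)[::-1]
    S2 = cs_P[f[ev]] / R[:, None, None]
    outer = mean[:, :, None] * mean[:, None, :]
    hess = -np.einsum("i,ijk->jk", wev, S2 - outer)
    return ll, grad, hess


def _breslow(beta, t, d, Xs, ws, uniq, first, group):
    eta = np.clip(Xs @ beta, -700, 700)
    we = ws * np.exp(eta)
    cs_we = np.cumsum(we[::-1])[::-1]
    dk = np.zeros(uniq.size)
    np.add.at(dk, group[d == 1], ws[d == 1])
    has_event = dk > 0
    R = np.clip(cs_we[first[has_event]], 1e-300, None)
    return BaselineHazard(uniq[has_event], dk[has_event] / R)


def _cox_objective(beta, t, d, Xs, ws, first, group, pen=None):
    ll, _, _ = _cox_loglik_grad_hess(beta, t, d, Xs, ws, first, group, want_hess=False)
    return ll - (pen(beta) if pen is not None else 0.0)


def _weighted_cox(time, delta, X, w, init=None, pen_deriv=None, pen=None,
                  tol=1e-8, max_iter=200, cap=COEF_CAP):
    """Maximize the weighted Cox partial likelihood (optionally penalized).

    Censored subjects enter risk sets with multiplier w_i; events carry
    weight 1 in the cure EM.  Ties use Breslow's approximation.
    """
    t, d, Xs, ws, uniq, first, group = _cox_prepare(time, delta, X, w)
    p = X.shape[1]
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    if p == 0:
        baseline = _breslow(beta, t, d, Xs, ws, uniq, first, group)
        return beta, baseline, True, False
    converged = False
    separation = False
    obj = _cox_objective(beta, t, d, Xs, ws, first, group, pen)
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_grad_hess(beta, t, d, Xs, ws, first, group)
        if pen_deriv is not None:
            D = pen_deriv(beta)
            grad = grad - D * beta
            hess = hess - np.diag(D)
        neg_h = -hess
        try:
            step = np.linalg.solve(neg_h, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(neg_h + 1e-8 * np.eye(p), grad)
        smax = np.max(np.abs(step)) if step.size else 0.0
        if smax > 10.0:
            step = step * (10.0 / smax)
        new = np.clip(beta + step, -cap, cap)
        new_obj = _cox_objective(new, t, d, Xs, ws, first, group, pen)
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 30:
            step *= 0.5
            new = np.clip(beta + step, -cap, cap)
            new_obj = _cox_objective(new, t, d, Xs, ws, first, group, pen)
            halvings += 1
        if new_obj < obj - 1e-12:
            new, new_obj = beta, obj
        if np.any(np.abs(new) >= cap - 1e-9):
            separation = True
        delta_c = np.max(np.abs(new - beta)) if p else 0.0
        beta, obj = new, new_obj
        if (np.max(np.abs(grad)) if p else 0.0) < tol or delta_c < 1e-12:
            converged = True
            break
    beta, obj, separation = _resolve_separation(
        beta, obj, separation, cap,
        lambda b: _cox_objective(b, t, d, Xs, ws, first, group, pen),
    )
    baseline = _breslow(beta, t, d, Xs, ws, uniq, first, group)
    return beta, baseline, converged, separation


def m_step_latency(cohort: CohortTable, weights, init=None,
                   tol: float = 1e-8) -> tuple[np.ndarray, BaselineHazard]:
    """Weighted Cox partial-likelihood maximization plus Breslow baseline."""
    w = np.asarray(weights, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    delta = (cohort.cause >= 1).astype(int)
    if delta.sum() == 0:
        raise ValueError("no events: latency M-step undefined")
    beta, baseline, _, separation = _weighted_cox(
        cohort.time, delta, cohort.X, w, init=init, tol=tol
    )
    if separation:
        warnings.warn("latency coefficients capped at bound", RuntimeWarning,
                      stacklevel=2)
    return beta, baseline


# ---------------------------------------------------------------------------
# fit driver
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """EM controls: parameter-change tolerance, iteration cap, coefficient cap."""

    tol: float = 1e-6
    max_iter: int = 500
    coef_cap: float = COEF_CAP
    standardize: bool = True


@dataclass
class FitResult:
    """A converged (or flagged) mixture cure fit with model-choice metadata."""

    params: CureModelParams
    loglik: float
    n: int
    df: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    penalty: object | None = None
    penalized_loglik: float | None = None

    @property
    def selected(self) -> dict[str, list[str]]:
        """Covariates with nonzero coefficients, per component."""
        names = self.params.covariate_names or [
            f"x{i}" for i in range(self.params.beta.size)
        ]
        return {
            "incidence": [n for n, v in zip(names, self.params.theta[1:]) if v != 0.0],
            "latency": [n for n, v in zip(names, self.params.beta) if v != 0.0],
        }

    def to_json(self) -> str:
        names = self.params.covariate_names or [
            f"x{i}" for i in range(self.params.beta.size)
        ]
        payload = {
            "incidence": {
                "names": ["(Intercept)"] + list(names),
                "estimate": self.params.theta.tolist(),
                "odds_ratio": np.exp(self.params.theta).tolist(),
            },
            "latency": {
                "names": list(names),
                "estimate": self.params.beta.tolist(),
                "hazard_ratio": np.exp(self.params.beta).tolist(),
            },
            "baseline": {
                "times": self.params.baseline.times.tolist(),
                "increments": self.params.baseline.increments.tolist(),
            },
            "loglik": self.loglik,
            "n": self.n,
            "df": self.df,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "warnings": list(self.warnings),
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def from_json(text: str) -> "FitResult":
        d = json.loads(text)
        params = CureModelParams(
            theta=np.array(d["incidence"]["estimate"]),
            beta=np.array(d["latency"]["estimate"]),
            baseline=BaselineHazard(
                np.array(d["baseline"]["times"]),
                np.array(d["baseline"]["increments"]),
            ),
            covariate_names=d["latency"]["names"],
        )
        return FitResult(
            params=params, loglik=d["loglik"], n=d["n"], df=d["df"],
            aic=d["aic"], bic=d["bic"], converged=d["converged"],
            n_iter=d["n_iter"], warnings=d.get("warnings", []),
        )


def _prune_collinear(X: np.ndarray, names: list[str]):
    """Indices of a maximal linearly independent, non-constant column subset."""
    n, p = X.shape
    keep: list[int] = []
    basis = np.ones((n, 1)) / np.sqrt(n)
    for j in range(p):
        col = X[:, j].astype(float)
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(np.linalg.norm(col), 1.0):
            keep.append(j)
            basis = np.hstack([basis, (resid / norm)[:, None]])
    return keep


def _standardize(X: np.ndarray):
    m = X.mean(axis=0)
    s = X.std(axis=0, ddof=0)
    s = np.where(s < 1e-12, 1.0, s)
    return (X - m) / s, m, s


def _destandardize(theta_s, beta_s, baseline_s, m, s):
    theta = np.empty_like(theta_s)
    theta[1:] = theta_s[1:] / s
    theta[0] = theta_s[0] - np.sum(theta_s[1:] * m / s)
    beta = beta_s / s
    k = float(np.sum(beta * m))
    baseline = BaselineHazard(baseline_s.times, baseline_s.increments * np.exp(-k))
    return theta, beta, baseline


def _restandardize(params: "CureModelParams", keep, m, s):
    """Map original-scale parameters onto the standardized working scale."""
    theta_o = params.theta
    beta_o = params.beta
    th = np.array([theta_o[0]] + [theta_o[j + 1] for j in keep])
    be = np.array([beta_o[j] for j in keep])
    theta_s = np.empty_like(th)
    theta_s[1:] = th[1:] * s
    theta_s[0] = th[0] + float(np.sum(th[1:] * m))
    beta_s = be * s
    k = float(np.sum(be * m))
    baseline_s = BaselineHazard(params.baseline.times,
                                params.baseline.increments * np.exp(k))
    return theta_s, beta_s, baseline_s


def _em_fit(cohort: CohortTable, options: FitOptions, penalty=None,
            init_params: "CureModelParams | None" = None) -> FitResult:
    """Shared EM driver for the unpenalized and penalized fits.

    With ``penalty`` (a :class:`pencure.penalized.PenaltySpec`), M-steps
    use a local quadratic approximation of the penalty and coefficients
    below 1e-6 in magnitude are hard-thresholded to exactly zero.
    """
    time = cohort.time
    delta = (cohort.cause >= 1).astype(int)
    if delta.sum() == 0:
        raise ValueError("cohort has no events for the target cause; cannot fit")
    X_full = cohort.X
    names = list(cohort.covariate_names)
    n, p_full = X_full.shape
    if n <= p_full:
        raise ValueError(f"n={n} must exceed covariate count p={p_full}")

    warn_msgs: list[str] = []
    keep = _prune_collinear(X_full, names)
    if len(keep) < p_full:
        dropped = [names[j] for j in range(p_full) if j not in keep]
        msg = f"collinear or constant covariate(s) pruned: {dropped}"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        warn_msgs.append(msg)
    X = X_full[:, keep]
    p = X.shape[1]

    if options.standardize and p:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(p), np.ones(p)
    Xd = _with_intercept(Xs)

    t_s, d_s, Xs_sorted, ws_sorted, uniq, first, group = _cox_prepare(
        time, delta, Xs, np.ones(n)
    )

    if penalty is not None:
        scale = float(n)
        def pen_val(vec, skip0):
            b = vec[1:] if skip0 else vec
            return scale * float(np.sum(penalty.penalty(np.abs(b))))
        def lqa_diag(vec, skip0):
            b = np.abs(vec[1:] if skip0 else vec)
            d = scale * penalty.derivative(b) / (b + 1e-8)
            return np.concatenate([[0.0], d]) if skip0 else d
        pen_inc = lambda v: pen_val(v, True)
        pend_inc = lambda v: lqa_diag(v, True)
        pen_lat = lambda v: pen_val(v, False)
        pend_lat = lambda v: lqa_diag(v, False)
    else:
        pen_inc = pend_inc = pen_lat = pend_lat = None

    # initialization: warm start if given; else a logistic fit of the
    # event indicator and a naive Cox fit.  The penalized path must not
    # start at exact zeros: the quadratic penalty approximation pins
    # zero coefficients, so it is anchored at the naive estimates too.
    if init_params is not None:
        theta, beta, baseline = _restandardize(init_params, keep, mu, sd)
    else:
        theta, _, _ = _weighted_logistic(Xd, delta.astype(float))
        beta, baseline, _, _ = _weighted_cox(time, delta, Xs, np.ones(n))

    trace: list[float] = []
    converged = False
    separation_seen = False
    it = 0
    for it in range(1, options.max_iter + 1):
        w, _ = _estep_arrays(time, delta, Xs, theta, beta, baseline)
        # warm-started M-steps; a modest inner cap suffices (generalized
        # EM: any likelihood-increasing update preserves the ascent)
        theta_new, _, sep1 = _weighted_logistic(
            Xd, w, init=theta, pen_deriv=pend_inc, pen=pen_inc,
            cap=options.coef_cap, max_iter=25,
        )
        beta_new, baseline, _, sep2 = _weighted_cox(
            time, delta, Xs, w, init=beta, pen_deriv=pend_lat, pen=pen_lat,
            cap=options.coef_cap, max_iter=25,
        )
        if penalty is not None:
            # intercept is never penalized or thresholded
            small = np.abs(theta_new[1:]) < 1e-6
            theta_new[1:] = np.where(small, 0.0, theta_new[1:])
            beta_new = np.where(np.abs(beta_new) < 1e-6, 0.0, beta_new)
        separation_seen = separation_seen or sep1 or sep2
        _, ll = _estep_arrays(time, delta, Xs, theta_new, beta_new, baseline)
        trace.append(ll)
        change = max(
            np.max(np.abs(theta_new - theta)),
            np.max(np.abs(beta_new - beta)) if p else 0.0,
        )
        theta, beta = theta_new, beta_new
        if change < options.tol:
            converged = True
            break
    if separation_seen:
        warn_msgs.append("separation: one or more coefficients reached the cap")

    _, ll = _estep_arrays(time, delta, Xs, theta, beta, baseline)
    pen_ll = None
    if penalty is not None:
        pen_ll = ll - float(n) * float(
            np.sum(penalty.penalty(np.abs(theta[1:])))
            + np.sum(penalty.penalty(np.abs(beta)))
        )

    theta_o, beta_o, baseline_o = _destandardize(theta, beta, baseline, mu, sd)
    # re-embed pruned columns as exact zeros
    theta_full = np.zeros(p_full + 1)
    beta_full = np.zeros(p_full)
    theta_full[0] = theta_o[0]
    for out_idx, j in enumerate(keep):
        theta_full[j + 1] = theta_o[out_idx + 1]
        beta_full[j] = beta_o[out_idx]

    df = int(np.sum(theta_full != 0.0) + np.sum(beta_full != 0.0))
    params = CureModelParams(theta_full, beta_full, baseline_o, names)
    return FitResult(
        params=params, loglik=ll, n=n, df=df,
        aic=-2.0 * ll + 2.0 * df, bic=-2.0 * ll + np.log(n) * df,
        converged=converged, n_iter=it, trace=trace, warnings=warn_msgs,
        penalty=penalty, penalized_loglik=pen_ll,
    )


def fit_full_model(cohort: CohortTable, options: FitOptions | None = None) -> FitResult:
    """Fit the unpenalized mixture cure model (all covariates retained).

    The cohort must already be cause-specifically recoded (binary cause).
    Non-convergence within the iteration cap is flagged on the result,
    not raised.
    """
    return _em_fit(cohort, options or FitOptions(), penalty=None)
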