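"""LASSO and SCAD penalized estimation with AIC/BIC lambda tuning.

The penalized objective is the observed-data log-likelihood minus
n * sum_j p_lambda(|b_j|) over the penalized coefficients (Fan-Li
scaling); intercepts are never penalized.  Penalized M-steps use a local
quadratic approximation (LQA) of the penalty around the current
coefficients inside the same Newton solvers as the unpenalized model,
with a hard threshold (|b| < 1e-6 -> exactly 0) producing sparse fits.
The SCAD derivative is

    p'_lambda(b) = lambda                    for b < lambda,
                   (a*lambda - b)_+ / (a-1)  for b >= lambda,

continuous at b = lambda and identically zero for b >= a*lambda, so
large coefficients are left nearly unbiased while small ones are
shrunk to zero.  The shape default a = 3.7 is the conventional choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .cure_em import (
    FitOptions,
    FitResult,
    _cox_loglik_grad_hess,
    _cox_prepare,
    _em_fit,
    _standardize,
    _weighted_cox,
    _weighted_logistic,
    _with_intercept,
)

__all__ = [
    "PenaltySpec",
    "TuningResult",
    "lasso_penalty",
    "scad_penalty",
    "scad_derivative",
    "penalized_m_step",
    "fit_penalized",
    "default_lambda_grid",
    "tune_lambda",
]

SCAD_DEFAULT_A = 3.7
HARD_THRESHOLD = 1e-6


def lasso_penalty(b, lam: float):
    """L1 penalty lambda * |b|."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return lam * np.abs(b)


def scad_derivative(b, lam: float, a: float = SCAD_DEFAULT_A):
    """First derivative of the SCAD penalty, defined for b >= 0."""
    if a <= 2:
        raise ValueError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b = np.asarray(b, dtype=float)
    out = np.where(b < lam, lam, np.clip(a * lam - b, 0.0, None) / (a - 1.0))
    return out if out.ndim else float(out)


def scad_penalty(b, lam: float, a: float = SCAD_DEFAULT_A):
    """SCAD penalty (the integral of :func:`scad_derivative`): linear up to
    lambda, quadratically clipped, constant (a+1) lambda^2 / 2 beyond a*lambda."""
    if a <= 2:
        raise ValueError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b = np.abs(np.asarray(b, dtype=float))
    lin = lam * b
    quad = (2.0 * a * lam * b - b**2 - lam**2) / (2.0 * (a - 1.0))
    flat = (a + 1.0) * lam**2 / 2.0
    out = np.where(b <= lam, lin, np.where(b <= a * lam, quad, flat))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family and tuning constants governing the penalized M-steps."""

    family: str
    lam: float
    a: float = SCAD_DEFAULT_A

    def __post_init__(self) -> None:
        if self.family not in ("lasso", "scad"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.family == "scad" and self.a <= 2:
            raise ValueError("SCAD shape parameter a must exceed 2")

    def penalty(self, babs):
        babs = np.abs(babs)
        if self.family == "lasso":
            return lasso_penalty(babs, self.lam)
        return scad_penalty(babs, self.lam, self.a)

    def derivative(self, babs):
        babs = np.abs(babs)
        if self.family == "lasso":
            return np.full_like(np.asarray(babs, dtype=float), self.lam)
        return scad_derivative(babs, self.lam, self.a)


def penalized_m_step(part: str, cohort: CohortTable, weights, spec: PenaltySpec,
                     current, tol: float = 1e-8):
    """One penalized M-step: LQA of the penalty around ``current`` and a
    step-halved penalized Newton solve; near-zero coefficients are set to 0.

    ``part`` selects the weighted-logistic incidence update (``current``
    is theta with intercept, which stays unpenalized) or the weighted-Cox
    latency update (``current`` is beta).
    """
    w = np.asarray(weights, dtype=float)
    n = cohort.n
    scale = float(n)

    def pen(vec, skip0):
        b = vec[1:] if skip0 else vec
        return scale * float(np.sum(spec.penalty(np.abs(b))))

    def lqa(vec, skip0):
        b = np.abs(vec[1:] if skip0 else vec)
        d = scale * spec.derivative(b) / (b + 1e-8)
        return np.concatenate([[0.0], d]) if skip0 else d

    if part == "incidence":
        Xd = _with_intercept(cohort.X)
        coef, _, _ = _weighted_logistic(
            Xd, w, init=np.asarray(current, dtype=float),
            pen_deriv=lambda v: lqa(v, True), pen=lambda v: pen(v, True), tol=tol,
        )
        coef[1:] = np.where(np.abs(coef[1:]) < HARD_THRESHOLD, 0.0, coef[1:])
        return coef
    if part == "latency":
        delta = (cohort.cause >= 1).astype(int)
        beta, _, _, _ = _weighted_cox(
            cohort.time, delta, cohort.X, w,
            init=np.asarray(current, dtype=float),
            pen_deriv=lambda v: lqa(v, False), pen=lambda v: pen(v, False), tol=tol,
        )
        return np.where(np.abs(beta) < HARD_THRESHOLD, 0.0, beta)
    raise ValueError(f"unknown likelihood part {part!r}")


def fit_penalized(cohort: CohortTable, spec: PenaltySpec,
                  options: FitOptions | None = None,
                  init_params=None) -> FitResult:
    """EM fit with both components penalized (intercept exempt).

    At lambda = 0 this coincides with the unpenalized full model.  The
    result carries both the unpenalized log-likelihood (for AIC/BIC) and
    the penalized one.
    """
    return _em_fit(cohort, options or FitOptions(), penalty=spec,
                   init_params=init_params)


def default_lambda_grid(cohort: CohortTable, n_points: int = 30,
                        ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from lambda_max down to ratio * lambda_max.

    lambda_max is the null-model score bound: the largest per-coordinate
    gradient (over both components, on standardized covariates, divided
    by n) at zero coefficients, below which every penalized coefficient
    stays at zero for the LASSO; a 5% margin is added.
    """
    n = cohort.n
    delta = (cohort.cause >= 1).astype(float)
    Xs, _, _ = _standardize(cohort.X)
    p0 = delta.mean()
    score_inc = np.abs(Xs.T @ (delta - p0)) / n
    t, d, Xo, wo, uniq, first, group = _cox_prepare(
        cohort.time, (cohort.cause >= 1).astype(int), Xs, delta.copy()
    )
    _, grad, _ = _cox_loglik_grad_hess(np.zeros(Xs.shape[1]), t, d, Xo, wo,
                                       first, group, want_hess=False)
    score_lat = np.abs(grad) / n
    # the event-indicator weights underestimate the converged E-step
    # weights, so the score bound gets a factor-2 margin to make sure the
    # top of the grid reaches the empty (intercept-only) model
    lam_max = 2.0 * max(score_inc.max(initial=0.0), score_lat.max(initial=0.0), 1e-4)
    return np.geomspace(lam_max, ratio * lam_max, n_points)


@dataclass
class TuningResult:
    """Per-lambda fits with AIC/BIC bookkeeping and the selected model.

    AIC = -2 loglik + 2 df and BIC = -2 loglik + ln(n) df, with df the
    count of nonzero coefficients across both components, intercept
    included.  Criterion ties are broken toward the larger lambda
    (sparser model).
    """

    family: str
    criterion: str
    lambdas: np.ndarray
    fits: list[FitResult]
    table: pd.DataFrame = field(init=False)
    selected_lambda: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for lam, fit in zip(self.lambdas, self.fits):
            rows.append({
                "lambda": float(lam), "df": fit.df, "loglik": fit.loglik,
                "aic": fit.aic, "bic": fit.bic, "converged": fit.converged,
            })
        tab = pd.DataFrame(rows)
        self.selected_lambda = {}
        order = np.argsort(-self.lambdas, kind="stable")  # descending: ties -> larger lambda
        for crit in ("aic", "bic"):
            vals = tab[crit].to_numpy()[order]
            best = order[int(np.argmin(vals))]
            self.selected_lambda[crit] = float(self.lambdas[best])
        for crit in ("aic", "bic"):
            tab[f"selected_{crit}"] = tab["lambda"] == self.selected_lambda[crit]
        self.table = tab

    @property
    def best(self) -> FitResult:
        lam = self.selected_lambda[self.criterion]
        idx = int(np.argmax(self.lambdas == lam))
        return self.fits[idx]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def tune_lambda(cohort: CohortTable, family: str, lambda_grid=None,
                criterion: str = "bic", options: FitOptions | None = None,
                a: float = SCAD_DEFAULT_A) -> TuningResult:
    """Fit the penalized model over a lambda grid and select by AIC or BIC.

    Fits proceed from the smallest lambda upward with warm starts: the
    local quadratic approximation can shrink a warm-started coefficient
    to zero but never revive one pinned at zero, so the path must move
    in the direction of increasing shrinkage.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(cohort)
    grid = np.asarray(sorted(set(float(l) for l in lambda_grid)), dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda grid must be nonempty and nonnegative")
    options = options or FitOptions()
    fits: list[FitResult] = []
    init = None
    for lam in grid:
        spec = PenaltySpec(family, float(lam), a)
        fit = fit_penalized(cohort, spec, options, init_params=init)
        fits.append(fit)
        init = fit.params
    if not any(f.converged for f in fits):
        raise RuntimeError("no penalized fit converged on the lambda grid")
    return TuningResult(family=family, criterion=criterion, lambdas=grid, fits=fits)
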