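"""Nonparametric descriptives: Kaplan-Meier, Aalen-Johansen, Maller-Zhou.

These are the model-free summaries used to motivate cure modelling: the
product-limit survival curve (whose terminal plateau estimates the cured
fraction under sufficient follow-up), the cumulative incidence function
per competing cause, and the Maller-Zhou check that follow-up extends
far enough past the last event for the plateau to be interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, recode_cause_specific

__all__ = ["StepFunction", "kaplan_meier", "aalen_johansen_cif", "maller_zhou_test",
           "MallerZhouReport"]


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with jumps at increasing times."""

    times: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate right-continuously: value of the last jump at or before t."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right")
        padded = np.concatenate([[self.initial], self.values])
        out = padded[idx]
        return out if t_arr.ndim else float(out)

    @property
    def terminal(self) -> float:
        """Value at (and beyond) the largest jump time."""
        return float(self.values[-1]) if self.values.size else float(self.initial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def _event_table(time: np.ndarray, event: np.ndarray):
    """Distinct observed times with event counts d and at-risk counts r.

    Ties between events and censorings at the same time are resolved by
    the standard convention that events precede censorings: both are in
    the risk set at that time.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first
    d = np.add.reduceat(e.astype(float), first)
    return uniq, d, at_risk


def kaplan_meier(cohort: CohortTable, target_cause: int | None = None) -> StepFunction:
    """Product-limit survival estimate, treating other causes as censored.

    With ``target_cause=None`` any event counts (the all-cause estimator
    whose complement the cause-specific CIFs partition).
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    if target_cause is not None:
        cohort = recode_cause_specific(cohort, target_cause)
    time = cohort.time
    event = (cohort.cause >= 1).astype(float)
    uniq, d, r = _event_table(time, event)
    surv = np.cumprod(1.0 - d / r)
    return StepFunction(uniq, surv, initial=1.0)


def aalen_johansen_cif(cohort: CohortTable) -> dict[int, StepFunction]:
    """Aalen-Johansen cumulative incidence per cause.

    CIF_j(t) = sum over event times t_k <= t of S(t_k-) d_jk / r_k with S
    the all-cause Kaplan-Meier, so that sum_j CIF_j(t) + S(t) = 1 at
    every t (an algebraic identity of the product-limit construction).
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    time = cohort.time
    cause = cohort.cause
    causes = sorted(c for c in cohort.cause_set if c >= 1)
    uniq, d_all, r = _event_table(time, (cause >= 1).astype(float))
    surv = np.cumprod(1.0 - d_all / r)
    surv_left = np.concatenate([[1.0], surv[:-1]])  # S(t-) at each distinct time
    out: dict[int, StepFunction] = {}
    for j in causes:
        d_j = np.zeros_like(uniq)
        tj = time[cause == j]
        if tj.size:
            idx = np.searchsorted(uniq, np.sort(tj))
            np.add.at(d_j, idx, 1.0)
        cif = np.cumsum(surv_left * d_j / r)
        out[j] = StepFunction(uniq, cif, initial=0.0)
    return out


@dataclass(frozen=True)
class MallerZhouReport:
    """Sufficient-follow-up check based on the tail interval of event times."""

    n: int
    n_tail_events: int
    q_n: float
    p_value: float
    largest_event_time: float
    largest_observed_time: float
    km_plateau: float
    sufficient_follow_up: str = field(default="")
    cured_fraction_verdict: str = field(default="")


def maller_zhou_test(cohort: CohortTable, target_cause: int) -> MallerZhouReport:
    """Maller-Zhou interval-count check of sufficient follow-up.

    Counts N_n, the uncensored times in (2 t*_n - t_n, t*_n] where t*_n
    is the largest event time and t_n the largest observed time; reports
    q_n = N_n / n and the conservative approximation alpha_n = (1-q_n)^n
    of the probability that follow-up is insufficient.  A small alpha_n
    supports reading the KM plateau as a cured fraction; the plateau
    itself is evidence of a nonzero cured fraction only when positive
    with the last observation censored.
    """
    recoded = recode_cause_specific(cohort, target_cause)
    time, event = recoded.time, recoded.cause.astype(bool)
    if not event.any():
        raise ValueError("no events for the target cause; test undefined")
    t_star = float(time[event].max())
    t_max = float(time.max())
    lo = 2.0 * t_star - t_max
    n = time.size
    n_tail = int(np.sum(event & (time > lo) & (time <= t_star)))
    q_n = n_tail / n
    p_value = float((1.0 - q_n) ** n)
    km = kaplan_meier(recoded, target_cause=1)
    plateau = km.terminal
    last_is_event = bool(event[np.argmax(time)]) and t_star == t_max
    sufficient = (
        "evidence of sufficient follow-up"
        if p_value < 0.05
        else "follow-up may be insufficient"
    )
    cured = (
        "evidence of a nonzero cured fraction"
        if plateau > 0 and not last_is_event
        else "no evidence of a cured fraction"
    )
    return MallerZhouReport(
        n=n,
        n_tail_events=n_tail,
        q_n=q_n,
        p_value=p_value,
        largest_event_time=t_star,
        largest_observed_time=t_max,
        km_plateau=plateau,
        sufficient_follow_up=sufficient,
        cured_fraction_verdict=cured,
    )
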