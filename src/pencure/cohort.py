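"""Cohort data model for competing-risks survival cohorts.

A cohort is a rectangular table with one row per subject: a follow-up
time (months), an integer cause code (0 = censored, 1..c = event types,
with cause 1 conventionally the event of interest, e.g. relapse, and
cause 2 a competing event, e.g. death before relapse), and a numeric
covariate matrix.  Categorical covariates are expanded to reference-cell
indicator columns (an L-level factor yields L-1 dummies; the declared
reference level maps to the all-zeros pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pencure")

__all__ = [
    "SchemaError",
    "ValidationError",
    "CovariateCoding",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "recode_cause_specific",
    "load_schema",
]


class SchemaError(ValueError):
    """A declared column or schema entry is missing or malformed."""


class ValidationError(ValueError):
    """Row-level data violates the cohort invariants."""


@dataclass(frozen=True)
class CovariateCoding:
    """Reference-cell dummy coding of one categorical variable.

    An L-level variable produces exactly L-1 indicator columns named
    ``<variable>=<level>``; rows at the reference level get all zeros.
    """

    variable: str
    levels: tuple[str, ...]
    reference: str
    columns: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise SchemaError(
                f"reference level {self.reference!r} not among levels of "
                f"{self.variable!r}: {list(self.levels)}"
            )
        cols = tuple(
            f"{self.variable}={lv}" for lv in self.levels if lv != self.reference
        )
        object.__setattr__(self, "columns", cols)

    def expand(self, values: pd.Series) -> pd.DataFrame:
        unknown = set(values.dropna().astype(str)) - set(self.levels)
        if unknown:
            raise ValidationError(
                f"unknown level(s) {sorted(unknown)} for variable {self.variable!r}"
            )
        out = pd.DataFrame(index=values.index)
        for lv in self.levels:
            if lv == self.reference:
                continue
            out[f"{self.variable}={lv}"] = (values.astype(str) == lv).astype(float)
        # Preserve missingness so complete-case filtering sees it.
        out.loc[values.isna(), list(out.columns)] = np.nan
        return out


@dataclass
class CohortTable:
    """Validated competing-risks cohort.

    Parameters
    ----------
    data
        Frame with columns ``subject_id``, ``time``, ``cause`` and one
        numeric column per covariate.
    covariate_names
        Ordered covariate column names (already expanded to indicators).
    cause_set
        Declared finite set of valid cause codes, always containing 0.
    """

    data: pd.DataFrame
    covariate_names: list[str]
    cause_set: frozenset[int] = frozenset({0, 1, 2})

    def __post_init__(self) -> None:
        self.cause_set = frozenset(int(c) for c in self.cause_set) | {0}
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def cause(self) -> np.ndarray:
        return self.data["cause"].to_numpy(dtype=int)

    @property
    def X(self) -> np.ndarray:
        """Covariate matrix, shape (n, p)."""
        return self.data[self.covariate_names].to_numpy(dtype=float)

    def validate(self) -> None:
        required = {"subject_id", "time", "cause"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"cohort frame lacks columns {sorted(missing)}")
        for name in self.covariate_names:
            if name not in self.data.columns:
                raise SchemaError(f"declared covariate column {name!r} missing")
        t = self.data["time"].to_numpy(dtype=float)
        if np.any(t < 0) or np.any(~np.isfinite(t)):
            bad = list(self.data.index[(t < 0) | ~np.isfinite(t)])
            raise ValidationError(f"negative or non-finite times at rows {bad}")
        causes = self.data["cause"].to_numpy()
        bad_cause = [
            i for i, c in zip(self.data.index, causes) if int(c) not in self.cause_set
        ]
        if bad_cause:
            raise ValidationError(
                f"cause codes outside declared set {sorted(self.cause_set)} "
                f"at rows {bad_cause}"
            )
        if self.data[self.covariate_names].isna().any().any():
            raise ValidationError("covariate matrix contains missing values")

    def n_events(self, cause: int | None = None) -> int:
        c = self.cause
        return int(np.sum(c >= 1) if cause is None else np.sum(c == cause))

    def subset(self, idx: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.data.iloc[idx].reset_index(drop=True),
            list(self.covariate_names),
            self.cause_set,
        )


def load_schema(source) -> dict:
    """Load a cohort schema from a YAML/JSON file path or pass a dict through."""
    if isinstance(source, dict):
        return source
    with open(source, "r", encoding="utf-8") as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError("schema file must contain a mapping")
    return schema


def _codings_from_schema(schema: dict) -> tuple[list[str], list[CovariateCoding], list[str]]:
    continuous: list[str] = []
    codings: list[CovariateCoding] = []
    order: list[str] = []
    for spec in schema.get("covariates", []):
        if isinstance(spec, str):
            spec = {"name": spec, "type": "continuous"}
        name = spec["name"]
        kind = spec.get("type", "continuous")
        if kind == "categorical":
            if "reference" not in spec:
                raise SchemaError(
                    f"categorical covariate {name!r} must declare a reference level"
                )
            coding = CovariateCoding(
                name, tuple(str(lv) for lv in spec["levels"]), str(spec["reference"])
            )
            codings.append(coding)
            order.extend(coding.columns)
        elif kind in ("continuous", "binary", "indicator"):
            continuous.append(name)
            order.append(name)
        else:
            raise SchemaError(f"unknown covariate type {kind!r} for {name!r}")
    return continuous, codings, order


def read_cohort(path, schema) -> CohortTable:
    """Read a CSV cohort and validate it against a schema.

    The schema (dict, or YAML/JSON path) names the time column, the cause
    column, a cause-label map, and the covariates with types and, for
    categoricals, level lists and reference levels.  Rows with missing
    values in any used column are dropped complete-case with a logged
    count.
    """
    schema = load_schema(schema)
    raw = pd.read_csv(path)
    time_col = schema.get("time", "time")
    cause_col = schema.get("cause", "cause")
    id_col = schema.get("subject_id")
    for col in (time_col, cause_col):
        if col not in raw.columns:
            raise SchemaError(f"declared column {col!r} not found in {path}")

    continuous, codings, order = _codings_from_schema(schema)
    for name in continuous + [c.variable for c in codings]:
        if name not in raw.columns:
            raise SchemaError(f"declared covariate column {name!r} not found in {path}")

    out = pd.DataFrame(index=raw.index)
    out["subject_id"] = (
        raw[id_col].astype(str) if id_col and id_col in raw.columns else raw.index.astype(str)
    )
    out["time"] = pd.to_numeric(raw[time_col], errors="coerce")

    cause_labels = schema.get("cause_labels")
    if cause_labels:
        mapped = raw[cause_col].map(
            lambda v: cause_labels.get(v, cause_labels.get(str(v), v))
        )
    else:
        mapped = raw[cause_col]
    out["cause"] = pd.to_numeric(mapped, errors="coerce")

    for name in continuous:
        out[name] = pd.to_numeric(raw[name], errors="coerce")
    for coding in codings:
        expanded = coding.expand(raw[coding.variable])
        out = pd.concat([out, expanded], axis=1)

    used = ["time", "cause"] + order
    keep = out[used].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_cohort: dropped %d row(s) with missing values", n_dropped)
    out = out.loc[keep].reset_index(drop=True)
    out["cause"] = out["cause"].astype(int)

    declared = schema.get("cause_set")
    if declared is None:
        declared = sorted(set(cause_labels.values())) if cause_labels else [0, 1, 2]
    return CohortTable(out, order, frozenset(int(c) for c in declared))


def write_cohort(cohort: CohortTable, path) -> None:
    """Echo a validated cohort to CSV (provenance copy; round-trips)."""
    cols = ["subject_id", "time", "cause"] + list(cohort.covariate_names)
    cohort.data[cols].to_csv(path, index=False)


def recode_cause_specific(cohort: CohortTable, target_cause: int) -> CohortTable:
    """Collapse cause codes to a binary indicator for one event type.

    Competing events become censorings (cause 0); rows with the target
    cause become cause 1.  Times are untouched.  This is the recoding
    behind cause-specific hazard modelling.
    """
    target_cause = int(target_cause)
    if target_cause < 1 or target_cause not in cohort.cause_set:
        raise ValueError(
            f"target cause {target_cause} not in declared set {sorted(cohort.cause_set)}"
        )
    data = cohort.data.copy()
    data["cause"] = (data["cause"] == target_cause).astype(int)
    return CohortTable(data, list(cohort.covariate_names), frozenset({0, 1}))
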