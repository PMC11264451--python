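"""Markdown rendering of a cause-specific analysis report.

Mirrors the conventional presentation of cure-model results: the full
model's coefficients with bootstrap CIs, the penalized models' selected
coefficients split into a cure (incidence) section and a hazard
(latency) section, and an AIC/BIC model-comparison table.  Rendering is
a pure function of the report object, so regeneration from a serialized
report is byte-identical.
"""

from __future__ import annotations

import numpy as np

from .cure_em import FitResult
from .pipeline import CauseSpecificReport, effect_size

__all__ = ["render_report"]


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def _penalized_section(fit: FitResult, label: str, decimals: int) -> list[str]:
    names = fit.params.covariate_names or [
        f"x{i}" for i in range(fit.params.beta.size)
    ]
    lines = [f"### {label}", "", "Cure (incidence) component", "",
             "| Term | Coefficient | OR |", "|---|---|---|"]
    lines.append(
        f"| Intercept | {_fmt(fit.params.theta[0])} | "
        f"{effect_size(float(fit.params.theta[0]), 'incidence_or', decimals)} |"
    )
    for name, v in zip(names, fit.params.theta[1:]):
        if v != 0.0:
            lines.append(
                f"| {name} | {_fmt(v)} | "
                f"{effect_size(float(v), 'incidence_or', decimals)} |"
            )
    lines += ["", "Event-specific hazard (latency) component", "",
              "| Term | Coefficient | HR |", "|---|---|---|"]
    any_latency = False
    for name, v in zip(names, fit.params.beta):
        if v != 0.0:
            any_latency = True
            lines.append(
                f"| {name} | {_fmt(v)} | "
                f"{effect_size(float(v), 'latency_hr', decimals)} |"
            )
    if not any_latency:
        lines.append("| (none selected) | - | - |")
    lines.append("")
    return lines


def render_report(report: CauseSpecificReport, decimals: int = 2) -> str:
    """Render one cause-specific report as a markdown document."""
    names = report.full.params.covariate_names or []
    lines = [f"# Mixture cure competing-risks analysis: {report.cause_label}", ""]
    lines += [f"- subjects: {report.full.n}",
              f"- full-model log-likelihood: {_fmt(report.full.loglik, 4)}",
              f"- EM converged: {report.full.converged} "
              f"({report.full.n_iter} iterations)", ""]

    lines += ["## Full model", "",
              "| Term | Cure (incidence) coef | Latency coef |", "|---|---|---|"]
    lines.append(f"| Intercept | {_fmt(report.full.params.theta[0])} | - |")
    for j, name in enumerate(names):
        lines.append(
            f"| {name} | {_fmt(report.full.params.theta[j + 1])} | "
            f"{_fmt(report.full.params.beta[j])} |"
        )
    lines.append("")

    if report.full_ci is not None:
        lines += ["### Bootstrap percentile CIs (full model)", "",
                  "| Term | Estimate | Lower | Upper |", "|---|---|---|---|"]
        for _, row in report.full_ci.iterrows():
            lines.append(
                f"| {row['name']} | {_fmt(row['estimate'])} | "
                f"{_fmt(row['lower'])} | {_fmt(row['upper'])} |"
            )
        lines.append("")

    lines += _penalized_section(report.scad.best,
                                "SCAD penalty (selected model)", decimals)
    lines += _penalized_section(report.lasso.best,
                                "LASSO penalty (selected model)", decimals)

    lines += ["## Model comparison", "", "| Method | BIC | AIC |", "|---|---|---|"]
    for _, row in report.comparison.iterrows():
        lines.append(f"| {row['method']} | {_fmt(row['bic'])} | {_fmt(row['aic'])} |")
    lines.append("")
    return "\n".join(lines)
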