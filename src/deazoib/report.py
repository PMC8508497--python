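"""Human-readable posterior report in the three-section layout used for
second-stage efficiency analyses: the mean-efficiency-index (mu) submodel,
the frontier-membership (omega01) submodel, and the nuisance block
(precision, one-inflation probability theta, random-effect scale).

Coefficient rows carry an exp-transformed effect column — the ratio of
mean efficiency indices (RMEI) in the mu-submodel, the odds ratio (OR) of
frontier membership in the omega01-submodel.  Reference factor levels are
rendered as "Reference" rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["report_table", "write_report"]

SECTION_MU = "Average Efficiency Index Model"
SECTION_OMEGA = "Probability of Being Situated on the Efficiency Frontier Model"
SECTION_NUISANCE = "Accuracy, Conditional Probability of Inflation one and Random Effect"

_NUISANCE_LABELS = {
    "precision": "Precision (phi)",
    "theta": "Probability of One-Inflation (theta)",
    "sigma_u0": "Random Effect sigma_u0",
}

COLUMNS = [
    "section",
    "parameter",
    "coefficient",
    "standard_error",
    "ci_2.5",
    "ci_97.5",
    "PCP",
    "NCP",
    "Rhat",
    "bulk_ESS",
    "tail_ESS",
    "RMEI_or_OR",
]


def _coef_rows(summary: pd.DataFrame, prefix: str, section: str, factor_refs: dict):
    rows = []
    intercept = f"{prefix}0"
    if intercept in summary.index:
        rows.append(_row(summary.loc[intercept], "Intercept", section, ratio=False))
    seen_factors = set()
    for name in summary.index:
        if not name.startswith(f"{prefix}["):
            continue
        label = name[len(prefix) + 1 : -1]
        for col, ref in (factor_refs or {}).items():
            if label.startswith(f"{col}[") and col not in seen_factors:
                seen_factors.add(col)
                rows.append(
                    dict.fromkeys(COLUMNS, "Reference")
                    | {"section": section, "parameter": f"{col}[{ref}]", "PCP": "", "NCP": ""}
                )
        rows.append(_row(summary.loc[name], label, section, ratio=True))
    return rows


def _row(s: pd.Series, label: str, section: str, ratio: bool, pcp: bool = True) -> dict:
    r2 = lambda v: round(float(v), 2)
    return {
        "section": section,
        "parameter": label,
        "coefficient": r2(s["mean"]),
        "standard_error": r2(s["sd"]),
        "ci_2.5": r2(s["p2_5"]),
        "ci_97.5": r2(s["p97_5"]),
        "PCP": r2(s["pcp"]) if pcp else "",
        "NCP": r2(s["ncp"]) if pcp else "",
        "Rhat": r2(s["rhat"]),
        "bulk_ESS": int(round(s["bulk_ess"])) if np.isfinite(s["bulk_ess"]) else "",
        "tail_ESS": int(round(s["tail_ess"])) if np.isfinite(s["tail_ess"]) else "",
        "RMEI_or_OR": r2(np.exp(s["mean"])) if ratio else "",
    }


def report_table(summary: pd.DataFrame, factor_refs: dict | None = None) -> pd.DataFrame:
    """Format a posterior summary (from :func:`deazoib.inference.summarize`)
    into the three-section report table, rounded to 2 decimals.

    An empty summary yields a header-only table.
    """
    rows = []
    rows += _coef_rows(summary, "beta", SECTION_MU, factor_refs)
    rows += _coef_rows(summary, "gamma", SECTION_OMEGA, factor_refs)
    for name, label in _NUISANCE_LABELS.items():
        if name in summary.index:
            rows.append(_row(summary.loc[name], label, SECTION_NUISANCE, ratio=False, pcp=False))
    return pd.DataFrame(rows, columns=COLUMNS)


def write_report(summary: pd.DataFrame, report: pd.DataFrame, out_dir) -> None:
    """Write the rounded report CSV plus a full-precision JSON sidecar of
    the raw summary."""
    out = Path(out_dir)
    report.to_csv(out / "report.csv", index=False)
    sidecar = {
        name: {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
               for k, v in row.items()}
        for name, row in summary.to_dict(orient="index").items()
    }
    (out / "summary.json").write_text(json.dumps(sidecar, indent=1))
    summary.reset_index().to_csv(out / "summary.csv", index=False)
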