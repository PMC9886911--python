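"""Group statistics and report assembly.

All between-group comparisons use the classic two-tailed Student's t-test
with pooled variance (Welch's correction is available behind a flag), and
results are annotated "*" for p < 0.05 and "**" for p < 0.005.  No
multiple-testing correction is applied; reports state this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateVarianceError, InvalidParameterError


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    df: float


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    annotation: str


def two_tailed_ttest(
    sample_a, sample_b, equal_var: bool = True
) -> TTestResult:
    """Two-sample Student's t-test, two-tailed.

    Pooled-variance by default; ``equal_var=False`` switches to Welch.
    Two identical zero-variance samples return t = 0, p = 1 by convention;
    zero variance with unequal means is a degenerate comparison and raises.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, a.size + b.size - 2)
        raise DegenerateVarianceError(
            "both samples have zero variance but different means"
        )
    result = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(result.df)
    return TTestResult(float(result.statistic), float(result.pvalue), float(df))


def annotate(p_value: float) -> str:
    """Significance annotation: "**" if p < 0.005, "*" if p < 0.05, else ""."""
    if not 0.0 <= p_value <= 1.0:
        raise InvalidParameterError("p-value must be in [0, 1]")
    if p_value < 0.005:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def compare_groups(
    metric: str,
    group_a: str,
    sample_a,
    group_b: str,
    sample_b,
    equal_var: bool = True,
) -> GroupComparison:
    """One annotated between-group comparison of a metric."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    result = two_tailed_ttest(a, b, equal_var=equal_var)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(sps.sem(a)) if a.size > 1 else float("nan"),
        sem_b=float(sps.sem(b)) if b.size > 1 else float("nan"),
        t_statistic=result.t_statistic,
        p_value=result.p_value,
        annotation=annotate(result.p_value),
    )


def comparison_table(
    values: pd.DataFrame,
    metric: str,
    control_group: str,
    value_column: str = "value",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Compare every study group against the control, per timepoint.

    ``values`` is a tidy frame with columns group, timepoint_h and the value
    column; returns one row per (study group, timepoint) with means,
    standard errors, t, p and the annotation.
    """
    rows = []
    for timepoint, at_t in values.groupby("timepoint_h"):
        control = at_t.loc[at_t["group"] == control_group, value_column].dropna()
        for group, sample in at_t.groupby("group"):
            if group == control_group:
                continue
            study = sample[value_column].dropna()
            if control.size < 2 or study.size < 2:
                continue
            comparison = compare_groups(
                metric, group, study, control_group, control, equal_var=equal_var
            )
            rows.append({"timepoint_h": timepoint, **comparison.__dict__})
    return pd.DataFrame(rows)


def build_report(
    tables: dict[str, pd.DataFrame],
    control_group: str = "syn",
    value_columns: dict[str, str] | None = None,
    rendering_paths: dict[str, str] | None = None,
) -> dict:
    """Assemble per-metric comparison tables plus a markdown summary.

    ``tables`` maps metric names to tidy per-animal frames (columns group,
    timepoint_h, value column).  Single-group tables are passed through with
    an explicit no-comparison flag.  Error bars throughout are standard
    errors of the group mean.
    """
    if not tables:
        raise InvalidParameterError("at least one assay table is required")
    value_columns = value_columns or {}
    comparisons: dict[str, pd.DataFrame] = {}
    lines = [
        "# Assay report",
        "",
        "Two-tailed Student's t-test (pooled variance) against the control "
        f"group {control_group!r}; * p < 0.05, ** p < 0.005; no "
        "multiple-testing correction applied. Error bars are standard errors.",
        "",
    ]
    for metric, table in tables.items():
        column = value_columns.get(metric, "value")
        lines.append(f"## {metric}")
        groups = table["group"].unique()
        if len(groups) < 2 or control_group not in groups:
            comparisons[metric] = pd.DataFrame()
            lines.append("single-group table: no comparisons possible\n")
            continue
        comp = comparison_table(table, metric, control_group, value_column=column)
        comparisons[metric] = comp
        for _, row in comp.iterrows():
            lines.append(
                f"- t={row.timepoint_h} h {row.group_a} vs {row.group_b}: "
                f"{row.mean_a:.3g}±{row.sem_a:.2g} vs {row.mean_b:.3g}±{row.sem_b:.2g}, "
                f"p={row.p_value:.3g} {row.annotation}"
            )
        lines.append("")
    for name, path in (rendering_paths or {}).items():
        lines.append(f"rendering {name}: {path}")
    return {"comparisons": comparisons, "markdown": "\n".join(lines)}
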