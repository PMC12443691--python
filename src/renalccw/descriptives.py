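"""Baseline characteristics tables and unadjusted outcome proportions."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mortality_proportion", "baseline_table", "table_to_markdown"]

#: variables summarised as mean (SD); everything else present is treated as
#: categorical n (%)
CONTINUOUS_DEFAULTS = (
    "age", "cci", "sofa", "heart_rate", "resp_rate", "sbp", "dbp", "mbp",
    "temperature", "spo2", "ph", "bicarbonate", "lactate", "hemoglobin",
    "urea_nitrogen", "creatinine",
)
CATEGORICAL_DEFAULTS = ("female", "race", "sepsis", "mech_vent", "vasopressor")


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mortality_proportion(events: int, n: int) -> float:
    """Percent dead, rounded half-up to one decimal — the convention of
    printed outcome rows like "318 (38.5)"."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    return _round_half_up(100.0 * events / n, 1)


def baseline_table(
    table: pd.DataFrame,
    group_by: str,
    continuous: tuple[str, ...] | None = None,
    categorical: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Two-group baseline characteristics table.

    Continuous variables: mean (SD) per group with a Welch two-sample t-test.
    Categorical variables: n (%) per level with a chi-square test (continuity
    corrected for 2x2).  Means are rounded to 2 decimals and percentages to 1,
    half-up.  Returns tidy rows: variable, level, per-group summary strings,
    p-value.
    """
    levels = [lv for lv in table[group_by].dropna().unique()]
    if len(levels) != 2:
        raise ValueError(f"grouping variable must have two levels, found {levels}")
    g0, g1 = sorted(levels, key=str)
    t0, t1 = table[table[group_by] == g0], table[table[group_by] == g1]
    if len(t0) == 0 or len(t1) == 0:
        raise ValueError("both groups must be nonempty")

    continuous = tuple(c for c in (continuous or CONTINUOUS_DEFAULTS)
                       if c in table.columns)
    categorical = tuple(c for c in (categorical or CATEGORICAL_DEFAULTS)
                        if c in table.columns and c != group_by)

    rows = []
    for v in continuous:
        x0, x1 = t0[v].dropna(), t1[v].dropna()
        if x0.std(ddof=1) == 0 and x1.std(ddof=1) == 0:
            p = 1.0 if x0.mean() == x1.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)
        rows.append({
            "variable": v, "level": "",
            f"{g0} (N={len(t0)})":
                f"{_round_half_up(x0.mean(), 2):.2f} ({_round_half_up(x0.std(ddof=1), 2):.2f})",
            f"{g1} (N={len(t1)})":
                f"{_round_half_up(x1.mean(), 2):.2f} ({_round_half_up(x1.std(ddof=1), 2):.2f})",
            "p": p, "kind": "continuous",
        })
    for v in categorical:
        ct = pd.crosstab(table[v], table[group_by])
        if ct.shape[0] < 2:
            p = 1.0
        else:
            correction = ct.shape == (2, 2)
            p = float(stats.chi2_contingency(ct.to_numpy(), correction=correction)[1])
        for lv in ct.index:
            n0 = int(ct.loc[lv, g0]) if g0 in ct.columns else 0
            n1 = int(ct.loc[lv, g1]) if g1 in ct.columns else 0
            rows.append({
                "variable": v, "level": str(lv),
                f"{g0} (N={len(t0)})": f"{n0} ({_round_half_up(100 * n0 / len(t0), 1)})",
                f"{g1} (N={len(t1)})": f"{n1} ({_round_half_up(100 * n1 / len(t1), 1)})",
                "p": p, "kind": "categorical",
            })
    return pd.DataFrame(rows)


def table_to_markdown(table1: pd.DataFrame) -> str:
    """Render a baseline table as GitHub-flavoured Markdown."""
    cols = [c for c in table1.columns if c != "kind"]
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join(["---"] * len(cols)) + "|"]
    for _, row in table1.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.3g}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
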