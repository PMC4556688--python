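"""Group summaries, planned pairwise t-tests, and report tables.

The study design has nine groups — an untreated control, two enzyme-digested
ectatic models (collagenase COLG, chondroitinase ChaseABC), and for each of
the three, a UVA-crosslinked (CXL) and a crosslinked-with-soluble-collagen
(CXL+Col) arm.  Differences are examined with two-sided two-sample Student
t-tests (pooled variance, as named by the study; Welch available as a flag)
along two planned families: each enzyme-treated group against the untreated
control, and each crosslinked group against the non-crosslinked group with
the same enzyme treatment.  No multiple-testing correction is applied — a
deliberate faithful-reproduction choice.  Significance is declared at
p < 0.05.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "GROUP_LABELS",
    "default_comparison_plan",
    "group_summary",
    "two_sample_ttest",
    "pairwise_ttests",
    "percent_swelling_reduction",
    "round_half_up",
    "build_report",
]

#: The nine experimental conditions, in presentation order.
GROUP_LABELS = (
    "Control",
    "Control-CXL",
    "Control-CXL+Col",
    "COLG",
    "COLG-CXL",
    "COLG-CXL+Col",
    "ChaseABC",
    "ChaseABC-CXL",
    "ChaseABC-CXL+Col",
)

#: footnote symbol attached to a comparison, keyed by its reference group
_FOOTNOTE = {"Control": "*", "COLG": "#", "ChaseABC": "^"}


def default_comparison_plan() -> list[tuple[str, str]]:
    """The study's two families of planned pairs as (group, reference).

    Family 1: enzyme-treated vs untreated control.  Family 2: crosslinked
    (with or without collagen) vs the non-crosslinked group with the same
    enzyme treatment.
    """
    plan = [("COLG", "Control"), ("ChaseABC", "Control")]
    for base in ("Control", "COLG", "ChaseABC"):
        plan.append((f"{base}-CXL", base))
        plan.append((f"{base}-CXL+Col", base))
    return plan


def _values(table: pd.DataFrame, group: str, measure: str | None) -> np.ndarray:
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    v = df.loc[df["group"] == group, "value"].to_numpy(dtype=float)
    if len(v) == 0:
        raise KeyError(f"group {group!r} absent from table")
    return v


def group_summary(table: pd.DataFrame, measure: str | None = None) -> pd.DataFrame:
    """Per-group sample mean and SD (n-1 denominator), one row per group.

    Raises ``ValueError`` if any group is a singleton (SD undefined).
    """
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    out = (
        df.groupby("group", sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, "group"].tolist()
        raise ValueError(f"singleton groups have undefined SD: {bad}")
    return out


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True, axis: int = -1
):
    """Two-sided two-sample t-test; Student (pooled variance) by default.

    Thin, vectorizable wrapper so Monte Carlo calibration exercises the same
    code path as the report layer.  Returns (t, p).
    """
    res = _stats.ttest_ind(a, b, equal_var=equal_var, axis=axis)
    return res.statistic, res.pvalue


def pairwise_ttests(
    table: pd.DataFrame,
    plan: list[tuple[str, str]] | None = None,
    measure: str | None = None,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the planned pairwise comparisons on a tidy per-eye table.

    ``table`` has columns ``group, value`` (optionally ``measure``); the plan
    is a list of (group_a, group_b) pairs, defaulting to the nine-group
    design's two comparison families.  Returns one row per pair with group
    means, SDs, the t statistic, the two-sided p-value and a significance
    flag at ``alpha``.

    Raises ``KeyError`` for a planned group missing from the table and
    ``ValueError`` for groups with fewer than two eyes.
    """
    if plan is None:
        plan = default_comparison_plan()
    rows = []
    for ga, gb in plan:
        va, vb = _values(table, ga, measure), _values(table, gb, measure)
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"comparison {ga} vs {gb} needs n >= 2 per group")
        t, p = two_sample_ttest(va, vb, equal_var=equal_var)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_a": float(np.mean(va)),
                "sd_a": float(np.std(va, ddof=1)),
                "mean_b": float(np.mean(vb)),
                "sd_b": float(np.std(vb, ddof=1)),
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def percent_swelling_reduction(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    measure: str = "swelled_cct_um",
) -> float:
    """Relative swelling reduction of ``group_a`` against reference ``group_b``.

    Returns ``100 * (mean_b - mean_a) / mean_b`` in percent, where b is the
    reference (conventional CXL) group; positive means a swelled less than b.
    Accepts either a tidy per-eye table (columns ``group, value[, measure]``)
    or a summary table with a ``{measure}_mean`` column.
    """
    mean_col = f"{measure}_mean"
    if mean_col in table.columns:
        def get(g: str) -> float:
            sel = table.loc[table["group"] == g, mean_col]
            if sel.empty:
                raise KeyError(f"group {g!r} absent from table")
            return float(sel.iloc[0])
        mean_a, mean_b = get(group_a), get(group_b)
    else:
        mean_a = float(np.mean(_values(table, group_a, measure)))
        mean_b = float(np.mean(_values(table, group_b, measure)))
    if mean_b == 0.0:
        raise ZeroDivisionError("reference group mean is zero")
    return 100.0 * (mean_b - mean_a) / mean_b


def build_report(
    tables: dict[str, pd.DataFrame],
    plan: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Assemble mean +- SD summary tables with significance footnotes.

    ``tables`` maps a measure name to a tidy per-eye table.  For each measure
    the output carries one row per group with a formatted ``mean_sd`` cell and
    the footnote symbols of all significant planned comparisons in which the
    group was compared against a reference (``*`` vs Control, ``#`` vs COLG,
    ``^`` vs ChaseABC).  A ``comparisons`` entry collects the raw test rows of
    every measure.  Empty measures are omitted; output is deterministic in its
    inputs.
    """
    if plan is None:
        plan = default_comparison_plan()
    report: dict[str, pd.DataFrame] = {}
    all_tests = []
    for measure, table in tables.items():
        if table is None or len(table) == 0:
            continue
        summary = group_summary(table, measure=measure if "measure" in table.columns else None)
        tests = pairwise_ttests(
            table,
            plan=plan,
            measure=measure if "measure" in table.columns else None,
            alpha=alpha,
        )
        tests.insert(0, "measure", measure)
        all_tests.append(tests)
        flags = {g: "" for g in summary["group"]}
        for _, row in tests.iterrows():
            if row["significant"] and row["group_b"] in _FOOTNOTE:
                flags[row["group_a"]] = flags.get(row["group_a"], "") + _FOOTNOTE[row["group_b"]]
        summary["mean_sd"] = [
            f"{m:.2f}±{s:.2f}" for m, s in zip(summary["mean"], summary["sd"])
        ]
        summary["flags"] = [flags.get(g, "") for g in summary["group"]]
        report[measure] = summary
    if all_tests:
        report["comparisons"] = pd.concat(all_tests, ignore_index=True)
    return report
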