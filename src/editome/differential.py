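"""Group comparison of editing levels and group-specificity classification.

The specificity score of a unit (gene or site) is

    score = mean_case / (mean_case + mean_ctrl)

over the unit's group-mean editing levels; a unit is case-specific when
score ≥ τ (default 0.75, inclusive) and control-specific under the mirrored
rule (1 − score ≥ τ), so relabeling the groups swaps the two classes exactly.
Group comparisons use the Wilcoxon signed-rank test on per-unit paired group
means, with Bonferroni adjustment across groupings.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import EditingMatrix, GeneSpecificity, GroupTestResult, SampleSheet

CLASS_CASE = "case-specific"
CLASS_CONTROL = "control-specific"
CLASS_SHARED = "shared"
CLASS_UNEVALUABLE = "unevaluable"


def group_mean_editing(
    levels: pd.DataFrame | EditingMatrix,
    sheet: Optional[SampleSheet] = None,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Per-unit arithmetic group means over non-missing cells.

    Accepts a unit × sample levels DataFrame plus a sample sheet, or an
    :class:`EditingMatrix`.  A group mean requires at least ``min_samples``
    non-missing samples; units lacking either group mean are marked
    unevaluable.
    """
    if isinstance(levels, EditingMatrix):
        sheet = levels.sheet
        levels = levels.levels
    if sheet is None:
        raise ValueError("a sample sheet is required")
    sheet.require_two_groups()
    cases = [s for s in levels.columns if s in set(sheet.cases)]
    ctrls = [s for s in levels.columns if s in set(sheet.controls)]
    n_case = levels[cases].notna().sum(axis=1)
    n_ctrl = levels[ctrls].notna().sum(axis=1)
    mean_case = levels[cases].mean(axis=1).where(n_case >= min_samples)
    mean_ctrl = levels[ctrls].mean(axis=1).where(n_ctrl >= min_samples)
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "n_case": n_case,
            "n_ctrl": n_ctrl,
        }
    )
    out["evaluable"] = out["mean_case"].notna() & out["mean_ctrl"].notna()
    return out


def enriched_sites(means: pd.DataFrame) -> set:
    """Units whose case mean strictly exceeds the control mean (ties excluded)."""
    ok = means["evaluable"] & (means["mean_case"] > means["mean_ctrl"])
    return set(means.index[ok])


def specificity_score(mean_case: float, mean_ctrl: float) -> float:
    """mean_case / (mean_case + mean_ctrl); NaN on 0/0 or missing input."""
    if mean_case != mean_case or mean_ctrl != mean_ctrl:  # NaN input
        return float("nan")
    if mean_case < 0 or mean_ctrl < 0:
        raise ValueError("group mean editing levels must be non-negative")
    total = mean_case + mean_ctrl
    if total == 0:
        return float("nan")
    return mean_case / total


def classify_specificity(means: pd.DataFrame, tau: float = 0.75):
    """Classify each unit as case-specific / control-specific / shared / unevaluable.

    Returns ``(specificities, class_counts)``; the inclusive rule is
    score ≥ τ for case-specific and (1 − score) ≥ τ for control-specific.
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0.5, 1], got {tau}")
    out = []
    counts = {CLASS_CASE: 0, CLASS_CONTROL: 0, CLASS_SHARED: 0, CLASS_UNEVALUABLE: 0}
    for unit, row in means.iterrows():
        if not row["evaluable"]:
            score, klass = float("nan"), CLASS_UNEVALUABLE
        else:
            score = specificity_score(row["mean_case"], row["mean_ctrl"])
            # tiny absolute tolerance so printed decimal boundaries such as
            # 0.6/(0.6+0.2) = 0.75 classify as the inclusive rule intends
            if score != score:
                klass = CLASS_UNEVALUABLE
            elif score >= tau - 1e-12:
                klass = CLASS_CASE
            elif 1.0 - score >= tau - 1e-12:
                klass = CLASS_CONTROL
            else:
                klass = CLASS_SHARED
        counts[klass] += 1
        out.append(
            GeneSpecificity(
                gene_id=str(unit),
                mean_case=float(row["mean_case"]),
                mean_ctrl=float(row["mean_ctrl"]),
                score=float(score),
                klass=klass,
            )
        )
    return out, counts


def specificity_frame(specificities: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.mean_case, s.mean_ctrl, s.score, s.klass) for s in specificities],
        columns=["gene_id", "mean_case", "mean_ctrl", "score", "class"],
    )


# ---------------------------------------------------------------------------
# signed-rank group comparison
# ---------------------------------------------------------------------------

def signed_rank_test(x: Sequence, y: Sequence, exact_max_n: int = 25):
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped before ranking.  The exact null
    distribution is used for n ≤ ``exact_max_n`` non-zero, untied
    differences; otherwise the normal approximation with continuity
    correction.  With fewer than one non-zero difference the p-value is
    reported as 1 with a flag (the documented convention for identical
    vectors).  Returns ``(statistic, p_value, flag)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = x - y
    diffs = diffs[(diffs == diffs)]  # drop NaN pairs
    nonzero = diffs[diffs != 0.0]
    if nonzero.size < 1:
        return 0.0, 1.0, "all-zero-differences"
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= exact_max_n and not has_ties:
        res = stats.wilcoxon(nonzero, method="exact", zero_method="wilcox")
        flag = ""
    else:
        res = stats.wilcoxon(nonzero, method="approx", correction=True, zero_method="wilcox")
        flag = "normal-approximation"
    return float(res.statistic), float(res.pvalue), flag


def compare_groups(
    paired: dict,
    adjust: str = "bonferroni",
) -> list:
    """Signed-rank comparison for one or more groupings, Bonferroni-adjusted.

    ``paired`` maps a grouping label to a ``(case_values, ctrl_values)``
    pair of equal-length per-unit vectors (typically per-unit group means).
    """
    labels = sorted(paired)
    raw = []
    for label in labels:
        x, y = paired[label]
        stat, p, flag = signed_rank_test(x, y)
        raw.append((label, stat, p, len(np.asarray(x)), flag))
    pvals = [r[2] for r in raw]
    if adjust == "bonferroni":
        adjusted = multipletests(pvals, method="bonferroni")[1]
    elif adjust in (None, "none"):
        adjusted = pvals
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        GroupTestResult(
            label=label,
            statistic=stat,
            p_value=p,
            adjusted_p=float(adj),
            n_units=n,
            flag=flag,
        )
        for (label, stat, p, n, flag), adj in zip(raw, adjusted)
    ]


def compare_matrix_groups(
    levels: pd.DataFrame | EditingMatrix,
    sheet: Optional[SampleSheet] = None,
    label: str = "case-vs-control",
    min_samples: int = 2,
) -> GroupTestResult:
    """Convenience wrapper: paired signed-rank on per-unit group means of a matrix."""
    means = group_mean_editing(levels, sheet, min_samples=min_samples)
    ok = means[means["evaluable"]]
    [result] = compare_groups({label: (ok["mean_case"].to_numpy(), ok["mean_ctrl"].to_numpy())})
    return result
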