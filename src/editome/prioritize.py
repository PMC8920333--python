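"""Three-criterion target prioritization and correlation ranking.

A candidate target must be (a) downregulated upon knockdown of the editing
enzyme (fold change strictly greater than the threshold, adjusted P strictly
below it), (b) reduced in editing level between conditions, and (c)
negatively associated with patient survival (median-split log-rank P < 0.05
with the high-expression stratum faring worse).  Survivors of the three-way
intersection are ranked by the sum of ranks of two product-moment
correlations across samples: editing-enzyme expression vs the gene's overall
editing level, and the gene's own expression vs its editing level.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test


def filter_downregulated(
    de: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> set:
    """Genes with fold change strictly greater than ``fc_threshold`` down and
    adjusted P strictly below ``p_threshold``."""
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    hits = de[
        (de["log2_fold_change"] < -math.log2(fc_threshold)) & (de["adjusted_p"] < p_threshold)
    ]
    return set(hits["gene_id"])


def editing_reduction_genes(
    levels_control: pd.DataFrame | pd.Series,
    levels_knockdown: pd.DataFrame | pd.Series,
    delta: float = 0.0,
) -> set:
    """Genes whose pooled editing level drops by strictly more than ``delta``.

    Inputs are gene × sample matrices of pooled levels (row means are taken
    over non-missing samples) or per-gene Series; genes must be evaluable
    in both conditions.
    """
    a = levels_control.mean(axis=1) if isinstance(levels_control, pd.DataFrame) else levels_control
    b = (
        levels_knockdown.mean(axis=1)
        if isinstance(levels_knockdown, pd.DataFrame)
        else levels_knockdown
    )
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    ok = a.notna() & b.notna() & ((a - b) > delta)
    return set(common[ok])


def survival_screen(
    survival: pd.DataFrame, genes: Iterable, alpha: float = 0.05
) -> pd.DataFrame:
    """Median-split expression survival screen.

    For each gene: split patients at the median expression (strictly above
    the median is "high"), compare the two Kaplan-Meier strata with a
    two-sided log-rank test, and take the hazard direction from a
    univariate proportional-hazards fit on the high-expression indicator.
    A gene passes iff p < alpha and high expression carries the worse
    outcome (hazard ratio > 1).  Genes with constant expression or a
    degenerate split are unevaluable.
    """
    rows = []
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    for gene in sorted(set(genes)):
        if gene not in survival.columns:
            rows.append((gene, np.nan, np.nan, np.nan, False, False))
            continue
        expr = survival[gene].to_numpy(dtype=float)
        median = float(np.median(expr))
        high = expr > median
        if high.sum() < 2 or (~high).sum() < 2 or event.sum() == 0:
            rows.append((gene, np.nan, np.nan, np.nan, False, False))
            continue
        lr = logrank_test(time[high], time[~high], event[high], event[~high])
        frame = pd.DataFrame({"time": time, "event": event, "high": high.astype(int)})
        try:
            cph = CoxPHFitter()
            cph.fit(frame, duration_col="time", event_col="event")
            coef = float(cph.params_["high"])
        except Exception:  # non-converging degenerate fits are unevaluable
            rows.append((gene, float(lr.test_statistic), float(lr.p_value), np.nan, False, False))
            continue
        adverse = coef > 0
        passes = (lr.p_value < alpha) and adverse
        rows.append(
            (gene, float(lr.test_statistic), float(lr.p_value), coef, bool(adverse), bool(passes))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "logrank_statistic", "p_value", "log_hazard_high", "adverse", "passes"],
    ).set_index("gene_id")


def intersect_candidates(
    downregulated: Iterable, editing_reduced: Iterable, adverse_survival: Iterable
) -> list:
    """Exact three-way intersection, deterministically sorted."""
    return sorted(set(downregulated) & set(editing_reduced) & set(adverse_survival))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    mask = (x == x) & (y == y)
    x, y = x[mask], y[mask]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rank_candidates(
    candidates: Sequence,
    enzyme_expression: pd.Series,
    editing_levels: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Rank candidates by correlation of editing with enzyme and own expression.

    ``enzyme_expression`` is a per-sample Series; ``editing_levels`` and
    ``expression`` are gene × sample matrices sharing those samples.
    ``combined_rank`` is the rank-sum of the two correlations (descending);
    candidates with an undefined correlation rank last, flagged, and ties
    break lexicographically by gene id.
    """
    samples = [s for s in editing_levels.columns if s in enzyme_expression.index]
    rows = []
    for gene in sorted(set(candidates)):
        if gene not in editing_levels.index or gene not in expression.index:
            rows.append((gene, float("nan"), float("nan")))
            continue
        editing = editing_levels.loc[gene, samples].to_numpy(dtype=float)
        r_enzyme = _safe_corr(enzyme_expression.loc[samples].to_numpy(dtype=float), editing)
        r_expr = _safe_corr(expression.loc[gene, samples].to_numpy(dtype=float), editing)
        rows.append((gene, r_enzyme, r_expr))
    out = pd.DataFrame(rows, columns=["gene_id", "r_enzyme_vs_editing", "r_expr_vs_editing"])
    out["degenerate"] = out["r_enzyme_vs_editing"].isna() | out["r_expr_vs_editing"].isna()
    # descending rank of each correlation; NaN ranks last
    rank_a = out["r_enzyme_vs_editing"].rank(ascending=False, na_option="bottom")
    rank_b = out["r_expr_vs_editing"].rank(ascending=False, na_option="bottom")
    out["rank_sum"] = rank_a + rank_b
    out = out.sort_values(["degenerate", "rank_sum", "gene_id"]).reset_index(drop=True)
    out["combined_rank"] = np.arange(1, len(out) + 1)
    return out


def run_prioritization(
    de: pd.DataFrame,
    levels_control: pd.DataFrame,
    levels_knockdown: pd.DataFrame,
    survival: pd.DataFrame,
    enzyme_expression: Optional[pd.Series] = None,
    editing_levels: Optional[pd.DataFrame] = None,
    expression: Optional[pd.DataFrame] = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    delta: float = 0.0,
    alpha: float = 0.05,
):
    """Full funnel: DE filter ∩ editing reduction ∩ adverse survival, then ranking.

    The survival screen is evaluated on the genes already passing the first
    two criteria (the screen is per-gene, so this does not change the
    intersection).  Returns ``(candidates, ranking, stage_sets)``; ranking
    is None when the expression inputs are not supplied.
    """
    downregulated = filter_downregulated(de, fc_threshold, p_threshold)
    reduced = editing_reduction_genes(levels_control, levels_knockdown, delta)
    pre = sorted(downregulated & reduced)
    screen = survival_screen(survival, pre, alpha)
    adverse = set(screen.index[screen["passes"]])
    candidates = intersect_candidates(downregulated, reduced, adverse)
    ranking = None
    if enzyme_expression is not None and editing_levels is not None and expression is not None:
        ranking = rank_candidates(candidates, enzyme_expression, editing_levels, expression)
    stage_sets = {
        "downregulated": downregulated,
        "editing_reduced": reduced,
        "adverse_survival": adverse,
    }
    return candidates, ranking, stage_sets
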