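"""Editing-level statistics at site, gene and sample resolution, plus context annotation.

The editing level of a site in a sample is the number of edited reads divided
by the total number of reads covering the site; it is *missing* (NaN) when
coverage is below the minimum depth.  Gene- and sample-level values pool raw
read counts before dividing (coverage-weighted pooling), not means of ratios:

    level = Σ edited_reads / Σ total_reads   over all covered sites.
"""
from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    ContextSummary,
    EditingMatrix,
    EditingSite,
    FilterThresholds,
    GeneModel,
    REGION_PRIORITY,
    REGIONS,
    REPEAT_FAMILIES,
    SampleSheet,
    site_key_str,
)


def site_editing_level(edited_reads: int, total_reads: int, min_coverage: int = 10) -> float:
    """Editing level of one site in one sample; NaN below ``min_coverage``."""
    if edited_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    if edited_reads > total_reads:
        raise ValueError(f"edited_reads ({edited_reads}) exceeds total_reads ({total_reads})")
    if total_reads < min_coverage:
        return float("nan")
    return edited_reads / total_reads


def pooled_editing_level(
    edited: Sequence, totals: Sequence, min_coverage: int = 10
) -> float:
    """Coverage-weighted pooled level: Σ edited / Σ total over covered sites."""
    edited = np.asarray(edited, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if edited.shape != totals.shape:
        raise ValueError("edited and total arrays must align")
    if (edited > totals).any():
        raise ValueError("edited_reads exceeds total_reads")
    covered = totals >= min_coverage
    denom = totals[covered].sum()
    if denom == 0:
        return float("nan")
    return float(edited[covered].sum() / denom)


def gene_editing_level(observations: Iterable, min_coverage: int = 10) -> float:
    """Pooled editing level over a gene's known sites (one sample or pooled samples)."""
    obs = list(observations)
    return pooled_editing_level(
        [o.edited_reads for o in obs], [o.total_reads for o in obs], min_coverage
    )


def sample_editing_level(observations: Iterable, min_coverage: int = 10) -> float:
    """Pooled editing level over all sites observed in one sample."""
    return gene_editing_level(observations, min_coverage)


def filter_observations(observations, sites: Sequence):
    """Subset a pileup (DataFrame or observation list) to a site universe.

    The pileup usually covers every candidate position; the editing matrix
    is built over discovered sites only, so restrict first.
    """
    wanted = {s.key for s in sites}
    if isinstance(observations, pd.DataFrame):
        keys = list(
            zip(
                observations["chrom"].astype(str),
                observations["pos"].astype(int),
                observations["ref"].astype(str),
                observations["alt"].astype(str),
            )
        )
        mask = pd.Series([k in wanted for k in keys], index=observations.index)
        return observations[mask]
    return [o for o in observations if o.key in wanted]


def build_editing_matrix(
    observations,
    sites: Sequence,
    sheet: SampleSheet,
    thresholds: FilterThresholds = FilterThresholds(),
) -> EditingMatrix:
    """Assemble the site × sample editing-level and coverage matrices.

    ``observations`` may be a list of :class:`SiteObservation` or an
    equivalent DataFrame.  Observations at sites or samples outside the
    given universe raise; rows and columns come out sorted, so the result
    is invariant to input order.
    """
    from .io import observations_to_frame

    frame = observations if isinstance(observations, pd.DataFrame) else observations_to_frame(observations)
    site_keys = {site_key_str(s.key): s for s in sites}
    samples = set(sheet.sample_ids)

    keys = (
        frame["chrom"].astype(str)
        + ":"
        + frame["pos"].astype(str)
        + ":"
        + frame["ref"].astype(str)
        + ">"
        + frame["alt"].astype(str)
    )
    unknown_sites = set(keys) - set(site_keys)
    if unknown_sites:
        raise ValueError(f"observations at unknown sites, e.g. {sorted(unknown_sites)[0]}")
    unknown_samples = set(frame["sample"]) - samples
    if unknown_samples:
        raise ValueError(f"observations for unknown samples: {sorted(unknown_samples)}")

    work = pd.DataFrame(
        {
            "site": keys,
            "sample": frame["sample"],
            "edited": frame["edited_reads"].astype(float),
            "total": frame["total_reads"].astype(float),
        }
    )
    cov = work.pivot_table(index="site", columns="sample", values="total", aggfunc="sum")
    edited = work.pivot_table(index="site", columns="sample", values="edited", aggfunc="sum")
    row_index = sorted(site_keys)
    col_index = sorted(sheet.sample_ids)
    cov = cov.reindex(index=row_index, columns=col_index)
    edited = edited.reindex(index=row_index, columns=col_index)
    levels = edited / cov.where(cov >= thresholds.min_coverage)
    coverage = cov.fillna(0.0)
    return EditingMatrix(levels=levels, coverage=coverage, sheet=sheet, sites=site_keys)


def build_gene_matrix(matrix: EditingMatrix, min_coverage: Optional[int] = None) -> pd.DataFrame:
    """Gene × sample matrix of pooled editing levels.

    Pools raw counts (level × coverage) across each gene's sites per sample;
    cells with no covered site are NaN.  Sites without a gene are dropped.
    """
    if min_coverage is None:
        min_coverage = 10
    gene_of = {k: s.gene_id for k, s in matrix.sites.items() if s.gene_id is not None}
    keys = [k for k in matrix.levels.index if k in gene_of]
    if not keys:
        return pd.DataFrame(columns=matrix.levels.columns)
    cov = matrix.coverage.loc[keys]
    covered = cov >= min_coverage
    edited = (matrix.levels.loc[keys] * cov).where(covered)
    genes = pd.Series([gene_of[k] for k in keys], index=keys, name="gene")
    sum_edited = edited.groupby(genes).sum(min_count=1)
    sum_total = cov.where(covered).groupby(genes).sum(min_count=1)
    out = sum_edited / sum_total
    return out.sort_index()


def sample_levels(matrix: EditingMatrix, min_coverage: int = 10) -> pd.Series:
    """Per-sample pooled editing level over all sites in the matrix."""
    cov = matrix.coverage
    covered = cov >= min_coverage
    edited = (matrix.levels * cov).where(covered)
    return edited.sum() / cov.where(covered).sum()


# ---------------------------------------------------------------------------
# context annotation
# ---------------------------------------------------------------------------

class _ContextIndex:
    """Per-chromosome interval trees over gene features and repeats."""

    def __init__(self, model: GeneModel) -> None:
        self.features: dict = defaultdict(IntervalTree)
        self.repeats: dict = defaultdict(IntervalTree)
        for iv in model.intervals:
            # IntervalTree is half-open; store [start, end+1)
            self.features[iv.chrom].addi(iv.start, iv.end + 1, iv)
        for rv in model.repeat_intervals:
            self.repeats[rv.chrom].addi(rv.start, rv.end + 1, rv)

    def features_at(self, chrom: str, pos: int) -> list:
        return [hit.data for hit in self.features[chrom].at(pos)]

    def repeats_at(self, chrom: str, pos: int) -> list:
        return [hit.data for hit in self.repeats[chrom].at(pos)]


_REGION_RANK = {region: i for i, region in enumerate(REGION_PRIORITY)}


def _assign_strand(site: EditingSite, strands: set) -> str:
    if len(strands) == 1:
        return next(iter(strands))
    if len(strands) == 2:
        # genes on both strands: take the strand whose orientation yields A->G
        # if exactly one does, otherwise leave unknown
        oriented = []
        for strand in ("+", "-"):
            pair = (site.ref_base, site.alt_base)
            if strand == "+" and pair == ("A", "G"):
                oriented.append(strand)
            if strand == "-" and pair == ("T", "C"):
                oriented.append(strand)
        if len(oriented) == 1:
            return oriented[0]
    return "unknown"


def annotate_site_context(sites: Sequence, model: GeneModel) -> list:
    """Fill gene_id, region, repeat_family and strand from the gene model.

    Region comes from the highest-priority overlapping feature
    (3UTR > 5UTR > CDS > ncRNA > intron > intergenic); the gene is the one
    contributing that feature.  Repeat family comes from any overlapping
    repeat interval, else "nonrepetitive".
    """
    index = _ContextIndex(model)
    out = []
    for site in sites:
        feats = index.features_at(site.chrom, site.pos)
        if feats:
            best = min(feats, key=lambda iv: (_REGION_RANK[iv.feature], iv.gene_id))
            strand = _assign_strand(site, {iv.strand for iv in feats})
            gene_id, region = best.gene_id, best.feature
        else:
            gene_id, region, strand = None, "intergenic", "unknown"
        reps = index.repeats_at(site.chrom, site.pos)
        family = sorted({r.family for r in reps})[0] if reps else "nonrepetitive"
        out.append(
            site.with_context(gene_id=gene_id, region=region, repeat_family=family, strand=strand)
        )
    return out


def summarize_context(sites: Sequence, labels: Optional[Sequence] = None) -> ContextSummary:
    """Counts of sites per region class and repeat family, per site-set label."""
    if labels is None:
        labels = ["all"] * len(sites)
    if len(labels) != len(sites):
        raise ValueError("labels must align with sites")
    label_values = sorted(set(labels))
    region_counts = pd.DataFrame(0, index=label_values, columns=list(REGIONS), dtype=int)
    repeat_counts = pd.DataFrame(0, index=label_values, columns=list(REPEAT_FAMILIES), dtype=int)
    for site, label in zip(sites, labels):
        region_counts.loc[label, site.region] += 1
        repeat_counts.loc[label, site.repeat_family] += 1
    return ContextSummary(region_counts=region_counts, repeat_counts=repeat_counts)
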