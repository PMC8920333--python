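"""The editing-site discovery cascade and the 12-type variant spectrum.

Raw per-sample RNA variant calls pass through, in order:

1. quality — ≥1 mismatched read, base quality ≥25, mapping quality ≥20,
   site coverage ≥10 (all inclusive, per record);
2. DNA-variant subtraction — remove any site key found in the matched WES
   calls or public germline/somatic catalogs;
3. editing-catalog restriction — keep only keys curated in the known-editing
   catalog (the RADAR-style whitelist);
4. informative-sample rule — keep sites covered at the minimum depth in at
   least the required number of samples.

Every stage is a pure set predicate over site keys, so the final site set is
invariant to record order and catalog order; only the attrition report
depends on stage order.
"""
from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .quantify import annotate_site_context
from .types import (
    BASES,
    COMPLEMENT,
    Catalog,
    EditingSite,
    FilterReport,
    FilterThresholds,
    GeneModel,
    SampleSheet,
)

logger = logging.getLogger(__name__)

#: the 12 transcript-oriented substitution classes
VARIANT_TYPES = tuple(
    f"{ref}-to-{alt}" for ref in BASES for alt in BASES if ref != alt
)


def classify_variant_type(ref_base: str, alt_base: str, strand: str, with_flag: bool = False):
    """Label a substitution as one of the 12 types, transcript-oriented.

    On the '−' strand both bases are complemented before labeling.  With
    unknown strand the label is in genomic orientation; pass
    ``with_flag=True`` to additionally receive ``True`` when the label is
    transcript-oriented, ``False`` when it is genomic-orientation only.
    """
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if strand not in ("+", "-", "unknown"):
        raise ValueError(f"strand must be +, - or unknown, got {strand!r}")
    if strand == "-":
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    label = f"{ref_base}-to-{alt_base}"
    if with_flag:
        return label, strand != "unknown"
    return label


def tabulate_variant_types(
    records: Sequence,
    model: Optional[GeneModel] = None,
    sheet: Optional[SampleSheet] = None,
):
    """Per-sample counts of the 12 substitution types, plus per-group means.

    Strand (hence transcript orientation) is taken from the gene model when
    given; without a model all records count in genomic orientation.
    Returns ``(counts, group_means)``; ``group_means`` is None without a
    sample sheet.
    """
    if sheet is not None:
        known = set(sheet.sample_ids)
        for r in records:
            if r.sample_id not in known:
                raise ValueError(f"sample {r.sample_id!r} absent from sample sheet")

    strand_of = {}
    if model is not None:
        keys = sorted({r.key for r in records})
        probes = [EditingSite(c, p, rb, ab) for c, p, rb, ab in keys]
        for key, annotated in zip(keys, annotate_site_context(probes, model)):
            strand_of[key] = annotated.strand

    samples = sorted(sheet.sample_ids) if sheet is not None else sorted({r.sample_id for r in records})
    counts = pd.DataFrame(0, index=samples, columns=list(VARIANT_TYPES), dtype=int)
    for r in records:
        strand = strand_of.get(r.key, "unknown")
        label = classify_variant_type(r.ref_base, r.alt_base, strand)
        counts.loc[r.sample_id, label] += 1

    group_means = None
    if sheet is not None:
        groups = pd.Series(
            {row.sample_id: row.group for row in sheet.frame.itertuples(index=False)}
        )
        group_means = counts.groupby(groups.reindex(counts.index)).mean()
    return counts, group_means


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def apply_quality_filters(records: Iterable, thresholds: FilterThresholds = FilterThresholds()) -> list:
    """Keep records passing all inclusive quality thresholds."""
    return [
        r
        for r in records
        if r.n_alt_reads >= thresholds.min_alt_reads
        and r.base_quality >= thresholds.min_base_quality
        and r.mapping_quality >= thresholds.min_mapping_quality
        and r.coverage >= thresholds.min_coverage
    ]


def subtract_known_dna_variants(records: Iterable, catalogs: Sequence):
    """Remove records whose key appears in the union of DNA-variant catalogs.

    Returns ``(survivors, removed_by_source)``; a removed record is
    attributed to the first catalog (in list order) containing its key.
    """
    removed_by_source: dict = {c.source_label: 0 for c in catalogs}
    survivors = []
    for r in records:
        hit = next((c for c in catalogs if r.key in c), None)
        if hit is None:
            survivors.append(r)
        else:
            removed_by_source[hit.source_label] += 1
    return survivors, removed_by_source


def restrict_to_editing_catalog(records: Iterable, editing_catalog: Catalog) -> list:
    """Keep only records at positions curated in the known-editing catalog."""
    if len(editing_catalog) == 0:
        warnings.warn("editing catalog is empty; no sites can survive", stacklevel=2)
    return [r for r in records if r.key in editing_catalog]


def select_informative_sites(
    observations: Iterable, thresholds: FilterThresholds = FilterThresholds()
) -> set:
    """Site keys covered at ≥ min_coverage in ≥ min_informative_samples samples."""
    per_site_samples: dict = defaultdict(set)
    for o in observations:
        if o.total_reads >= thresholds.min_coverage:
            per_site_samples[o.key].add(o.sample_id)
    return {
        key
        for key, samps in per_site_samples.items()
        if len(samps) >= thresholds.min_informative_samples
    }


def run_discovery(
    records: Sequence,
    catalogs: Sequence = (),
    editing_catalog: Optional[Catalog] = None,
    model: Optional[GeneModel] = None,
    thresholds: FilterThresholds = FilterThresholds(),
    observations: Optional[Sequence] = None,
):
    """Run the full cascade; returns ``(sites, report)``.

    ``records`` are the pooled per-sample variant calls (any order).  The
    informative-sample rule uses the pileup ``observations`` when given —
    a site can be deeply covered in samples where it shows no mismatch —
    and falls back to the coverage carried on the variant records otherwise.
    Surviving sites are annotated against ``model`` when provided.
    """
    report = FilterReport()
    n_input = len({r.key for r in records})

    kept = apply_quality_filters(records, thresholds)
    report.add_stage("quality", n_input, len({r.key for r in kept}))

    kept, removed_by_source = subtract_known_dna_variants(kept, catalogs)
    report.removed_by_source = removed_by_source
    report.add_stage("dna_subtraction", report.stages[-1][2], len({r.key for r in kept}))

    if editing_catalog is not None:
        kept = restrict_to_editing_catalog(kept, editing_catalog)
    report.add_stage("editing_catalog", report.stages[-1][2], len({r.key for r in kept}))

    keys = {r.key for r in kept}
    if observations is not None:
        informative = select_informative_sites(observations, thresholds)
    else:
        informative = select_informative_sites(
            (
                _record_as_observation(r)
                for r in records
            ),
            thresholds,
        )
    keys &= informative
    report.add_stage("informative", report.stages[-1][2], len(keys))

    sites = [EditingSite(c, p, rb, ab) for c, p, rb, ab in sorted(keys)]
    if model is not None:
        sites = annotate_site_context(sites, model)
    logger.info("discovery cascade: %s", report.to_frame().to_dict("records"))
    return sites, report


def _record_as_observation(record):
    from .types import SiteObservation

    return SiteObservation(
        chrom=record.chrom,
        pos=record.pos,
        ref_base=record.ref_base,
        alt_base=record.alt_base,
        sample_id=record.sample_id,
        edited_reads=record.n_alt_reads,
        total_reads=record.coverage,
    )
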