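"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* VCF (v4.x, plain text or bgzipped) carries per-record site-aggregate
  annotations in INFO: ``DP`` (total depth), ``AD`` (ref,alt depths, Number=R),
  ``BQ`` (mean alt base quality) and ``MQ`` (mean mapping quality).  These are
  the fields the quality filters consume; multiallelic records are split into
  biallelic records on read and indels are skipped with a logged count.
* VCF and the in-memory model are 1-based inclusive; BED is 0-based
  half-open and converted once at this boundary.
* All tabular formats are plain TSV read/written with pandas.
"""
from __future__ import annotations

import logging
import os
import warnings
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .types import (
    BASES,
    Catalog,
    GeneInterval,
    GeneModel,
    RepeatInterval,
    SampleSheet,
    SiteObservation,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_VCF_INFO_LINES = (
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">',
    '##INFO=<ID=AD,Number=R,Type=Integer,Description="Read depths per allele (ref first)">',
    '##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality of mismatched reads">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality at the site">',
)

OBSERVATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "edited_reads", "total_reads"]


def _require_file(path) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")


# ---------------------------------------------------------------------------
# variant records (VCF)
# ---------------------------------------------------------------------------

def read_variant_records(path, sample_id: str) -> list:
    """Read one sample's variant calls from a VCF into :class:`VariantRecord` s.

    Multiallelic lines are split into biallelic records; indels and
    symbolic alleles are skipped (the skip count is logged).
    """
    _require_file(path)
    records: list = []
    n_skipped_indels = 0
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for line_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                ref = rec.ref
                alts = rec.alts or ()
                info = rec.info
                depth = int(info["DP"])
                ad = tuple(int(x) for x in info["AD"])
                bq = float(info["BQ"])
                mq = float(info["MQ"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed record #{line_no} at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            for i, alt in enumerate(alts):
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    n_skipped_indels += 1
                    continue
                n_alt = ad[i + 1] if len(ad) > i + 1 else 0
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_base=ref,
                        alt_base=alt,
                        n_alt_reads=n_alt,
                        base_quality=bq,
                        mapping_quality=mq,
                        coverage=depth,
                        sample_id=sample_id,
                    )
                )
    if n_skipped_indels:
        logger.info("%s: skipped %d indel/non-SNV alleles", path, n_skipped_indels)
    read_variant_records.last_skip_count = n_skipped_indels
    return records


read_variant_records.last_skip_count = 0


def _vcf_header(records: Sequence) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chrom_max: dict = {}
    for r in records:
        chrom_max[r.chrom] = max(chrom_max.get(r.chrom, 0), r.pos)
    for chrom in sorted(chrom_max):
        header.add_line(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1000}>")
    for line in _VCF_INFO_LINES:
        header.add_line(line)
    return header


def write_variant_records(path, records: Sequence) -> None:
    """Write :class:`VariantRecord` s to a plain-text VCF (sorted by position)."""
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_base, r.alt_base))
    header = _vcf_header(ordered)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for r in ordered:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos, alleles=(r.ref_base, r.alt_base)
            )
            rec.info["DP"] = r.coverage
            rec.info["AD"] = (r.coverage - r.n_alt_reads, r.n_alt_reads)
            rec.info["BQ"] = round(float(r.base_quality), 2)
            rec.info["MQ"] = round(float(r.mapping_quality), 2)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# catalogs (VCF or TSV)
# ---------------------------------------------------------------------------

def read_catalog(path, source_label: str) -> Catalog:
    """Read a known-variant catalog from VCF or TSV; duplicates collapse."""
    _require_file(path)
    name = str(path)
    keys: set = set()
    if name.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(os.fspath(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1 and rec.ref in BASES and alt in BASES:
                        keys.add((rec.chrom, rec.pos, rec.ref, alt))
    else:
        if os.path.getsize(path) == 0:
            warnings.warn(f"catalog file {path} is empty", stacklevel=2)
            return Catalog(frozenset(), source_label)
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: catalog missing columns {sorted(missing)}")
        if frame.empty:
            warnings.warn(f"catalog file {path} has no entries", stacklevel=2)
        keys = {
            (str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"])
        }
    return Catalog(frozenset(keys), source_label)


def write_catalog(path, catalog: Catalog) -> None:
    frame = pd.DataFrame(sorted(catalog.entries), columns=["chrom", "pos", "ref", "alt"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pileup observations (TSV)
# ---------------------------------------------------------------------------

def read_observations(path) -> list:
    """Read a pileup table of per-site, per-sample edited/total read counts."""
    frame = read_observation_frame(path)
    return [
        SiteObservation(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_base=str(row.ref),
            alt_base=str(row.alt),
            sample_id=str(row.sample),
            edited_reads=int(row.edited_reads),
            total_reads=int(row.total_reads),
        )
        for row in frame.itertuples(index=False)
    ]


def read_observation_frame(path) -> pd.DataFrame:
    """Read and validate the pileup TSV as a DataFrame (file order preserved)."""
    _require_file(path)
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample": str})
    missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: pileup missing columns {sorted(missing)}")
    neg = (frame["edited_reads"] < 0) | (frame["total_reads"] < 0)
    if neg.any():
        row = int(frame.index[neg][0])
        raise ValueError(f"{path}: negative read count at row {row}")
    bad = frame["edited_reads"] > frame["total_reads"]
    if bad.any():
        row = int(frame.index[bad][0])
        raise ValueError(f"{path}: edited_reads > total_reads at row {row}")
    return frame


def observations_to_frame(observations: Iterable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (o.chrom, o.pos, o.ref_base, o.alt_base, o.sample_id, o.edited_reads, o.total_reads)
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )


def write_observations(path, observations) -> None:
    if isinstance(observations, pd.DataFrame):
        frame = observations[OBSERVATION_COLUMNS]
    else:
        frame = observations_to_frame(observations)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    _require_file(path)
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleSheet(frame)


def write_sample_sheet(path, sheet: SampleSheet) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene model (BED6 / GFF3)
# ---------------------------------------------------------------------------

def read_gene_model(features_bed, repeats_bed=None) -> GeneModel:
    """Build a :class:`GeneModel` from BED6 files.

    The feature BED encodes ``gene_id|feature`` in the name column; the
    repeat BED encodes the repeat family in the name column.  BED 0-based
    half-open coordinates are converted to 1-based inclusive here.
    """
    _require_file(features_bed)
    intervals = []
    bed = pd.read_csv(
        features_bed,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    for row in bed.itertuples(index=False):
        gene_id, feature = str(row.name).split("|", 1)
        intervals.append(
            GeneInterval(
                chrom=str(row.chrom),
                start=int(row.start) + 1,
                end=int(row.end),
                strand=str(row.strand),
                gene_id=gene_id,
                feature=feature,
            )
        )
    repeats = _read_repeat_bed(repeats_bed) if repeats_bed is not None else []
    return GeneModel(intervals=intervals, repeat_intervals=repeats)


def _read_repeat_bed(repeats_bed) -> list:
    _require_file(repeats_bed)
    rbed = pd.read_csv(
        repeats_bed,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return [
        RepeatInterval(
            chrom=str(row.chrom), start=int(row.start) + 1, end=int(row.end), family=str(row.name)
        )
        for row in rbed.itertuples(index=False)
    ]


_GFF_FEATURE_MAP = {
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "CDS": "CDS",
    "intron": "intron",
    "ncRNA": "ncRNA",
    "exon": "CDS",  # exon annotations lacking a UTR/CDS split map to CDS
}


def read_gene_model_gff(gff_path, repeats_bed=None) -> GeneModel:
    """Build a :class:`GeneModel` from a GFF3 file (gene_id from ``Parent`` or ``ID``)."""
    import gffutils

    _require_file(gff_path)
    db = gffutils.create_db(
        os.fspath(gff_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    intervals = []
    for feat in db.all_features():
        feature = _GFF_FEATURE_MAP.get(feat.featuretype)
        if feature is None:
            continue
        parent = feat.attributes.get("Parent", feat.attributes.get("ID", ["?"]))[0]
        intervals.append(
            GeneInterval(
                chrom=feat.seqid,
                start=feat.start,  # GFF3 is already 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                gene_id=parent,
                feature=feature,
            )
        )
    repeats = []
    if repeats_bed is not None:
        repeats = _read_repeat_bed(repeats_bed)
    return GeneModel(intervals=intervals, repeat_intervals=repeats)


def write_gene_model(features_bed, repeats_bed, model: GeneModel) -> None:
    rows = [
        (iv.chrom, iv.start - 1, iv.end, f"{iv.gene_id}|{iv.feature}", 0, iv.strand)
        for iv in model.intervals
    ]
    pd.DataFrame(rows).to_csv(features_bed, sep="\t", index=False, header=False)
    rrows = [(rv.chrom, rv.start - 1, rv.end, rv.family, 0, ".") for rv in model.repeat_intervals]
    pd.DataFrame(rrows).to_csv(repeats_bed, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# matrices and generic tables
# ---------------------------------------------------------------------------

def write_matrix(path, frame: pd.DataFrame, index_name: str = "site") -> None:
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    _require_file(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2_fold_change, adjusted_p."""
    _require_file(path)
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2_fold_change", "adjusted_p"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    if ((frame["adjusted_p"] < 0) | (frame["adjusted_p"] > 1)).any():
        raise ValueError(f"{path}: adjusted_p outside [0, 1]")
    return frame


def read_survival_table(path) -> pd.DataFrame:
    """Survival table: patient_id, time, event, plus one expression column per gene."""
    _require_file(path)
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: survival table missing columns {sorted(missing)}")
    if (frame["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    if not set(frame["event"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: event must be binary 0/1")
    return frame


def load_config(path) -> dict:
    import yaml

    _require_file(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
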