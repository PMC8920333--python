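"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the in-memory model (the VCF
convention); BED inputs are converted at the I/O boundary.  A *site key* is
the tuple ``(chrom, pos, ref_base, alt_base)`` with genomic plus-strand
bases — keying on ref *and* alt means a T>C germline SNP never masks an A>G
edit at the same locus.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: transcript regions, in annotation priority order (highest first)
REGION_PRIORITY = ("3UTR", "5UTR", "CDS", "ncRNA", "intron")
REGIONS = REGION_PRIORITY + ("intergenic",)

REPEAT_FAMILIES = ("AluY", "AluS", "AluJ", "other-repeat", "nonrepetitive")

GROUP_CASE = "case"
GROUP_CONTROL = "control"

SiteKey = tuple  # (chrom, pos, ref_base, alt_base)


def _check_base(base: str, name: str) -> None:
    if base not in BASES:
        raise ValueError(f"{name} must be one of A,C,G,T, got {base!r}")


def site_key_str(key: SiteKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


def parse_site_key(text: str) -> SiteKey:
    chrom, pos, sub = text.split(":")
    ref, alt = sub.split(">")
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic SNV call in one sample, with site-aggregate qualities."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    n_alt_reads: int
    base_quality: float
    mapping_quality: float
    coverage: int
    sample_id: str

    def __post_init__(self) -> None:
        _check_base(self.ref_base, "ref_base")
        _check_base(self.alt_base, "alt_base")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_alt_reads < 0 or self.coverage < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_alt_reads > self.coverage:
            raise ValueError(
                f"n_alt_reads ({self.n_alt_reads}) exceeds coverage ({self.coverage})"
            )

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class Catalog:
    """A set of known-variant keys (e.g. a WES, SNP-database or editing-database stand-in)."""

    entries: frozenset
    source_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", frozenset(self.entries))

    def __contains__(self, key: SiteKey) -> bool:
        return tuple(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SampleSheet:
    """Sample → group assignment (case ≙ tumour stem cells, control ≙ normal)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad = set(self.frame["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected case/control")
        if "subtype" not in self.frame.columns:
            self.frame = self.frame.assign(subtype=None)
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SampleSheet":
        rows = [r if len(r) == 3 else (*r, None) for r in records]
        return cls(pd.DataFrame(rows, columns=["sample_id", "group", "subtype"]))

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    @property
    def cases(self) -> list:
        return list(self.frame.loc[self.frame["group"] == GROUP_CASE, "sample_id"])

    @property
    def controls(self) -> list:
        return list(self.frame.loc[self.frame["group"] == GROUP_CONTROL, "sample_id"])

    def group_of(self, sample_id: str) -> str:
        sel = self.frame.loc[self.frame["sample_id"] == sample_id, "group"]
        if sel.empty:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return sel.iloc[0]

    def require_two_groups(self) -> None:
        if not self.cases or not self.controls:
            raise ValueError("both case and control groups must be non-empty")


@dataclass(frozen=True, slots=True)
class GeneInterval:
    """One transcript feature interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    feature: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.feature not in ("5UTR", "CDS", "3UTR", "intron", "ncRNA"):
            raise ValueError(f"unknown feature {self.feature!r}")


@dataclass(frozen=True, slots=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    family: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.family not in ("AluY", "AluS", "AluJ", "other-repeat"):
            raise ValueError(f"unknown repeat family {self.family!r}")


@dataclass
class GeneModel:
    """Transcript-feature and repeat annotation used for site context."""

    intervals: list = field(default_factory=list)
    repeat_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict = {}
        for iv in self.intervals:
            prev = seen.setdefault(iv.gene_id, (iv.chrom, iv.strand))
            if prev != (iv.chrom, iv.strand):
                raise ValueError(
                    f"gene {iv.gene_id} has intervals on multiple chromosomes/strands"
                )


@dataclass(frozen=True, slots=True)
class SiteObservation:
    """Edited/total read counts for one site in one sample."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    sample_id: str
    edited_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        _check_base(self.ref_base, "ref_base")
        _check_base(self.alt_base, "alt_base")
        if self.edited_reads < 0 or self.total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.edited_reads > self.total_reads:
            raise ValueError(
                f"edited_reads ({self.edited_reads}) exceeds total_reads ({self.total_reads})"
            )

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True, slots=True)
class EditingSite:
    """A genomic position with substitution, strand and transcript context.

    ``ref_base``/``alt_base`` are genomic plus-strand bases; a site is an
    A-to-I candidate iff the transcript-oriented substitution is A→G
    (genomic A>G on '+', T>C on '−').
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    strand: str = "unknown"
    gene_id: Optional[str] = None
    region: str = "intergenic"
    repeat_family: str = "nonrepetitive"

    def __post_init__(self) -> None:
        _check_base(self.ref_base, "ref_base")
        _check_base(self.alt_base, "alt_base")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"strand must be +, - or unknown, got {self.strand!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.repeat_family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.repeat_family!r}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)

    @property
    def is_a_to_i(self) -> bool:
        if self.strand == "+":
            return (self.ref_base, self.alt_base) == ("A", "G")
        if self.strand == "-":
            return (self.ref_base, self.alt_base) == ("T", "C")
        return (self.ref_base, self.alt_base) in {("A", "G"), ("T", "C")}

    def with_context(self, **kwargs) -> "EditingSite":
        return replace(self, **kwargs)


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """Inclusive (≥) thresholds of the discovery cascade."""

    min_alt_reads: int = 1
    min_base_quality: float = 25.0
    min_mapping_quality: float = 20.0
    min_coverage: int = 10
    min_informative_samples: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_alt_reads",
            "min_base_quality",
            "min_mapping_quality",
            "min_coverage",
            "min_informative_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FilterReport:
    """Per-stage site attrition of the discovery cascade."""

    stages: list = field(default_factory=list)  # (stage, entering, kept)
    removed_by_source: dict = field(default_factory=dict)

    def add_stage(self, name: str, entering: int, kept: int) -> None:
        if kept > entering:
            raise ValueError(f"stage {name}: kept {kept} > entering {entering}")
        if self.stages and entering != self.stages[-1][2]:
            raise ValueError(
                f"stage {name}: entering {entering} != previous kept {self.stages[-1][2]}"
            )
        self.stages.append((name, entering, kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, e, k, e - k) for s, e, k in self.stages],
            columns=["stage", "entering", "kept", "removed"],
        )

    @property
    def final_count(self) -> int:
        return self.stages[-1][2] if self.stages else 0


@dataclass
class EditingMatrix:
    """Site × sample editing levels with a companion coverage matrix.

    ``levels`` holds editing levels in [0,1] with NaN wherever coverage is
    below the minimum; ``coverage`` holds total read counts.  Rows are
    indexed by site-key strings ("chrom:pos:ref>alt"), columns by sample id;
    both are sorted for deterministic output.
    """

    levels: pd.DataFrame
    coverage: pd.DataFrame
    sheet: SampleSheet
    sites: dict = field(default_factory=dict)  # key-string -> EditingSite

    def __post_init__(self) -> None:
        if not self.levels.index.equals(self.coverage.index) or not self.levels.columns.equals(
            self.coverage.columns
        ):
            raise ValueError("levels and coverage matrices must be aligned")
        vals = self.levels.to_numpy()
        finite = vals == vals  # not NaN
        if ((vals < 0) & finite).any() or ((vals > 1) & finite).any():
            raise ValueError("editing levels must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.levels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.levels.shape[1]

    def case_columns(self) -> list:
        return [s for s in self.levels.columns if s in set(self.sheet.cases)]

    def control_columns(self) -> list:
        return [s for s in self.levels.columns if s in set(self.sheet.controls)]


@dataclass(frozen=True, slots=True)
class GeneSpecificity:
    """Group means, specificity score and class call for one unit (gene or site)."""

    gene_id: str
    mean_case: float
    mean_ctrl: float
    score: float  # NaN when unevaluable
    klass: str  # case-specific | control-specific | shared | unevaluable


@dataclass(frozen=True, slots=True)
class GroupTestResult:
    label: str
    statistic: float
    p_value: float
    adjusted_p: float
    n_units: int
    flag: str = ""


@dataclass
class ContextSummary:
    """Counts and proportions of sites per region class and repeat family."""

    region_counts: pd.DataFrame  # labels × region classes
    repeat_counts: pd.DataFrame  # labels × repeat families

    def proportions(self, which: str = "region") -> pd.DataFrame:
        counts = self.region_counts if which == "region" else self.repeat_counts
        totals = counts.sum(axis=1)
        return counts.div(totals.where(totals > 0), axis=0)
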