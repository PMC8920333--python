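"""Synthetic editing cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-site editing rates drawn from a Beta prior (beta-binomial read counts,
  capturing overdispersion of editing levels across sites);
* negative-binomial sequencing coverage;
* a per-sample global editing propensity (logit shift) standing in for
  variable editing-enzyme activity, plus per-gene×sample noise;
* planted group effects acting on the logit of the rate, so specificity
  scores can be set via the two group means;
* germline A>G SNP contamination with allelic ratios near 0 / 0.5 / 1 —
  indistinguishable from editing by the quality filters, removable only by
  catalog subtraction;
* sequencing-error mismatches spread uniformly over the 12 substitution
  types at background positions;
* Alu-enriched repeat context and transcript-region placement;
* planted knockdown-downregulation, editing-reduction and survival-hazard
  signal for one target gene.

Identical config (including seed) reproduces byte-identical output files;
every stage draws from its own named substream derived from the global seed.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    BASES,
    Catalog,
    GeneInterval,
    GeneModel,
    RepeatInterval,
    SampleSheet,
    VariantRecord,
)

_GENE_LENGTH = 20_000
_GENE_SPACING = 30_000
_FEATURE_SPANS = {  # offsets within a coding gene (1-based, inclusive)
    "5UTR": (0, 999),
    "CDS": (1000, 6999),
    "intron": (7000, 15999),
    "3UTR": (16000, 19999),
}
_SLOT_STEP = 700  # site slots are spaced so ±150 bp repeat blocks never overlap
_SLOT_MARGIN = 160
_GAP_OFFSETS = {"intergenic": 160, "decoy": 330, "noise": 510}

_ORDERED_PAIRS = [(r, a) for r in BASES for a in BASES if r != a]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimConfig:
    """Full generative parameterization of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: 31 case (tumour
    stem cell) vs 5 control (neural stem cell) samples, ~5,000 candidate
    sites, mean coverage 60×, Beta(2, 8) editing rates and a 0.002 per-base
    error rate.
    """

    seed: int = 0
    n_case: int = 31
    n_ctrl: int = 5
    n_genes: int = 1000
    sites_per_gene: int = 5
    rate_alpha: float = 2.0
    rate_beta: float = 8.0
    coverage_mean: float = 60.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.002
    n_noise_sites: Optional[int] = None  # defaults to 2 * n_genes * sites_per_gene
    snp_fraction: float = 0.1
    alu_fractions: tuple = (
        ("AluY", 0.15),
        ("AluS", 0.45),
        ("AluJ", 0.15),
        ("other-repeat", 0.05),
        ("nonrepetitive", 0.20),
    )
    region_fractions: tuple = (
        ("5UTR", 0.05),
        ("CDS", 0.07),
        ("3UTR", 0.35),
        ("intron", 0.30),
        ("ncRNA", 0.08),
        ("intergenic", 0.15),
    )
    sample_effect_sd: float = 0.3
    gene_sample_sd: float = 0.5
    global_case_shift: float = 0.3
    planted_specific: tuple = ()  # ((gene_id, logit_shift), ...)
    planted_rate_alpha: float = 1.5
    planted_rate_beta: float = 30.0
    planted_target: Optional[str] = None
    # knockdown experiment
    n_kd_control: int = 3
    n_kd: int = 3
    kd_margin: float = 1.5
    kd_log2fc_sd: float = 0.05
    de_null_log2fc_sd: float = 0.4
    kd_editing_drop: float = 3.0
    # survival cohort
    n_patients: int = 200
    survival_beta: float = math.log(3.0)
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    # catalogs
    wes_miss_rate: float = 0.0
    n_decoys: int = 200
    # expression / ranking
    enzyme_name: str = "ADAR1"
    expr_noise_sd: float = 0.15
    # per-record quality annotations
    bq_mean: float = 32.0
    bq_sd: float = 4.0
    mq_mean: float = 50.0
    mq_sd: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("n_case and n_ctrl must be >= 1")
        if self.n_genes < 0 or self.sites_per_gene < 0:
            raise ValueError("n_genes and sites_per_gene must be non-negative")
        for name in ("error_rate", "snp_fraction", "wes_miss_rate", "censoring_rate"):
            v = getattr(self, name)
            if name == "censoring_rate":
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must lie in [0, 1]")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, fracs in (("alu_fractions", self.alu_fractions), ("region_fractions", self.region_fractions)):
            total = sum(f for _, f in fracs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(f < 0 for _, f in fracs):
                raise ValueError(f"{name} entries must be non-negative")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage model parameters must be positive")
        if self.rate_alpha <= 0 or self.rate_beta <= 0:
            raise ValueError("rate prior parameters must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_genes * self.sites_per_gene

    @property
    def planted_gene_ids(self) -> set:
        ids = {g for g, _ in self.planted_specific}
        if self.planted_target:
            ids.add(self.planted_target)
        return ids


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: Generator seeded by (global seed, crc32 of the name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    sites: pd.DataFrame  # key parts + gene/region/repeat/strand/is_snp/maf/logit_base/case_shift
    samples: pd.DataFrame  # sample_id, group, propensity u_j
    gene_noise: pd.DataFrame  # gene × sample logit noise v_gj
    gene_ids: list
    planted_specific: dict  # gene_id -> planted logit shift
    planted_target: Optional[str]
    survival_beta: dict  # gene_id -> log-hazard per SD expression
    true_specificity: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def snp_keys(self) -> set:
        snp = self.sites[self.sites["is_snp"]]
        return set(zip(snp["chrom"], snp["pos"], snp["ref"], snp["alt"]))

    @property
    def edit_keys(self) -> set:
        edit = self.sites[~self.sites["is_snp"]]
        return set(zip(edit["chrom"], edit["pos"], edit["ref"], edit["alt"]))

    def rate_matrix(self) -> pd.DataFrame:
        """Expected per-site × sample editing rates implied by the model."""
        logit_base = self.sites["logit_base"].to_numpy()[:, None]
        shift = self.sites["case_shift"].to_numpy()[:, None]
        is_case = (self.samples["group"] == "case").to_numpy()[None, :]
        u = self.samples["propensity"].to_numpy()[None, :]
        genes = self.sites["gene"].to_numpy()
        v = np.zeros((len(self.sites), len(self.samples)))
        gn = self.gene_noise
        known = pd.Series(np.arange(len(gn.index)), index=gn.index)
        mask = pd.Series(genes).isin(gn.index).to_numpy()
        if mask.any():
            rows = known.loc[pd.Series(genes)[mask]].to_numpy()
            v[mask] = gn.to_numpy()[rows]
        logits = logit_base + shift * is_case + u + v
        rates = _sigmoid(logits)
        snp = self.sites["is_snp"].to_numpy()
        if snp.any():  # SNP sites follow genotype ratios, not editing rates
            rates[snp] = np.nan
        return pd.DataFrame(
            rates, index=self.sites["key"].to_numpy(), columns=self.samples["sample_id"].to_numpy()
        )

    def to_json(self, path) -> None:
        payload = {
            "sites": self.sites.to_dict("list"),
            "samples": self.samples.to_dict("list"),
            "gene_noise": {
                "index": list(self.gene_noise.index),
                "columns": list(self.gene_noise.columns),
                "values": self.gene_noise.to_numpy().round(10).tolist(),
            },
            "gene_ids": self.gene_ids,
            "planted_specific": self.planted_specific,
            "planted_target": self.planted_target,
            "survival_beta": self.survival_beta,
            "true_specificity": self.true_specificity.round(10).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gn = payload["gene_noise"]
        return cls(
            sites=pd.DataFrame(payload["sites"]),
            samples=pd.DataFrame(payload["samples"]),
            gene_noise=pd.DataFrame(gn["values"], index=gn["index"], columns=gn["columns"]),
            gene_ids=payload["gene_ids"],
            planted_specific=payload["planted_specific"],
            planted_target=payload["planted_target"],
            survival_beta=payload["survival_beta"],
            true_specificity=pd.Series(payload["true_specificity"], dtype=float),
        )


@dataclass
class SyntheticCohort:
    config: SimConfig
    truth: GroundTruth
    observations: pd.DataFrame  # pileup: chrom pos ref alt sample edited_reads total_reads
    sheet: SampleSheet
    model: GeneModel
    expression: pd.DataFrame  # (genes + enzyme) × samples
    variants: dict = field(default_factory=dict)  # sample -> [VariantRecord]


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _feature_slots(gene_start: int, feature: str) -> list:
    lo, hi = _FEATURE_SPANS[feature]
    start, end = gene_start + lo, gene_start + hi
    return list(range(start + _SLOT_MARGIN, end - _SLOT_MARGIN + 1, _SLOT_STEP))


def _gap_slots(gene_start: int, kind: str) -> list:
    gap_start = gene_start + _GENE_LENGTH
    gap_end = gene_start + _GENE_SPACING - 1
    return list(
        range(gap_start + _GAP_OFFSETS[kind], gap_end - _SLOT_MARGIN + 1, _SLOT_STEP)
    )


def _build_layout(config: SimConfig, rng: np.random.Generator):
    """Place genes, features, repeats and candidate sites on one chromosome."""
    region_fracs = dict(config.region_fractions)
    alu_names = [n for n, _ in config.alu_fractions]
    alu_probs = np.array([f for _, f in config.alu_fractions])
    planted = config.planted_gene_ids

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    for gid in planted:
        if gid not in gene_ids:
            raise ValueError(f"planted gene {gid!r} is outside the gene universe")

    coding_regions = ["5UTR", "CDS", "intron", "3UTR"]
    coding_probs = np.array([region_fracs[r] for r in coding_regions])
    coding_probs = coding_probs / coding_probs.sum()
    # fraction of genic sites reassigned to the intergenic space
    genic_total = 1.0 - region_fracs.get("intergenic", 0.0)
    p_intergenic = region_fracs.get("intergenic", 0.0)
    p_ncrna_gene = region_fracs.get("ncRNA", 0.0) / genic_total if genic_total > 0 else 0.0

    intervals: list = []
    repeats: list = []
    site_rows: list = []

    for gi, gene_id in enumerate(gene_ids):
        gene_start = 1 + gi * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        is_ncrna = (rng.random() < p_ncrna_gene) and gene_id not in planted
        if is_ncrna:
            intervals.append(
                GeneInterval(
                    chrom="chr1",
                    start=gene_start,
                    end=gene_start + _GENE_LENGTH - 1,
                    strand=strand,
                    gene_id=gene_id,
                    feature="ncRNA",
                )
            )
            slot_pool = {"ncRNA": _feature_slots_ncrna(gene_start)}
        else:
            for feature, (lo, hi) in _FEATURE_SPANS.items():
                intervals.append(
                    GeneInterval(
                        chrom="chr1",
                        start=gene_start + lo,
                        end=gene_start + hi,
                        strand=strand,
                        gene_id=gene_id,
                        feature=feature,
                    )
                )
            slot_pool = {f: _feature_slots(gene_start, f) for f in coding_regions}
        gap_pool = _gap_slots(gene_start, "intergenic")

        for _ in range(config.sites_per_gene):
            to_intergenic = (
                gene_id not in planted and p_intergenic > 0 and rng.random() < p_intergenic
            )
            if to_intergenic and gap_pool:
                pos = gap_pool.pop(0)
                region, site_gene, site_strand = "intergenic", None, "unknown"
            else:
                if is_ncrna:
                    region = "ncRNA"
                else:
                    order = rng.permutation(len(coding_regions))
                    region = None
                    draw = rng.choice(len(coding_regions), p=coding_probs)
                    for idx in [draw, *order]:
                        candidate = coding_regions[idx]
                        if slot_pool[candidate]:
                            region = candidate
                            break
                    if region is None:
                        continue  # gene out of slots; drop the site
                pos = slot_pool[region].pop(0)
                site_gene, site_strand = gene_id, strand
            ref, alt = ("A", "G") if site_strand in ("+", "unknown") else ("T", "C")
            family = alu_names[rng.choice(len(alu_names), p=alu_probs)]
            if family != "nonrepetitive":
                repeats.append(
                    RepeatInterval(chrom="chr1", start=pos - 150, end=pos + 150, family=family)
                )
            site_rows.append(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "strand": site_strand,
                    "gene": site_gene,
                    "region": region,
                    "repeat_family": family,
                }
            )

    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "ref", "alt", "strand", "gene", "region", "repeat_family"],
    )
    if not sites.empty:
        sites = sites.sort_values("pos", kind="mergesort").reset_index(drop=True)
        sites["key"] = (
            sites["chrom"] + ":" + sites["pos"].astype(str) + ":" + sites["ref"] + ">" + sites["alt"]
        )
    else:
        sites["key"] = pd.Series(dtype=str)
    model = GeneModel(intervals=intervals, repeat_intervals=repeats)
    return gene_ids, sites, model


def _feature_slots_ncrna(gene_start: int) -> list:
    start, end = gene_start, gene_start + _GENE_LENGTH - 1
    return list(range(start + _SLOT_MARGIN, end - _SLOT_MARGIN + 1, _SLOT_STEP))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_cohort(config: SimConfig, with_variants: bool = True) -> SyntheticCohort:
    """Generate the main case/control cohort: pileup, variants, truth."""
    seed = config.seed
    layout_rng = stream_rng(seed, "layout")
    gene_ids, sites, model = _build_layout(config, layout_rng)
    n_sites = len(sites)

    sample_ids = [f"CASE{i + 1:02d}" for i in range(config.n_case)] + [
        f"CTRL{i + 1:02d}" for i in range(config.n_ctrl)
    ]
    groups = ["case"] * config.n_case + ["control"] * config.n_ctrl
    sheet = SampleSheet.from_records(list(zip(sample_ids, groups)))

    rates_rng = stream_rng(seed, "rates")
    planted_shift = dict(config.planted_specific)
    base = rates_rng.beta(config.rate_alpha, config.rate_beta, size=n_sites)
    is_planted_gene = sites["gene"].isin(planted_shift).to_numpy() if n_sites else np.array([], bool)
    if is_planted_gene.any():
        base[is_planted_gene] = rates_rng.beta(
            config.planted_rate_alpha, config.planted_rate_beta, size=int(is_planted_gene.sum())
        )
    base = np.clip(base, 1e-4, 1 - 1e-4)
    case_shift = np.full(n_sites, config.global_case_shift)
    for gid, shift in planted_shift.items():
        case_shift[(sites["gene"] == gid).to_numpy()] = shift

    snp_rng = stream_rng(seed, "snps")
    in_planted_or_target = sites["gene"].isin(config.planted_gene_ids).to_numpy() if n_sites else np.array([], bool)
    is_snp = (snp_rng.random(n_sites) < config.snp_fraction) & ~in_planted_or_target
    maf = np.where(is_snp, snp_rng.uniform(0.1, 0.5, size=n_sites), np.nan)

    samples_rng = stream_rng(seed, "samples")
    u = samples_rng.normal(0.0, config.sample_effect_sd, size=len(sample_ids))
    noise_rng = stream_rng(seed, "gene-noise")
    v = noise_rng.normal(0.0, config.gene_sample_sd, size=(len(gene_ids), len(sample_ids)))
    planted_rows = [gene_ids.index(g) for g in sorted(config.planted_gene_ids)]
    v[planted_rows, :] = 0.0  # planted genes track global enzyme activity exactly
    gene_noise = pd.DataFrame(v, index=gene_ids, columns=sample_ids)

    truth_sites = sites.assign(
        is_snp=is_snp, maf=maf, logit_base=_logit(base), case_shift=case_shift
    )
    samples_frame = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "propensity": u}
    )
    truth = GroundTruth(
        sites=truth_sites,
        samples=samples_frame,
        gene_noise=gene_noise,
        gene_ids=gene_ids,
        planted_specific=planted_shift,
        planted_target=config.planted_target,
        survival_beta={config.planted_target: config.survival_beta}
        if config.planted_target
        else {},
    )

    # per-cell expected rates
    rate = truth.rate_matrix().to_numpy() if n_sites else np.zeros((0, len(sample_ids)))
    counts_rng = stream_rng(seed, "counts")
    coverage = _negbin(
        counts_rng, config.coverage_mean, config.coverage_dispersion, (n_sites, len(sample_ids))
    )
    # SNP sites: per-sample genotype allelic ratios near 0 / 0.5 / 1
    geno_rng = stream_rng(seed, "genotypes")
    if is_snp.any():
        maf_col = maf[is_snp][:, None]
        genotypes = geno_rng.binomial(2, np.broadcast_to(maf_col, (int(is_snp.sum()), len(sample_ids))))
        ratio = np.clip(genotypes / 2.0 + geno_rng.normal(0, 0.02, genotypes.shape), 0.0, 1.0)
        rate[is_snp] = ratio
    edited = counts_rng.binomial(coverage, np.nan_to_num(rate))

    observations = _pileup_frame(sites, sample_ids, edited, coverage)

    # true gene-level specificity implied by expected rates and groups
    truth.true_specificity = _true_gene_specificity(truth)

    expression = _generate_expression(config, truth)

    variants = {}
    if with_variants:
        variants = _variant_calls(config, seed, sites, sample_ids, edited, coverage)
        _add_noise_variants(config, seed, variants, sample_ids)
    return SyntheticCohort(
        config=config,
        truth=truth,
        observations=observations,
        sheet=sheet,
        model=model,
        expression=expression,
        variants=variants,
    )


def _pileup_frame(sites, sample_ids, edited, coverage) -> pd.DataFrame:
    n_sites = len(sites)
    if n_sites == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "sample", "edited_reads", "total_reads"]
        )
    rep = np.repeat(np.arange(n_sites), len(sample_ids))
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[rep],
            "pos": sites["pos"].to_numpy()[rep],
            "ref": sites["ref"].to_numpy()[rep],
            "alt": sites["alt"].to_numpy()[rep],
            "sample": np.tile(sample_ids, n_sites),
            "edited_reads": edited.ravel(),
            "total_reads": coverage.ravel(),
        }
    )


def _true_gene_specificity(truth: GroundTruth) -> pd.Series:
    """Coverage-free truth: per-gene pooled specificity of expected rates."""
    sites = truth.sites
    genic = sites[(~sites["is_snp"]) & sites["gene"].notna()]
    if genic.empty:
        return pd.Series(dtype=float)
    rates = truth.rate_matrix().loc[genic["key"]]
    is_case = (truth.samples["group"] == "case").to_numpy()
    mean_case = rates.iloc[:, is_case].mean(axis=1)
    mean_ctrl = rates.iloc[:, ~is_case].mean(axis=1)
    frame = pd.DataFrame(
        {"gene": genic["gene"].to_numpy(), "case": mean_case.to_numpy(), "ctrl": mean_ctrl.to_numpy()}
    )
    pooled = frame.groupby("gene").mean()
    return pooled["case"] / (pooled["case"] + pooled["ctrl"])


def _generate_expression(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene (+ enzyme) × sample expression for the correlation ranking.

    Enzyme expression tracks the per-sample global editing propensity; the
    planted target's expression tracks its own realized editing level; all
    other genes are independent noise.
    """
    rng = stream_rng(config.seed, "expression")
    sample_ids = list(truth.samples["sample_id"])
    u = truth.samples["propensity"].to_numpy()
    n = len(sample_ids)
    expr = rng.normal(8.0, 1.0, size=(len(truth.gene_ids), n))
    frame = pd.DataFrame(expr, index=truth.gene_ids, columns=sample_ids)
    if truth.planted_target:
        rates = truth.rate_matrix()
        target_sites = truth.sites[
            (truth.sites["gene"] == truth.planted_target) & (~truth.sites["is_snp"])
        ]["key"]
        level = rates.loc[target_sites].mean(axis=0).to_numpy()
        z = (level - level.mean()) / (level.std() or 1.0)
        frame.loc[truth.planted_target] = 8.0 + z + rng.normal(0, config.expr_noise_sd, n)
    enzyme = 8.0 + (u - u.mean()) / (u.std() or 1.0) + rng.normal(0, config.expr_noise_sd, n)
    frame.loc[config.enzyme_name] = enzyme
    return frame


def _variant_calls(config, seed, sites, sample_ids, edited, coverage) -> dict:
    """Per-sample VariantRecords at candidate sites with ≥1 mismatched read."""
    qual_rng = stream_rng(seed, "qualities")
    n_sites = len(sites)
    bq = np.clip(
        qual_rng.normal(config.bq_mean, config.bq_sd, (n_sites, len(sample_ids))), 2.0, 45.0
    )
    mq = np.clip(
        qual_rng.normal(config.mq_mean, config.mq_sd, (n_sites, len(sample_ids))), 10.0, 60.0
    )
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    variants: dict = {s: [] for s in sample_ids}
    site_idx, sample_idx = np.nonzero(edited >= 1)
    for i, j in zip(site_idx, sample_idx):
        variants[sample_ids[j]].append(
            VariantRecord(
                chrom=str(chroms[i]),
                pos=int(poss[i]),
                ref_base=str(refs[i]),
                alt_base=str(alts[i]),
                n_alt_reads=int(edited[i, j]),
                base_quality=round(float(bq[i, j]), 2),
                mapping_quality=round(float(mq[i, j]), 2),
                coverage=int(coverage[i, j]),
                sample_id=sample_ids[j],
            )
        )
    return variants


def _noise_positions(config: SimConfig) -> list:
    # default background breadth reproduces the reported 30-70x A-to-G
    # dominance of the mismatch spectrum at the default error rate
    n_noise = config.n_noise_sites if config.n_noise_sites is not None else 2 * config.n_sites
    slots: list = []
    gi = 0
    while len(slots) < n_noise:
        gene_start = 1 + gi * _GENE_SPACING
        slots.extend(_gap_slots(gene_start, "noise"))
        gi += 1
        if gi > max(config.n_genes, 1) * 4 + 10_000:
            break
    return slots[:n_noise]


def _add_noise_variants(config, seed, variants, sample_ids) -> None:
    """Sequencing-error mismatches at background positions, uniform over 12 types."""
    positions = _noise_positions(config)
    if not positions:
        return
    rng = stream_rng(seed, "noise-sites")
    pair_idx = rng.integers(0, len(_ORDERED_PAIRS), size=len(positions))
    coverage = _negbin(
        rng, config.coverage_mean, config.coverage_dispersion, (len(positions), len(sample_ids))
    )
    alt_reads = rng.binomial(coverage, config.error_rate)
    bq = np.clip(rng.normal(config.bq_mean, config.bq_sd, coverage.shape), 2.0, 45.0)
    mq = np.clip(rng.normal(config.mq_mean, config.mq_sd, coverage.shape), 10.0, 60.0)
    site_idx, sample_idx = np.nonzero(alt_reads >= 1)
    for i, j in zip(site_idx, sample_idx):
        ref, alt = _ORDERED_PAIRS[pair_idx[i]]
        variants[sample_ids[j]].append(
            VariantRecord(
                chrom="chr1",
                pos=int(positions[i]),
                ref_base=ref,
                alt_base=alt,
                n_alt_reads=int(alt_reads[i, j]),
                base_quality=round(float(bq[i, j]), 2),
                mapping_quality=round(float(mq[i, j]), 2),
                coverage=int(coverage[i, j]),
                sample_id=sample_ids[j],
            )
        )


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def generate_catalogs(config: SimConfig, truth: GroundTruth):
    """WES / SNP-database / editing-database stand-ins.

    WES and the SNP database contain exactly the germline SNP keys (each
    independently thinned by ``wes_miss_rate``); the editing database
    contains all true editing-site keys plus decoy entries at positions the
    cohort never touches.
    """
    snp_keys = sorted(truth.snp_keys)
    rng = stream_rng(config.seed, "catalogs")

    def thin(keys):
        if config.wes_miss_rate <= 0:
            return keys
        keep = rng.random(len(keys)) >= config.wes_miss_rate
        return [k for k, ok in zip(keys, keep) if ok]

    wes = Catalog(frozenset(thin(snp_keys)), "wes")
    snp_db = Catalog(frozenset(thin(snp_keys)), "snp-db")

    decoy_positions: list = []
    gi = 0
    while len(decoy_positions) < config.n_decoys:
        gene_start = 1 + gi * _GENE_SPACING
        decoy_positions.extend(_gap_slots(gene_start, "decoy"))
        gi += 1
        if gi > max(config.n_genes, 1) * 4 + 10_000:
            break
    decoys = {("chr1", p, "A", "G") for p in decoy_positions[: config.n_decoys]}
    editing_db = Catalog(frozenset(truth.edit_keys | decoys), "editing-db")
    return wes, snp_db, editing_db


# ---------------------------------------------------------------------------
# knockdown experiment
# ---------------------------------------------------------------------------

@dataclass
class KnockdownBundle:
    de_table: pd.DataFrame
    observations_control: pd.DataFrame
    observations_kd: pd.DataFrame
    sheet: SampleSheet  # control condition -> "control", knockdown -> "case"


def generate_knockdown(config: SimConfig, truth: GroundTruth) -> KnockdownBundle:
    """Enzyme-knockdown DE table plus control/knockdown pileups.

    The planted target is downregulated past the fold-change threshold by
    the configured margin and loses ``kd_editing_drop`` logits of editing in
    the knockdown pileup; null genes get centred log2 fold changes and
    uniform adjusted P values.
    """
    if config.planted_target is None:
        raise ValueError("generate_knockdown requires config.planted_target")
    rng = stream_rng(config.seed, "knockdown")
    genes = truth.gene_ids
    log2fc = rng.normal(0.0, config.de_null_log2fc_sd, size=len(genes))
    adj_p = rng.uniform(0.0, 1.0, size=len(genes))
    de = pd.DataFrame({"gene_id": genes, "log2_fold_change": log2fc, "adjusted_p": adj_p})
    t = genes.index(config.planted_target)
    de.loc[t, "log2_fold_change"] = -math.log2(2.0 * config.kd_margin) + rng.normal(
        0.0, config.kd_log2fc_sd
    )
    de.loc[t, "adjusted_p"] = 10.0 ** -(6.0 + abs(rng.normal(0.0, 1.0)))

    # mini-cohorts: both conditions draw from the case-group rate model
    ctrl_ids = [f"KDCTRL{i + 1:02d}" for i in range(config.n_kd_control)]
    kd_ids = [f"KD{i + 1:02d}" for i in range(config.n_kd)]
    sheet = SampleSheet.from_records(
        [(s, "control") for s in ctrl_ids] + [(s, "case") for s in kd_ids]
    )
    sites = truth.sites[~truth.sites["is_snp"]].reset_index(drop=True)
    logit_base = sites["logit_base"].to_numpy()[:, None]
    shift = sites["case_shift"].to_numpy()[:, None]
    n_sites = len(sites)

    def draw(ids, drop_target: bool):
        u = rng.normal(0.0, config.sample_effect_sd, size=len(ids))[None, :]
        logits = logit_base + shift + u
        if drop_target:
            on_target = (sites["gene"] == config.planted_target).to_numpy()
            logits[on_target] -= config.kd_editing_drop
        rates = _sigmoid(logits)
        coverage = _negbin(
            rng, config.coverage_mean, config.coverage_dispersion, (n_sites, len(ids))
        )
        edited = rng.binomial(coverage, rates)
        return _pileup_frame(sites, ids, edited, coverage)

    obs_ctrl = draw(ctrl_ids, drop_target=False)
    obs_kd = draw(kd_ids, drop_target=True)
    return KnockdownBundle(
        de_table=de, observations_control=obs_ctrl, observations_kd=obs_kd, sheet=sheet
    )


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def generate_survival(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Expression-survival table with exponential event times.

    log-hazard = β · standardized expression for planted genes (β = 0
    otherwise), with independent exponential censoring at the configured
    rate.  ``censoring_rate`` = 1 yields an all-censored table.
    """
    rng = stream_rng(config.seed, "survival")
    genes = truth.gene_ids
    n = config.n_patients
    expr = rng.normal(0.0, 1.0, size=(n, len(genes)))
    loghaz = np.full(n, math.log(config.baseline_hazard))
    for gene, beta in truth.survival_beta.items():
        gi = genes.index(gene)
        z = (expr[:, gi] - expr[:, gi].mean()) / expr[:, gi].std()
        loghaz = loghaz + beta * z
    event_time = rng.exponential(1.0 / np.exp(loghaz))
    r = config.censoring_rate
    if r >= 1.0:
        time = rng.exponential(1.0 / config.baseline_hazard, size=n)
        event = np.zeros(n, dtype=int)
    elif r <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        censor_rate = config.baseline_hazard * r / (1.0 - r)
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)
    meta = pd.DataFrame(
        {"patient_id": [f"P{i + 1:04d}" for i in range(n)], "time": time, "event": event}
    )
    expr_frame = pd.DataFrame(expr, columns=genes)
    return pd.concat([meta, expr_frame], axis=1)


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_bundle(config: SimConfig, out_dir) -> dict:
    """Generate everything and write the full input bundle for the pipeline.

    Emits pileup, per-sample VCFs, sample sheet, gene-model BEDs, catalogs,
    expression, knockdown DE/pileups, survival table and truth.json.
    Returns the path map.  Identical config reproduces byte-identical files.
    """
    import os

    from . import io as eio

    cohort = generate_cohort(config, with_variants=True)
    wes, snp_db, editing_db = generate_catalogs(config, cohort.truth)
    os.makedirs(out_dir, exist_ok=True)
    vcf_dir = os.path.join(out_dir, "variants")
    os.makedirs(vcf_dir, exist_ok=True)
    paths = {}

    paths["pileup"] = os.path.join(out_dir, "pileup.tsv")
    eio.write_observations(paths["pileup"], cohort.observations)
    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    eio.write_sample_sheet(paths["samples"], cohort.sheet)
    paths["features"] = os.path.join(out_dir, "features.bed")
    paths["repeats"] = os.path.join(out_dir, "repeats.bed")
    eio.write_gene_model(paths["features"], paths["repeats"], cohort.model)
    for sample, records in cohort.variants.items():
        paths[f"vcf:{sample}"] = os.path.join(vcf_dir, f"{sample}.vcf")
        eio.write_variant_records(paths[f"vcf:{sample}"], records)
    for name, cat in (("wes", wes), ("snp_db", snp_db), ("editing_db", editing_db)):
        paths[name] = os.path.join(out_dir, f"{name}.tsv")
        eio.write_catalog(paths[name], cat)
    paths["expression"] = os.path.join(out_dir, "expression.tsv")
    eio.write_matrix(paths["expression"], cohort.expression, index_name="gene_id")
    if config.planted_target is not None:
        kd = generate_knockdown(config, cohort.truth)
        paths["de"] = os.path.join(out_dir, "de.tsv")
        kd.de_table.to_csv(paths["de"], sep="\t", index=False, float_format="%.10g")
        paths["kd_control_pileup"] = os.path.join(out_dir, "kd_control_pileup.tsv")
        eio.write_observations(paths["kd_control_pileup"], kd.observations_control)
        paths["kd_pileup"] = os.path.join(out_dir, "kd_pileup.tsv")
        eio.write_observations(paths["kd_pileup"], kd.observations_kd)
        paths["kd_samples"] = os.path.join(out_dir, "kd_samples.tsv")
        eio.write_sample_sheet(paths["kd_samples"], kd.sheet)
        surv = generate_survival(config, cohort.truth)
        paths["survival"] = os.path.join(out_dir, "survival.tsv")
        surv.to_csv(paths["survival"], sep="\t", index=False, float_format="%.10g")
    paths["truth"] = os.path.join(out_dir, "truth.json")
    cohort.truth.to_json(paths["truth"])
    return paths
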