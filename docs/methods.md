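# Methods

This note documents the models, conventions and numerical choices behind
`editome`: what each stage computes, what the synthetic-cohort generator
does and does not emulate, and where the design was genuinely open.

## Coordinates, keys and formats

All in-memory coordinates are 1-based inclusive (the VCF convention); BED
input/output is 0-based half-open and converted exactly once at the I/O
boundary; GFF3 is read as-is (already 1-based).  A *site key* is
`(chrom, pos, ref, alt)` in genomic plus-strand bases.  Keying on both
alleles — not position alone — means a T>C germline SNP entry cannot mask an
A>G editing candidate at the same locus; this is deliberately stricter than
position-only matching.

Variant VCFs carry the quality aggregates the filters consume in INFO
fields: `DP` (site depth), `AD` (ref,alt depths), `BQ` (mean mismatch base
quality) and `MQ` (mean mapping quality).  Which annotations carry these
values out of a variant caller varies between pipelines, so the required
fields are fixed here and documented; multiallelic records are split into
biallelic records on read and indels are skipped with a logged count.
Quality thresholds therefore apply to per-site aggregates, not individual
reads.

## Discovery cascade

Stages run in the order quality → DNA-variant subtraction → editing-catalog
restriction → informative-sample rule.  Every threshold comparison is
inclusive (≥): a record survives the quality stage iff mismatched reads ≥ 1,
base quality ≥ 25, mapping quality ≥ 20 and coverage ≥ 10; a site is
informative iff covered ≥ 10× in ≥ 10 samples (a total-sample minimum —
no per-group minimum is imposed).  Each stage is a pure set predicate over
site keys, so the surviving set is invariant to record order and catalog
order; only the attrition report depends on stage order, and removed
records are attributed to the first catalog (in list order) containing
their key.

The informative-sample rule prefers the pileup observations when supplied,
because a site can be deeply covered in samples where it shows no mismatch
(and hence has no variant record); without a pileup it falls back to the
coverage carried on the variant records, which undercounts and is stricter.

Strand assignment comes from the overlapping gene's strand.  Intergenic
sites get strand `unknown` and are reported in genomic orientation.  Where
genes on both strands overlap a site, the strand whose orientation yields
A→G is taken if exactly one does; otherwise `unknown`.  Transcript-region
labels resolve overlaps by the fixed priority 3′UTR > 5′UTR > CDS > ncRNA >
intron > intergenic (plain exon annotations lacking a UTR/CDS split map to
CDS); repeat family comes from any overlapping repeat interval, ties broken
alphabetically, else `nonrepetitive`.  Interval queries use per-chromosome
interval trees and are oracle-tested against a brute-force scan.

## Editing levels

Site level = edited reads / total reads, missing (NaN) when coverage
< 10 (configurable).  Gene and sample levels pool raw counts over covered
sites — Σ edited / Σ total, i.e. the coverage-weighted mean of site levels —
never the unweighted mean of ratios.  Gene-level pooling runs over the
gene's *discovered* sites (the set every downstream step uses), not over
all catalog positions.  Missing cells are excluded from every downstream
mean rather than zero-imputed; zero-imputation would bias specificity
scores toward the better-covered group.

## Group specificity

For a unit with group means m₁ (case) and m₀ (control), computed as
arithmetic means over non-missing samples and requiring ≥ 2 non-missing
samples per group (configurable; units failing this are `unevaluable`):

    score s = m₁ / (m₁ + m₀)        (NaN on 0/0)

Classes: case-specific iff s ≥ τ (default τ = 0.75, inclusive),
control-specific iff 1 − s ≥ τ (the mirrored rule, so relabeling the groups
swaps the two classes exactly), else shared.  Threshold comparisons use a
1 × 10⁻¹² absolute tolerance so decimal boundaries behave as printed in
binary floating point (0.6/(0.6+0.2) classifies as exactly 0.75).
"Enriched" units use the strict inequality m₁ > m₀ with ties excluded.

Group tests are Wilcoxon signed-rank on per-unit paired group means — the
pairing that makes a signed-rank test well defined for unequal group sizes.
Zero differences are dropped before ranking; the exact null distribution is
used for ≤ 25 non-zero untied differences and the normal approximation with
continuity correction otherwise (implemented via `scipy.stats.wilcoxon`,
cross-checked in the tests against full enumeration of sign assignments for
n ≤ 10); identical vectors report p = 1 with a flag.  Bonferroni adjustment
(via `statsmodels`) applies across groupings.  Both site-level and
gene-level pairings are available; gene-level pooled means are the default
unit for classification.

## Target prioritization

The funnel intersects three gene sets:

1. *Knockdown-downregulated*: log₂FC < −log₂(2) and adjusted P < 0.05,
   both strict, from a supplied differential-expression table (DE model
   fitting itself is out of scope — the funnel, not the DE model, is the
   analysis here).
2. *Editing-reduced*: pooled gene editing level drops by more than δ
   between conditions (default δ = 0, strict; δ is configurable because at
   finite coverage roughly half of null genes drift downward, and a
   noise-scale δ — e.g. 0.05 at 60× over a few sites — suppresses that).
3. *Adverse survival*: median split on expression (strictly above the
   median is "high"), two-sided log-rank test (lifelines), pass iff
   p < 0.05 *and* the high stratum fares worse; the direction comes from a
   univariate Cox proportional-hazards fit on the high-expression
   indicator, used only for the sign, never for significance.  Genes with
   constant expression, a degenerate split or no events are unevaluable.

The expression-based survival screen is the implemented variant; a
per-editing-site survival screen over external tumour-atlas editing tables
would follow the same median-split machinery but is not implemented.
Candidates are ranked by the rank-sum of two Pearson correlations across
samples (enzyme expression vs gene editing level; own expression vs gene
editing level), descending, requiring ≥ 3 complete samples; undefined
correlations rank last with a flag, and ties break lexicographically by
gene id (the ranking rule is this package's own convention — no canonical
weighting exists for combining the two correlations).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
defaults matching the targeted study design: 31 case vs 5 control samples,
1,000 genes × 5 sites (~5,000 candidate sites), and for site s in sample j

    logit(rate_sj) = logit(p_s) + Δ_g(s)·[j ∈ case] + u_j + v_{g(s),j}
    coverage_sj ~ NegBin(mean 60, dispersion 5)
    edited_sj   ~ Binomial(coverage_sj, rate_sj)

* p_s ~ Beta(2, 8): beta-binomial overdispersion of editing across sites.
* u_j ~ Normal(0, 0.3): a per-sample global editing propensity standing in
  for variable editing-enzyme activity; it induces the within-group
  variation the correlation ranking needs.
* v_gj ~ Normal(0, 0.5): per-gene × sample noise, zeroed for planted genes
  so their editing tracks global enzyme activity exactly.
* Δ_g: +0.3 logits for all genes in cases (elevated editing in the case
  group), overridden by the planted per-gene shift (default 3.0 logits) for
  genes with planted group-specific editing; planted genes draw their base
  rates from Beta(1.5, 30) so the implied true specificity score exceeds
  0.8 — group effects act on the logit precisely so scores can be set via
  the two group means.
* A configurable fraction (default 0.1) of non-planted candidate sites are
  germline A>G SNPs with per-sample allelic ratios near 0 / 0.5 / 1
  (Hardy-Weinberg genotypes from a uniform 0.1–0.5 allele frequency, plus
  N(0, 0.02) noise): they pass every quality filter and are removable only
  by catalog subtraction, which is exactly the stage they exercise.
* Sequencing errors appear at background positions (default 2 × the
  candidate-site count) at 0.002 per base, uniform over the 12 substitution
  types; at these defaults the simulated mismatch spectrum shows the
  expected ~30–70-fold A-to-G dominance.
* Context: genes are tiled on one synthetic chromosome with fixed 5′UTR /
  CDS / intron / 3′UTR blocks (ncRNA genes are single-feature); sites land
  on a 700-bp grid so the ±150 bp repeat blocks written for Alu-context
  sites never overlap.  Default context mix: 75% Alu (AluS-heavy) and a
  3′UTR-heavy region distribution.  Repeat and region labels are assigned,
  not derived from sequence — the generator emits no Alu sequence content.
* The knockdown experiment emits a DE table (planted target at
  log₂FC ≈ −log₂(3) with tiny adjusted P; nulls at N(0, 0.4) with uniform
  P) and two 3-sample mini-cohorts drawn from the case-group rate model,
  with the planted target dropped by 3 logits in the knockdown arm.
* Survival: exponential event times with log-hazard = log(3) per SD of the
  planted target's expression (β = 0 elsewhere), exponential independent
  censoring calibrated to a 0.3 censoring fraction, n = 200 patients.
  A censoring rate of 1 yields an all-censored, unevaluable table.

Determinism: every stage draws from a named substream seeded by
`(global seed, crc32(stream name))`, so identical configs reproduce
byte-identical output bundles and any module can regenerate its substream
independently.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: alignment and mapping artifacts (the dominant
real-world false-positive source the quality filters exist for), strand
inference errors, hyper-editing read clusters, isoform structure, linkage
between nearby sites, batch effects, and real Alu sequence context.  The
tests certify the *arithmetic and logic* of the pipeline (cascade
equivalence with set oracles, estimator consistency, null calibration,
planted-signal recovery), not variant-calling accuracy upstream of it.

## Problem sizes used in the checks

The test suite and acceptance script run scaled synthetic studies chosen to
make the statistical checks sharp: cascade/oracle equivalence on 2,000
candidate sites × 36 samples with 15% SNP contamination and catalog decoys;
parameter recovery and planted-specificity recovery at the default 31+5 ×
~5,000-site design; null calibration over 2,000 genes plus 2,000 signed-rank
replicates of 50 pairs; and 100 independent seeds of a 300-gene funnel for
end-to-end target recovery.

## Known limitations

* The cascade consumes per-site aggregate qualities; pipelines that filter
  per read before aggregation may admit slightly different site sets.
* The signed-rank exact path refuses tied absolute differences and falls
  back to the normal approximation; at gene-level editing means ties are
  vanishingly rare but possible at very low coverage.
* Gene-level pooling assigns each site to exactly one gene (the
  highest-priority overlapping feature); overlapping genes sharing a site
  contribute it to only one of them.
* The correlation ranking needs within-cohort variation in editing; in a
  cohort with near-constant editing the ranking degenerates (flagged, not
  silently dropped).
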