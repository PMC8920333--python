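# editome

A reusable pipeline for adenosine-to-inosine (A-to-I) RNA-editome analysis in
case/control cohorts — built for the setting where a panel of tumour
stem-cell cultures (e.g. glioblastoma stem cells, GSCs) is compared against
normal controls (e.g. neural stem cells, NSCs) to find editing events that
mark the malignant state and to nominate editing-dependent target genes.

A-to-I editing is catalysed by ADAR enzymes on double-stranded RNA (largely
inverted Alu repeats); inosine is read as guanosine, so edits appear as A>G
mismatches between RNA-seq reads and the genome. `editome` takes per-sample
RNA variant calls and pileup read counts (it does not align reads or call
variants) and provides:

* **Site discovery** — the filter cascade from raw RNA variant calls to a
  high-confidence editing-site set: quality filters (≥1 mismatched read,
  base quality ≥25, mapping quality ≥20, coverage ≥10), subtraction of
  known DNA variants (matched WES plus germline/somatic catalogs),
  restriction to a curated known-editing catalog (RADAR-style whitelist),
  and an informative-site rule (covered ≥10× in ≥10 samples); plus the
  12-type, transcript-oriented variant spectrum.
* **Quantification** — editing levels at site, gene and sample resolution.
  A site's level in a sample is edited reads / total reads; gene- and
  sample-level values pool raw counts (Σ edited / Σ total), not means of
  ratios.  Sites are annotated with gene, transcript region (5′UTR / CDS /
  3′UTR / intron / ncRNA / intergenic) and repeat context (AluY/S/J).
* **Group specificity** — for each gene (or site) with group means
  m₁ (case) and m₀ (control), the specificity score

      s = m₁ / (m₁ + m₀)

  classifies the unit as *case-specific* (s ≥ 0.75, inclusive),
  *control-specific* (1 − s ≥ 0.75) or *shared*; group comparisons use the
  Wilcoxon signed-rank test on per-unit paired group means (exact null for
  n ≤ 25, normal approximation with continuity correction above) with
  Bonferroni adjustment across groupings.
* **Target prioritization** — the three-criterion funnel: genes
  (a) downregulated on editing-enzyme knockdown (fold change > 2,
  adjusted P < 0.05, from a supplied differential-expression table),
  (b) reduced in editing level between conditions, and (c) adversely
  associated with patient survival (median-split log-rank P < 0.05 with the
  high-expression stratum faring worse; hazard direction from a univariate
  Cox fit).  Survivors are ranked by the rank-sum of two per-sample
  correlations: enzyme expression vs the gene's editing level, and the
  gene's own expression vs its editing level.
* **Synthetic cohorts** — a fully parameterized generator (beta-binomial
  editing, negative-binomial coverage, germline SNP contamination, Alu and
  region context, planted group-specific and target-gene signals) with
  ground truth, so every stage is testable end to end with no external data.

## Worked example

```python
from editome import (SimConfig, generate_cohort, generate_catalogs, run_discovery,
                     build_editing_matrix, build_gene_matrix, group_mean_editing,
                     classify_specificity, compare_matrix_groups, FilterThresholds)
from editome.quantify import filter_observations

cfg = SimConfig(seed=42, n_genes=200, sites_per_gene=5, n_case=31, n_ctrl=5,
                snp_fraction=0.1, planted_specific=(("G0002", 3.0), ("G0003", 3.0)))
cohort = generate_cohort(cfg)
wes, snp_db, editing_db = generate_catalogs(cfg, cohort.truth)
records = [r for recs in cohort.variants.values() for r in recs]
sites, report = run_discovery(records, [wes, snp_db], editing_db, cohort.model)
print(report.to_frame().to_string(index=False))

matrix = build_editing_matrix(filter_observations(cohort.observations, sites),
                              sites, cohort.sheet)
gene_levels = build_gene_matrix(matrix)
means = group_mean_editing(gene_levels, cohort.sheet)
specs, counts = classify_specificity(means, tau=0.75)
print("class counts:", counts)
test = compare_matrix_groups(gene_levels, cohort.sheet)
print(f"signed-rank p = {test.p_value:.3g} over {test.n_units} genes")
```

prints

```
          stage  entering  kept  removed
        quality      2965  2957        8
dna_subtraction      2957  2840      117
editing_catalog      2840   883     1957
    informative       883   881        2
class counts: {'case-specific': 2, 'control-specific': 0, 'shared': 196, 'unevaluable': 0}
signed-rank p = 2.33e-16 over 198 genes
```

Reading the output: of 2,965 distinct mismatch positions entering the
cascade, 8 fail the quality thresholds, 117 match known DNA variants
(germline SNP contamination), 1,957 are not in the known-editing catalog
(sequencing-error background), 2 are not deeply covered in enough samples,
and 881 high-confidence sites survive.  Both
genes carrying planted case-biased editing — and only those — are called
case-specific (their scores are 0.864 and 0.889, above the 0.75 rule), and
the paired signed-rank test confirms globally elevated editing in the case
group.

The same steps are available as CLI subcommands, each seeded and
config-driven:

```sh
editome simulate --seed 11 --out bundle/
editome discover --vcf-dir bundle/variants --wes bundle/wes.tsv \
    --snp-db bundle/snp_db.tsv --editing-db bundle/editing_db.tsv \
    --annotation bundle/features.bed --repeats bundle/repeats.bed \
    --samples bundle/samples.tsv --pileup bundle/pileup.tsv --out discovered/
editome quantify  --sites discovered/sites.tsv --pileup bundle/pileup.tsv \
    --samples bundle/samples.tsv --out quantified/
editome specificity --matrix quantified/gene_levels.tsv \
    --samples bundle/samples.tsv --tau 0.75 --out specificity/
editome prioritize --de bundle/de.tsv --matrix-a kd_ctrl.tsv --matrix-b kd.tsv \
    --survival bundle/survival.tsv --expression bundle/expression.tsv \
    --editing quantified/gene_levels.tsv --enzyme ADAR1 --out prioritized/
```

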