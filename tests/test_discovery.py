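"""Filter cascade stages against independent set-arithmetic oracles."""
import random
import warnings
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from editome.discovery import (
    VARIANT_TYPES,
    apply_quality_filters,
    classify_variant_type,
    restrict_to_editing_catalog,
    run_discovery,
    select_informative_sites,
    subtract_known_dna_variants,
    tabulate_variant_types,
)
from editome.types import Catalog, FilterThresholds, SampleSheet, SiteObservation, VariantRecord


def make_record(
    pos=100, ref="A", alt="G", alt_reads=3, bq=30.0, mq=50.0, cov=40, sample="S1", chrom="chr1"
):
    return VariantRecord(chrom, pos, ref, alt, alt_reads, bq, mq, cov, sample)


class TestClassifyVariantType:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected",
        [
            ("A", "G", "+", "A-to-G"),
            ("T", "C", "-", "A-to-G"),
            ("C", "T", "+", "C-to-T"),
            ("G", "A", "-", "C-to-T"),
            ("A", "G", "unknown", "A-to-G"),
            ("T", "C", "unknown", "T-to-C"),
        ],
    )
    def test_orientation(self, ref, alt, strand, expected):
        assert classify_variant_type(ref, alt, strand) == expected

    def test_twelve_distinct_types(self):
        labels = {
            classify_variant_type(r, a, "+")
            for r in "ACGT"
            for a in "ACGT"
            if r != a
        }
        assert labels == set(VARIANT_TYPES) and len(labels) == 12

    def test_unknown_strand_is_flagged_genomic(self):
        label, oriented = classify_variant_type("T", "C", "unknown", with_flag=True)
        assert label == "T-to-C" and oriented is False
        label, oriented = classify_variant_type("T", "C", "-", with_flag=True)
        assert label == "A-to-G" and oriented is True

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_variant_type("N", "G", "+")
        with pytest.raises(ValueError):
            classify_variant_type("A", "A", "+")
        with pytest.raises(ValueError):
            classify_variant_type("A", "G", "*")

    @given(ref=st.sampled_from("ACGT"), alt=st.sampled_from("ACGT"))
    @settings(max_examples=20, derandomize=True)
    def test_minus_strand_equals_complemented_plus(self, ref, alt):
        if ref == alt:
            return
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert classify_variant_type(ref, alt, "-") == classify_variant_type(
            comp[ref], comp[alt], "+"
        )


class TestTabulate:
    def test_pure_a_to_g(self):
        records = [make_record(pos=100 + i, sample="S1") for i in range(10)]
        counts, _ = tabulate_variant_types(records)
        assert counts.loc["S1", "A-to-G"] == 10
        assert counts.loc["S1"].sum() == 10

    def test_empty_records_all_zero(self):
        sheet = SampleSheet.from_records([("S1", "case"), ("S2", "control")])
        counts, means = tabulate_variant_types([], sheet=sheet)
        assert (counts.to_numpy() == 0).all()
        assert set(means.index) == {"case", "control"}

    def test_unknown_sample_errors(self):
        sheet = SampleSheet.from_records([("S1", "case"), ("S2", "control")])
        with pytest.raises(ValueError, match="absent"):
            tabulate_variant_types([make_record(sample="S9")], sheet=sheet)

    def test_rows_sum_to_per_sample_record_counts(self, small_records, small_cohort):
        counts, _ = tabulate_variant_types(
            small_records, small_cohort.model, small_cohort.sheet
        )
        per_sample = defaultdict(int)
        for r in small_records:
            per_sample[r.sample_id] += 1
        for sample, n in per_sample.items():
            assert counts.loc[sample].sum() == n

    def test_editing_dominant_generator_gives_modal_a_to_g(self, small_records, small_cohort):
        counts, _ = tabulate_variant_types(
            small_records, small_cohort.model, small_cohort.sheet
        )
        totals = counts.sum(axis=0)
        assert totals.idxmax() == "A-to-G"
        assert totals["A-to-G"] > 10 * totals.drop("A-to-G").mean()


class TestQualityFilters:
    def test_boundaries(self):
        thr = FilterThresholds()
        assert apply_quality_filters([make_record(cov=9)], thr) == []
        assert len(apply_quality_filters([make_record(cov=10)], thr)) == 1
        assert len(apply_quality_filters([make_record(bq=25.0)], thr)) == 1
        assert apply_quality_filters([make_record(bq=24.9)], thr) == []
        assert apply_quality_filters([make_record(mq=19.9)], thr) == []
        assert apply_quality_filters([make_record(alt_reads=0)], thr) == []

    def test_fuzzed_records_match_brute_force_predicate(self):
        rng = np.random.default_rng(11)
        thr = FilterThresholds()
        records = [
            make_record(
                pos=int(rng.integers(1, 10_000)),
                alt_reads=int(rng.integers(0, 15)),
                bq=float(rng.uniform(15, 40)),
                mq=float(rng.uniform(10, 60)),
                cov=int(rng.integers(15, 60)),
                sample=f"S{rng.integers(5)}",
            )
            for _ in range(200)
        ]
        expected = [
            r
            for r in records
            if r.n_alt_reads >= 1
            and r.base_quality >= 25
            and r.mapping_quality >= 20
            and r.coverage >= 10
        ]
        assert apply_quality_filters(records, thr) == expected


class TestCatalogStages:
    def test_removal_and_attribution(self):
        cat = Catalog({("chr1", 100, "A", "G")}, "wes")
        kept, removed = subtract_known_dna_variants(
            [make_record(pos=100), make_record(pos=200)], [cat]
        )
        assert [r.pos for r in kept] == [200]
        assert removed == {"wes": 1}

    def test_key_includes_alt_allele(self):
        cat = Catalog({("chr1", 100, "T", "C")}, "wes")
        kept, _ = subtract_known_dna_variants([make_record(pos=100, ref="A", alt="G")], [cat])
        assert len(kept) == 1  # a T>C SNP entry does not mask an A>G edit

    def test_set_difference_oracle(self):
        rng = random.Random(5)
        keys = [("chr1", rng.randrange(1, 2000), "A", "G") for _ in range(500)]
        records = [make_record(pos=p) for _, p, _, _ in keys]
        catalogs = [
            Catalog({k for k in keys if rng.random() < 0.2}, f"db{i}") for i in range(3)
        ]
        union = set().union(*(c.entries for c in catalogs))
        kept, _ = subtract_known_dna_variants(records, catalogs)
        assert {r.key for r in kept} == {r.key for r in records} - union

    def test_restrict_keeps_only_catalog_members(self):
        cat = Catalog({("chr1", 100, "A", "G")}, "editing-db")
        assert len(restrict_to_editing_catalog([make_record(pos=100)], cat)) == 1
        assert restrict_to_editing_catalog([make_record(pos=200)], cat) == []

    def test_empty_editing_catalog_warns(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            restrict_to_editing_catalog([make_record()], Catalog(frozenset(), "editing-db"))
        assert any("empty" in str(w.message) for w in caught)


class TestInformativeSites:
    def _obs(self, pos, sample, total):
        return SiteObservation("chr1", pos, "A", "G", sample, 0, total)

    @pytest.mark.parametrize("n_samples,expected", [(9, 0), (10, 1)])
    def test_minimum_sample_boundary(self, n_samples, expected):
        obs = [self._obs(100, f"S{i}", 12) for i in range(n_samples)]
        assert len(select_informative_sites(obs, FilterThresholds())) == expected

    def test_low_coverage_samples_do_not_count(self):
        obs = [self._obs(100, f"S{i}", 12) for i in range(9)] + [self._obs(100, "S9", 9)]
        assert select_informative_sites(obs, FilterThresholds()) == set()

    def test_counting_oracle_on_random_matrix(self):
        rng = np.random.default_rng(3)
        thr = FilterThresholds(min_coverage=10, min_informative_samples=10)
        obs, per_site = [], defaultdict(int)
        for pos in range(100, 160):
            for j in range(15):
                total = int(rng.integers(0, 25))
                obs.append(self._obs(pos, f"S{j}", total))
                if total >= 10:
                    per_site[("chr1", pos, "A", "G")] += 1
        expected = {k for k, n in per_site.items() if n >= 10}
        assert select_informative_sites(obs, thr) == expected


class TestRunDiscovery:
    def test_everything_fails_coverage(self):
        records = [make_record(pos=100 + i, cov=5, alt_reads=2) for i in range(10)]
        sites, report = run_discovery(records)
        assert sites == []
        frame = report.to_frame().set_index("stage")
        assert frame.loc["quality", "removed"] == 10

    def test_no_catalogs_stages_are_identity(self, small_records, small_observations):
        sites, report = run_discovery(
            small_records, catalogs=[], editing_catalog=None, observations=small_observations
        )
        frame = report.to_frame().set_index("stage")
        assert frame.loc["dna_subtraction", "removed"] == 0
        assert frame.loc["editing_catalog", "removed"] == 0

    def test_report_counts_non_increasing_and_consistent(
        self, small_records, small_catalogs, small_observations, small_cohort
    ):
        wes, snp_db, editing_db = small_catalogs
        _, report = run_discovery(
            small_records, [wes, snp_db], editing_db, small_cohort.model,
            observations=small_observations,
        )
        frame = report.to_frame()
        assert (frame["kept"] <= frame["entering"]).all()
        assert (frame["entering"].to_numpy()[1:] == frame["kept"].to_numpy()[:-1]).all()
        assert (frame["removed"] + frame["kept"] == frame["entering"]).all()

    def test_cascade_invariant_to_record_and_catalog_order(
        self, small_records, small_catalogs, small_observations, small_cohort
    ):
        wes, snp_db, editing_db = small_catalogs
        sites_a, _ = run_discovery(
            small_records, [wes, snp_db], editing_db, small_cohort.model,
            observations=small_observations,
        )
        shuffled = list(small_records)
        random.Random(1).shuffle(shuffled)
        sites_b, _ = run_discovery(
            shuffled, [snp_db, wes], editing_db, small_cohort.model,
            observations=small_observations,
        )
        assert [s.key for s in sites_a] == [s.key for s in sites_b]

    def test_matches_composed_set_arithmetic_oracle(
        self, small_records, small_catalogs, small_observations, small_cohort
    ):
        """The full cascade equals plain set arithmetic computed independently."""
        wes, snp_db, editing_db = small_catalogs
        thr = FilterThresholds()
        sites, _ = run_discovery(
            small_records, [wes, snp_db], editing_db, small_cohort.model,
            thresholds=thr, observations=small_observations,
        )
        quality = {
            r.key
            for r in small_records
            if r.n_alt_reads >= 1 and r.base_quality >= 25
            and r.mapping_quality >= 20 and r.coverage >= 10
        }
        after_dna = quality - (wes.entries | snp_db.entries)
        after_catalog = after_dna & editing_db.entries
        per_site = defaultdict(set)
        for o in small_observations:
            if o.total_reads >= 10:
                per_site[o.key].add(o.sample_id)
        informative = {k for k, s in per_site.items() if len(s) >= 10}
        assert {s.key for s in sites} == after_catalog & informative
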