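"""Editing-level arithmetic, matrix building and context annotation."""
import math

import numpy as np
import pandas as pd
import pytest

from editome.quantify import (
    annotate_site_context,
    build_editing_matrix,
    filter_observations,
    gene_editing_level,
    sample_editing_level,
    sample_levels,
    site_editing_level,
    summarize_context,
)
from editome import io
from editome.types import (
    EditingSite,
    GeneInterval,
    GeneModel,
    RepeatInterval,
    SampleSheet,
    SiteObservation,
)


def obs(pos, edited, total, sample="S1", ref="A", alt="G"):
    return SiteObservation("chr1", pos, ref, alt, sample, edited, total)


class TestSiteLevel:
    @pytest.mark.parametrize("edited,total,expected", [(0, 50, 0.0), (25, 50, 0.5), (50, 50, 1.0)])
    def test_ratio(self, edited, total, expected):
        assert site_editing_level(edited, total) == expected

    def test_below_coverage_is_missing(self):
        assert math.isnan(site_editing_level(3, 9, min_coverage=10))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            site_editing_level(7, 5)
        with pytest.raises(ValueError):
            site_editing_level(-1, 5)


class TestPooledLevels:
    def test_gene_pooling_is_coverage_weighted_not_mean_of_ratios(self):
        level = gene_editing_level([obs(1, 2, 10), obs(2, 30, 40)])
        assert level == pytest.approx(32 / 50)
        assert level != pytest.approx((0.2 + 0.75) / 2)

    def test_single_site_equals_site_level(self):
        assert gene_editing_level([obs(1, 5, 10)]) == 0.5

    def test_no_covered_sites_is_missing(self):
        assert math.isnan(gene_editing_level([obs(1, 1, 5)], min_coverage=10))

    def test_summation_oracle_random_fixture(self):
        rng = np.random.default_rng(8)
        totals = rng.integers(0, 80, size=200)
        edited = rng.binomial(totals, 0.3)
        observations = [obs(i, int(e), int(t)) for i, (e, t) in enumerate(zip(edited, totals))]
        covered = totals >= 10
        expected = edited[covered].sum() / totals[covered].sum()
        assert gene_editing_level(observations) == pytest.approx(expected)

    def test_sample_level_examples(self):
        assert sample_editing_level([obs(1, 1, 10), obs(2, 9, 10)]) == 0.5
        assert sample_editing_level([obs(1, 0, 10), obs(2, 0, 30)]) == 0.0

    def test_gene_level_equals_coverage_weighted_mean_of_site_levels(self):
        rng = np.random.default_rng(9)
        totals = rng.integers(10, 80, size=50)
        edited = rng.binomial(totals, 0.2)
        observations = [obs(i, int(e), int(t)) for i, (e, t) in enumerate(zip(edited, totals))]
        levels = edited / totals
        weighted = float(np.average(levels, weights=totals))
        assert gene_editing_level(observations) == pytest.approx(weighted)


def _sheet():
    return SampleSheet.from_records([("S1", "case"), ("S2", "control")])


def _sites(n=3):
    return [EditingSite("chr1", 100 + i, "A", "G", gene_id="G1", region="3UTR") for i in range(n)]


class TestBuildMatrix:
    def test_fully_covered_cells_finite(self):
        sites = _sites(3)
        observations = [obs(100 + i, 3, 20, s) for i in range(3) for s in ("S1", "S2")]
        m = build_editing_matrix(observations, sites, _sheet())
        assert m.levels.shape == (3, 2)
        assert int(m.levels.notna().sum().sum()) == 6

    def test_low_coverage_cell_is_missing(self):
        sites = _sites(1)
        observations = [obs(100, 3, 20, "S1"), obs(100, 2, 8, "S2")]
        m = build_editing_matrix(observations, sites, _sheet())
        assert int(m.levels.isna().sum().sum()) == 1
        assert m.coverage.loc["chr1:100:A>G", "S2"] == 8

    def test_unknown_site_or_sample_errors(self):
        sites = _sites(1)
        with pytest.raises(ValueError, match="unknown site"):
            build_editing_matrix([obs(999, 1, 20)], sites, _sheet())
        with pytest.raises(ValueError, match="unknown sample"):
            build_editing_matrix([obs(100, 1, 20, sample="SX")], sites, _sheet())

    def test_permutation_invariance(self):
        sites = _sites(4)
        observations = [obs(100 + i, i, 20 + i, s) for i in range(4) for s in ("S1", "S2")]
        m1 = build_editing_matrix(observations, sites, _sheet())
        m2 = build_editing_matrix(observations[::-1], sites[::-1], _sheet())
        pd.testing.assert_frame_equal(m1.levels, m2.levels)

    def test_matrix_tsv_round_trip(self, tmp_path):
        sites = _sites(3)
        observations = [obs(100 + i, i, 20, s) for i in range(3) for s in ("S1", "S2")]
        m = build_editing_matrix(observations, sites, _sheet())
        path = tmp_path / "matrix.tsv"
        io.write_matrix(path, m.levels)
        back = io.read_matrix(path)
        pd.testing.assert_frame_equal(back, m.levels, check_names=False)

    def test_filter_observations_restricts_to_universe(self):
        sites = _sites(1)
        observations = [obs(100, 1, 20), obs(999, 1, 20)]
        assert len(filter_observations(observations, sites)) == 1


class TestAnnotation:
    def _model(self):
        return GeneModel(
            intervals=[
                GeneInterval("chr1", 100, 199, "+", "G1", "5UTR"),
                GeneInterval("chr1", 200, 599, "+", "G1", "CDS"),
                GeneInterval("chr1", 600, 999, "+", "G1", "3UTR"),
                GeneInterval("chr1", 2000, 2999, "-", "G2", "intron"),
            ],
            repeat_intervals=[RepeatInterval("chr1", 650, 720, "AluS")],
        )

    def test_region_gene_and_repeat(self):
        [site] = annotate_site_context([EditingSite("chr1", 700, "A", "G")], self._model())
        assert (site.gene_id, site.region, site.repeat_family, site.strand) == (
            "G1", "3UTR", "AluS", "+",
        )

    def test_no_overlap_is_intergenic(self):
        [site] = annotate_site_context([EditingSite("chr1", 5000, "A", "G")], self._model())
        assert (site.gene_id, site.region, site.strand) == (None, "intergenic", "unknown")

    def test_minus_strand_gene(self):
        [site] = annotate_site_context([EditingSite("chr1", 2500, "T", "C")], self._model())
        assert (site.strand, site.region) == ("-", "intron")
        assert site.is_a_to_i

    def test_both_strand_overlap_resolved_by_a_to_g_orientation(self):
        model = GeneModel(
            intervals=[
                GeneInterval("chr1", 100, 999, "+", "GP", "intron"),
                GeneInterval("chr1", 100, 999, "-", "GM", "intron"),
            ]
        )
        [plus] = annotate_site_context([EditingSite("chr1", 500, "A", "G")], model)
        assert plus.strand == "+"
        [minus] = annotate_site_context([EditingSite("chr1", 500, "T", "C")], model)
        assert minus.strand == "-"
        [ambiguous] = annotate_site_context([EditingSite("chr1", 500, "C", "T")], model)
        assert ambiguous.strand == "unknown"

    def test_priority_3utr_over_intron(self):
        model = GeneModel(
            intervals=[
                GeneInterval("chr1", 100, 999, "+", "G1", "intron"),
                GeneInterval("chr1", 400, 600, "+", "G2", "3UTR"),
            ]
        )
        [site] = annotate_site_context([EditingSite("chr1", 500, "A", "G")], model)
        assert (site.region, site.gene_id) == ("3UTR", "G2")

    def test_interval_scan_oracle_random_sites(self, small_cohort):
        """Tree-based annotation equals a brute-force scan over all intervals."""
        model = small_cohort.model
        rng = np.random.default_rng(4)
        positions = rng.integers(1, 60 * 30_000, size=1000)
        probes = [EditingSite("chr1", int(p), "A", "G") for p in positions]
        annotated = annotate_site_context(probes, model)
        rank = {"3UTR": 0, "5UTR": 1, "CDS": 2, "ncRNA": 3, "intron": 4}
        for probe, got in zip(probes, annotated):
            hits = [
                iv for iv in model.intervals if iv.chrom == probe.chrom and iv.start <= probe.pos <= iv.end
            ]
            if hits:
                best = min(hits, key=lambda iv: (rank[iv.feature], iv.gene_id))
                assert (got.gene_id, got.region) == (best.gene_id, best.feature)
            else:
                assert got.region == "intergenic"
            rhits = [
                rv.family
                for rv in model.repeat_intervals
                if rv.chrom == probe.chrom and rv.start <= probe.pos <= rv.end
            ]
            assert got.repeat_family == (sorted(set(rhits))[0] if rhits else "nonrepetitive")


class TestContextSummary:
    def test_homogeneous_set(self):
        sites = [
            EditingSite("chr1", 100 + i, "A", "G", repeat_family="AluS", region="3UTR")
            for i in range(10)
        ]
        summary = summarize_context(sites)
        assert summary.proportions("repeat").loc["all", "AluS"] == 1.0
        assert summary.proportions("region").loc["all"].sum() == pytest.approx(1.0)

    def test_empty_set_no_division_by_zero(self):
        summary = summarize_context([])
        assert summary.region_counts.to_numpy().sum() == 0
        assert summary.proportions("region").isna().all(axis=None) or summary.proportions(
            "region"
        ).empty

    def test_generator_alu_fractions_recovered_within_two_se(self, small_cohort, small_config):
        sites = small_cohort.truth.sites
        p = dict(small_config.alu_fractions)["AluS"]
        n = len(sites)
        observed = (sites["repeat_family"] == "AluS").mean()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 2 * se + 1e-9


class TestSampleLevels:
    def test_pooled_level_matches_manual(self):
        sheet = _sheet()
        sites = _sites(2)
        observations = [
            obs(100, 2, 20, "S1"), obs(101, 8, 20, "S1"),
            obs(100, 0, 20, "S2"), obs(101, 4, 5, "S2"),
        ]
        m = build_editing_matrix(observations, sites, sheet)
        levels = sample_levels(m)
        assert levels["S1"] == pytest.approx(10 / 40)
        assert levels["S2"] == pytest.approx(0 / 20)  # low-coverage site excluded
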