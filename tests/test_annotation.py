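"""Unified annotation, fractional counting and enrichment statistics."""

import numpy as np
import pytest
from scipy import stats

from crspipe.annotation import (
    CATEGORIES,
    NcRnaFeature,
    assign_fractional_categories,
    compare_screens,
    enrichment_pvalue,
    expected_overlap,
    filter_ncrna_features,
    fold_enrichment,
    ncrna_recovery_table,
    round_half_up,
    unify_annotation,
)
from crspipe.intervals import GenomicInterval, Track, merge_track
from crspipe.io import GeneModel, GeneSet


def iv(chrom, start, end, strand=".", name=""):
    return GenomicInterval(chrom, start, end, strand, name)


def tiny_gene_set():
    """One coding gene (two exons), one non-coding gene, 10 kb chromosome.

    Coding gene on +: span 1000-3000; exon1 1000-1400, exon2 2200-3000;
    CDS 1200-2600 -> 5'-UTR 1000-1200, 3'-UTR 2600-3000.
    ncRNA gene: single exon 5000-5200.
    """
    gs = GeneSet(chrom_sizes={"chr1": 10_000})
    coding = GeneModel(
        "gA", "chr1", 1000, 3000, "+",
        exons=[iv("chr1", 1000, 1400, "+"), iv("chr1", 2200, 3000, "+")],
        cds=[iv("chr1", 1200, 1400, "+"), iv("chr1", 2200, 2600, "+")],
    )
    nc = GeneModel("gB", "chr1", 5000, 5200, "+", exons=[iv("chr1", 5000, 5200, "+")])
    gs.genes = {"gA": coding, "gB": nc}
    return gs


class TestUnify:
    def label_at(self, ua, chrom, pos):
        starts, ends, codes = ua.segments[chrom]
        i = np.searchsorted(ends, pos, side="right")
        return CATEGORIES[codes[i]]

    def test_basic_categories(self):
        ua = unify_annotation(tiny_gene_set())
        assert self.label_at(ua, "chr1", 1100) == "utr5_exon"
        assert self.label_at(ua, "chr1", 1300) == "coding_exon"
        assert self.label_at(ua, "chr1", 1800) == "intron"
        assert self.label_at(ua, "chr1", 2700) == "utr3_exon"
        assert self.label_at(ua, "chr1", 5100) == "ncrna_exon"
        assert self.label_at(ua, "chr1", 9000) == "intergenic"

    def test_ncrna_feature_overrides_utr(self):
        nc = Track("nc", [iv("chr1", 1050, 1150)])
        ua = unify_annotation(tiny_gene_set(), nc)
        assert self.label_at(ua, "chr1", 1100) == "ncrna_exon"
        assert self.label_at(ua, "chr1", 1180) == "utr5_exon"

    def test_overlapping_utr5_and_utr3_become_both(self):
        gs = tiny_gene_set()
        # a second '+' gene whose 5'-UTR overlaps gA's 3'-UTR (2600-3000)
        gs.genes["gC"] = GeneModel(
            "gC", "chr1", 2800, 4000, "+",
            exons=[iv("chr1", 2800, 4000, "+")],
            cds=[iv("chr1", 3100, 3800, "+")],
        )
        ua = unify_annotation(gs)
        assert self.label_at(ua, "chr1", 2900) == "both_utr_exon"

    def test_partition_covers_chromosome_exactly(self, genome):
        ua = unify_annotation(
            genome.genes, Track("nc", [f.interval for f in genome.ncrna_features])
        )
        for chrom, size in genome.genes.chrom_sizes.items():
            starts, ends, codes = ua.segments[chrom]
            assert starts[0] == 0 and ends[-1] == size
            assert np.all(starts[1:] == ends[:-1])  # no gaps, no overlaps

    def test_exonless_gene_rejected(self):
        gs = tiny_gene_set()
        gs.genes["bad"] = GeneModel("bad", "chr1", 6000, 6500, "+")
        with pytest.raises(Exception, match="bad"):
            unify_annotation(gs)


class TestFractionalCounts:
    def test_single_and_split_weights(self):
        ua = unify_annotation(tiny_gene_set())
        loci = Track("l", [
            iv("chr1", 1500, 1600, name="in_intron"),       # 1 intron element
            iv("chr1", 1380, 1420, name="cds_and_intron"),  # coding exon + intron
            iv("chr1", 9000, 9100, name="intergenic"),
        ], merged=True)
        counts = assign_fractional_categories(loci, ua)
        assert counts["intron"] == pytest.approx(1.5)
        assert counts["coding_exon"] == pytest.approx(0.5)
        assert counts["intergenic"] == pytest.approx(1.0)

    def test_unmapped_chromosome(self):
        ua = unify_annotation(tiny_gene_set())
        loci = Track("l", [iv("chrX", 0, 100, name="x")], merged=True)
        assert assign_fractional_categories(loci, ua)["unmapped"] == 1.0

    def test_counts_sum_to_locus_count(self, genome, rng):
        ua = unify_annotation(
            genome.genes, Track("nc", [f.interval for f in genome.ncrna_features])
        )
        starts = rng.integers(0, 119_000, 150)
        loci = Track("l", [
            iv("chr1" if k % 2 else "chr2", int(s), int(s) + int(rng.integers(30, 400)),
               name=f"L{k}")
            for k, s in enumerate(starts)
        ], merged=True)
        counts = assign_fractional_categories(loci, ua)
        assert sum(counts.values()) == pytest.approx(len(loci))


class TestEnrichmentStats:
    def test_fold_enrichment_examples(self):
        assert fold_enrichment(50, 100, 1000, 4000) == pytest.approx(2.0)
        assert fold_enrichment(7, 7, 1234, 1234) == pytest.approx(1.0)
        assert fold_enrichment(0, 100, 1000, 4000) == 0.0
        assert np.isnan(fold_enrichment(5, 100, 0, 4000))

    def test_pvalue_examples(self):
        assert enrichment_pvalue(25.0, 100, 0.25) == pytest.approx(0.5)
        # z = (50-25)/sqrt(18.75) = 5.7735
        assert enrichment_pvalue(50, 100, 0.25) == pytest.approx(
            float(stats.norm.sf(25 / np.sqrt(18.75))), rel=1e-12
        )
        assert enrichment_pvalue(50, 100, 0.25) < 5e-9
        assert enrichment_pvalue(10, 100, 0.25) < 0.5  # lower tail

    def test_pvalue_rejects_degenerate_fraction(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(5, 10, 0.0)

    def test_pvalue_agrees_with_binomial_monte_carlo(self, rng):
        # moderate-p regime where the normal approximation should track a
        # direct binomial null within Monte-Carlo error
        n, f = 400, 0.3
        draws = rng.binomial(n, f, size=10_000)
        for observed in (130, 140, 150):
            p_mc = float(np.mean(draws >= observed))
            p_norm = enrichment_pvalue(observed, n, f)
            if 1e-3 <= p_mc <= 0.5:
                assert abs(p_norm - p_mc) < 0.02


class TestNcRnaRecovery:
    def features(self):
        blocks = merge_track(Track("b", [iv("chr1", 0, 2000)]), 0)
        repeats = merge_track(Track("r", [iv("chr1", 900, 1100)]), 0)
        feats = [
            NcRnaFeature(iv("chr1", 100, 200, name="f_ok"), "snRNA", 0.6),
            NcRnaFeature(iv("chr1", 100, 200, name="f_weak"), "snRNA", 0.29),
            NcRnaFeature(iv("chr1", 1920, 2120, name="f_outside"), "snRNA", 0.6),
            NcRnaFeature(iv("chr1", 950, 1050, name="f_repeat"), "snRNA", 0.6),
        ]
        return feats, blocks, repeats

    def test_filter_rules(self):
        feats, blocks, repeats = self.features()
        kept = filter_ncrna_features(feats, blocks, repeats)
        assert [f.interval.name for f in kept] == ["f_ok"]

    def test_recovery_percentages(self):
        feats = [
            NcRnaFeature(iv("chr1", i * 1000, i * 1000 + 100, name=f"s{i}"), "scaRNA", 0.6)
            for i in range(6)
        ] + [
            NcRnaFeature(iv("chr1", 50_000 + i * 1000, 50_000 + i * 1000 + 100,
                            name=f"t{i}"), "tRNA", 0.6)
            for i in range(2)
        ]
        loci = Track("l", [
            iv("chr1", 0, 100, name="L1"),
            iv("chr1", 1000, 1100, name="L2"),
            iv("chr1", 2000, 2060, name="L3"),  # covers 60% of itself in s2
        ], merged=True)
        table = ncrna_recovery_table(loci, feats).set_index("rna_class")
        assert table.loc["scaRNA", "n_overlapped"] == 3
        assert table.loc["scaRNA", "pct_overlapped"] == 50.0
        assert table.loc["tRNA", "n_overlapped"] == 0
        assert table.loc["All", "n_filtered"] == 8
        assert table.loc["All", "n_crs"] == 3

    def test_empty_class_percentage_is_nan(self):
        table = ncrna_recovery_table(Track("l", [], merged=True), [])
        assert np.isnan(table.loc[0, "pct_overlapped"])


class TestScreens:
    def test_expected_overlap_product(self):
        assert expected_overlap(0.18, 0.65) == pytest.approx(0.117)
        assert round_half_up(expected_overlap(0.18, 0.65), 2) == 0.12

    def test_identical_and_disjoint_screens(self):
        a = Track("a", [iv("c", 0, 100, name="a1"), iv("c", 500, 600, name="a2")])
        b = Track("b", [iv("c", 2000, 2100, name="b1")])
        mat = compare_screens({"A": a, "A2": a, "B": b})
        assert mat.loc["A", "A"] == 2          # diagonal = screen size
        assert mat.loc["A", "A2"] == 2         # identical screens: all overlap
        assert mat.loc["A", "B"] == 0 and mat.loc["B", "A"] == 0


def test_round_half_up_at_exact_halves():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(2.5) == 3.0
    assert round_half_up(17.65, 1) == 17.7
    assert round_half_up(3.523, 1) == 3.5
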