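"""Co-expression scoring and cross-species synteny of CRS-gene pairs."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crspipe.coexpression import (
    compute_coexpression,
    coexpression_score,
    synteny_tests,
)
from crspipe.intervals import GenomicInterval, Track
from crspipe.simulate import (
    OrthologyConfig,
    SimulationConfig,
    generate_orthology,
)


def iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, ".", name)


class TestScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((29, 29, 0, 51), 1.0),    # perfect positive
            ((0, 5, 75, 75), -1.0),    # perfect negative
            ((2, 4, 38, 76), 0.0),     # independence
            ((3, 4, 8, 76), float(Fraction(3, 4) - Fraction(8, 76))),
        ],
    )
    def test_reference_values(self, counts, expected):
        assert coexpression_score(*counts) == pytest.approx(expected, abs=1e-12)

    def test_nc_zero_defines_ratio2_zero(self):
        assert coexpression_score(10, 10, 0, 0) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            coexpression_score(5, 4, 0, 10)  # E_cg > E_c
        with pytest.raises(ValueError):
            coexpression_score(0, 0, 0, 10)  # E_c = 0

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_extremes(self, data):
        e_c = data.draw(st.integers(1, 40))
        e_nc = data.draw(st.integers(0, 40))
        e_cg = data.draw(st.integers(0, e_c))
        e_gnc = data.draw(st.integers(0, e_nc))
        s = coexpression_score(e_cg, e_c, e_gnc, e_nc)
        assert -1.0 <= s <= 1.0
        assert (s == 1.0) == (e_cg == e_c and e_gnc == 0)
        if e_nc > 0:
            assert (s == -1.0) == (e_cg == 0 and e_gnc == e_nc)


def _matrix(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows).T.astype(bool)


class TestComputeCoexpression:
    def scene(self):
        loci = Track("l", [iv("c", 1000, 1100, "crs1"), iv("c", 5000, 5100, "crs2")],
                     merged=True)
        elements = Track("e", [iv("c", 1200, 1400, "gA:utr5:1200"),
                               iv("c", 6000, 6200, "gB:utr3:6000")])
        return loci, elements

    def test_planted_perfect_positive(self):
        loci, elements = self.scene()
        m = _matrix({
            "crs1": [1, 1, 1, 0, 0, 0],
            "gA:utr5:1200": [1, 1, 1, 0, 0, 0],
            "crs2": [0, 0, 0, 0, 0, 0],
            "gB:utr3:6000": [0, 0, 0, 1, 1, 1],
        })
        recs = compute_coexpression(loci, elements, m, min_expr=3)
        assert len(recs) == 1  # crs2 expressed in 0 < 3 experiments
        r = recs[0]
        assert (r.crs_id, r.element_id) == ("crs1", "gA:utr5:1200")
        assert r.score == 1.0 and r.coexpr_class == "positive"
        assert r.distance == 100

    def test_min_expression_filter(self):
        loci, elements = self.scene()
        m = _matrix({
            "crs1": [1, 1, 0, 0, 0, 0],
            "gA:utr5:1200": [1, 1, 0, 0, 0, 0],
            "crs2": [0] * 6, "gB:utr3:6000": [0] * 6,
        })
        assert compute_coexpression(loci, elements, m, min_expr=3) == []

    def test_inclusive_thresholds_classify(self):
        loci = Track("l", [iv("c", 0, 100, "crs1")], merged=True)
        elements = Track("e", [iv("c", 200, 300, "el")])
        # E_cg=2, E_c=4, E_gnc=0, E_nc=4 -> score 0.5 -> positive (inclusive)
        m = _matrix({"crs1": [1, 1, 1, 1, 0, 0, 0, 0],
                     "el": [1, 1, 0, 0, 0, 0, 0, 0]})
        r = compute_coexpression(loci, elements, m, min_expr=3)[0]
        assert r.score == pytest.approx(0.5) and r.coexpr_class == "positive"
        # score just below 0.5 -> independent
        m2 = _matrix({"crs1": [1, 1, 1, 1, 1, 0, 0, 0],
                      "el": [1, 1, 0, 0, 0, 0, 0, 0]})
        r2 = compute_coexpression(loci, elements, m2, min_expr=3)[0]
        assert r2.coexpr_class == "independent"

    def test_tied_neighbors_produce_flagged_records(self):
        loci = Track("l", [iv("c", 1000, 1100, "crs1")], merged=True)
        elements = Track("e", [iv("c", 880, 990, "left"), iv("c", 1110, 1220, "right")])
        m = _matrix({"crs1": [1, 1, 1, 0], "left": [1, 1, 1, 0], "right": [0, 0, 0, 1]})
        recs = compute_coexpression(loci, elements, m, min_expr=3)
        assert len(recs) == 2 and all(r.tied for r in recs)

    def test_no_neighbor_chromosome(self):
        loci = Track("l", [iv("c", 0, 100, "crs1")], merged=True)
        elements = Track("e", [iv("d", 0, 100, "el")])
        m = _matrix({"crs1": [1, 1, 1, 0], "el": [0, 0, 0, 0]})
        recs = compute_coexpression(loci, elements, m, min_expr=3)
        assert recs[0].status == "no_neighbor"

    def test_score_invariant_under_experiment_permutation(self, rng):
        loci, elements = self.scene()
        crs = rng.random(12) < 0.5
        crs[:3] = True
        gene = rng.random(12) < 0.5
        m = _matrix({"crs1": crs.astype(int).tolist(),
                     "gA:utr5:1200": gene.astype(int).tolist(),
                     "crs2": [0] * 12, "gB:utr3:6000": [0] * 12})
        base = compute_coexpression(loci, elements, m, min_expr=1)[0].score
        perm = rng.permutation(12)
        m2 = m.iloc[:, perm]
        assert compute_coexpression(loci, elements, m2, min_expr=1)[0].score == base


def synteny_scene(ocfg: OrthologyConfig):
    cfg = SimulationConfig(seed=5, orthology=ocfg)
    crs = iv("chr1", 50_000, 50_100, "crsA")
    gene = iv("chr1", 50_400, 51_000, "gene0001")
    orth, gene_tracks, crs_tracks = generate_orthology(cfg, [(crs, gene)])

    class R:  # minimal co-expression record stand-in
        crs_id, gene_id, status = "crsA", "gene0001", "ok"

    focal_crs = Track("crs", [crs], merged=True)
    focal_genes = Track("genes", [gene])
    return synteny_tests([R()], orth, gene_tracks, crs_tracks, focal_crs, focal_genes)


class TestSynteny:
    def test_rearrangement_free_pair_passes_all(self):
        v = synteny_scene(OrthologyConfig(n_species=6))[0]
        assert v.strict_pass and v.orientation_pass and v.distance_pass
        assert v.n_available == 6

    def test_insertion_breaks_strict_only(self):
        v = synteny_scene(OrthologyConfig(n_species=6, insertion_rate=1.0))[0]
        assert not v.strict_pass
        assert v.orientation_pass and v.distance_pass

    def test_distance_inflation_breaks_distance_only(self):
        v = synteny_scene(OrthologyConfig(n_species=6, distance_inflation=25_000))[0]
        assert v.orientation_pass and not v.distance_pass

    def test_rearrangement_breaks_orientation(self):
        v = synteny_scene(OrthologyConfig(n_species=6, rearrangement_rate=1.0))[0]
        assert not v.orientation_pass and not v.distance_pass

    def test_missing_orthologs_shrink_denominator(self):
        v = synteny_scene(OrthologyConfig(n_species=6, missing_rate=1.0))
        assert v == [] or v[0].n_available == 0

    def test_distance_pass_subset_of_orientation_pass(self):
        for rate in (0.0, 0.4, 0.8):
            verdicts = synteny_scene(
                OrthologyConfig(n_species=9, rearrangement_rate=rate,
                                distance_inflation=0)
            )
            for v in verdicts:
                assert (not v.distance_pass) or v.orientation_pass
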