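"""Stage-specific expression ratios, their tests, and E_diff scoring."""

import numpy as np
import pandas as pd
import pytest

from crspipe.filtering import BinGrid
from crspipe.intervals import GenomicInterval, Track
from crspipe.io import GeneModel
from crspipe.stages import (
    BiotypeInstance,
    diff_expression_matrix,
    diff_expression_score,
    filter_instances,
    find_independent_introns,
    intergenic_window_ratios,
    ratio_difference,
    stage_enrichment_table,
)
from crspipe.stages import test_ratio_difference as ratio_significance


def iv(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, ".", name)


def inst(name, has_crs, vec, biotype="intron", interval=None):
    return BiotypeInstance(name, biotype, interval or iv("c", 0, 100, name),
                           has_crs, np.array(vec, dtype=bool))


class TestRatioDifference:
    def test_share_denominator_arithmetic(self):
        # CRS stratum: 5 expressed in E_0, 20 expression events elsewhere
        crs = [inst(f"c{i}", True, [1] + [0] * 4) for i in range(5)]
        crs += [inst(f"cx{i}", True, [0, 1, 1, 1, 1]) for i in range(5)]
        # non-CRS: 10 in E_0, 100 events elsewhere
        non = [inst(f"n{i}", False, [1] + [0] * 4) for i in range(10)]
        non += [inst(f"nx{i}", False, [0, 1, 1, 1, 1]) for i in range(25)]
        r_crs, r_non, r_d = ratio_difference(crs + non, 0)
        assert r_crs == pytest.approx(5 / 20)
        assert r_non == pytest.approx(10 / 100)
        assert r_d == pytest.approx(0.15)

    def test_identical_strata_give_zero(self):
        a = [inst(f"a{i}", True, [1, 0, 1, 0]) for i in range(4)]
        b = [inst(f"b{i}", False, [1, 0, 1, 0]) for i in range(4)]
        _, _, r_d = ratio_difference(a + b, 0)
        assert r_d == 0.0

    def test_any_denominator_mode(self):
        insts = [
            inst("a", True, [1, 1, 1]),
            inst("b", True, [1, 0, 0]),
            inst("n1", False, [1, 1, 0]),
            inst("n2", False, [0, 1, 0]),
        ]
        r_crs, r_non, _ = ratio_difference(insts, 0, denominator="any")
        assert r_crs == pytest.approx(2 / 1)  # both expressed in E0; 1 expressed elsewhere
        assert r_non == pytest.approx(1 / 2)

    def test_zero_denominator_flagged_nan(self):
        insts = [inst("a", True, [1, 0]), inst("n", False, [1, 0])]
        r_crs, _, r_d = ratio_difference(insts, 0)
        assert np.isnan(r_crs) and np.isnan(r_d)


class TestSignificance:
    def test_centred_symmetric_sample_is_null(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        p, p_adj, test, alt = ratio_significance(0.4, x, "intron")
        assert 0.3 < p <= 1.0
        assert test == "wilcoxon"

    def test_bonferroni_multiplication_and_cap(self):
        x = [0.0, 0.0, 0.01, 0.02, 0.01, 0.0]
        p, p_adj, _, _ = ratio_significance(0.9, x, "intron", n_tests=100)
        assert p_adj == pytest.approx(min(1.0, p * 100))

    def test_t_family_for_coding_and_utr5(self):
        x = [0.1, 0.12, 0.11, 0.13, 0.09, 0.1, 0.12]
        for bt in ("coding_exon", "utr5_exon"):
            assert ratio_significance(0.3, x, bt)[2] == "t"
        assert ratio_significance(0.3, x, "utr3_exon")[2] == "wilcoxon"

    def test_constant_sample_falls_back_to_sign_test(self):
        p, _, test, _ = ratio_significance(0.3, [0.1] * 6, "coding_exon")
        assert test == "sign(fallback)"
        # all six constant values lie below R_CRS: binomial tail (1/2)^6
        assert p == pytest.approx(0.5**6)

    def test_direction_follows_sign_of_difference(self):
        x = [0.1, 0.2, 0.15, 0.12, 0.18]
        assert ratio_significance(0.5, x, "intron")[3] == "less"
        assert ratio_significance(0.01, x, "intron")[3] == "greater"

    def test_planted_enrichment_detected_only_in_its_group(self, rng):
        n_exp = 12
        group = np.zeros(n_exp, dtype=bool)
        group[:4] = True  # experiments 0-3 form the enriched stage
        crs = [
            inst(f"c{i}", True, group | (rng.random(n_exp) < 0.05))
            for i in range(30)
        ]
        non = [
            inst(f"n{i}", False, rng.random(n_exp) < 0.4) for i in range(60)
        ]
        table = stage_enrichment_table(
            {"intron": crs + non}, [f"e{k}" for k in range(n_exp)]
        )
        # enrichment-direction discoveries must sit inside the planted group
        # (mirror-image depletion in the remaining stages is a real signal
        # of the planted pattern and may also reach significance)
        enriched = table[(table.p_adj < 0.05) & (table.R_d > 0)]
        assert set(enriched.experiment) <= {f"e{k}" for k in range(4)}
        assert len(enriched) >= 2


class TestWindowSampling:
    def test_bin_matched_counts(self):
        rng_windows = pd.DataFrame(
            {
                "chrom": "c", "start": np.arange(600) * 100,
                "end": np.arange(600) * 100 + 100,
                "gc": np.tile([0.25, 0.75], 300),
                "identity": np.tile([0.4, 0.8], 300),
            }
        )
        grid = BinGrid(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.6, 1.0]))
        got = intergenic_window_ratios(rng_windows, grid, {(0, 0): 10, (1, 1): 3}, seed=2)
        g, i = grid.assign(got["gc"], got["identity"])
        assert int(np.sum((g == 0) & (i == 0))) == 10
        assert int(np.sum((g == 1) & (i == 1))) == 3
        assert len(got) == 13

    def test_zero_request_and_determinism(self):
        windows = pd.DataFrame(
            {"chrom": "c", "start": [0, 100], "end": [100, 200],
             "gc": [0.3, 0.3], "identity": [0.5, 0.5]}
        )
        grid = BinGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert len(intergenic_window_ratios(windows, grid, {(0, 0): 0}, seed=1)) == 0
        a = intergenic_window_ratios(windows, grid, {(0, 0): 1}, seed=9)
        b = intergenic_window_ratios(windows, grid, {(0, 0): 1}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_undersized_bin_warns_and_returns_all(self):
        windows = pd.DataFrame(
            {"chrom": "c", "start": [0], "end": [100], "gc": [0.3], "identity": [0.5]}
        )
        grid = BinGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="sampling all"):
            got = intergenic_window_ratios(windows, grid, {(0, 0): 5}, seed=1)
        assert len(got) == 1


class TestDiffExpression:
    def test_reference_values(self):
        crs = np.array([[1, 0], [1, 0], [1, 0]], dtype=bool)
        non = np.array([[1, 1], [0, 0]], dtype=bool)
        assert diff_expression_score(crs, non, 0, 1) == 1.0  # D_H 1 vs 0
        assert diff_expression_score(crs, non, 0, 0) == 0.0  # diagonal

    def test_partial_distances(self):
        crs = np.array([[1, 0], [1, 0], [1, 1], [0, 0]], dtype=bool)  # D_H = 0.5
        non = np.array([[1, 0], [1, 1], [0, 0], [1, 1], [0, 0]], dtype=bool)  # 0.2
        assert diff_expression_score(crs, non, 0, 1) == pytest.approx(0.15)

    def test_empty_stratum_undefined(self):
        assert np.isnan(diff_expression_score(np.empty((0, 2)), np.ones((2, 2)), 0, 1))

    def test_matrix_symmetric_zero_diagonal_bounded(self, rng):
        insts = [
            inst(f"i{k}", bool(rng.random() < 0.5), rng.random(6) < 0.5)
            for k in range(20)
        ]
        m = diff_expression_matrix(insts, 6)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert np.nanmin(m) >= 0.0 and np.nanmax(m) <= 1.0


class TestInstanceFilter:
    def test_min_expression_and_block_containment(self):
        blocks = Track("b", [iv("c", 0, 60)])
        kept = filter_instances(
            [
                inst("in_blocks", True, [1, 1, 1, 0]),      # covered 60/100 >= 0.5
                inst("rarely_on", True, [1, 1, 0, 0]),      # expressed in 2 < 3
            ],
            blocks,
        )
        assert [k.instance_id for k in kept] == ["in_blocks"]


class TestIndependentIntrons:
    def scene(self):
        g = GeneModel(
            "g1", "c", 0, 1000, "+",
            exons=[iv("c", 0, 100), iv("c", 300, 400), iv("c", 700, 800)],
        )
        intron1 = inst("g1:intron0", True, [1, 0], biotype="intron",
                       interval=iv("c", 100, 300, "g1:intron0"))
        return g, intron1

    def test_flanks_off_distal_on_is_tier1_only(self):
        g, intron1 = self.scene()
        exon_expr = {"g1:exon0": [0, 1], "g1:exon1": [0, 1], "g1:exon2": [1, 0]}
        t1, t2 = find_independent_introns(
            [intron1], {"g1": g}, {"g1:intron0": "g1"},
            {k: np.array(v, dtype=bool) for k, v in exon_expr.items()}, 0,
        )
        assert t1 == ["g1:intron0"] and t2 == []

    def test_whole_gene_silent_is_both_tiers(self):
        g, intron1 = self.scene()
        exon_expr = {k: np.zeros(2, dtype=bool)
                     for k in ("g1:exon0", "g1:exon1", "g1:exon2")}
        t1, t2 = find_independent_introns(
            [intron1], {"g1": g}, {"g1:intron0": "g1"}, exon_expr, 0,
        )
        assert t1 == ["g1:intron0"] and t2 == ["g1:intron0"]

    def test_coexpressed_with_flanks_is_neither(self):
        g, intron1 = self.scene()
        exon_expr = {k: np.array([1, 1], dtype=bool)
                     for k in ("g1:exon0", "g1:exon1", "g1:exon2")}
        t1, t2 = find_independent_introns(
            [intron1], {"g1": g}, {"g1:intron0": "g1"}, exon_expr, 0,
        )
        assert t1 == [] and t2 == []
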