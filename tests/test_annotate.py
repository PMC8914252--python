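"""Context categories and leading/lagging fork-orientation geometry."""

import numpy as np
import pytest

from rnpchip.annotate import (
    annotate_peaks,
    assign_fork_orientation,
    classify_context,
    fork_direction,
    relative_position_in_gene,
    summarize_by_replicon,
)
from rnpchip.genome import GeneAnnotation, Replicon
from rnpchip.peakcall import Peak


def pk(start, end, replicon="chr"):
    return Peak(replicon, start, end, (start + end) // 2, 1.0, 1.0, 1.0)


def gene(start, end, strand, replicon="chr", gid="g"):
    return GeneAnnotation(replicon, start, end, strand, gid)


REP = Replicon("chr", 10_000, 0, 5_000)


class TestClassifyContext:
    def test_peak_inside_gene_is_cds(self):
        assert classify_context(pk(150, 300), [gene(100, 400, "+")], REP) == "CDS"

    def test_peak_between_genes_is_ir(self):
        genes = [gene(100, 400, "+"), gene(600, 900, "+")]
        assert classify_context(pk(450, 550), genes, REP) == "IR"

    def test_bridge_between_tandem_plus_genes(self):
        genes = [gene(100, 400, "+"), gene(600, 900, "+")]
        assert classify_context(pk(350, 650), genes, REP) == "CDS5_IR_CDS3"

    def test_bridge_between_tandem_minus_genes(self):
        genes = [gene(100, 400, "-"), gene(600, 900, "-")]
        assert classify_context(pk(350, 650), genes, REP) == "CDS5_IR_CDS3"

    @pytest.mark.parametrize("s1,s2", [("+", "-"), ("-", "+")])
    def test_bridge_between_opposing_genes_is_other(self, s1, s2):
        genes = [gene(100, 400, s1), gene(600, 900, s2)]
        assert classify_context(pk(350, 650), genes, REP) == "OTHER"

    def test_ir_plus_left_edge_of_minus_gene_is_three_prime(self):
        # the minus gene's 3' end sits at its low-coordinate edge
        genes = [gene(100, 400, "+"), gene(600, 900, "-")]
        assert classify_context(pk(450, 700), genes, REP) == "IR_3CDS"

    def test_ir_plus_left_edge_of_plus_gene_is_five_prime(self):
        genes = [gene(100, 400, "+"), gene(600, 900, "+")]
        assert classify_context(pk(450, 700), genes, REP) == "IR_5CDS"

    def test_ir_plus_right_edge_strand_cases(self):
        assert classify_context(pk(300, 500), [gene(100, 400, "+")], REP) == "IR_3CDS"
        assert classify_context(pk(300, 500), [gene(100, 400, "-")], REP) == "IR_5CDS"

    def test_peak_engulfing_a_whole_gene_is_other(self):
        assert classify_context(pk(50, 450), [gene(100, 400, "+")], REP) == "OTHER"

    def test_overlapping_genes_give_other(self):
        genes = [gene(100, 400, "+"), gene(300, 700, "-")]
        assert classify_context(pk(250, 350), genes, REP) == "OTHER"

    def test_seam_wrapping_peak_inside_seam_spanning_region(self):
        # peak wraps; gene at the start of the replicon catches its tail
        genes = [gene(0, 400, "+")]
        assert classify_context(pk(9_900, 10_000 + 300), genes, REP) == "IR_5CDS"


class TestRelativePosition:
    def test_midpoint_at_gene_centre_is_half_for_both_strands(self):
        for strand in "+-":
            g = gene(0, 1000, strand)
            assert relative_position_in_gene(pk(400, 600), g) == pytest.approx(0.5)

    def test_plus_gene_near_end(self):
        g = gene(0, 1000, "+")
        assert relative_position_in_gene(pk(850, 950), g) == pytest.approx(0.9)

    def test_minus_gene_reflects(self):
        g = gene(0, 1000, "-")
        assert relative_position_in_gene(pk(850, 950), g) == pytest.approx(0.1)

    def test_requires_containment(self):
        with pytest.raises(ValueError):
            relative_position_in_gene(pk(900, 1100), gene(0, 1000, "+"))


class TestForkDirection:
    REP = Replicon("chr", 1000, 0, 500)

    def test_cw_arc(self):
        assert fork_direction(250, self.REP) == "CW"

    def test_ccw_arc(self):
        assert fork_direction(750, self.REP) == "CCW"

    def test_landmarks_ambiguous(self):
        assert fork_direction(0, self.REP) == "AMBIGUOUS"
        assert fork_direction(500, self.REP) == "AMBIGUOUS"

    def test_agrees_with_walker_oracle_on_random_geometries(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            L = int(rng.integers(10, 500))
            ori = int(rng.integers(0, L))
            ter = int(rng.integers(0, L))
            if ori == ter:
                continue
            p = int(rng.integers(0, L))
            rep = Replicon("c", L, ori, ter)
            assert fork_direction(p, rep) == walker_oracle(p, ori, ter, L)


def walker_oracle(p, ori, ter, L):
    """Step from ori in both directions until ter; who reaches p first wins."""
    if p == ori or p == ter:
        return "AMBIGUOUS"
    cw, ccw = ori, ori
    cw_alive = ccw_alive = True
    for _ in range(L):
        if cw_alive:
            cw = (cw + 1) % L
            if cw == p:
                return "CW"
            if cw == ter:
                cw_alive = False
        if ccw_alive:
            ccw = (ccw - 1) % L
            if ccw == p:
                return "CCW"
            if ccw == ter:
                ccw_alive = False
    raise AssertionError("walker never reached the position")


class TestAssignForkOrientation:
    REP = Replicon("chr", 1000, 0, 500)

    def test_cw_fork_plus_gene_is_lagging(self):
        genes = [gene(200, 320, "+")]
        assert assign_fork_orientation(pk(230, 280), genes, self.REP) == "LAG"

    def test_ccw_fork_plus_gene_is_leading(self):
        genes = [gene(700, 820, "+")]
        assert assign_fork_orientation(pk(730, 780), genes, self.REP) == "LEAD"

    def test_intergenic_peak_is_nd(self):
        assert assign_fork_orientation(pk(230, 280), [], self.REP) == "ND"

    def test_disagreeing_gene_strands_give_nd(self):
        genes = [gene(200, 260, "+"), gene(270, 330, "-")]
        assert assign_fork_orientation(pk(230, 300), genes, self.REP) == "ND"

    def test_peak_spanning_ori_or_ter_is_nd(self):
        genes = [gene(450, 560, "+")]
        assert assign_fork_orientation(pk(460, 550), genes, self.REP) == "ND"

    def test_strand_flip_with_ori_ter_swap_preserves_partition(self):
        # flipping every gene strand and swapping ori<->ter flips the fork
        # direction and the template strand together: calls are unchanged
        rng = np.random.default_rng(1)
        rep = Replicon("chr", 1000, 100, 700)
        swapped = Replicon("chr", 1000, 700, 100)
        for _ in range(100):
            s = int(rng.integers(0, 900))
            g = [gene(s, s + 80, "+" if rng.random() < 0.5 else "-")]
            flipped = [
                GeneAnnotation(x.replicon, x.start, x.end,
                               "+" if x.strand == "-" else "-", x.gene_id)
                for x in g
            ]
            peak = pk(s + 10, s + 70)
            assert assign_fork_orientation(peak, g, rep) == assign_fork_orientation(
                peak, flipped, swapped
            )


class TestAnnotateAndSummaries:
    def test_rotation_covariance_of_full_annotation(self):
        rng = np.random.default_rng(2)
        L, k = 10_000, 3_000
        rep = Replicon("chr", L, 1_000, 6_000)
        rot = Replicon("chr", L, (1_000 + k) % L, (6_000 + k) % L)
        genes, peaks = [], []
        for i in range(30):
            s = int(rng.integers(0, L - 500))
            genes.append(gene(s, s + 200, "+" if rng.random() < 0.5 else "-",
                              gid=f"g{i}"))
            peaks.append(pk(s + 20, s + 150))
        genes_rot = [
            GeneAnnotation("chr", (g.start + k) % L, (g.start + k) % L + 200,
                           g.strand, g.gene_id)
            for g in genes
        ]
        peaks_rot = [pk((p.start + k) % L, (p.start + k) % L + (p.end - p.start))
                     for p in peaks]
        a1 = annotate_peaks(peaks, genes, {"chr": rep})
        a2 = annotate_peaks(peaks_rot, genes_rot, {"chr": rot})
        assert a1["category"].tolist() == a2["category"].tolist()
        assert a1["fork"].tolist() == a2["fork"].tolist()
        assert a1["ori_distance"].tolist() == a2["ori_distance"].tolist()

    def test_summary_conservation_and_percentages(self):
        rep = Replicon("chr", 1000, 0, 500)
        genes = [gene(200, 320, "+")]
        peaks = [pk(230, 280)] * 10
        ann = annotate_peaks(peaks, genes, {"chr": rep})
        cat, fork = summarize_by_replicon(ann)
        assert int(cat.drop(columns="replicon").sum(axis=1).iloc[0]) == 10
        assert fork.loc[0, "LAG"] == pytest.approx(100.0)
        assert fork.loc[0, "n"] == 10

    def test_empty_input_gives_empty_tables(self):
        cat, fork = summarize_by_replicon(
            annotate_peaks([], [], {"chr": Replicon("chr", 100, 0, 50)})
        )
        assert len(cat) == 0 and len(fork) == 0

    def test_unknown_replicon_rejected(self):
        with pytest.raises(ValueError, match="unknown replicon"):
            annotate_peaks([pk(0, 10, replicon="nope")], [], {"chr": REP})
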