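"""Genomic-context classification and replication-fork orientation of peaks.

Context categories follow the standard vocabulary for bacterial ChIP peaks:
fully inside a coding sequence (CDS), fully intergenic (IR), intergenic plus
the 5'- or 3'-terminal part of one adjacent gene (IR_5CDS / IR_3CDS),
spanning the 3' end of one gene, the intergenic region and the 5' end of the
next (CDS5_IR_CDS3), or anything else (OTHER; e.g. a peak engulfing a whole
gene or lying across overlapping genes).  A peak overlapping both a gene's
3' end and the IR is reported as IR_3CDS and never promoted into
CDS5_IR_CDS3.

Fork orientation: on a circular replicon with a bidirectional origin, one
fork travels clockwise (coordinate-increasing) from ori to ter and the other
counter-clockwise.  For a clockwise fork the plus (top) strand runs 5'->3'
in the fork direction, so it cannot template continuous synthesis: it is the
lagging-strand template.  A peak is called LAG when the strand of its (unique,
consistent) overlapping gene equals the local lagging-strand template, LEAD
otherwise, and ND when orientation is indeterminate (no gene, disagreeing
strands, peak spanning ori/ter, or midpoint at ori/ter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome import GeneAnnotation, Replicon
from .oristats import circular_distance
from .peakcall import Peak

CONTEXT_CATEGORIES = ("CDS", "IR", "IR_5CDS", "IR_3CDS", "CDS5_IR_CDS3", "OTHER")
FORK_CALLS = ("LEAD", "LAG", "ND")


@dataclass
class AnnotatedPeak:
    peak: Peak
    category: str
    fork: str
    ori_distance: int
    relative_gene_position: float | None = None


def fork_direction(position: int, replicon: Replicon) -> str:
    """CW if *position* lies on the ori->ter coordinate-increasing arc.

    Returns ``"AMBIGUOUS"`` exactly at ori or ter, where the two forks meet.
    """
    L = replicon.length
    if not 0 <= position < L:
        raise ValueError(f"position {position} outside [0, {L})")
    if position == replicon.ori or position == replicon.ter:
        return "AMBIGUOUS"
    cw_arc = (replicon.ter - replicon.ori) % L
    if (position - replicon.ori) % L < cw_arc:
        return "CW"
    return "CCW"


def lagging_template_strand(direction: str) -> str:
    """Template strand of discontinuous synthesis under a CW or CCW fork."""
    if direction == "CW":
        return "+"
    if direction == "CCW":
        return "-"
    raise ValueError(f"no lagging template for direction {direction!r}")


def _relative_gene_frame(
    peak_start: int, peak_len: int, genes: Sequence[GeneAnnotation], L: int
) -> list[tuple[int, int, GeneAnnotation]]:
    """Genes overlapping the peak, in coordinates where the peak is [0, peak_len).

    Rotating by ``-peak_start`` makes the circular overlap test linear; a gene
    straddling the rotation origin is given a negative start.
    """
    out = []
    for g in genes:
        gs = (g.start - peak_start) % L
        glen = g.end - g.start
        if gs + glen > L:
            gs -= L
        if gs < peak_len and gs + glen > 0:
            out.append((gs, gs + glen, g))
    out.sort(key=lambda t: t[0])
    return out


def classify_context(
    peak: Peak, genes: Sequence[GeneAnnotation], replicon: Replicon
) -> str:
    """Assign exactly one context category to a peak."""
    L = replicon.length
    plen = peak.end - peak.start
    if plen >= L:
        return "OTHER"
    overlaps = _relative_gene_frame(peak.start % L, plen, genes, L)
    if not overlaps:
        return "IR"
    # overlapping genes among the hits -> undefined context
    for (s1, e1, _), (s2, e2, _) in zip(overlaps, overlaps[1:]):
        if s2 < e1:
            return "OTHER"
    if len(overlaps) == 1:
        gs, ge, g = overlaps[0]
        if gs <= 0 and ge >= plen:
            return "CDS"  # peak contained in the gene
        if gs >= 0 and ge <= plen:
            return "OTHER"  # peak engulfs the whole gene
        if gs > 0:  # peak sticks out on the gene's coordinate-left side
            covered_left_part = True
        else:  # ge < plen: peak sticks out on the right, covers gene's right part
            covered_left_part = False
        # left part of a + gene is its 5' end; of a - gene its 3' end
        if covered_left_part:
            return "IR_5CDS" if g.strand == "+" else "IR_3CDS"
        return "IR_3CDS" if g.strand == "+" else "IR_5CDS"
    if len(overlaps) == 2:
        (s1, e1, g1), (s2, e2, g2) = overlaps
        partial1 = s1 < 0 < e1 <= plen  # covers g1's right part only
        partial2 = 0 <= s2 < plen < e2  # covers g2's left part only
        if partial1 and partial2 and g1.strand == g2.strand:
            # same strand: 3' end of the upstream gene, IR, 5' end of the next
            return "CDS5_IR_CDS3"
        return "OTHER"
    return "OTHER"


def relative_position_in_gene(peak: Peak, gene: GeneAnnotation) -> float:
    """Peak midpoint within the gene, 0 at the 5' end, 1 at the 3' end."""
    if not (gene.start <= peak.start and peak.end <= gene.end):
        raise ValueError("peak is not contained in the gene")
    mid = (peak.start + peak.end) / 2
    rel = (mid - gene.start) / gene.length
    return rel if gene.strand == "+" else 1.0 - rel


def assign_fork_orientation(
    peak: Peak, genes: Sequence[GeneAnnotation], replicon: Replicon
) -> str:
    """LEAD/LAG/ND call from overlapping-gene strand vs lagging template."""
    L = replicon.length
    plen = peak.end - peak.start
    ps = peak.start % L
    for landmark in (replicon.ori, replicon.ter):
        if (landmark - ps) % L < plen:
            return "ND"
    overlaps = _relative_gene_frame(ps, plen, genes, L)
    strands = {g.strand for _, _, g in overlaps}
    if len(strands) != 1:
        return "ND"
    mid = (ps + plen // 2) % L
    direction = fork_direction(mid, replicon)
    if direction == "AMBIGUOUS":
        return "ND"
    return "LAG" if strands.pop() == lagging_template_strand(direction) else "LEAD"


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    replicons: Mapping[str, Replicon],
) -> pd.DataFrame:
    """Full per-peak annotation table (context, fork call, ori distance)."""
    genes_by_rep: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        genes_by_rep.setdefault(g.replicon, []).append(g)
    rows = []
    for pk in peaks:
        rep = replicons.get(pk.replicon)
        if rep is None:
            raise ValueError(f"peak on unknown replicon {pk.replicon!r}")
        rep_genes = genes_by_rep.get(pk.replicon, [])
        category = classify_context(pk, rep_genes, rep)
        fork = assign_fork_orientation(pk, rep_genes, rep)
        mid = (pk.start + (pk.end - pk.start) // 2) % rep.length
        dist = int(circular_distance(mid, rep.ori, rep.length))
        rel = None
        if category == "CDS":
            host = next(
                g
                for _, _, g in _relative_gene_frame(
                    pk.start % rep.length, pk.end - pk.start, rep_genes, rep.length
                )
            )
            # containment holds by the CDS definition unless the peak wraps
            if pk.end <= rep.length and host.start <= pk.start and pk.end <= host.end:
                rel = relative_position_in_gene(pk, host)
        rows.append(
            {
                "replicon": pk.replicon,
                "start": pk.start,
                "end": pk.end,
                "name": pk.name,
                "category": category,
                "fork": fork,
                "ori_distance": dist,
                "relative_gene_position": rel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicon", "start", "end", "name", "category", "fork",
            "ori_distance", "relative_gene_position",
        ],
    )


def summarize_by_replicon(
    annotated: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts per replicon x category and percentages per replicon x fork call.

    Fork percentages sum to 100 per replicon over LEAD/LAG/ND.
    """
    if annotated.empty:
        return (
            pd.DataFrame(columns=["replicon", *CONTEXT_CATEGORIES]),
            pd.DataFrame(columns=["replicon", *FORK_CALLS, "n"]),
        )
    cat = (
        annotated.groupby(["replicon", "category"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=CONTEXT_CATEGORIES, fill_value=0)
        .reset_index()
    )
    fork_counts = (
        annotated.groupby(["replicon", "fork"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=FORK_CALLS, fill_value=0)
    )
    n = fork_counts.sum(axis=1)
    fork_pct = fork_counts.div(n, axis=0) * 100.0
    fork_pct["n"] = n
    return cat, fork_pct.reset_index()
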