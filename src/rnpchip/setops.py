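"""Interval subtraction with bedtools ``intersect -v`` semantics.

An element of set A survives only if it shares zero base pairs with every
element of set B on the same replicon; a single overlapping base pair (the
bedtools default, no ``-f`` fraction) removes it.  Half-open abutment is not
overlap.  Seam-wrapping intervals are compared through their wrap-split
segments; overlap on either segment counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence, TypeVar

from intervaltree import IntervalTree

T = TypeVar("T")  # anything with .replicon, .start, .end (Peak, interval record)


def _segments(item, lengths: Mapping[str, int] | None) -> list[tuple[int, int]]:
    L = lengths.get(item.replicon) if lengths else None
    if L is not None and item.end > L:
        return [(item.start, L), (0, item.end - L)]
    return [(item.start, item.end)]


def subtract_overlapping(
    a: Sequence[T],
    b: Sequence,
    replicon_lengths: Mapping[str, int] | None = None,
) -> list[T]:
    """Elements of *a* with zero overlap against every element of *b*.

    Order of *a* is preserved; empty sets are allowed.  *replicon_lengths* is
    only needed when seam-wrapping intervals (``end > L``) may be present.
    """
    trees: dict[str, IntervalTree] = {}
    for item in b:
        tree = trees.setdefault(item.replicon, IntervalTree())
        for s, e in _segments(item, replicon_lengths):
            if e > s:
                tree.addi(s, e)
    out: list[T] = []
    for item in a:
        tree = trees.get(item.replicon)
        hit = tree is not None and any(
            tree.overlap(s, e) for s, e in _segments(item, replicon_lengths)
        )
        if not hit:
            out.append(item)
    return out


def unique_peaks(
    tagged_rnp: Sequence[T],
    iep_only: Sequence,
    untagged: Sequence,
    replicon_lengths: Mapping[str, int] | None = None,
) -> list[T]:
    """Two-step unique-peak filter for the tagged-RNP construct.

    First removes tagged-RNP peaks overlapping any IEP-only peak, then removes
    survivors overlapping any untagged-RNP peak (the order is fixed, though
    the two subtractions commute).
    """
    step1 = subtract_overlapping(tagged_rnp, iep_only, replicon_lengths)
    return subtract_overlapping(step1, untagged, replicon_lengths)
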