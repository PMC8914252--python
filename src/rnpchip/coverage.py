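"""Fragment-extension pileup on circular replicons and coverage comparisons.

Each sequenced read stands for a sheared fragment; with no model building the
caller extends every read to a fixed fragment length from its 5' end in read
orientation (the ``--nomodel`` convention).  Coverage wraps across the
circular seam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome import LibraryKey, Replicon

DEFAULT_EXTENSION = 300  # bp; midpoint of the 0.2-0.5 kb sheared-fragment range


@dataclass
class CoverageTrack:
    """Per-base fragment coverage of one replicon."""

    replicon: str
    values: np.ndarray

    @property
    def length(self) -> int:
        return len(self.values)


def fragment_bounds(
    reads: pd.DataFrame, extension: int, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-fragment intervals ``[a, a+extension)`` with ``a`` in [0, L).

    ``a`` is the fragment's coordinate-left edge: the 5' end for a plus read,
    ``end - extension`` for a minus read (whose 5' end is its right edge).
    """
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    plus = (reads["strand"] == "+").to_numpy()
    a = np.where(plus, start, end - extension) % length
    return a, a + extension


def pileup(
    reads: pd.DataFrame, replicon: Replicon, extension: int = DEFAULT_EXTENSION
) -> CoverageTrack:
    """Per-base coverage of extended fragments, wrapping at the seam.

    Conservation: ``values.sum() == n_fragments * extension`` exactly.
    """
    L = replicon.length
    sub = reads[reads["replicon"] == replicon.name]
    if len(sub):
        if (sub["start"].min() < 0) or (sub["start"].max() >= L):
            raise ValueError(f"read start outside [0, {L}) on {replicon.name}")
    a, b = fragment_bounds(sub, extension, L)
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, a, 1)
    np.add.at(diff, np.minimum(b, L), -1)
    wrapped = b[b > L] - L
    if len(wrapped):
        diff[0] += len(wrapped)
        np.add.at(diff, wrapped, -1)
    return CoverageTrack(replicon.name, np.cumsum(diff[:L]))


def region_values(track: CoverageTrack, start: int, end: int) -> np.ndarray:
    """Values over a circular region ``[start, end)`` (``end`` may exceed L)."""
    L = track.length
    if end <= start:
        raise ValueError("empty region")
    if end - start >= L:
        return track.values
    idx = np.arange(start, end) % L
    return track.values[idx]


def mean_coverage(
    track: CoverageTrack, region: tuple[int, int] | None = None
) -> float:
    """Arithmetic mean of per-base coverage over a region or the whole replicon."""
    if region is None:
        return float(track.values.mean())
    return float(region_values(track, *region).mean())


def welch_t_test(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, two-sided p)``.

    Degenerate convention: if both groups have zero variance and equal means,
    ``p = 1``; zero variance with unequal means gives ``p = 0``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(len(a) + len(b) - 2)
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    with warnings.catch_warnings():
        # near-identical groups trip a scipy precision warning; the degenerate
        # exact-equality cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ori_window_region(replicon: Replicon, ori_window: int) -> tuple[int, int]:
    """All positions within circular distance <= ori_window of ori (both arms)."""
    L = replicon.length
    span = min(2 * ori_window, L)
    start = (replicon.ori - ori_window) % L
    return start, start + span


def compare_input_vs_ip(
    tracks: Mapping[LibraryKey, Mapping[str, CoverageTrack]],
    replicons: Mapping[str, Replicon],
    ori_window: int = 1000,
    normalize: bool = True,
    by_construct: bool = False,
) -> pd.DataFrame:
    """Welch tests of mean coverage, input vs IP, per replicon and pooled.

    For every replicon two scopes are tested: the whole replicon, and the
    positions within *ori_window* circular bp of ori (replication is
    bidirectional, so the window covers both arms).  Genome-pooled rows
    (``replicon == "genome"``) aggregate across replicons.  With *normalize*
    each library's coverage is scaled to genome-wide mean 1, removing
    sequencing-depth differences so only the spatial distribution is compared
    (the whole-genome pooled test is then p = 1 by construction).
    """
    keys = sorted(tracks)
    inputs = [k for k in keys if k.fraction == "input"]
    ips = [k for k in keys if k.fraction == "IP"]
    if len(inputs) < 2 or len(ips) < 2:
        raise ValueError("need at least 2 input and 2 IP libraries")
    genome_len = sum(r.length for r in replicons.values())

    scale = {}
    for k in keys:
        total = float(sum(t.values.sum() for t in tracks[k].values()))
        if total == 0:
            raise ValueError(f"library {k.name} has zero coverage")
        scale[k] = total / genome_len if normalize else 1.0

    def lib_mean(k: LibraryKey, rep: str, region: tuple[int, int] | None) -> float:
        return mean_coverage(tracks[k][rep], region) / scale[k]

    groupings: list[tuple[str, list[LibraryKey], list[LibraryKey]]]
    if by_construct:
        groupings = []
        for c in sorted({k.construct for k in keys}):
            groupings.append(
                (
                    c,
                    [k for k in inputs if k.construct == c],
                    [k for k in ips if k.construct == c],
                )
            )
    else:
        groupings = [("all", inputs, ips)]

    rows = []
    for label, grp_in, grp_ip in groupings:
        if len(grp_in) < 2 or len(grp_ip) < 2:
            raise ValueError("fewer than 2 samples per group")
        scopes: list[tuple[str, str, tuple[int, int] | None]] = []
        for rep in replicons.values():
            scopes.append((rep.name, "whole", None))
            scopes.append((rep.name, "ori_window", ori_window_region(rep, ori_window)))
        for rep_name, scope, region in scopes:
            a = [lib_mean(k, rep_name, region) for k in grp_in]
            b = [lib_mean(k, rep_name, region) for k in grp_ip]
            t, df, p = welch_t_test(np.array(a), np.array(b))
            rows.append((label, rep_name, scope, len(a), len(b), t, df, p))
        # genome-pooled scopes: length-weighted across replicons
        weights = np.array([r.length for r in replicons.values()], dtype=float)
        win_w = np.array(
            [
                ori_window_region(r, ori_window)[1] - ori_window_region(r, ori_window)[0]
                for r in replicons.values()
            ],
            dtype=float,
        )
        for scope, w in (("whole", weights), ("ori_window", win_w)):
            def pooled(k: LibraryKey) -> float:
                means = [
                    lib_mean(
                        k,
                        r.name,
                        None if scope == "whole" else ori_window_region(r, ori_window),
                    )
                    for r in replicons.values()
                ]
                return float(np.average(means, weights=w))

            a = [pooled(k) for k in grp_in]
            b = [pooled(k) for k in grp_ip]
            t, df, p = welch_t_test(np.array(a), np.array(b))
            rows.append((label, "genome", scope, len(a), len(b), t, df, p))

    return pd.DataFrame(
        rows,
        columns=["group", "replicon", "scope", "n_input", "n_ip", "t", "df", "p"],
    )
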