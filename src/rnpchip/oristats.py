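"""Origin-distance statistics, GC skew and cumulative-skew ori/ter location.

On a circular replicon with a bidirectional origin, a peak position that is
uniform on the circle has a circular distance to ori that is uniform on
``[0, L/2]``; normalising by ``L/2`` gives an exactly Uniform(0,1) null, so
visual "clustering around ori" becomes a one-sample KS test (plus a binomial
test of the fraction of peaks within a near-ori quantile).

GC skew per window is ``(G - C) / (G + C)``.  Because leading and lagging
strands mutate asymmetrically, the skew sign flips at ori and ter; the
running (cumulative) skew therefore attains its minimum at ori and maximum
at ter.  Skew values are mean-centred before cumulating so the circular walk
closes and the extrema do not drift with overall base composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_SKEW_WINDOW = 10_000  # bp; resolves ori/ter against per-window noise


def circular_distance(p, o, length):
    """Shorter-arc distance between positions on a circle of given length."""
    d = np.abs(np.asarray(p) - np.asarray(o))
    out = np.minimum(d, length - d)
    return out if out.ndim else out.item()


def normalized_ori_distances(positions, ori: int, length: int) -> np.ndarray:
    """Map positions to u = d(p, ori) / (L/2) in [0, 1]; uniform under no bias."""
    d = circular_distance(np.asarray(positions), ori, length)
    return np.asarray(d) / (length / 2)


@dataclass
class UniformityTestResult:
    n: int
    ks_stat: float
    ks_p: float
    frac_within: float
    binom_p: float
    tau: float


def ori_uniformity_test(u, tau: float = 0.1) -> UniformityTestResult:
    """KS test of u against Uniform(0,1) plus a binomial near-ori excess test.

    The binomial component tests ``#{u <= tau}`` against ``Binomial(n, tau)``
    (two-sided).  Refuses fewer than 5 observations.
    """
    u = np.asarray(u, dtype=float)
    if len(u) < 5:
        raise ValueError(f"need at least 5 distances, got {len(u)}")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("normalized distances must lie in [0, 1]")
    ks = stats.kstest(u, "uniform")
    k = int(np.sum(u <= tau))
    binom = stats.binomtest(k, len(u), tau, alternative="two-sided")
    return UniformityTestResult(
        n=len(u),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        frac_within=k / len(u),
        binom_p=float(binom.pvalue),
        tau=tau,
    )


@dataclass
class SkewTrack:
    replicon: str
    window: int
    starts: np.ndarray  # window start coordinates
    skew: np.ndarray  # (G - C) / (G + C) per window; 0 where G + C == 0
    cumulative: np.ndarray  # exclusive prefix sum of mean-centred skew


def gc_skew(sequence: str, window: int, replicon: str = "") -> SkewTrack:
    """Per-window GC skew over tiling windows (last window may be partial)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if not sequence:
        raise ValueError("empty sequence")
    if len(sequence) < window:
        raise ValueError("sequence shorter than one window")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    starts = np.arange(0, len(arr), window)
    g = np.add.reduceat((arr == ord("G")).astype(np.int64), starts)
    c = np.add.reduceat((arr == ord("C")).astype(np.int64), starts)
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    centred = skew - skew.mean()
    cumulative = np.concatenate([[0.0], np.cumsum(centred)])[:-1]
    return SkewTrack(
        replicon=replicon, window=window, starts=starts, skew=skew,
        cumulative=cumulative,
    )


def locate_ori_ter(track: SkewTrack) -> tuple[int | None, int | None]:
    """Ori/ter estimates from the cumulative-skew extrema.

    The exclusive-prefix cumulative walk descends across the ter->ori arc
    (negative skew) and ascends across ori->ter, so its minimum marks ori and
    its maximum marks ter, each reported as a window-start coordinate.
    Returns ``(None, None)`` when the skew carries no signal (constant).
    """
    if np.ptp(track.skew) == 0:
        return None, None
    ori = int(track.starts[int(np.argmin(track.cumulative))])
    ter = int(track.starts[int(np.argmax(track.cumulative))])
    return ori, ter
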