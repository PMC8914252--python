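"""Poisson background model, BH correction and peak assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from rnpchip.coverage import CoverageTrack
from rnpchip.genome import Replicon
from rnpchip.peakcall import (
    PeakCallerConfig,
    bh_qvalues,
    call_peaks,
    estimate_lambda,
    poisson_pvalue,
)


class TestPoissonPvalue:
    def test_zero_count_gives_one(self):
        assert poisson_pvalue(0, 3.7) == 1.0

    def test_matches_direct_series_summation(self):
        lam, count = 2.0, 10
        expected = 1.0 - sum(
            math.exp(-lam) * lam**k / math.factorial(k) for k in range(count)
        )
        assert poisson_pvalue(count, lam) == pytest.approx(expected, rel=1e-12)

    def test_tail_monotonicity(self):
        lam = 5.0
        ps = [poisson_pvalue(c, lam) for c in range(0, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            poisson_pvalue(1, 0.0)


class TestBH:
    def test_hand_evaluated_step_up(self):
        q = bh_qvalues([0.001, 0.01, 0.02, 0.04])
        assert q == pytest.approx([0.004, 0.02, 0.08 / 3, 0.04])

    def test_equal_ps_unchanged(self):
        assert bh_qvalues([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_single_p_identity(self):
        assert bh_qvalues([0.17]) == pytest.approx([0.17])

    def test_returns_input_order(self):
        p = [0.04, 0.001, 0.02, 0.01]
        q = bh_qvalues(p)
        assert q == pytest.approx([0.04, 0.004, 0.08 / 3, 0.02])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestEstimateLambda:
    def test_flat_input_gives_background_rate(self):
        cfg = PeakCallerConfig(local_windows=(1000, 5000))
        track = CoverageTrack("chr", np.full(20_000, 6.0))
        lam = estimate_lambda(track, 4321, cfg, depth_ratio=2.0)
        # flat coverage: every window mean equals the genome-wide rate
        expected = 2.0 * 6.0 * cfg.bin_width / cfg.extension
        assert lam == pytest.approx(expected)

    def test_local_spike_dominates_background(self):
        cfg = PeakCallerConfig(local_windows=(1000,))
        vals = np.full(20_000, 2.0)
        vals[5000:5500] = 40.0
        track = CoverageTrack("chr", vals)
        lam_spike = estimate_lambda(track, 5250, cfg, depth_ratio=1.0)
        lam_bg = estimate_lambda(track, 15_000, cfg, depth_ratio=1.0)
        assert lam_spike > 3 * lam_bg

    def test_matches_bruteforce_recomputation_on_random_tracks(self):
        rng = np.random.default_rng(7)
        cfg = PeakCallerConfig(local_windows=(500, 2000))
        L = 10_000
        vals = rng.integers(0, 30, L).astype(float)
        track = CoverageTrack("chr", vals)
        depth_ratio = 3.5
        n_frag = vals.sum() / cfg.extension
        for center in rng.integers(0, L, 20):
            spans = []
            for span in cfg.local_windows:
                idx = np.arange(center - span // 2, center - span // 2 + span) % L
                spans.append(vals[idx].mean())
            bg = n_frag * cfg.extension / L
            expected = (
                depth_ratio * max([bg] + spans) * cfg.bin_width / cfg.extension
            )
            got = estimate_lambda(track, int(center), cfg, depth_ratio)
            assert got == pytest.approx(expected, rel=1e-9)


def _uniform_reads(rng, L, n, name="chr"):
    start = rng.integers(0, L, n)
    return pd.DataFrame(
        {
            "replicon": name,
            "start": start,
            "end": start + 75,
            "strand": rng.choice(["+", "-"], n),
        }
    )


class TestCallPeaks:
    def test_self_comparison_yields_no_peaks(self):
        rng = np.random.default_rng(0)
        rep = Replicon("chr", 50_000, 0, 25_000)
        reads = _uniform_reads(rng, 50_000, 5000)
        peaks = call_peaks(reads, reads.copy(), {"chr": rep})
        assert peaks == []

    def test_planted_spike_recovered_with_valid_peak_invariants(self):
        rng = np.random.default_rng(1)
        L = 50_000
        rep = Replicon("chr", L, 0, 25_000)
        inp = _uniform_reads(rng, L, 5000)
        ip = _uniform_reads(rng, L, 5000)
        spike_start = rng.integers(20_000, 20_400, 600)
        spike = pd.DataFrame(
            {
                "replicon": "chr",
                "start": spike_start,
                "end": spike_start + 75,
                "strand": rng.choice(["+", "-"], 600),
            }
        )
        cfg = PeakCallerConfig()
        peaks = call_peaks(pd.concat([ip, spike]), inp, {"chr": rep}, cfg)
        assert len(peaks) == 1
        (pk,) = peaks
        assert pk.start <= 20_400 and pk.end >= 20_100
        assert pk.q_value <= cfg.q_threshold
        assert pk.length >= cfg.min_peak_len
        assert pk.start <= pk.summit < pk.end
        assert pk.fold_enrichment > 2

    def test_peaks_are_disjoint_and_all_significant(self, small_dataset):
        genome, reads = small_dataset
        ip = pd.concat(
            [df for k, df in reads.items()
             if k.construct == "pKG4_FlagIEP" and k.fraction == "IP"],
            ignore_index=True,
        )
        inp = pd.concat(
            [df for k, df in reads.items()
             if k.construct == "pKG4_FlagIEP" and k.fraction == "input"],
            ignore_index=True,
        )
        cfg = PeakCallerConfig()
        peaks = call_peaks(ip, inp, genome.replicons, cfg)
        assert len(peaks) > 0
        for pk in peaks:
            assert pk.q_value <= cfg.q_threshold
            assert pk.length >= cfg.min_peak_len
        by_rep: dict[str, list] = {}
        for pk in peaks:
            by_rep.setdefault(pk.replicon, []).append(pk)
        for name, group in by_rep.items():
            L = genome.replicons[name].length
            covered = np.zeros(L, dtype=int)
            for pk in group:
                for s, e in pk.segments(L):
                    covered[s:e] += 1
            assert covered.max() <= 1  # disjoint after merging

    def test_joint_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        L, k = 20_000, 4_000
        rep = Replicon("chr", L, 0, 10_000)
        inp = _uniform_reads(rng, L, 3000)
        spike_start = rng.integers(6_000, 6_300, 400)
        ip = pd.concat(
            [
                _uniform_reads(rng, L, 3000),
                pd.DataFrame(
                    {
                        "replicon": "chr",
                        "start": spike_start,
                        "end": spike_start + 75,
                        "strand": rng.choice(["+", "-"], 400),
                    }
                ),
            ]
        )

        def rotate(df):
            start = (df["start"] + k) % L
            return df.assign(start=start, end=start + 75)

        p1 = call_peaks(ip, inp, {"chr": rep})
        p2 = call_peaks(rotate(ip), rotate(inp), {"chr": rep})
        assert [(pk.start + k) % L for pk in p1] == [pk.start % L for pk in p2]
        assert [pk.length for pk in p1] == [pk.length for pk in p2]

    def test_empty_ip_rejected(self):
        rep = Replicon("chr", 1000, 0, 500)
        empty = pd.DataFrame(columns=["replicon", "start", "end", "strand"])
        with pytest.raises(ValueError):
            call_peaks(empty, empty, {"chr": rep})

    def test_unregistered_replicon_rejected(self):
        rng = np.random.default_rng(0)
        rep = Replicon("chr", 1000, 0, 500)
        reads = _uniform_reads(rng, 1000, 50, name="other")
        with pytest.raises(ValueError, match="unregistered"):
            call_peaks(reads, reads, {"chr": rep})
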