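"""End-to-end orchestration: simulate -> pileup -> call -> subtract ->
annotate -> origin statistics -> site scan -> coverage test -> report.

One seeded, configured run writes a complete result bundle; identical config
and seed give byte-identical outputs.  Every output table carries the seed
and a hash of the full configuration in its header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import coverage as cov
from . import oristats, setops, sitescan
from .genome import (
    GeneAnnotation,
    LibraryKey,
    Replicon,
    read_fasta,
    read_gff3,
    read_replicon_table,
    read_reads_bed,
    write_bed,
    write_fasta,
    write_gff3,
    write_replicon_table,
    write_reads_bed,
)
from .peakcall import Peak, PeakCallerConfig, call_peaks, peaks_to_frame
from .simulate import SyntheticConfig, RepliconSpec, generate_dataset

log = logging.getLogger("rnpchip")


@dataclass
class RealInputPaths:
    genome_fasta: str
    gff3: str
    replicon_table: str
    reads_dir: str  # one <library name>.bed per LibraryKey


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    real: RealInputPaths | None = None
    caller: PeakCallerConfig = field(default_factory=PeakCallerConfig)
    ori_window: int = 1000
    skew_window: int = oristats.DEFAULT_SKEW_WINDOW
    tau: float = 0.1
    read_length: int = 75
    outdir: str = "rnpchip_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.real is None):
            raise ValueError("exactly one of synthetic/real inputs must be set")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location and log level
        do not change results and are excluded)."""
        params = dataclasses.asdict(self)
        params.pop("outdir", None)
        params.pop("log_level", None)
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in raw:
        syn = dict(raw["synthetic"] or {})
        if "replicon_specs" in syn:
            syn["replicon_specs"] = tuple(
                RepliconSpec(**spec) for spec in syn["replicon_specs"]
            )
        kwargs["synthetic"] = SyntheticConfig(**syn)
    if "real" in raw:
        kwargs["synthetic"] = None
        kwargs["real"] = RealInputPaths(**raw["real"])
    if "caller" in raw:
        caller = dict(raw["caller"] or {})
        if "local_windows" in caller:
            caller["local_windows"] = tuple(caller["local_windows"])
        kwargs["caller"] = PeakCallerConfig(**caller)
    for key in ("ori_window", "skew_window", "tau", "read_length", "outdir",
                "seed", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "seed" in raw and "synthetic" in kwargs and kwargs["synthetic"] is not None:
        kwargs["synthetic"] = dataclasses.replace(
            kwargs["synthetic"], seed=int(raw["seed"])
        )
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    replicons: dict[str, Replicon]
    genes: list[GeneAnnotation]
    peaks_by_construct: dict[str, list[Peak]]
    unique_peaks: list[Peak]
    annotated: pd.DataFrame
    category_summary: pd.DataFrame
    fork_summary: pd.DataFrame
    ori_stats: pd.DataFrame
    skew_estimates: pd.DataFrame
    site_report: sitescan.SiteOccupancyReport | None
    coverage_report: pd.DataFrame
    metrics: dict
    outdir: Path


def _header(cfg: PipelineConfig) -> str:
    return f"rnpchip seed={cfg.seed} config={cfg.config_hash()}"


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_bedgraph(
    path: Path, cfg: PipelineConfig, chrom: str, starts, ends, values
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def _overlap_hits(
    called: Sequence[Peak], truth: pd.DataFrame, lengths: Mapping[str, int]
) -> tuple[int, int]:
    """(#truth rows hit, #called peaks hitting truth), >= 1 bp overlap."""
    truth_peaks = [
        Peak(r["replicon"], int(r["start"]), int(r["end"]), 0, 0.0, 1.0, 1.0)
        for _, r in truth.iterrows()
    ]
    truth_hit = len(truth_peaks) - len(
        setops.subtract_overlapping(truth_peaks, called, lengths)
    )
    called_hit = len(called) - len(
        setops.subtract_overlapping(list(called), truth_peaks, lengths)
    )
    return truth_hit, called_hit


def recall_precision(
    called: Sequence[Peak], truth: pd.DataFrame, lengths: Mapping[str, int]
) -> tuple[float, float]:
    """Planted-truth recovery: overlap of >= 1 bp counts as a hit."""
    if len(truth) == 0 or len(called) == 0:
        return 0.0, 0.0
    truth_hit, called_hit = _overlap_hits(called, truth, lengths)
    return truth_hit / len(truth), called_hit / len(called)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths_of = lambda reps: {n: r.length for n, r in reps.items()}

    # ---- stage: inputs -----------------------------------------------------
    truth = None
    sequences: dict[str, str] = {}
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        genome, reads = generate_dataset(syn)
        replicons, genes, truth = genome.replicons, genome.genes, genome.truth
        sequences = genome.sequences
        log.info("simulated %d replicons, %d genes, %d planted peaks",
                 len(replicons), len(genes), len(truth.peaks))
        write_fasta(outdir / "genome.fa", sequences)
        write_gff3(outdir / "genes.gff3", genes, lengths_of(replicons))
        write_replicon_table(outdir / "replicons.tsv", replicons)
        for key, df in reads.items():
            write_reads_bed(outdir / f"{key.name}.bed", df, lengths_of(replicons))
        _write_table(truth.peaks, outdir / "truth_peaks.tsv", cfg)
        _write_table(truth.decoys, outdir / "truth_decoys.tsv", cfg)
        _write_table(truth.is_copies, outdir / "truth_is_copies.tsv", cfg)
        read_length = syn.read_length
    else:
        sequences = read_fasta(cfg.real.genome_fasta)
        replicons = read_replicon_table(cfg.real.replicon_table)
        replicons = {
            n: r.with_sequence(sequences[n]) if n in sequences else r
            for n, r in replicons.items()
        }
        genes = read_gff3(cfg.real.gff3)
        reads = {}
        for key in LibraryKey.all_keys():
            path = Path(cfg.real.reads_dir) / f"{key.name}.bed"
            if path.exists():
                reads[key] = read_reads_bed(path, lengths_of(replicons))
        if not reads:
            raise RuntimeError("stage inputs: no read libraries found")
        read_length = cfg.read_length

    lengths = lengths_of(replicons)
    constructs = sorted({k.construct for k in reads})

    # ---- stage: peak calling (pooled replicates per construct) -------------
    peaks_by_construct: dict[str, list[Peak]] = {}
    for construct in constructs:
        ip = pd.concat(
            [df for k, df in reads.items()
             if k.construct == construct and k.fraction == "IP"],
            ignore_index=True,
        )
        inp = pd.concat(
            [df for k, df in reads.items()
             if k.construct == construct and k.fraction == "input"],
            ignore_index=True,
        )
        peaks = call_peaks(ip, inp, replicons, cfg.caller)
        peaks_by_construct[construct] = peaks
        log.info("peak calling: %s -> %d peaks", construct, len(peaks))
        write_bed(outdir / f"peaks_{construct}.bed", peaks_to_frame(peaks),
                  header=_header(cfg))

    # ---- stage: unique-peak subtraction ------------------------------------
    uniq = setops.unique_peaks(
        peaks_by_construct.get("pKG4_FlagIEP", []),
        peaks_by_construct.get("pKG_FlagIEP", []),
        peaks_by_construct.get("pKGEMA4", []),
        lengths,
    )
    log.info("subtraction filter: %d -> %d unique peaks",
             len(peaks_by_construct.get("pKG4_FlagIEP", [])), len(uniq))
    write_bed(outdir / "unique_peaks.bed", peaks_to_frame(uniq), header=_header(cfg))

    # ---- stage: annotation -------------------------------------------------
    annotated = ann.annotate_peaks(uniq, genes, replicons)
    cat_summary, fork_summary = ann.summarize_by_replicon(annotated)
    _write_table(annotated, outdir / "annotated_peaks.tsv", cfg)
    _write_table(cat_summary, outdir / "summary_context.tsv", cfg)
    _write_table(fork_summary, outdir / "summary_fork.tsv", cfg)

    # ---- stage: origin-distance statistics ---------------------------------
    ori_rows = []
    for name, rep in replicons.items():
        sub = annotated[annotated["replicon"] == name]
        mids = ((sub["start"] + (sub["end"] - sub["start"]) // 2) % rep.length
                ).to_numpy()
        row: dict = {"replicon": name, "n": len(mids)}
        if len(mids) >= 5:
            u = oristats.normalized_ori_distances(mids, rep.ori, rep.length)
            res = oristats.ori_uniformity_test(u, tau=cfg.tau)
            row.update(
                ks_stat=res.ks_stat, ks_p=res.ks_p,
                frac_within=res.frac_within, binom_p=res.binom_p,
            )
        else:
            row.update(ks_stat=np.nan, ks_p=np.nan, frac_within=np.nan,
                       binom_p=np.nan)
        ori_rows.append(row)
    ori_stats = pd.DataFrame(ori_rows)
    _write_table(ori_stats, outdir / "ori_distance_stats.tsv", cfg)

    # ---- stage: GC skew + CIRCOS-ready tracks ------------------------------
    skew_rows = []
    for name, rep in replicons.items():
        if rep.sequence is None:
            continue
        track = oristats.gc_skew(rep.sequence, cfg.skew_window, replicon=name)
        ends = np.minimum(track.starts + cfg.skew_window, rep.length)
        _write_bedgraph(outdir / f"skew_{name}.bedgraph", cfg, name,
                        track.starts, ends, track.skew)
        ori_est, ter_est = oristats.locate_ori_ter(track)
        skew_rows.append(
            {"replicon": name, "ori_estimate": ori_est, "ter_estimate": ter_est,
             "planted_ori": rep.ori, "planted_ter": rep.ter,
             "window": cfg.skew_window}
        )
    skew_estimates = pd.DataFrame(skew_rows)
    if len(skew_estimates):
        _write_table(skew_estimates, outdir / "skew_ori_ter.tsv", cfg)
    _write_circos_tracks(outdir, cfg, replicons, genes, uniq, truth)

    # ---- stage: site-occupancy scan ----------------------------------------
    site_report = None
    if sequences:
        scan = sitescan.scan_placements(sequences, reads, read_length)
        site_report = sitescan.compare_site_occupancy(scan)
        _write_table(scan, outdir / "site_scan.tsv", cfg)
        _write_table(site_report.ratios, outdir / "site_ratios.tsv", cfg)
        _write_table(site_report.tests, outdir / "site_tests.tsv", cfg)

    # ---- stage: input-vs-IP coverage comparison ----------------------------
    tracks: dict[LibraryKey, dict[str, cov.CoverageTrack]] = {}
    for key, df in reads.items():
        tracks[key] = {
            name: cov.pileup(df, rep, cfg.caller.extension)
            for name, rep in replicons.items()
        }
    coverage_report = cov.compare_input_vs_ip(
        tracks, replicons, ori_window=cfg.ori_window
    )
    _write_table(coverage_report, outdir / "coverage_test.tsv", cfg)

    # ---- stage: run summary ------------------------------------------------
    metrics: dict = {
        "n_peaks": {c: len(p) for c, p in peaks_by_construct.items()},
        "n_unique_peaks": len(uniq),
    }
    if truth is not None:
        rec, prec = recall_precision(uniq, truth.peaks, lengths)
        metrics["unique_peak_recall"] = rec
        metrics["unique_peak_precision"] = prec
    if site_report is not None:
        metrics["depletion_detected"] = site_report.depletion_detected
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "parameters": dataclasses.asdict(cfg),
        "metrics": metrics,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)

    return PipelineResult(
        replicons=replicons,
        genes=genes,
        peaks_by_construct=peaks_by_construct,
        unique_peaks=uniq,
        annotated=annotated,
        category_summary=cat_summary,
        fork_summary=fork_summary,
        ori_stats=ori_stats,
        skew_estimates=skew_estimates,
        site_report=site_report,
        coverage_report=coverage_report,
        metrics=metrics,
        outdir=outdir,
    )


def _write_circos_tracks(
    outdir: Path,
    cfg: PipelineConfig,
    replicons: Mapping[str, Replicon],
    genes: Sequence[GeneAnnotation],
    uniq: Sequence[Peak],
    truth,
) -> None:
    """Plain-text track files (chrom start end value): genes +/- strand,
    unique peaks, IS copies -- ready for an external CIRCOS render."""
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for strand, label in (("+", "genes_fwd"), ("-", "genes_rev")):
        rows = [(g.replicon, g.start, g.end, 1) for g in genes if g.strand == strand]
        _write_track(trackdir / f"{label}.txt", rows)
    lengths = {n: r.length for n, r in replicons.items()}
    peak_rows = []
    for pk in uniq:
        for s, e in pk.segments(lengths[pk.replicon]):
            peak_rows.append((pk.replicon, s, e, round(pk.fold_enrichment, 3)))
    _write_track(trackdir / "unique_peaks.txt", peak_rows)
    if truth is not None:
        is_rows = [
            (r["replicon"], int(r["site_start"]), int(r["site_end"]), 1)
            for _, r in truth.is_copies.iterrows()
        ]
        _write_track(trackdir / "is_copies.txt", is_rows)


def _write_track(path: Path, rows) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
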