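"""Synthetic tripartite genome and ChIP library generator with planted truth.

Emulates the statistical structure the downstream analysis assumes, at 1/10
of the real genome scale so the whole pipeline runs in seconds: three
circular replicons of very different sizes (chromosome 365 kb, megaplasmid
147 kb, chromid 161 kb), non-overlapping genes on both strands, a GC-skew
sign change at the planted ori/ter of every replicon, 13 planted IS-element
cassettes carrying the printed insertion-site 25-mer with its upstream and
downstream flanking 25-mers at -50/+50, uniform input libraries, IP
libraries whose enrichment peaks sit at circular distances from ori drawn
from an exponential decay and inside genes whose strand matches the local
lagging-strand template with probability ``p_lag``, disjoint decoy peak sets
for the two control constructs (so the unique-peak subtraction has an exact
planted answer), and optional read depletion at the insertion-site locus in
the IP libraries of active-RNP constructs (emulating retrohoming).

Not emulated: sequencing errors, PCR duplicates, paired ends, mappability
or GC bias of coverage.  All randomness flows from one explicitly seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import fork_direction, lagging_template_strand
from .genome import CONSTRUCTS, GeneAnnotation, LibraryKey, Replicon
from .sitescan import DOWNSTREAM_50, INSERTION_SITE, UPSTREAM_50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepliconSpec:
    name: str
    length: int
    ori: int
    ter: int
    gene_density: float = 0.85
    mean_gene_length: int = 800

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        if not 0 < self.gene_density < 1:
            raise ValueError("gene density must be in (0, 1)")


def default_replicon_specs() -> tuple[RepliconSpec, ...]:
    """Three replicons at 1/10 real scale, ori/ter roughly antipodal."""
    return (
        RepliconSpec("chromosome", 365_000, ori=10_000, ter=192_500),
        RepliconSpec("pSymA", 147_000, ori=5_000, ter=78_500),
        RepliconSpec("pSymB", 161_000, ori=7_000, ter=87_500),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    replicon_specs: tuple[RepliconSpec, ...] = field(
        default_factory=default_replicon_specs
    )
    n_is_copies: int = 13
    n_true_peaks: int = 300
    n_decoy_peaks: int = 40  # per control construct (~1/10 of real-scale counts)
    peak_enrichment: float = 8.0
    ori_decay_scale: int = 30_000  # bp; exponential scale of peak distance to ori
    p_lag: float = 0.70
    depth_input: float = 10.0
    depth_ip: float = 50.0
    read_length: int = 75
    fragment_length: int = 300
    deplete_insertion_site: float = 0.5  # fraction removed; 0 disables
    gc_content: float = 0.62
    gc_skew_amplitude: float = 0.05
    #: clearance between planted true peaks and decoy/IS intervals, so called
    #: peak boundaries (which smear by ~ fragment length) never cross sets
    min_interval_separation: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_lag <= 1:
            raise ValueError("p_lag must be in [0, 1]")
        if not 0 <= self.deplete_insertion_site <= 1:
            raise ValueError("depletion fraction must be in [0, 1]")
        if self.peak_enrichment < 1:
            raise ValueError("peak_enrichment must be >= 1")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.depth_input <= 0 or self.depth_ip <= 0:
            raise ValueError("depths must be positive")


@dataclass
class TruthTable:
    """Planted ground truth for the whole dataset."""

    peaks: pd.DataFrame  # replicon,start,end,gene_id,gene_strand,fork_label,enrichment
    decoys: pd.DataFrame  # construct,replicon,start,end
    is_copies: pd.DataFrame  # replicon,cassette_start,site_start,site_end
    origins: pd.DataFrame  # replicon,length,ori,ter


@dataclass
class SyntheticGenome:
    replicons: dict[str, Replicon]
    genes: list[GeneAnnotation]
    truth: TruthTable
    config: SyntheticConfig

    @property
    def sequences(self) -> dict[str, str]:
        return {
            name: rep.sequence
            for name, rep in self.replicons.items()
            if rep.sequence is not None
        }


def _rng_children(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    genome_ss, reads_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(genome_ss), np.random.default_rng(reads_ss)


def _skewed_sequence(spec: RepliconSpec, cfg: SyntheticConfig, rng) -> str:
    """Random sequence with skew +s on the ori->ter clockwise arm, -s opposite."""
    gc, s = cfg.gc_content, cfg.gc_skew_amplitude
    at = (1 - gc) / 2
    p_cw = [at, gc / 2 * (1 - s), gc / 2 * (1 + s), at]  # A, C, G, T
    p_ccw = [at, gc / 2 * (1 + s), gc / 2 * (1 - s), at]
    L = spec.length
    cw_len = (spec.ter - spec.ori) % L
    arm_cw = rng.choice(4, size=cw_len, p=p_cw)
    arm_ccw = rng.choice(4, size=L - cw_len, p=p_ccw)
    codes = np.empty(L, dtype=np.int64)
    cw_idx = (spec.ori + np.arange(cw_len)) % L
    ccw_idx = (spec.ter + np.arange(L - cw_len)) % L
    codes[cw_idx] = arm_cw
    codes[ccw_idx] = arm_ccw
    return _BASES[codes].tobytes().decode("ascii")


def _place_genes(spec: RepliconSpec, rng) -> list[dict]:
    """Non-overlapping genes on both strands; none crosses the seam."""
    mean_gap = max(
        20, int(spec.mean_gene_length * (1 - spec.gene_density) / spec.gene_density)
    )
    genes: list[dict] = []
    pos = int(rng.exponential(mean_gap)) + 1
    i = 0
    while True:
        glen = int(
            np.clip(
                rng.normal(spec.mean_gene_length, spec.mean_gene_length / 4),
                150,
                3 * spec.mean_gene_length,
            )
        )
        if pos + glen >= spec.length:
            break
        genes.append(
            {
                "start": pos,
                "end": pos + glen,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_id": f"{spec.name}_g{i:05d}",
            }
        )
        i += 1
        pos += glen + int(rng.exponential(mean_gap)) + 1
    if not genes:
        raise ValueError("requested gene mass exceeds replicon length")
    return genes


def _is_clear(start: int, end: int, taken: list[tuple[int, int]], margin: int) -> bool:
    """True if [start, end) is at least *margin* bp from every taken interval."""
    return all(end + margin <= s or e + margin <= start for s, e in taken)


def _apportion(total: int, weights: Sequence[float], rng) -> list[int]:
    """Largest-remainder apportionment of *total* by *weights*."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for j in range(rem):
        base[order[j]] += 1
    return base.tolist()


def generate_genome(
    cfg: SyntheticConfig,
    with_sequence: bool = True,
    rng: np.random.Generator | None = None,
) -> SyntheticGenome:
    """Generate replicons, genes, planted peaks/decoys/IS copies and truth."""
    if rng is None:
        rng = _rng_children(cfg.seed)[0]
    replicons: dict[str, Replicon] = {}
    genes_by_rep: dict[str, list[dict]] = {}
    for spec in cfg.replicon_specs:
        replicons[spec.name] = Replicon(
            spec.name, spec.length, ori=spec.ori % spec.length,
            ter=spec.ter % spec.length,
        )
        genes_by_rep[spec.name] = _place_genes(spec, rng)

    lengths = [s.length for s in cfg.replicon_specs]
    peak_counts = _apportion(cfg.n_true_peaks, lengths, rng)

    peak_rows: list[dict] = []
    taken_by_rep: dict[str, list[tuple[int, int]]] = {s.name: [] for s in cfg.replicon_specs}
    for spec, n_peaks in zip(cfg.replicon_specs, peak_counts):
        rep = replicons[spec.name]
        genes = genes_by_rep[spec.name]
        starts = np.array([g["start"] for g in genes])
        occupied: set[int] = set()
        taken = taken_by_rep[spec.name]
        margin = cfg.min_interval_separation
        L = spec.length
        # true peaks live in distinct host genes, which already separates
        # them; the clearance margin is enforced against decoys/IS later

        def usable(gi: int) -> bool:
            if gi < 0 or gi >= len(genes) or gi in occupied:
                return False
            g = genes[gi]
            if g["end"] - g["start"] < 260:
                return False
            for landmark in (rep.ori, rep.ter):  # keep fork call determinate
                if g["start"] - margin <= landmark < g["end"] + margin:
                    return False
            return True

        for _ in range(n_peaks):
            gi_sel = None
            for _attempt in range(400):
                d = rng.exponential(cfg.ori_decay_scale)
                if d >= L / 2 - 1000:
                    continue
                arm = 1 if rng.random() < 0.5 else -1
                pos = int(rep.ori + arm * d) % L
                gi = int(np.searchsorted(starts, pos, "right")) - 1
                if not usable(gi):
                    continue
                g = genes[gi]
                if not (g["start"] <= pos < g["end"]):
                    continue
                gi_sel = gi
                break
            if gi_sel is None:  # dense near-ori gene occupancy: any free gene
                free = [i for i in range(len(genes)) if usable(i)]
                if not free:
                    raise ValueError("not enough genes to host planted peaks")
                gi_sel = int(rng.choice(free))
            g = genes[gi_sel]
            glen = g["end"] - g["start"]
            width = int(min(rng.uniform(200, 500), glen - 40))
            lo = g["start"] + 10
            hi = g["end"] - 10 - width
            start = int(rng.integers(lo, hi + 1))
            end = start + width
            occupied.add(gi_sel)
            taken.append((start, end))
            mid = (start + end) // 2
            direction = fork_direction(mid, rep)
            lag_strand = lagging_template_strand(direction)
            want_lag = rng.random() < cfg.p_lag
            strand = lag_strand if want_lag else ("+" if lag_strand == "-" else "-")
            g["strand"] = strand
            peak_rows.append(
                {
                    "replicon": spec.name,
                    "start": start,
                    "end": end,
                    "gene_id": g["gene_id"],
                    "gene_strand": strand,
                    "fork_label": "LAG" if want_lag else "LEAD",
                    "enrichment": cfg.peak_enrichment,
                }
            )

    # Disjoint decoy peak sets for the two control constructs.
    decoy_rows: list[dict] = []
    for construct in ("pKG_FlagIEP", "pKGEMA4"):
        counts = _apportion(cfg.n_decoy_peaks, lengths, rng)
        for spec, n_dec in zip(cfg.replicon_specs, counts):
            taken = taken_by_rep[spec.name]
            for _ in range(n_dec):
                for _attempt in range(400):
                    width = int(rng.uniform(200, 500))
                    start = int(rng.integers(0, spec.length - width))
                    if _is_clear(start, start + width, taken, cfg.min_interval_separation):
                        taken.append((start, start + width))
                        decoy_rows.append(
                            {
                                "construct": construct,
                                "replicon": spec.name,
                                "start": start,
                                "end": start + width,
                            }
                        )
                        break
                else:
                    raise ValueError("could not place disjoint decoy peaks")

    # IS-element cassettes: upstream 25-mer at -50, site, downstream at +50.
    is_counts = _apportion(cfg.n_is_copies, lengths, rng)
    is_rows: list[dict] = []
    cassette_len = 125
    for spec, n_is in zip(cfg.replicon_specs, is_counts):
        taken = taken_by_rep[spec.name]
        for _ in range(n_is):
            for _attempt in range(400):
                start = int(rng.integers(0, spec.length - cassette_len))
                if _is_clear(start, start + cassette_len, taken, cfg.min_interval_separation):
                    taken.append((start, start + cassette_len))
                    is_rows.append(
                        {
                            "replicon": spec.name,
                            "cassette_start": start,
                            "site_start": start + 50,
                            "site_end": start + 75,
                        }
                    )
                    break
            else:
                raise ValueError("could not place IS cassettes")

    if with_sequence:
        for spec in cfg.replicon_specs:
            seq = _skewed_sequence(spec, cfg, rng)
            arr = bytearray(seq, "ascii")
            for row in is_rows:
                if row["replicon"] != spec.name:
                    continue
                s = row["cassette_start"]
                gap1 = "".join(_BASES[rng.integers(0, 4, 25)].tobytes().decode())
                gap2 = "".join(_BASES[rng.integers(0, 4, 25)].tobytes().decode())
                cassette = (
                    UPSTREAM_50.sequence + gap1 + INSERTION_SITE.sequence
                    + gap2 + DOWNSTREAM_50.sequence
                )
                arr[s : s + cassette_len] = cassette.encode("ascii")
            replicons[spec.name] = replicons[spec.name].with_sequence(
                arr.decode("ascii")
            )

    genes = [
        GeneAnnotation(spec.name, g["start"], g["end"], g["strand"], g["gene_id"])
        for spec in cfg.replicon_specs
        for g in genes_by_rep[spec.name]
    ]
    truth = TruthTable(
        peaks=pd.DataFrame(
            peak_rows,
            columns=[
                "replicon", "start", "end", "gene_id", "gene_strand",
                "fork_label", "enrichment",
            ],
        ),
        decoys=pd.DataFrame(
            decoy_rows, columns=["construct", "replicon", "start", "end"]
        ),
        is_copies=pd.DataFrame(
            is_rows, columns=["replicon", "cassette_start", "site_start", "site_end"]
        ),
        origins=pd.DataFrame(
            [
                {"replicon": s.name, "length": s.length, "ori": s.ori, "ter": s.ter}
                for s in cfg.replicon_specs
            ]
        ),
    )
    return SyntheticGenome(replicons=replicons, genes=genes, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _uniform_fragments(L: int, depth: float, flen: int, rng) -> np.ndarray:
    n = rng.poisson(depth * L / flen)
    return rng.integers(0, L, size=n)


def _reads_from_fragment_starts(
    frag_starts: np.ndarray, L: int, rl: int, flen: int, rng
) -> pd.DataFrame:
    """75-bp single-end reads from fragment 5' ends, random strand.

    A plus read is the fragment's first *rl* bp; a minus read its last *rl*
    bp (5' end at the fragment's right edge).  Extension to *flen* from the
    read 5' end reconstructs the fragment either way.
    """
    minus = rng.random(len(frag_starts)) < 0.5
    start = np.where(minus, frag_starts + flen - rl, frag_starts) % L
    return pd.DataFrame(
        {
            "start": start.astype(np.int64),
            "end": start.astype(np.int64) + rl,
            "strand": np.where(minus, "-", "+"),
        }
    )


def _enriched_fragments(
    intervals: pd.DataFrame, L: int, fold: float, depth: float, flen: int, rng
) -> np.ndarray:
    """Extra fragment starts producing (fold-1) x base coverage over intervals."""
    delta = depth / flen  # background fragment starts per bp
    out = []
    for _, row in intervals.iterrows():
        plen = int(row["end"] - row["start"])
        n = rng.poisson((fold - 1.0) * delta * plen)
        # centre the enriched fragment mass on the interval
        starts = rng.integers(row["start"] - flen // 2, row["end"] - flen // 2, size=n)
        out.append(starts % L)
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _deplete_insertion_sites(
    reads: pd.DataFrame, sites: pd.DataFrame, L: int, rl: int, fraction: float, rng
) -> pd.DataFrame:
    """Drop a fraction of reads overlapping any insertion-site 25-mer."""
    if fraction == 0 or len(sites) == 0 or len(reads) == 0:
        return reads
    starts = reads["start"].to_numpy()
    hit = np.zeros(len(reads), dtype=bool)
    for _, s in sites.iterrows():
        site_start, site_end = int(s["site_start"]), int(s["site_end"])
        width = site_end - site_start  # overlap iff (start - (site_start-rl+1)) mod L < rl+width-1
        rel = (starts - (site_start - rl + 1)) % L
        hit |= rel < (rl + width - 1)
    drop = hit & (rng.random(len(reads)) < fraction)
    return reads[~drop].reset_index(drop=True)


def generate_reads(
    genome: SyntheticGenome,
    cfg: SyntheticConfig | None = None,
    constructs: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[LibraryKey, pd.DataFrame]:
    """Read placements for the (up to) 18 libraries of the ChIP design.

    Input libraries are uniform at ``depth_input``.  IP libraries carry a
    uniform background at ``depth_ip`` plus enriched fragments at the
    construct's own planted intervals: true peaks for the tagged-RNP
    construct, the disjoint decoy sets for the two controls.  Active-RNP IP
    libraries lose a fraction of reads overlapping the insertion-site 25-mer
    when depletion is enabled.
    """
    cfg = cfg or genome.config
    if rng is None:
        rng = _rng_children(cfg.seed)[1]
    constructs = tuple(constructs) if constructs else CONSTRUCTS
    flen, rl = cfg.fragment_length, cfg.read_length
    enriched_intervals = {
        "pKG4_FlagIEP": genome.truth.peaks,
        "pKG_FlagIEP": genome.truth.decoys[
            genome.truth.decoys["construct"] == "pKG_FlagIEP"
        ],
        "pKGEMA4": genome.truth.decoys[
            genome.truth.decoys["construct"] == "pKGEMA4"
        ],
    }
    active_rnp = ("pKG4_FlagIEP", "pKGEMA4")  # constructs with a ribozyme

    out: dict[LibraryKey, pd.DataFrame] = {}
    for construct in constructs:
        for fraction in ("input", "IP"):
            depth = cfg.depth_input if fraction == "input" else cfg.depth_ip
            for replicate in (1, 2, 3):
                frames = []
                for name, rep in genome.replicons.items():
                    L = rep.length
                    frag = _uniform_fragments(L, depth, flen, rng)
                    if fraction == "IP":
                        ivs = enriched_intervals[construct]
                        ivs = ivs[ivs["replicon"] == name]
                        extra = _enriched_fragments(
                            ivs, L, cfg.peak_enrichment, depth, flen, rng
                        )
                        frag = np.concatenate([frag, extra])
                    df = _reads_from_fragment_starts(frag, L, rl, flen, rng)
                    if (
                        fraction == "IP"
                        and construct in active_rnp
                        and cfg.deplete_insertion_site > 0
                    ):
                        sites = genome.truth.is_copies
                        df = _deplete_insertion_sites(
                            df,
                            sites[sites["replicon"] == name],
                            L,
                            rl,
                            cfg.deplete_insertion_site,
                            rng,
                        )
                    df.insert(0, "replicon", name)
                    frames.append(df)
                out[LibraryKey(construct, fraction, replicate)] = pd.concat(
                    frames, ignore_index=True
                )
    return out


def read_sequences(
    sequences: Mapping[str, str], reads: pd.DataFrame, read_length: int
) -> list[str]:
    """Extract (error-free) read sequences; minus reads are reverse-complemented."""
    from .sitescan import reverse_complement

    out = []
    for name, grp in reads.groupby("replicon", sort=False):
        seq = sequences[name]
        ext = seq + seq[:read_length]
        for start, strand in zip(grp["start"], grp["strand"]):
            s = ext[start : start + read_length]
            out.append(s if strand == "+" else reverse_complement(s))
    return out


def generate_dataset(
    cfg: SyntheticConfig, constructs: Sequence[str] | None = None,
    with_sequence: bool = True,
) -> tuple[SyntheticGenome, dict[LibraryKey, pd.DataFrame]]:
    """Genome plus libraries from one seed (genome and reads use split streams)."""
    g_rng, r_rng = _rng_children(cfg.seed)
    genome = generate_genome(cfg, with_sequence=with_sequence, rng=g_rng)
    reads = generate_reads(genome, cfg, constructs=constructs, rng=r_rng)
    return genome, reads
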