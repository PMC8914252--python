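"""Genome, annotation and read-placement I/O for multi-replicon circular genomes.

Coordinate convention: every interval held in memory is 0-based, half-open,
on a single replicon.  GFF3 (1-based, inclusive) is converted at the I/O
boundary; BED is native.  A feature crossing the circular seam is never
stored with coordinates outside ``[0, L)`` on disk: it is split into two BED
records sharing a name.  In-memory read/peak tables may use ``end > L`` as a
compact wrap notation; writers split at the seam.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: The three expression constructs assayed: tagged active RNPs, tagged IEP
#: without the ribozyme, and untagged active RNPs (IP specificity control).
CONSTRUCTS = ("pKG4_FlagIEP", "pKG_FlagIEP", "pKGEMA4")
FRACTIONS = ("input", "IP")
REPLICATES = (1, 2, 3)


@dataclass(frozen=True, order=True)
class LibraryKey:
    """Identity of one sequencing library: construct x fraction x replicate."""

    construct: str
    fraction: str
    replicate: int

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.replicate not in REPLICATES:
            raise ValueError(f"replicate must be in {REPLICATES}")

    @property
    def name(self) -> str:
        return f"{self.construct}_{self.fraction}_rep{self.replicate}"

    @classmethod
    def all_keys(cls) -> list["LibraryKey"]:
        """The full 3 x 2 x 3 = 18-library design."""
        return [
            cls(c, f, r) for c in CONSTRUCTS for f in FRACTIONS for r in REPLICATES
        ]


@dataclass(frozen=True)
class Replicon:
    """One circular DNA molecule with bidirectional replication ori/ter."""

    name: str
    length: int
    ori: int
    ter: int
    topology: str = "circular"
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("replicon length must be positive")
        if not (0 <= self.ori < self.length and 0 <= self.ter < self.length):
            raise ValueError("ori/ter must lie in [0, length)")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        if self.topology != "circular":
            raise ValueError("only circular replicons are supported")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match replicon length")

    def with_sequence(self, sequence: str) -> "Replicon":
        return replace(self, sequence=sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded coding interval (0-based half-open) on a replicon."""

    replicon: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped sequencing read, tagged with its library of origin."""

    replicon: str
    start: int
    end: int
    strand: str
    library: LibraryKey

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``.

    Preserves input order.  Rejects empty records and characters outside
    A/C/G/T/N.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"illegal character(s) {sorted(bad)} in FASTA record {rec.id!r}"
            )
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_STRANDS = {"+": "+", "-": "-", "−": "-"}


def read_gff3(
    path: str | os.PathLike,
    feature_types: Sequence[str] = ("gene", "CDS"),
) -> list[GeneAnnotation]:
    """Parse GFF3 gene/CDS rows into 0-based half-open :class:`GeneAnnotation`.

    GFF3 columns are 1-based inclusive; ``start-1, end`` converts.  Rows whose
    type is not in *feature_types* are skipped.
    """
    genes: list[GeneAnnotation] = []
    wanted = set(feature_types)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            if ftype not in wanted:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in _GFF_STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = f"{seqid}:{lineno}"
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
                if kv.startswith("locus_tag="):
                    gene_id = kv[10:]
            genes.append(
                GeneAnnotation(
                    replicon=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=_GFF_STRANDS[strand],
                    gene_id=gene_id,
                )
            )
    return genes


def write_gff3(
    path: str | os.PathLike,
    genes: Iterable[GeneAnnotation],
    replicon_lengths: Mapping[str, int] | None = None,
    feature_type: str = "gene",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if replicon_lengths:
            for name, length in replicon_lengths.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.replicon}\trnpchip\t{feature_type}\t{g.start + 1}\t{g.end}\t."
                f"\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with up to 6 named columns.

    Coordinates are 0-based half-open (BED native).  ``start >= end`` or
    non-integer coordinates raise a format error naming the line.
    """
    rows: list[list] = []
    ncols = 3

    def _parse(fh) -> None:
        nonlocal ncols
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"BED line {lineno}: start >= end")
            row = [cols[0], start, end] + cols[3:6]
            ncols = max(ncols, len(row))
            rows.append(row)

    if isinstance(path, io.IOBase):
        _parse(path)
    else:
        with open(path) as fh:
            _parse(fh)
    cols = list(BED_COLUMNS[:ncols])
    rows = [r + [None] * (ncols - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=cols)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(
    path: str | os.PathLike,
    df: pd.DataFrame,
    header: str | None = None,
) -> None:
    """Write a BED3-6 DataFrame, preserving row order."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=cols)


def split_wrapped(
    df: pd.DataFrame, lengths: Mapping[str, int], chrom_col: str = "chrom"
) -> pd.DataFrame:
    """Split rows whose ``end`` exceeds the replicon length at the seam.

    The two half-rows share the original ``name`` so the record can be
    re-joined; no stored coordinate leaves ``[0, L]``.
    """
    out = []
    for _, row in df.iterrows():
        L = lengths[row[chrom_col]]
        if row["end"] <= L:
            out.append(row)
        else:
            left = row.copy()
            left["end"] = L
            right = row.copy()
            right["start"] = 0
            right["end"] = row["end"] - L
            out.append(left)
            out.append(right)
    return pd.DataFrame(out).reset_index(drop=True)


def join_wrapped(df: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Inverse of :func:`split_wrapped` for BED frames carrying a name column."""
    if "name" not in df.columns:
        return df.reset_index(drop=True)
    pieces = []
    for (_chrom, _name), grp in df.groupby(["chrom", "name"], sort=False):
        if len(grp) == 2:
            L = lengths[grp.iloc[0]["chrom"]]
            ends_at_seam = grp[grp["end"] == L]
            starts_at_zero = grp[grp["start"] == 0]
            if len(ends_at_seam) == 1 and len(starts_at_zero) == 1:
                row = ends_at_seam.iloc[0].copy()
                row["end"] = L + starts_at_zero.iloc[0]["end"]
                pieces.append(row.to_frame().T)
                continue
        pieces.append(grp)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Replicon registry
# ---------------------------------------------------------------------------


def read_replicon_table(path: str | os.PathLike) -> dict[str, Replicon]:
    """Read the flat replicon config (TSV: name, length, ori, ter)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "length", "ori", "ter"}
    if not required.issubset(df.columns):
        raise ValueError(f"replicon table must have columns {sorted(required)}")
    return {
        str(r["name"]): Replicon(
            name=str(r["name"]), length=int(r["length"]), ori=int(r["ori"]),
            ter=int(r["ter"]),
        )
        for _, r in df.iterrows()
    }


def write_replicon_table(
    path: str | os.PathLike, replicons: Mapping[str, Replicon]
) -> None:
    df = pd.DataFrame(
        [
            {"name": r.name, "length": r.length, "ori": r.ori, "ter": r.ter}
            for r in replicons.values()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read-placement tables
# ---------------------------------------------------------------------------

READ_COLUMNS = ("replicon", "start", "end", "strand")


def reads_frame(records: Iterable[ReadPlacement]) -> pd.DataFrame:
    """Pack :class:`ReadPlacement` records into the internal read table."""
    return pd.DataFrame(
        [(r.replicon, r.start, r.end, r.strand) for r in records],
        columns=list(READ_COLUMNS),
    )


def write_reads_bed(
    path: str | os.PathLike, reads: pd.DataFrame, lengths: Mapping[str, int]
) -> None:
    """Emit one BED6 per library; seam-crossing reads are split (shared name)."""
    df = reads.rename(columns={"replicon": "chrom"}).copy()
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["score"] = 0
    df = df[["chrom", "start", "end", "name", "score", "strand"]]
    L = df["chrom"].map(lengths).to_numpy()
    wraps = df["end"].to_numpy() > L
    if wraps.any():
        left = df[wraps].copy()
        left["end"] = L[wraps]
        right = df[wraps].copy()
        right["end"] = right["end"] - L[wraps]
        right["start"] = 0
        df = pd.concat([df[~wraps], left, right], ignore_index=True)
    write_bed(path, df)


def read_reads_bed(
    path: str | os.PathLike, lengths: Mapping[str, int]
) -> pd.DataFrame:
    df = read_bed(path)
    df = join_wrapped(df, lengths)
    df = df.rename(columns={"chrom": "replicon"})
    return df[["replicon", "start", "end", "strand"]].astype(
        {"start": int, "end": int}
    )
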