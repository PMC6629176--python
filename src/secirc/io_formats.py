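"""Readers/writers for the formats the pipeline touches.

Every genomic coordinate inside the package is BED-native: 0-based,
half-open. One-based inputs do not exist here; nothing converts back and
forth internally. All readers are gzip-transparent (a ``.gz`` suffix or
gzip magic bytes trigger decompression).
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_STRANDS = {"+", "-", "."}
_SEQ_ALPHABET = set("ACGTUN")


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.line = line


@dataclass(frozen=True)
class Interval:
    """A genomic region, 0-based half-open, optionally stranded and scored.

    ``signal`` is a non-negative density (e.g. H3K27ac read density over the
    region); ``None`` when the source file carried no signal column.
    """

    chrom: str
    start: int
    end: int
    id: str = "."
    strand: str = "."
    signal: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.signal is not None and self.signal < 0:
            raise ValueError(f"negative signal {self.signal} on {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SampleDescriptor:
    """Expression-matrix column label, parsed from ``tissue:stage:rep``."""

    tissue: str
    stage: str
    replicate: int

    def __str__(self) -> str:
        return f"{self.tissue}:{self.stage}:{self.replicate}"

    @classmethod
    def parse(cls, text: str) -> "SampleDescriptor":
        parts = text.split(":")
        if len(parts) != 3:
            raise ParseError(f"sample descriptor {text!r} is not 'tissue:stage:rep'")
        try:
            rep = int(parts[2])
        except ValueError as exc:
            raise ParseError(f"replicate index in {text!r} is not an integer") from exc
        return cls(tissue=parts[0], stage=parts[1], replicate=rep)


@dataclass
class ExpressionMatrix:
    """circRNA x sample RPM matrix with parsed sample annotations.

    Wraps a dense :class:`pandas.DataFrame` (rows = circRNA ids, columns =
    the raw ``tissue:stage:rep`` strings) plus the parsed descriptors in
    column order.
    """

    values: pd.DataFrame
    samples: list[SampleDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = [SampleDescriptor.parse(c) for c in self.values.columns]
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("sample descriptors do not match matrix width")
        if len(set(map(str, self.samples))) != len(self.samples):
            raise ValueError("duplicate sample descriptors")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate circRNA id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative RPM value in expression matrix")

    @property
    def circ_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.tissue, None)
        return list(seen)

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.stage, None)
        return list(seen)

    def mean_by_tissue(self) -> pd.DataFrame:
        """Mean RPM per (circ, tissue), averaging stages and replicates."""
        groups = pd.Series([s.tissue for s in self.samples], index=self.values.columns)
        return self.values.T.groupby(groups, sort=False).mean().T

    def mean_by_stage(self) -> pd.DataFrame:
        """Mean RPM per (circ, stage), averaging tissues and replicates."""
        groups = pd.Series([s.stage for s in self.samples], index=self.values.columns)
        return self.values.T.groupby(groups, sort=False).mean().T


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED file into :class:`Interval` records, order preserved.

    Columns beyond 6 are ignored except a numeric column 7, which is taken
    as the per-region signal density. ``track``/``browser``/``#`` lines are
    skipped.
    """
    out: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("fewer than 3 columns", path, lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {fields[1]!r}/{fields[2]!r}", path, lineno)
            if end <= start or start < 0:
                raise ParseError(f"invalid span {start}-{end}", path, lineno)
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] else "."
            if strand not in VALID_STRANDS:
                raise ParseError(f"invalid strand {strand!r}", path, lineno)
            signal = None
            if len(fields) > 6 and fields[6] != "":
                try:
                    signal = float(fields[6])
                except ValueError:
                    raise ParseError(f"non-numeric signal {fields[6]!r}", path, lineno)
                if signal < 0:
                    raise ParseError(f"negative signal {signal}", path, lineno)
            out.append(Interval(chrom, start, end, name, strand, signal))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write BED6, plus a 7th signal column when any interval carries one."""
    intervals = list(intervals)
    with_signal = any(iv.signal is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            row = [iv.chrom, str(iv.start), str(iv.end), iv.id, "0", iv.strand]
            if with_signal:
                row.append(repr(iv.signal) if iv.signal is not None else "")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV RPM matrix (header ``circ_id<TAB>tissue:stage:rep...``)."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty file", path, 1)
        cols = header.split("\t")[1:]
        if not cols:
            raise ParseError("header has no sample columns", path, 1)
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(cols) + 1:
                raise ParseError(
                    f"ragged row: {len(fields) - 1} values for {len(cols)} samples", path, lineno
                )
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError:
                raise ParseError("non-numeric expression value", path, lineno)
            if any(v < 0 for v in vals):
                raise ParseError("negative RPM value", path, lineno)
            ids.append(fields[0])
            rows.append(vals)
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ParseError(f"duplicate circRNA id {dup!r}", path)
    frame = pd.DataFrame(rows, index=ids, columns=cols, dtype=float)
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\t" + "\t".join(matrix.values.columns) + "\n")
        for circ_id, row in matrix.values.iterrows():
            fh.write(circ_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``; uppercased, U normalized to T.

    Rejects duplicate headers and characters outside ACGTUN.
    """
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seqs:
                raise ParseError(f"duplicate FASTA header {record.id!r}", path)
            seq = str(record.seq).upper()
            bad = set(seq) - _SEQ_ALPHABET
            if bad:
                raise ParseError(
                    f"illegal character(s) {sorted(bad)} in record {record.id!r}", path
                )
            seqs[record.id] = seq.replace("U", "T")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ortholog tables and JSON reports
# ---------------------------------------------------------------------------

def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-species ortholog TSV; empty cells mean 'no ortholog'."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.shape[1] != 3:
        raise ParseError(f"ortholog table must have 3 species columns, got {table.shape[1]}", path)
    return table


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with _open_text(path) as fh:
        return json.load(fh)
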