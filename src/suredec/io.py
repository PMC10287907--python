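"""Readers and writers for the file formats the package touches.

All genomic coordinates are 0-based half-open (BED convention) everywhere:
in memory, on input and on output. Strand is ``'+'`` or ``'-'`` internally;
the unicode minus sign is accepted on input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SuREElement",
    "Region",
    "ParseError",
    "ValidationError",
    "read_fragments",
    "write_fragments",
    "read_bed",
    "read_narrowpeak",
    "read_fasta",
    "read_motif_counts",
    "write_bedgraph",
    "read_bedgraph",
]

STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}  # U+2212 minus sign


class ParseError(ValueError):
    """Raised when a file cannot be parsed into the expected schema."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


@dataclass(frozen=True)
class SuREElement:
    """One barcoded reporter fragment.

    ``ipcr_count`` (n_i) is the fragment's abundance in the input plasmid
    library; ``cdna_count`` (y_i) is the summed reporter barcode count
    across the selected biological replicates.
    """

    chrom: str
    start: int
    end: int
    strand: str
    library_id: int
    ipcr_count: int
    cdna_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"element {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand symbol {self.strand!r}")
        if self.ipcr_count < 1:
            raise ValidationError(
                f"element {self.chrom}:{self.start}-{self.end}: iPCR count must be >= 1"
            )
        if self.cdna_count < 0:
            raise ValidationError("cDNA count must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Region:
    """A plain genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "library", "ipcr"]


def read_fragments(path, cdna_columns: Sequence[str]) -> list[SuREElement]:
    """Read a fragment TSV into a list of :class:`SuREElement`.

    The table must carry header columns ``chrom, start, end, strand,
    library, ipcr`` plus one or more cDNA replicate count columns;
    ``cdna_columns`` names the replicates to pool (summed per row).
    Order-preserving and deterministic.
    """
    if not cdna_columns:
        raise ValueError("at least one cDNA column must be selected")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"{path}: cannot parse fragment table: {exc}") from exc
    missing = [c for c in FRAGMENT_COLUMNS + list(cdna_columns) if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    elements: list[SuREElement] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        try:
            strand_raw = str(row_d["strand"])
            if strand_raw not in STRAND_ALIASES:
                raise ValidationError(f"unknown strand symbol {strand_raw!r}")
            y = 0
            for col in cdna_columns:
                v = row_d[col]
                if pd.isna(v) or int(v) != v or int(v) < 0:
                    raise ValidationError(f"cDNA count {col}={v!r} not a non-negative integer")
                y += int(v)
            elements.append(
                SuREElement(
                    chrom=str(row_d["chrom"]),
                    start=int(row_d["start"]),
                    end=int(row_d["end"]),
                    strand=STRAND_ALIASES[strand_raw],
                    library_id=int(row_d["library"]),
                    ipcr_count=int(row_d["ipcr"]),
                    cdna_count=y,
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: line {line_no}: {exc}") from exc
    return elements


def write_fragments(elements: Iterable[SuREElement], path, cdna_column: str = "cdna") -> None:
    """Write elements back to the fragment TSV schema (single pooled cDNA column)."""
    rows = [
        (e.chrom, e.start, e.end, e.strand, e.library_id, e.ipcr_count, e.cdna_count)
        for e in elements
    ]
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS + [cdna_column])
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[Region]:
    """Read a BED3+/BED6 file (0-based half-open) into Regions."""
    regions: list[Region] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {line_no}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "+"
            if strand == ".":
                strand = "+"
            if strand in STRAND_ALIASES:
                strand = STRAND_ALIASES[strand]
            if start >= end:
                raise ValidationError(f"{path}: line {line_no}: start >= end")
            regions.append(Region(chrom, start, end, strand, name))
    return regions


def read_narrowpeak(path) -> list[Region]:
    """Read an ENCODE narrowPeak file into Regions (first six columns used)."""
    return read_bed(path)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an uppercase contig name -> sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_BASES = ("A", "C", "G", "T")


def read_motif_counts(path) -> np.ndarray:
    """Read a JASPAR-style nucleotide count block into a 4 x width array.

    Rows are returned in fixed A, C, G, T order regardless of the order in
    the file. Lines like ``A  [ 10  5  0 ]`` or ``A 10 5 0`` are accepted;
    a ``>`` header line is skipped.
    """
    counts: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            token = line.split()[0].upper()
            if token not in _BASES:
                continue
            body = line[len(line.split()[0]):].replace("[", " ").replace("]", " ")
            try:
                values = [float(v) for v in body.split()]
            except ValueError as exc:
                raise ParseError(f"{path}: malformed count row for base {token}") from exc
            counts[token] = values
    missing = [b for b in _BASES if b not in counts]
    if missing:
        raise ParseError(f"{path}: missing base row(s) {missing}")
    widths = {len(v) for v in counts.values()}
    if len(widths) != 1 or widths == {0}:
        raise ParseError(f"{path}: base rows have inconsistent widths {sorted(widths)}")
    mat = np.array([counts[b] for b in _BASES], dtype=float)
    if (mat < 0).any():
        raise ValidationError(f"{path}: negative motif counts")
    return mat


# ---------------------------------------------------------------------------
# bedGraph


def _runs(positions: np.ndarray, values: np.ndarray):
    """Yield (start, end, value) runs of adjacent equal-valued positions."""
    if positions.size == 0:
        return
    brk = np.flatnonzero((np.diff(positions) != 1) | (np.diff(values) != 0))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk + 1, [positions.size]))
    for s, e in zip(starts, ends):
        yield int(positions[s]), int(positions[e - 1]) + 1, float(values[s])


def write_bedgraph(track_values: Mapping, path, strand_mode: str = "suffix") -> list[Path]:
    """Write per-position values to bedGraph.

    ``track_values`` maps ``(chrom, strand)`` to ``(positions, values)``
    (parallel arrays, positions sorted ascending and unique). Runs of
    adjacent equal values are merged into single intervals.

    strand_mode 'suffix' writes ``<path>.plus.bedgraph`` /
    ``<path>.minus.bedgraph``; 'column' writes one file with a 5th strand
    column (non-standard but self-contained).
    """
    path = Path(path)
    written: list[Path] = []
    if strand_mode == "suffix":
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            out = path.with_name(path.name + f".{suffix}.bedgraph")
            with open(out, "w") as fh:
                for (chrom, s), (pos, val) in sorted(track_values.items()):
                    if s != strand:
                        continue
                    _check_sorted(pos, chrom, strand)
                    for start, end, v in _runs(np.asarray(pos), np.asarray(val, dtype=float)):
                        fh.write(f"{chrom}\t{start}\t{end}\t{v:.10g}\n")
            written.append(out)
    elif strand_mode == "column":
        with open(path, "w") as fh:
            for (chrom, strand), (pos, val) in sorted(track_values.items()):
                _check_sorted(pos, chrom, strand)
                for start, end, v in _runs(np.asarray(pos), np.asarray(val, dtype=float)):
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:.10g}\t{strand}\n")
        written.append(path)
    else:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    return written


def _check_sorted(pos, chrom, strand):
    pos = np.asarray(pos)
    if pos.size and (np.diff(pos) <= 0).any():
        raise RuntimeError(
            f"internal error: positions for {chrom}{strand} not strictly increasing "
            "(would produce overlapping bedGraph intervals)"
        )


def read_bedgraph(path, strand: str = "+") -> dict:
    """Read a bedGraph file into a ``(chrom, strand) -> (positions, values)`` map.

    A 5th column, if present, overrides the ``strand`` argument per line.
    """
    per_key: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {line_no}: expected >= 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            st = STRAND_ALIASES.get(parts[4], parts[4]) if len(parts) > 4 else strand
            if start >= end:
                raise ValidationError(f"{path}: line {line_no}: start >= end")
            per_key.setdefault((chrom, st), []).append((start, end, value))
    out = {}
    for key, intervals in per_key.items():
        intervals.sort()
        pos = np.concatenate([np.arange(s, e) for s, e, _ in intervals])
        val = np.concatenate([np.full(e - s, v) for s, e, v in intervals])
        if (np.diff(pos) <= 0).any():
            raise ValidationError(f"{path}: overlapping intervals for {key}")
        out[key] = (pos.astype(np.int64), val.astype(float))
    return out
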