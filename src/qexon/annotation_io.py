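"""Exon extraction from genome annotation and (de)serialization of length series.

An exon-length series treats the ordered exon lengths along one chromosome as a
discrete "time series": the i-th exon (ordered by genomic start) contributes
the i-th observation, its length in base pairs.  Coordinates follow the GFF3
convention (1-based, inclusive), so ``length = end - start + 1``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, ParseError, ValidationError

__all__ = [
    "ExonRecord",
    "ExonSeries",
    "parse_exons",
    "build_series",
    "read_series",
    "write_series",
]

_STRANDS = {"+", "-", "unknown"}


@dataclass(frozen=True)
class ExonRecord:
    """One exon feature: 1-based inclusive coordinates on a chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    gene_id: str | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(
                f"exon end {self.end} < start {self.start} on {self.chromosome}"
            )
        if self.start < 1:
            raise ValidationError(f"exon start {self.start} < 1")
        if self.strand not in _STRANDS:
            object.__setattr__(self, "strand", "unknown")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExonSeries:
    """Ordered exon lengths (bp) for one chromosome; index t = 1..n."""

    chromosome: str
    lengths: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.lengths)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("series must be a non-empty 1-D sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("lengths must be integers (bp)")
            arr = np.round(arr).astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if np.any(arr < 1):
            raise ValidationError("all lengths must be >= 1 bp")
        arr.setflags(write=False)
        object.__setattr__(self, "lengths", arr)

    @property
    def n(self) -> int:
        return int(self.lengths.size)

    @property
    def indices(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def __len__(self) -> int:
        return self.n


def _open_lines(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as fh:
            yield from fh
    elif isinstance(source, io.TextIOBase):
        yield from source
    else:  # iterable of lines
        yield from source


def _parse_gff3_line(line: str, lineno: int) -> tuple[str, str, int, int, str, str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise ParseError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
    seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
    return seqid, ftype, start, end, strand, attrs

def _gene_id_from_attrs(attrs: str) -> str | None:
    for key in ("gene_id=", "Parent=", "gene=", "ID="):
        for part in attrs.split(";"):
            part = part.strip()
            if part.startswith(key):
                return part[len(key):].split(",")[0] or None
    return None


def parse_exons(
    annotation_stream,
    chromosome_filter: set[str] | None = None,
    fmt: str = "auto",
) -> list[ExonRecord]:
    """Extract exon records from GFF3 or NCBI feature-table text.

    Parameters
    ----------
    annotation_stream
        Path, open text handle, or iterable of lines.
    chromosome_filter
        If given, keep only exons on these chromosomes.
    fmt
        ``gff3``, ``feature_table`` or ``auto`` (sniff: a ``>Feature`` header
        switches to feature-table mode).

    Order of appearance in the stream is preserved; coordinates are kept
    verbatim.  A malformed line raises :class:`ParseError` naming the line;
    zero exons after filtering raises :class:`EmptyInputError`.
    """
    records: list[ExonRecord] = []
    mode = fmt
    current_seqid: str | None = None  # feature-table state
    pending: tuple[int, int, int] | None = None

    for lineno, raw in enumerate(_open_lines(annotation_stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">Feature"):
            mode = "feature_table" if fmt == "auto" else mode
            if mode != "feature_table":
                raise ParseError("unexpected feature-table header", lineno)
            parts = line.split()
            current_seqid = parts[1] if len(parts) > 1 else "unknown"
            continue
        if line.startswith("#"):
            continue
        if mode == "auto":
            mode = "gff3"

        if mode == "gff3":
            seqid, ftype, start, end, strand, attrs = _parse_gff3_line(line, lineno)
            if ftype.lower() != "exon":
                continue
            if end < start:
                raise ParseError(f"end {end} < start {start}", lineno)
            if chromosome_filter is not None and seqid not in chromosome_filter:
                continue
            records.append(
                ExonRecord(seqid, start, end,
                           strand if strand in ("+", "-") else "unknown",
                           _gene_id_from_attrs(attrs))
            )
        else:  # NCBI 5-column feature table: start<TAB>end<TAB>feature
            cols = line.split("\t")
            if current_seqid is None:
                raise ParseError("feature line before >Feature header", lineno)
            if len(cols) >= 3 and cols[0].strip():
                try:
                    start = int(cols[0].lstrip("<>"))
                    end = int(cols[1].lstrip("<>"))
                except ValueError:
                    raise ParseError("non-integer feature coordinates", lineno)
                if cols[2].strip().lower() == "exon":
                    pending = (min(start, end), max(start, end), lineno)
                    strand = "+" if end >= start else "-"
                    if chromosome_filter is None or current_seqid in chromosome_filter:
                        records.append(ExonRecord(current_seqid, pending[0],
                                                  pending[1], strand))
                else:
                    pending = None
            # qualifier/continuation lines are ignored

    if not records:
        raise EmptyInputError("no exon records after parsing/filtering")
    return records


def build_series(
    records: Sequence[ExonRecord],
    chromosome: str,
    ordering: str = "by_start",
    dedup: bool = False,
) -> ExonSeries:
    """Build the ordered exon-length series for one chromosome.

    ``by_start`` orders by genomic start with a deterministic tie-break
    (smaller end first, then input order); ``by_file_order`` keeps stream
    order.  With ``dedup`` exact duplicate intervals (isoform-shared exons)
    collapse to one.
    """
    if ordering not in ("by_start", "by_file_order"):
        raise ValidationError(f"unknown ordering {ordering!r}")
    chosen = [r for r in records if r.chromosome == chromosome]
    if not chosen:
        raise EmptyInputError(f"no records for chromosome {chromosome!r}")
    if dedup:
        seen: set[tuple[int, int]] = set()
        uniq = []
        for r in chosen:
            key = (r.start, r.end)
            if key not in seen:
                seen.add(key)
                uniq.append(r)
        chosen = uniq
    if ordering == "by_start":
        chosen = sorted(
            enumerate(chosen), key=lambda ir: (ir[1].start, ir[1].end, ir[0])
        )
        chosen = [r for _, r in chosen]
    return ExonSeries(chromosome, np.array([r.length for r in chosen], dtype=np.int64))


def write_series(series: ExonSeries, path) -> None:
    """Write a series as TSV with header ``index\\tlength_bp`` (UTF-8, LF)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("index\tlength_bp\n")
        for i, l in zip(series.indices, series.lengths):
            fh.write(f"{i}\t{l}\n")


def read_series(path, chromosome: str | None = None) -> ExonSeries:
    """Read a series TSV written by :func:`write_series`."""
    lengths: list[int] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["index", "length_bp"]:
            raise ParseError("expected header 'index\\tlength_bp'", 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError("expected 2 columns", lineno)
            try:
                idx, l = int(cols[0]), int(cols[1])
            except ValueError:
                raise ParseError("non-integer fields", lineno)
            if idx != len(lengths) + 1:
                raise ParseError(f"index {idx} out of order", lineno)
            lengths.append(l)
    if not lengths:
        raise EmptyInputError("series file contains no data rows")
    name = chromosome or os.path.splitext(os.path.basename(str(path)))[0]
    return ExonSeries(name, np.array(lengths, dtype=np.int64))
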