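"""Readers, writers and signal-quantification primitives.

Formats handled (all plain text, header lines starting with ``#`` or
``track`` are skipped):

* BED3/6 read intervals (tagAlign-style) and enriched-region BED
* narrowPeak (summit = start + column-10 offset)
* BEDPE loop calls with configurable PET-count / FDR columns (ChIA-PET2 style)
* FIMO TSV motif occurrences (1-based, converted to 0-based half-open)
* fixed-step wig or bedGraph conservation scores
* tab-separated expression tables (gene id, chrom, TSS, strand, FPKM)
* 3-column sparse Hi-C contact matrix text + one-float-per-line KR vector
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, LoopRecord, count_overlaps, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "SignalTrack",
    "ConservationTrack",
    "ContactMatrix",
    "ExpressionRecord",
    "LoopFileDialect",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_loop_file",
    "write_loop_file",
    "read_fimo",
    "read_expression_table",
    "write_expression_table",
    "read_conservation",
    "read_contact_matrix",
    "rpkm",
    "mask_reads",
]


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# Read sets and signal tracks
# ---------------------------------------------------------------------------


class ReadSet:
    """A set of aligned, de-duplicated read intervals with a library size.

    ``library_size`` is the total number of mapped, de-duplicated reads in the
    library; it is the RPKM denominator and is deliberately *not* changed by
    enriched-region masking.
    """

    def __init__(
        self,
        intervals: Mapping[str, np.ndarray] | Iterable[GenomicInterval],
        library_size: int,
    ):
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if isinstance(intervals, Mapping):
            per_chrom = {c: np.asarray(a, dtype=np.int64) for c, a in intervals.items()}
        else:
            buf: dict[str, list[tuple[int, int]]] = {}
            for iv in intervals:
                buf.setdefault(iv.chrom, []).append((iv.start, iv.end))
            per_chrom = {
                c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in buf.items()
            }
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._raw: dict[str, np.ndarray] = {}
        n = 0
        for chrom, arr in per_chrom.items():
            arr = arr.reshape(-1, 2)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            self._raw[chrom] = arr
            self._starts[chrom] = arr[:, 0].copy()
            self._ends[chrom] = np.sort(arr[:, 1])
            n += len(arr)
        self.n_reads = n
        if library_size < n:
            raise ValueError(
                f"library_size {library_size} smaller than read count {n}"
            )
        self.library_size = int(library_size)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._raw)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) sorted by start."""
        return self._raw.get(chrom, np.empty((0, 2), dtype=np.int64))

    def count(self, chrom: str, qstart, qend):
        """Number of reads overlapping [qstart, qend) by >= 1 bp (vectorised)."""
        if chrom not in self._starts:
            return np.zeros_like(np.asarray(qstart)) if np.ndim(qstart) else 0
        return count_overlaps(self._starts[chrom], self._ends[chrom], qstart, qend)

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.chroms:
            for s, e in self._raw[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


@dataclass
class SignalTrack:
    """A named DNase/ChIP signal: reads plus the enriched regions they must hit."""

    name: str
    reads: ReadSet
    enriched_regions: list[GenomicInterval] = field(default_factory=list)

    def masked(self) -> "SignalTrack":
        """Track with reads restricted to enriched regions (noise removal)."""
        return SignalTrack(
            self.name, mask_reads(self.reads, self.enriched_regions), self.enriched_regions
        )


def mask_reads(reads: ReadSet, regions: Sequence[GenomicInterval]) -> ReadSet:
    """Retain only reads overlapping >= 1 enriched region by >= 1 bp.

    The library size (RPKM denominator) is preserved from the input.
    """
    if not regions:
        return ReadSet({}, reads.library_size)
    merged = merge_intervals(regions)
    reg_s: dict[str, np.ndarray] = {}
    reg_e: dict[str, np.ndarray] = {}
    for iv in merged:
        reg_s.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[arg-type]
        reg_e.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[arg-type]
    kept: dict[str, np.ndarray] = {}
    for chrom in reads.chroms:
        arr = reads.intervals(chrom)
        if chrom not in reg_s or not len(arr):
            continue
        rs = np.asarray(reg_s[chrom])
        re_ = np.asarray(reg_e[chrom])
        # merged regions are disjoint and sorted: the only region that can
        # overlap read [s, e) is the first one with region_end > s
        idx = np.searchsorted(re_, arr[:, 0], side="right")
        ok = (idx < len(rs)) & (rs[np.minimum(idx, len(rs) - 1)] < arr[:, 1])
        if ok.any():
            kept[chrom] = arr[ok]
    return ReadSet(kept, reads.library_size)


def rpkm(track: SignalTrack | ReadSet, region: GenomicInterval) -> float:
    """Reads per kilobase per million mapped reads over ``region``.

    A read counts if it overlaps the region by >= 1 bp.  The denominator uses
    the library's total mapped read count, not the post-masking count.
    """
    reads = track.reads if isinstance(track, SignalTrack) else track
    if len(region) <= 0:
        raise ValueError("zero-length region")
    n = int(reads.count(region.chrom, region.start, region.end))
    return n / ((len(region) / 1000.0) * (reads.library_size / 1e6))


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        try:
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed BED row at line {lineno}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


@dataclass(frozen=True)
class PeakRecord:
    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0

    @property
    def summit(self) -> int:
        return self.interval.start + self.summit_offset


def read_narrowpeak(path) -> list[PeakRecord]:
    """narrowPeak: columns 1-3 interval, column 7 signalValue, column 10 summit offset."""
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        try:
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            score = float(f[6]) if len(f) > 6 else 0.0
            offset = int(f[9]) if len(f) > 9 else len(iv) // 2
            if offset < 0:
                offset = len(iv) // 2
            out.append(PeakRecord(iv, offset, score))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed narrowPeak row at line {lineno}") from exc
    return out


# ---------------------------------------------------------------------------
# Loop files (BEDPE + PET / FDR columns)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoopFileDialect:
    """Which 0-based columns of a BEDPE-like file hold PET count and FDR.

    ChIA-PET2 output columns vary by version, so both indices are
    configurable.  ``None`` means the column is absent.
    """

    pet_column: int | None = 7
    fdr_column: int | None = 8
    probability_column: int | None = None


def read_loop_file(path, dialect: LoopFileDialect = LoopFileDialect()) -> list[LoopRecord]:
    """Read a BEDPE-like loop file; anchors are normalised left-to-right.

    Inter-chromosomal rows are dropped (with a logged count), malformed rows
    raise with the offending line number.
    """
    records: list[LoopRecord] = []
    n_trans = 0
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        try:
            a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
            def _field(col: int | None) -> str | None:
                if col is None or len(f) <= col or f[col] in (".", "NA", ""):
                    return None
                return f[col]

            pet_tok = _field(dialect.pet_column)
            pet = int(float(pet_tok)) if pet_tok is not None else None
            fdr_tok = _field(dialect.fdr_column)
            fdr = float(fdr_tok) if fdr_tok is not None else None
            prob_tok = _field(dialect.probability_column)
            prob = float(prob_tok) if prob_tok is not None else None
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed BEDPE row at line {lineno}") from exc
        if a1.chrom != a2.chrom:
            n_trans += 1
            continue
        records.append(LoopRecord(a1, a2, pet_count=pet, fdr=fdr, probability=prob))
    if n_trans:
        logger.info("%s: dropped %d inter-chromosomal rows", path, n_trans)
    return records


def write_loop_file(
    loops: Iterable[LoopRecord], path, dialect: LoopFileDialect = LoopFileDialect()
) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            f = [
                lp.chrom,
                str(lp.anchor1.start),
                str(lp.anchor1.end),
                lp.chrom,
                str(lp.anchor2.start),
                str(lp.anchor2.end),
                ".",
            ]
            ncol = max(
                x for x in (dialect.pet_column, dialect.fdr_column, dialect.probability_column, 6)
                if x is not None
            )
            f += ["."] * (ncol + 1 - len(f))
            if dialect.pet_column is not None:
                f[dialect.pet_column] = str(lp.pet_count if lp.pet_count is not None else ".")
            if dialect.fdr_column is not None:
                f[dialect.fdr_column] = (
                    repr(lp.fdr) if lp.fdr is not None else "."
                )
            if dialect.probability_column is not None:
                f[dialect.probability_column] = (
                    repr(lp.probability) if lp.probability is not None else "."
                )
            fh.write("\t".join(f) + "\n")


# ---------------------------------------------------------------------------
# FIMO motif occurrences
# ---------------------------------------------------------------------------


def read_fimo(path) -> list["MotifOccurrence"]:
    """FIMO TSV: motif_id, motif_alt, chrom, start, stop, strand, score, ...

    FIMO coordinates are 1-based inclusive; converted to 0-based half-open.
    A slimmer 5-column dialect (chrom, start, stop, strand, score) is also
    accepted.
    """
    from .sites import MotifOccurrence

    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if f[0] in ("motif_id", "chrom"):  # header without '#'
            continue
        try:
            if len(f) >= 7 and not _is_number(f[1]):
                chrom, start, stop, strand, score = f[2], f[3], f[4], f[5], f[6]
            else:
                chrom, start, stop, strand, score = f[0], f[1], f[2], f[3], f[4]
            iv = GenomicInterval(chrom, int(start) - 1, int(stop), strand)
            out.append(MotifOccurrence(iv, float(score)))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed FIMO row at line {lineno}") from exc
    return out


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionRecord:
    """A gene's TSS (1 bp point interval, stranded) and its FPKM."""

    gene_id: str
    tss: GenomicInterval
    fpkm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fpkm) or self.fpkm < 0:
            raise ValueError(f"bad FPKM for {self.gene_id}")

    def promoter(self, flank: int = 2000) -> GenomicInterval:
        pos = self.tss.start
        return GenomicInterval(self.tss.chrom, max(0, pos - flank), pos + flank)


def read_expression_table(path) -> list[ExpressionRecord]:
    """TSV: gene_id, chrom, tss_position (0-based), strand, fpkm."""
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if f[0] == "gene_id":
            continue
        try:
            tss = GenomicInterval(f[1], int(f[2]), int(f[2]) + 1, f[3])
            out.append(ExpressionRecord(f[0], tss, float(f[4])))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed expression row at line {lineno}") from exc
    return out


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tfpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.tss.chrom}\t{r.tss.start}\t{r.tss.strand}\t{r.fpkm:.6g}\n")


# ---------------------------------------------------------------------------
# Conservation scores
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Per-base conservation (phastCons) scores held as value intervals.

    Bases not covered by any interval score 0 (missing-data convention of the
    feature schema).
    """

    def __init__(self, per_chrom: Mapping[str, np.ndarray]):
        # each value: (n, 3) float array of [start, end, score]
        self._data = {}
        for chrom, arr in per_chrom.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            order = np.argsort(arr[:, 0])
            self._data[chrom] = arr[order]

    def mean(self, region: GenomicInterval) -> float:
        """Mean per-base score over the region, uncovered bases counted as 0."""
        arr = self._data.get(region.chrom)
        if arr is None or not len(arr):
            return 0.0
        s = np.maximum(arr[:, 0], region.start)
        e = np.minimum(arr[:, 1], region.end)
        w = np.clip(e - s, 0, None)
        return float(np.dot(w, arr[:, 2]) / len(region))


def read_conservation(path) -> ConservationTrack:
    """Read a bedGraph or fixed-step wig file of per-base scores."""
    per_chrom: dict[str, list[list[float]]] = {}
    chrom = None
    pos = step = span = 1
    fixed = False
    for lineno, line in _data_lines(path):
        f = line.split()
        if f[0] == "fixedStep":
            kv = dict(p.split("=") for p in f[1:])
            chrom = kv["chrom"]
            pos = int(kv["start"]) - 1  # wig is 1-based
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            fixed = True
            continue
        if fixed and len(f) == 1:
            per_chrom.setdefault(chrom, []).append([pos, pos + span, float(f[0])])
            pos += step
            continue
        try:
            per_chrom.setdefault(f[0], []).append([int(f[1]), int(f[2]), float(f[3])])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed conservation row at line {lineno}") from exc
    return ConservationTrack({c: np.asarray(v) for c, v in per_chrom.items()})


# ---------------------------------------------------------------------------
# Hi-C contact matrices
# ---------------------------------------------------------------------------


class ContactMatrix:
    """Sparse symmetric intra-chromosomal contact counts at fixed resolution.

    Normalised lookups divide the raw count by the product of the two bins'
    Knight–Ruiz factors; a missing (NaN) factor makes the normalised value
    missing (NaN), never zero.
    """

    def __init__(self, resolution: int, entries: Mapping[tuple[int, int], float], kr: np.ndarray):
        self.resolution = int(resolution)
        self.entries: dict[tuple[int, int], float] = {}
        for (i, j), v in entries.items():
            self.entries[(min(i, j), max(i, j))] = float(v)
        self.kr = np.asarray(kr, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.kr)

    def bin_of(self, position: int) -> int:
        return int(position) // self.resolution

    def raw(self, i: int, j: int) -> float:
        return self.entries.get((min(i, j), max(i, j)), 0.0)

    def normalized(self, i: int, j: int) -> float:
        """KR-normalised count; NaN if either bin's factor is missing."""
        if i >= len(self.kr) or j >= len(self.kr) or i < 0 or j < 0:
            return float("nan")
        ki, kj = self.kr[i], self.kr[j]
        if not (np.isfinite(ki) and np.isfinite(kj)):
            return float("nan")
        return self.raw(i, j) / (ki * kj)

    def normalized_at(self, pos_i: int, pos_j: int) -> float:
        return self.normalized(self.bin_of(pos_i), self.bin_of(pos_j))


def read_contact_matrix(matrix_path, kr_path, resolution: int) -> ContactMatrix:
    """3-column sparse text (bin_i_start, bin_j_start, count) + KR vector file."""
    entries: dict[tuple[int, int], float] = {}
    max_bin = -1
    for lineno, line in _data_lines(matrix_path):
        f = line.split()
        try:
            bi, bj, c = int(f[0]), int(f[1]), float(f[2])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{matrix_path}: malformed row at line {lineno}") from exc
        if bi % resolution or bj % resolution:
            raise ValueError(
                f"{matrix_path}: coordinate {bi},{bj} at line {lineno} not a "
                f"multiple of resolution {resolution}"
            )
        i, j = bi // resolution, bj // resolution
        entries[(min(i, j), max(i, j))] = c
        max_bin = max(max_bin, i, j)
    kr_vals = []
    for _, line in _data_lines(kr_path):
        tok = line.strip()
        kr_vals.append(float("nan") if tok.lower() == "nan" else float(tok))
    kr = np.asarray(kr_vals, dtype=float)
    if len(kr) <= max_bin:
        kr = np.concatenate([kr, np.full(max_bin + 1 - len(kr), np.nan)])
    return ContactMatrix(resolution, entries, kr)


def write_contact_matrix(matrix: ContactMatrix, matrix_path, kr_path) -> None:
    with open(matrix_path, "w") as fh:
        for (i, j) in sorted(matrix.entries):
            v = matrix.entries[(i, j)]
            fh.write(f"{i * matrix.resolution}\t{j * matrix.resolution}\t{v:.6g}\n")
    with open(kr_path, "w") as fh:
        for v in matrix.kr:
            fh.write("NaN\n" if not np.isfinite(v) else f"{v:.6g}\n")
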