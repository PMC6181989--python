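"""Core coordinate types shared by every stage of the pipeline.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
FIMO-style 1-based inputs are converted at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "LoopRecord",
    "overlaps",
    "count_overlaps",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval ``chrom:[start, end)`` with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


@dataclass
class LoopRecord:
    """An ordered pair of same-chromosome anchors, stored left-to-right.

    ``summit1``/``summit2`` are the anchor reference points (CTCF peak summits
    where known, anchor midpoints otherwise); loop length is measured
    summit-to-summit.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int | None = None
    fdr: float | None = None
    probability: float | None = None
    label: str = "unlabeled"
    summit1: int | None = None
    summit2: int | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("inter-chromosomal loop")
        if self.anchor1.start > self.anchor2.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1
            self.summit1, self.summit2 = self.summit2, self.summit1
        if self.summit1 is None:
            self.summit1 = self.anchor1.midpoint
        if self.summit2 is None:
            self.summit2 = self.anchor2.midpoint
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def length(self) -> int:
        """Summit-to-summit loop length in bp."""
        return abs(self.summit2 - self.summit1)

    def anchor_key(self) -> tuple:
        return (
            self.chrom,
            self.anchor1.start,
            self.anchor1.end,
            self.anchor2.start,
            self.anchor2.end,
        )


# ---------------------------------------------------------------------------
# Vectorised interval arithmetic on sorted arrays.
# ---------------------------------------------------------------------------


def count_overlaps(
    starts_sorted: np.ndarray,
    ends_sorted: np.ndarray,
    qstart,
    qend,
):
    """Count intervals overlapping each query by >= 1 bp.

    ``starts_sorted`` and ``ends_sorted`` are the interval starts and ends,
    each sorted independently.  An interval [s, e) overlaps query [qs, qe)
    iff s < qe and e > qs, so the count is
    ``#{s < qe} - #{e <= qs}`` (every interval with e <= qs also has s < qe).
    """
    qs = np.asarray(qstart)
    qe = np.asarray(qend)
    n_start_before = np.searchsorted(starts_sorted, qe, side="left")
    n_end_before = np.searchsorted(ends_sorted, qs, side="right")
    return n_start_before - n_end_before


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent-by-overlap intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged
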