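"""Construction of labeled training sets.

Positives are significant ChIA-PET loops (FDR <= 0.05, PET >= 2) with
summit-to-summit length between 10 kb and 1 Mb.  Negatives are random
same-chromosome pairings of CTCF binding sites in the same length range,
excluding any pair with ChIA-PET support (PET >= 1 anywhere in the
unfiltered call set) or present in a Hi-C loop list; their count is a fixed
multiple of the positives (5x by default).  Wiring negatives re-pair the
anchors of the positive loops themselves (3x) to isolate the "which anchors
connect to which" part of the problem from anchor detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GenomicInterval, LoopRecord
from .matching import LoopIndex
from .sites import BindingSite

MIN_LOOP_LENGTH = 10_000
MAX_LOOP_LENGTH = 1_000_000

__all__ = [
    "TrainingSet",
    "select_positives",
    "build_negatives",
    "build_wiring_negatives",
    "MIN_LOOP_LENGTH",
    "MAX_LOOP_LENGTH",
]


@dataclass
class TrainingSet:
    positives: list[LoopRecord]
    negatives: list[LoopRecord]
    negative_ratio: float
    seed: int

    @property
    def loops(self) -> list[LoopRecord]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives), dtype=int), np.zeros(len(self.negatives), dtype=int)]
        )


def _length_ok(length: int, min_length: int, max_length: int) -> bool:
    return min_length <= length <= max_length


def select_positives(
    loops: Sequence[LoopRecord],
    fdr_max: float = 0.05,
    min_pet: int = 2,
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
) -> list[LoopRecord]:
    """Filter ChIA-PET calls to significant, length-bounded positive loops."""
    out = []
    for lp in loops:
        if lp.fdr is None or lp.pet_count is None:
            raise ValueError("loop record missing FDR or PET count")
        if (
            lp.fdr <= fdr_max
            and lp.pet_count >= min_pet
            and _length_ok(lp.length, min_length, max_length)
        ):
            out.append(
                LoopRecord(
                    lp.anchor1,
                    lp.anchor2,
                    pet_count=lp.pet_count,
                    fdr=lp.fdr,
                    probability=lp.probability,
                    label="positive",
                    summit1=lp.summit1,
                    summit2=lp.summit2,
                )
            )
    return out


def _site_pair_loop(s1: BindingSite, s2: BindingSite) -> LoopRecord:
    left, right = (s1, s2) if s1.summit <= s2.summit else (s2, s1)
    return LoopRecord(
        left.extent,
        right.extent,
        pet_count=0,
        label="negative",
        summit1=left.summit,
        summit2=right.summit,
    )


def _rejection_sample(
    candidates_fn,
    quota: int,
    exclude: Sequence[LoopIndex],
    positives_keys: set,
    rng: np.random.Generator,
    max_attempts: int,
) -> list[LoopRecord]:
    accepted: list[LoopRecord] = []
    seen: set = set(positives_keys)
    attempts = 0
    while len(accepted) < quota:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"candidate pool exhausted: {len(accepted)}/{quota} negatives "
                f"accepted after {attempts} attempts"
            )
        attempts += 1
        loop = candidates_fn(rng)
        if loop is None:
            continue
        key = loop.anchor_key()
        if key in seen:
            continue
        if any(loop in idx for idx in exclude):
            continue
        seen.add(key)
        accepted.append(loop)
    return accepted


def build_negatives(
    sites: Sequence[BindingSite],
    positives: Sequence[LoopRecord],
    all_chiapet_loops: Sequence[LoopRecord],
    hic_loops: Sequence[LoopRecord] = (),
    ratio: float = 5.0,
    seed: int = 0,
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
    max_attempt_factor: int = 100,
) -> list[LoopRecord]:
    """Random site pairings with no ChIA-PET (PET >= 1) or Hi-C support.

    Deterministic given ``seed``; raises when the feasible pool is exhausted
    before the quota of ``round(ratio * len(positives))`` pairs is met.
    """
    quota = int(round(ratio * len(positives)))
    by_chrom: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    chroms = sorted(c for c, lst in by_chrom.items() if len(lst) >= 2)
    if not chroms:
        raise RuntimeError("candidate pool exhausted: 0 negatives accepted (no site pairs)")
    weights = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    supported = LoopIndex([l for l in all_chiapet_loops if (l.pet_count or 0) >= 1])
    hic_index = LoopIndex(list(hic_loops))
    pos_keys = {p.anchor_key() for p in positives}
    rng = np.random.default_rng(seed)

    def candidate(r: np.random.Generator) -> LoopRecord | None:
        chrom = chroms[int(r.choice(len(chroms), p=weights))]
        lst = by_chrom[chrom]
        i, j = r.choice(len(lst), size=2, replace=False)
        s1, s2 = lst[int(i)], lst[int(j)]
        if not _length_ok(abs(s1.summit - s2.summit), min_length, max_length):
            return None
        return _site_pair_loop(s1, s2)

    return _rejection_sample(
        candidate, quota, [supported, hic_index], pos_keys, rng, max_attempt_factor * max(quota, 1)
    )


def build_wiring_negatives(
    positives: Sequence[LoopRecord],
    all_chiapet_loops: Sequence[LoopRecord] = (),
    hic_loops: Sequence[LoopRecord] = (),
    ratio: float = 3.0,
    seed: int = 0,
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
    max_attempt_factor: int = 100,
) -> list[LoopRecord]:
    """Random re-pairings of the positive loops' own anchors (3x positives).

    The same length bounds and support exclusions as :func:`build_negatives`
    apply; in particular a sampled pair identical (anchor-overlapping) to an
    existing positive is rejected.
    """
    quota = int(round(ratio * len(positives)))
    anchors: list[tuple[GenomicInterval, int]] = []
    seen_anchor = set()
    for p in positives:
        for iv, summit in ((p.anchor1, p.summit1), (p.anchor2, p.summit2)):
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen_anchor:
                seen_anchor.add(key)
                anchors.append((iv, summit))
    by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for a in anchors:
        by_chrom.setdefault(a[0].chrom, []).append(a)
    chroms = sorted(c for c, lst in by_chrom.items() if len(lst) >= 2)
    if not chroms:
        raise RuntimeError("candidate pool exhausted: no anchor pairs available")
    weights = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    positive_index = LoopIndex(list(positives))
    supported = LoopIndex([l for l in all_chiapet_loops if (l.pet_count or 0) >= 1])
    hic_index = LoopIndex(list(hic_loops))
    rng = np.random.default_rng(seed)

    def candidate(r: np.random.Generator) -> LoopRecord | None:
        chrom = chroms[int(r.choice(len(chroms), p=weights))]
        lst = by_chrom[chrom]
        i, j = r.choice(len(lst), size=2, replace=False)
        (iv1, sm1), (iv2, sm2) = lst[int(i)], lst[int(j)]
        if not _length_ok(abs(sm1 - sm2), min_length, max_length):
            return None
        return LoopRecord(
            iv1, iv2, pet_count=0, label="negative", summit1=sm1, summit2=sm2
        )

    pos_keys = {p.anchor_key() for p in positives}
    return _rejection_sample(
        candidate,
        quota,
        [positive_index, supported, hic_index],
        pos_keys,
        rng,
        max_attempt_factor * max(quota, 1),
    )
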