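"""Motif-orientation-only loop constructors used as comparison baselines.

The naive constructor pairs every CTCF-bound forward-strand motif with the
nearest downstream reverse-strand motif on the same chromosome — the
convergent-orientation rule.  The Oti-style constructor repeats that rule on
intensity-thresholded subsets of the sites (top 100/80/60/40/20% by CTCF
peak strength) and pools the rounds, partially recovering nested loops.
"""

from __future__ import annotations

from typing import Sequence

from .core import LoopRecord
from .matching import LoopIndex
from .sites import BindingSite
from .training import MAX_LOOP_LENGTH, MIN_LOOP_LENGTH

__all__ = ["naive_method", "oti_method", "baseline_point"]

OTI_FRACTIONS = (1.0, 0.8, 0.6, 0.4, 0.2)


def _motif_sites(sites: Sequence[BindingSite]) -> list[BindingSite]:
    return [s for s in sites if s.best_motif is not None]


def _site_loop(left: BindingSite, right: BindingSite) -> LoopRecord:
    return LoopRecord(
        left.extent, right.extent, summit1=left.summit, summit2=right.summit
    )


def naive_method(
    sites: Sequence[BindingSite],
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
    blocking: bool = False,
) -> list[LoopRecord]:
    """Pair each forward motif to the nearest downstream reverse motif.

    Sites without an attached motif are ignored.  With ``blocking=True`` only
    innermost convergent pairs are emitted: a forward motif is skipped when
    another forward motif lies between it and its reverse partner.
    Duplicate anchor pairs are de-duplicated and loops outside
    ``[min_length, max_length]`` (summit-to-summit) are dropped.
    """
    motif_sites = sorted(_motif_sites(sites), key=lambda s: (s.chrom, s.summit))
    loops: list[LoopRecord] = []
    seen: set = set()
    by_chrom: dict[str, list[BindingSite]] = {}
    for s in motif_sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, lst in by_chrom.items():
        for i, s in enumerate(lst):
            if s.best_motif.interval.strand != "+":
                continue
            partner = None
            blocked = False
            for t in lst[i + 1 :]:
                strand = t.best_motif.interval.strand
                if strand == "-":
                    partner = t
                    break
                if blocking and strand == "+":
                    blocked = True
                    break
            if partner is None or blocked:
                continue
            lp = _site_loop(s, partner)
            if not (min_length <= lp.length <= max_length):
                continue
            key = lp.anchor_key()
            if key not in seen:
                seen.add(key)
                loops.append(lp)
    return loops


def oti_method(
    sites: Sequence[BindingSite],
    fractions: Sequence[float] = OTI_FRACTIONS,
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
    blocking: bool = False,
) -> list[LoopRecord]:
    """Pool naive-rule loops over intensity-thresholded site subsets.

    Active motif sites are ranked by CTCF peak intensity (descending, ties
    broken by coordinate); the naive rule is applied to the top fraction for
    each entry of ``fractions`` and the resulting loop sets are unioned,
    de-duplicated by anchor pair.
    """
    motif_sites = _motif_sites(sites)
    ranked = sorted(motif_sites, key=lambda s: (-s.intensity, s.chrom, s.summit))
    loops: list[LoopRecord] = []
    seen: set = set()
    for frac in fractions:
        k = int(round(frac * len(ranked)))
        subset = ranked[:k]
        for lp in naive_method(subset, min_length, max_length, blocking=blocking):
            key = lp.anchor_key()
            if key not in seen:
                seen.add(key)
                loops.append(lp)
    return loops


def baseline_point(
    predicted: Sequence[LoopRecord],
    positives: Sequence[LoopRecord],
    negatives: Sequence[LoopRecord],
) -> tuple[float, float]:
    """The (precision, recall) operating point of a loop constructor.

    Predictions are matched (both anchors, >= 1 bp) against the labeled
    universe; precision is computed over predictions hitting that universe,
    recall over the positives.
    """
    if not positives:
        raise ValueError("empty positive set")
    pos_index = LoopIndex(list(positives))
    neg_index = LoopIndex(list(negatives))
    n_pos_hits = n_scored = 0
    for lp in predicted:
        in_pos = lp in pos_index
        in_neg = lp in neg_index
        if in_pos or in_neg:
            n_scored += 1
        if in_pos:
            n_pos_hits += 1
    pred_index = LoopIndex(list(predicted))
    matched_positives = sum(1 for p in positives if p in pred_index)
    precision = n_pos_hits / n_scored if n_scored else 0.0
    recall = matched_positives / len(positives)
    return precision, recall
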