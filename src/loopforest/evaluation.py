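"""Assessment protocols: cross-cell evaluation, anchor- and wiring-level
dissection, genome-wide scanning, ChIA-PET support categorisation, Hi-C
contact validation, and the PET down-sampling surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from .classifier import LoopClassifier, PerformanceSummary
from .core import GenomicInterval, LoopRecord
from .features import DataBundle, FeatureConfig, LoopFeaturizer
from .matching import LoopIndex, match_loops
from .sites import BindingSite
from .training import MAX_LOOP_LENGTH, MIN_LOOP_LENGTH

__all__ = [
    "SupportCategory",
    "match_loops",
    "evaluate_labeled",
    "evaluate_cross_cell",
    "evaluate_anchors",
    "evaluate_wiring",
    "scan_genome",
    "categorize_predictions",
    "hic_support_test",
    "thin_pet_counts",
]


class SupportCategory(str, Enum):
    """ChIA-PET support level of a predicted loop."""

    SIGNIFICANT = "Significant"  # matched call with FDR <= 0.05 and PET >= 2
    WITH_EVIDENCE = "WithEvidence"  # matched call with PET = 1 or FDR > 0.05
    NO_SUPPORT = "NoSupport"  # no matching PET evidence at all


def _summary_from_scores(y: np.ndarray, scores: np.ndarray) -> PerformanceSummary:
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    prec, rec, _ = precision_recall_curve(y, scores)
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    return PerformanceSummary(
        auroc_values=[float(roc_auc_score(y, scores))],
        aupr_values=[float(average_precision_score(y, scores))],
        roc_curve_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_curve_points=pd.DataFrame({"precision": prec, "recall": rec}),
        precision_at_half=tp / max(int((pred == 1).sum()), 1),
        recall_at_half=tp / max(int((y == 1).sum()), 1),
    )


def evaluate_labeled(
    model: LoopClassifier,
    X: pd.DataFrame,
    y,
) -> PerformanceSummary:
    """Score a labeled feature matrix with a trained model (no refitting)."""
    y = np.asarray(y)
    return _summary_from_scores(y, model.predict_probability(X))


def evaluate_cross_cell(
    model: LoopClassifier,
    target_features: pd.DataFrame,
    target_labels,
) -> PerformanceSummary:
    """Apply a model trained in cell type A to cell type B's labeled set.

    The feature configuration must be identical across cells: a column
    mismatch raises.  Restriction to cell-specific positives is done by the
    caller through the rows it passes in.
    """
    return evaluate_labeled(model, target_features, target_labels)


def evaluate_wiring(
    model: LoopClassifier,
    positive_features: pd.DataFrame,
    wiring_negative_features: pd.DataFrame,
) -> PerformanceSummary:
    """Wiring-level evaluation: positives vs anchor-re-pairing negatives."""
    X = pd.concat([positive_features, wiring_negative_features], ignore_index=True)
    y = np.concatenate(
        [np.ones(len(positive_features), dtype=int), np.zeros(len(wiring_negative_features), dtype=int)]
    )
    return evaluate_labeled(model, X, y)


# ---------------------------------------------------------------------------
# Anchor-level evaluation
# ---------------------------------------------------------------------------


class _AnchorUniverse:
    """Merged labeled anchor universe with vectorised overlap queries.

    Anchors overlapping by >= 1 bp collapse into one universe node; a node is
    positive if any positive-loop anchor contributed to it, so anchors
    belonging only to negative loops are the negative class.
    """

    def __init__(self, positives: Sequence[LoopRecord], negatives: Sequence[LoopRecord]):
        from .core import merge_intervals

        pos_anchors = [a for lp in positives for a in (lp.anchor1, lp.anchor2)]
        neg_anchors = [a for lp in negatives for a in (lp.anchor1, lp.anchor2)]
        nodes = merge_intervals(pos_anchors + neg_anchors)
        self.nodes = nodes
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(nodes):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            self._starts[chrom] = np.asarray([nodes[i].start for i in idx])
            self._ends[chrom] = np.asarray([nodes[i].end for i in idx])
            self._ids[chrom] = np.asarray(idx)
        self.labels = np.zeros(len(nodes), dtype=int)
        for iv in pos_anchors:
            for i in self.query(iv):
                self.labels[i] = 1

    def query(self, iv: GenomicInterval) -> np.ndarray:
        """Node ids overlapping the interval (nodes are disjoint, sorted)."""
        if iv.chrom not in self._starts:
            return np.empty(0, dtype=int)
        starts, ends = self._starts[iv.chrom], self._ends[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return self._ids[iv.chrom][lo:hi]


def evaluate_anchors(
    predicted: Sequence[LoopRecord],
    positives: Sequence[LoopRecord],
    negatives: Sequence[LoopRecord],
) -> tuple[PerformanceSummary, pd.DataFrame]:
    """Anchor-usage evaluation over a probability-threshold sweep.

    Each labeled anchor's score is the highest probability among predicted
    loops whose anchor overlaps it (0 when none); sweeping the threshold over
    these scores reproduces the "anchor predicted at probability >= t"
    protocol.  Returns the summary plus the explicit threshold curve
    (degenerate zero-prediction points are skipped).
    """
    universe = _AnchorUniverse(positives, negatives)
    labels = universe.labels
    scores = np.zeros(len(labels))
    for lp in predicted:
        p = lp.probability if lp.probability is not None else 0.0
        for iv in (lp.anchor1, lp.anchor2):
            for i in universe.query(iv):
                scores[i] = max(scores[i], p)
    rows = []
    for t in sorted({float(s) for s in scores}, reverse=True):
        pred = scores >= t
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue  # undefined precision: skipped point
        tp = int((pred & (labels == 1)).sum())
        rows.append(
            {
                "threshold": t,
                "precision": tp / n_pred,
                "recall": tp / max(int((labels == 1).sum()), 1),
            }
        )
    summary = _summary_from_scores(labels, scores)
    return summary, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome-wide de novo prediction
# ---------------------------------------------------------------------------


def scan_genome(
    model: LoopClassifier,
    sites: Sequence[BindingSite],
    bundle: DataBundle,
    p_cutoff: float = 0.5,
    config: FeatureConfig | None = None,
    min_length: int = MIN_LOOP_LENGTH,
    max_length: int = MAX_LOOP_LENGTH,
    chunk_size: int = 5000,
) -> list[LoopRecord]:
    """Score every same-chromosome site pair within the length bounds.

    Candidates are featurized and scored in chunks so memory stays bounded;
    pairs with probability >= ``p_cutoff`` are returned as predicted loops.
    """
    featurizer = LoopFeaturizer(bundle, config).fit()
    by_chrom: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    predicted: list[LoopRecord] = []
    chunk: list[LoopRecord] = []

    def _flush() -> None:
        if not chunk:
            return
        X = featurizer.transform(chunk)
        probs = model.predict_probability(X)
        for lp, p in zip(chunk, probs):
            if p >= p_cutoff:
                lp.probability = float(p)
                predicted.append(lp)
        chunk.clear()

    for chrom in sorted(by_chrom):
        lst = sorted(by_chrom[chrom], key=lambda s: s.summit)
        summits = np.asarray([s.summit for s in lst])
        for i, s in enumerate(lst):
            hi = int(np.searchsorted(summits, s.summit + max_length, side="right"))
            lo = int(np.searchsorted(summits, s.summit + min_length, side="left"))
            for j in range(lo, hi):
                chunk.append(
                    LoopRecord(
                        s.extent,
                        lst[j].extent,
                        summit1=s.summit,
                        summit2=lst[j].summit,
                    )
                )
                if len(chunk) >= chunk_size:
                    _flush()
    _flush()
    return predicted


def categorize_predictions(
    predicted: Sequence[LoopRecord],
    chiapet_calls: Sequence[LoopRecord],
    fdr_max: float = 0.05,
    min_pet: int = 2,
) -> tuple[list[SupportCategory], dict[str, float]]:
    """Classify each prediction by its level of ChIA-PET support.

    ``chiapet_calls`` should include sub-threshold loops (PET >= 1).  Returns
    per-loop categories plus summary fractions.
    """
    index = LoopIndex(list(chiapet_calls))
    cats: list[SupportCategory] = []
    for lp in predicted:
        best = index.best_match(lp)
        if best is None or (best.pet_count or 0) == 0:
            cats.append(SupportCategory.NO_SUPPORT)
        elif (
            best.fdr is not None
            and best.fdr <= fdr_max
            and (best.pet_count or 0) >= min_pet
        ):
            cats.append(SupportCategory.SIGNIFICANT)
        else:
            cats.append(SupportCategory.WITH_EVIDENCE)
    n = max(len(cats), 1)
    fractions = {
        c.value: sum(1 for x in cats if x is c) / n for c in SupportCategory
    }
    return cats, fractions


# ---------------------------------------------------------------------------
# Hi-C validation
# ---------------------------------------------------------------------------


def hic_support_test(
    loops: Sequence[LoopRecord],
    matrices: Mapping[str, "ContactMatrix"],
    chrom_sizes: Mapping[str, int],
    n_controls: int | None = None,
    seed: int = 0,
    return_controls: bool = False,
):
    """Compare loop contact frequencies against length-matched random controls.

    Each loop contributes the KR-normalised contact value at its summit bin
    pair.  Controls reuse every loop's exact length with a uniformly random
    start on the same chromosome, so the control length distribution matches
    the loop length distribution exactly (``n_controls`` defaults to one
    control per loop; larger values cycle through the loops).  Returns the
    two frequency samples and the one-sided Mann–Whitney U p-value for loops
    having higher contact than controls.
    """
    from .io import ContactMatrix  # noqa: F401  (typing only)

    rng = np.random.default_rng(seed)
    loop_vals = []
    for lp in loops:
        mat = matrices.get(lp.chrom)
        if mat is None:
            continue
        v = mat.normalized_at(lp.summit1, lp.summit2)
        if np.isfinite(v):
            loop_vals.append(v)
    if not loop_vals:
        raise ValueError("no loop has a defined KR-normalised contact value")
    n_controls = n_controls if n_controls is not None else len(loops)
    control_vals: list[float] = []
    control_loops: list[LoopRecord] = []
    k = 0
    attempts = 0
    max_attempts = 100 * max(n_controls, 1)
    while len(control_vals) < n_controls and attempts < max_attempts:
        attempts += 1
        lp = loops[k % len(loops)]
        mat = matrices.get(lp.chrom)
        size = chrom_sizes[lp.chrom]
        length = lp.length
        if mat is None or size <= length:
            k += 1
            continue
        start = int(rng.integers(0, size - length))
        v = mat.normalized_at(start, start + length)
        if np.isfinite(v):
            control_vals.append(v)
            control_loops.append(
                LoopRecord(
                    GenomicInterval(lp.chrom, max(0, start - 500), start + 500),
                    GenomicInterval(lp.chrom, start + length - 500, start + length + 500),
                    summit1=start,
                    summit2=start + length,
                )
            )
            k += 1
    if not control_vals:
        raise ValueError("could not sample controls with defined KR values")
    loop_arr = np.asarray(loop_vals)
    ctrl_arr = np.asarray(control_vals)
    _, p = mannwhitneyu(loop_arr, ctrl_arr, alternative="greater")
    if return_controls:
        return loop_arr, ctrl_arr, float(p), control_loops
    return loop_arr, ctrl_arr, float(p)


def thin_pet_counts(
    chiapet_calls: Sequence[LoopRecord],
    fraction: float = 0.15,
    seed: int = 0,
) -> list[LoopRecord]:
    """Binomially thin PET counts — the desk-scale library down-sampling
    surrogate.  Each loop's count becomes Binomial(pet, fraction); loops
    falling to zero PETs are dropped.  Deterministic per seed."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(chiapet_calls)
    rng = np.random.default_rng(seed)
    out = []
    for lp in chiapet_calls:
        if lp.pet_count is None:
            raise ValueError("loop record missing PET count")
        new = int(rng.binomial(lp.pet_count, fraction))
        if new > 0:
            out.append(
                LoopRecord(
                    lp.anchor1,
                    lp.anchor2,
                    pet_count=new,
                    fdr=lp.fdr,
                    probability=lp.probability,
                    label=lp.label,
                    summit1=lp.summit1,
                    summit2=lp.summit2,
                )
            )
    return out
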