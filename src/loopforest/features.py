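"""The loop feature schema and its featurizer.

Every candidate loop is summarised by genomic scalars (length, motif
orientation code, motif strength, sequence conservation), gene expression
inside the loop, and — for each DNase/ChIP track — five signal summaries:
local average and spread over the two anchors, average over the loop
interior, and the two flanking windows from each anchor out to the nearest
CTCF-binding event.  Under the canonical 14-track configuration this yields
7 + 14 x 5 = 77 features.

``LoopFeaturizer`` is a scikit-learn transformer: ``transform`` maps a list
of :class:`~loopforest.core.LoopRecord` to a feature ``DataFrame`` whose
column order is fixed by the :class:`FeatureConfig` and persisted with any
trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import GenomicInterval, LoopRecord
from .io import ConservationTrack, ExpressionRecord, SignalTrack, rpkm
from .sites import BindingSite

CANONICAL_TRACKS = (
    "CTCF",
    "RAD21",
    "DNase",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K27ac",
    "H3K9ac",
    "H3K27me3",
    "H3K36me3",
    "H3K9me3",
    "H3K79me2",
    "H4K20me1",
    "H2A.Z",
)

TRACK_FEATURES = ("local_avg", "local_std", "in_between", "flank_left", "flank_right")

__all__ = [
    "FeatureConfig",
    "DataBundle",
    "LoopFeaturizer",
    "featurize",
    "motif_orientation_code",
    "local_features",
    "in_between_feature",
    "flanking_features",
    "expression_feature",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature schema: track list, toggles, and window sizes (bp)."""

    tracks: tuple[str, ...] = CANONICAL_TRACKS
    use_motif: bool = True
    use_conservation: bool = True
    use_expression: bool = True
    local_flank: int = 2000
    motif_flank: int = 1000
    conservation_flank: int = 20
    promoter_flank: int = 2000
    flank_fallback: int = 10_000

    def feature_names(self) -> list[str]:
        names = ["length"]
        if self.use_motif:
            names += ["motif_orientation", "motif_strength_avg", "motif_strength_std"]
        if self.use_conservation:
            names += ["conservation_avg", "conservation_std"]
        if self.use_expression:
            names += ["expression_in_between"]
        for t in self.tracks:
            names += [f"{t}_{f}" for f in TRACK_FEATURES]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


@dataclass
class DataBundle:
    """Everything the featurizer quantifies: masked signal tracks, CTCF
    binding sites (motifs attached), conservation scores, and expression."""

    tracks: Mapping[str, SignalTrack]
    ctcf_sites: Sequence[BindingSite]
    conservation: ConservationTrack | None = None
    expression: Sequence[ExpressionRecord] | None = None


def motif_orientation_code(anchor1: BindingSite | None, anchor2: BindingSite | None) -> int:
    """Encode the motif-orientation pattern of a loop's two anchors.

    0: neither anchor has a motif; 1: exactly one anchor has a motif;
    2: divergent (left −, right +); 3: tandem (same strand);
    4: convergent (left +, right −).  ``anchor1`` must be the left anchor.
    """
    s1 = anchor1.motif_strand if anchor1 else None
    s2 = anchor2.motif_strand if anchor2 else None
    if s1 is None and s2 is None:
        return 0
    if s1 is None or s2 is None:
        return 1
    if s1 == "+" and s2 == "-":
        return 4
    if s1 == "-" and s2 == "+":
        return 2
    return 3


def _pair_stats(v1: float, v2: float) -> tuple[float, float]:
    """Mean and population standard deviation of a pair."""
    return (v1 + v2) / 2.0, abs(v1 - v2) / 2.0


def local_features(
    loop: LoopRecord, track: SignalTrack, flank: int = 2000
) -> tuple[float, float]:
    """Mean and population std of the anchor RPKMs (summit ± ``flank``)."""
    vals = []
    for summit in (loop.summit1, loop.summit2):
        win = GenomicInterval(loop.chrom, max(0, summit - flank), summit + flank)
        vals.append(rpkm(track, win))
    return _pair_stats(*vals)


def in_between_feature(loop: LoopRecord, track: SignalTrack) -> float:
    """RPKM over the inter-summit span of the loop."""
    if loop.length <= 0:
        raise ValueError("loop length must be positive")
    return rpkm(track, GenomicInterval(loop.chrom, loop.summit1, loop.summit2))


def flanking_features(
    loop: LoopRecord,
    track: SignalTrack,
    ctcf_sites: Sequence[BindingSite],
    fallback: int = 10_000,
) -> tuple[float, float]:
    """RPKM from each anchor out to the nearest outside CTCF-binding event.

    When no CTCF site exists beyond an anchor, a ``fallback``-bp window is
    used instead (chromosome-edge behaviour).
    """
    summits = np.asarray(
        sorted(s.summit for s in ctcf_sites if s.chrom == loop.chrom), dtype=np.int64
    )
    i = int(np.searchsorted(summits, loop.summit1, side="left")) - 1
    left_lo = int(summits[i]) if i >= 0 else max(0, loop.summit1 - fallback)
    j = int(np.searchsorted(summits, loop.summit2, side="right"))
    right_hi = int(summits[j]) if j < len(summits) else loop.summit2 + fallback
    left = rpkm(track, GenomicInterval(loop.chrom, left_lo, loop.summit1)) if left_lo < loop.summit1 else 0.0
    right = rpkm(track, GenomicInterval(loop.chrom, loop.summit2, right_hi)) if right_hi > loop.summit2 else 0.0
    return left, right


def expression_feature(
    loop: LoopRecord, expression: Sequence[ExpressionRecord], promoter_flank: int = 2000
) -> float:
    """Average FPKM of genes whose full promoter (TSS ± flank) lies inside
    the inter-summit span; 0 when no such gene exists."""
    vals = [
        r.fpkm
        for r in expression
        if r.tss.chrom == loop.chrom
        and r.promoter(promoter_flank).start >= loop.summit1
        and r.promoter(promoter_flank).end <= loop.summit2
    ]
    return float(np.mean(vals)) if vals else 0.0


class LoopFeaturizer(TransformerMixin, BaseEstimator):
    """Transform loops into the fixed-order feature matrix.

    Parameters
    ----------
    bundle
        The data bundle to quantify.  Tracks listed in ``config.tracks`` must
        all be present.
    config
        Feature schema; defaults to the canonical 77-feature configuration.
    """

    def __init__(self, bundle: DataBundle | None = None, config: FeatureConfig | None = None):
        self.bundle = bundle
        self.config = config

    # -- scikit-learn plumbing ---------------------------------------------
    def fit(self, X=None, y=None) -> "LoopFeaturizer":
        cfg = self.config or FeatureConfig()
        if self.bundle is None:
            raise ValueError("LoopFeaturizer requires a DataBundle")
        missing = [t for t in cfg.tracks if t not in self.bundle.tracks]
        if missing:
            raise ValueError(f"missing tracks in bundle: {', '.join(missing)}")
        self.config_ = cfg
        self.feature_names_ = cfg.feature_names()
        self._index_sites()
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    # -- internals ---------------------------------------------------------
    def _index_sites(self) -> None:
        by_chrom: dict[str, list[BindingSite]] = {}
        for s in self.bundle.ctcf_sites:
            by_chrom.setdefault(s.chrom, []).append(s)
        self._sites_by_chrom: dict[str, list[BindingSite]] = {}
        self._summits_by_chrom: dict[str, np.ndarray] = {}
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda s: s.summit)
            self._sites_by_chrom[chrom] = lst
            self._summits_by_chrom[chrom] = np.asarray([s.summit for s in lst], dtype=np.int64)
        if self.bundle.expression:
            expr: dict[str, list[ExpressionRecord]] = {}
            for r in self.bundle.expression:
                expr.setdefault(r.tss.chrom, []).append(r)
            for lst in expr.values():
                lst.sort(key=lambda r: r.tss.start)
            self._expr_by_chrom = {
                c: (np.asarray([r.tss.start for r in lst]), lst) for c, lst in expr.items()
            }
        else:
            self._expr_by_chrom = {}

    def _site_for_anchor(self, anchor: GenomicInterval, summit: int) -> BindingSite | None:
        """Site whose ±500 bp extent overlaps the anchor, nearest to its summit."""
        lst = self._sites_by_chrom.get(anchor.chrom)
        if not lst:
            return None
        summits = self._summits_by_chrom[anchor.chrom]
        lo = int(np.searchsorted(summits, anchor.start - 1000))
        hi = int(np.searchsorted(summits, anchor.end + 1000))
        best, best_d = None, None
        for s in lst[lo:hi]:
            if s.extent.overlaps(anchor):
                d = abs(s.summit - summit)
                if best_d is None or d < best_d:
                    best, best_d = s, d
        return best

    def _genomic_block(self, loops: Sequence[LoopRecord]) -> dict[str, np.ndarray]:
        cfg = self.config_
        n = len(loops)
        cols: dict[str, np.ndarray] = {"length": np.array([lp.length for lp in loops], dtype=float)}
        cons = self.bundle.conservation
        if cfg.use_motif:
            orient = np.zeros(n)
            m_avg = np.zeros(n)
            m_std = np.zeros(n)
        if cfg.use_conservation:
            c_avg = np.zeros(n)
            c_std = np.zeros(n)
        if cfg.use_expression:
            expr = np.zeros(n)
        for i, lp in enumerate(loops):
            if cfg.use_motif or cfg.use_conservation:
                site1 = self._site_for_anchor(lp.anchor1, lp.summit1)
                site2 = self._site_for_anchor(lp.anchor2, lp.summit2)
            if cfg.use_motif:
                orient[i] = motif_orientation_code(site1, site2)
                sc1 = site1.motif_score if site1 else 0.0
                sc2 = site2.motif_score if site2 else 0.0
                m_avg[i], m_std[i] = _pair_stats(sc1, sc2)
            if cfg.use_conservation:
                if cons is not None:
                    f = cfg.conservation_flank
                    v = []
                    for summit in (lp.summit1, lp.summit2):
                        win = GenomicInterval(lp.chrom, max(0, summit - f), summit + f)
                        v.append(cons.mean(win))
                    c_avg[i], c_std[i] = _pair_stats(*v)
            if cfg.use_expression:
                chrom_expr = self._expr_by_chrom.get(lp.chrom)
                if chrom_expr is not None:
                    tss, lst = chrom_expr
                    pf = cfg.promoter_flank
                    lo = int(np.searchsorted(tss, lp.summit1 + pf))
                    hi = int(np.searchsorted(tss, lp.summit2 - pf, side="right"))
                    vals = [
                        r.fpkm
                        for r in lst[lo:hi]
                        if r.promoter(pf).start >= lp.summit1 and r.promoter(pf).end <= lp.summit2
                    ]
                    expr[i] = float(np.mean(vals)) if vals else 0.0
        if cfg.use_motif:
            cols["motif_orientation"] = orient
            cols["motif_strength_avg"] = m_avg
            cols["motif_strength_std"] = m_std
        if cfg.use_conservation:
            cols["conservation_avg"] = c_avg
            cols["conservation_std"] = c_std
        if cfg.use_expression:
            cols["expression_in_between"] = expr
        return cols

    def _track_block(self, loops: Sequence[LoopRecord], name: str) -> dict[str, np.ndarray]:
        cfg = self.config_
        track = self.bundle.tracks[name]
        reads = track.reads
        lib_m = reads.library_size / 1e6
        n = len(loops)
        s1 = np.array([lp.summit1 for lp in loops], dtype=np.int64)
        s2 = np.array([lp.summit2 for lp in loops], dtype=np.int64)
        chroms = np.array([lp.chrom for lp in loops])
        out = {f"{name}_{f}": np.zeros(n) for f in TRACK_FEATURES}
        for chrom in np.unique(chroms):
            m = chroms == chrom
            a, b = s1[m], s2[m]
            f = cfg.local_flank
            lo1, hi1 = np.maximum(0, a - f), a + f
            lo2, hi2 = np.maximum(0, b - f), b + f
            r1 = reads.count(chrom, lo1, hi1) / ((hi1 - lo1) / 1000.0 * lib_m)
            r2 = reads.count(chrom, lo2, hi2) / ((hi2 - lo2) / 1000.0 * lib_m)
            out[f"{name}_local_avg"][m] = (r1 + r2) / 2.0
            out[f"{name}_local_std"][m] = np.abs(r1 - r2) / 2.0
            span = np.maximum(b - a, 1)
            out[f"{name}_in_between"][m] = reads.count(chrom, a, b) / (span / 1000.0 * lib_m)
            summits = self._summits_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            if len(summits):
                li = np.searchsorted(summits, a, side="left") - 1
                left_lo = np.where(
                    li >= 0, summits[np.maximum(li, 0)], np.maximum(0, a - cfg.flank_fallback)
                )
                rj = np.searchsorted(summits, b, side="right")
                right_hi = np.where(
                    rj < len(summits),
                    summits[np.minimum(rj, len(summits) - 1)],
                    b + cfg.flank_fallback,
                )
            else:
                left_lo = np.maximum(0, a - cfg.flank_fallback)
                right_hi = b + cfg.flank_fallback
            lw = np.maximum(a - left_lo, 1)
            rw = np.maximum(right_hi - b, 1)
            out[f"{name}_flank_left"][m] = np.where(
                a > left_lo, reads.count(chrom, left_lo, a) / (lw / 1000.0 * lib_m), 0.0
            )
            out[f"{name}_flank_right"][m] = np.where(
                right_hi > b, reads.count(chrom, b, right_hi) / (rw / 1000.0 * lib_m), 0.0
            )
        return out

    def transform(self, X: Sequence[LoopRecord]) -> pd.DataFrame:
        """Featurize loops into a DataFrame with the configured column order."""
        if not hasattr(self, "config_"):
            self.fit()
        loops = list(X)
        cols = self._genomic_block(loops)
        for name in self.config_.tracks:
            cols.update(self._track_block(loops, name))
        df = pd.DataFrame(cols, columns=self.feature_names_)
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("non-finite feature values produced")
        return df


def featurize(
    loops: Sequence[LoopRecord],
    bundle: DataBundle,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`LoopFeaturizer`."""
    return LoopFeaturizer(bundle, config).fit().transform(loops)
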