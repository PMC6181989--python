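"""CTCF binding sites: construction from peaks, motif attachment, and
cross-cell-type repertoire comparison.

A binding site is a peak summit extended by ±500 bp; its intensity is the
RPKM of the (masked) CTCF reads over summit ± 2 kb, and its motif is the
highest-scoring occurrence within summit ± 1 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np

from .core import GenomicInterval
from .io import PeakRecord, SignalTrack, rpkm

SITE_HALF_WIDTH = 500
INTENSITY_FLANK = 2000
MOTIF_FLANK = 1000

__all__ = [
    "MotifOccurrence",
    "BindingSite",
    "build_sites",
    "attach_best_motif",
    "attach_motifs",
    "classify_sites_across_celltypes",
    "relative_fluctuation",
]


@dataclass(frozen=True)
class MotifOccurrence:
    """A stranded motif match with its FIMO-style score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif occurrence must be stranded")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class BindingSite:
    """A CTCF peak summit with ±500 bp extent, signal intensity and best motif."""

    chrom: str
    summit: int
    extent: GenomicInterval
    intensity: float = 0.0
    best_motif: MotifOccurrence | None = None

    @property
    def motif_strand(self) -> str | None:
        return self.best_motif.interval.strand if self.best_motif else None

    @property
    def motif_score(self) -> float:
        """Motif-strength feature value; 0 when the site has no occurrence."""
        return self.best_motif.score if self.best_motif else 0.0


def build_sites(
    peaks: Sequence[PeakRecord],
    ctcf_track: SignalTrack | None = None,
    half_width: int = SITE_HALF_WIDTH,
    intensity_flank: int = INTENSITY_FLANK,
) -> list[BindingSite]:
    """One site per peak: extent = summit ± ``half_width`` (clipped at 0),
    intensity = RPKM of CTCF reads over summit ± ``intensity_flank``.

    Sites are returned sorted by (chrom, summit) regardless of input order.
    """
    sites = []
    for pk in peaks:
        if not (pk.interval.start <= pk.summit < pk.interval.end):
            raise ValueError(f"summit outside peak bounds: {pk}")
        chrom = pk.interval.chrom
        extent = GenomicInterval(chrom, max(0, pk.summit - half_width), pk.summit + half_width)
        intensity = 0.0
        if ctcf_track is not None:
            win = GenomicInterval(
                chrom, max(0, pk.summit - intensity_flank), pk.summit + intensity_flank
            )
            intensity = rpkm(ctcf_track, win)
        sites.append(BindingSite(chrom, pk.summit, extent, intensity))
    sites.sort(key=lambda s: (s.chrom, s.summit))
    return sites


def attach_best_motif(
    site: BindingSite,
    motifs: Sequence[MotifOccurrence],
    flank: int = MOTIF_FLANK,
) -> BindingSite:
    """Attach the best-scoring occurrence overlapping summit ± ``flank``.

    Score ties are broken by distance of the occurrence midpoint to the
    summit (nearest wins), then by leftmost coordinate.
    """
    lo, hi = site.summit - flank, site.summit + flank
    best: MotifOccurrence | None = None
    best_key = None
    for m in motifs:
        if m.interval.chrom != site.chrom:
            continue
        if m.interval.start >= hi or m.interval.end <= lo:
            continue
        key = (-m.score, abs(m.midpoint - site.summit), m.interval.start)
        if best_key is None or key < best_key:
            best, best_key = m, key
    return replace(site, best_motif=best)


def attach_motifs(
    sites: Sequence[BindingSite],
    motifs: Sequence[MotifOccurrence],
    flank: int = MOTIF_FLANK,
) -> list[BindingSite]:
    """Vector form of :func:`attach_best_motif` using a per-chromosome index."""
    by_chrom: dict[str, list[MotifOccurrence]] = {}
    for m in motifs:
        by_chrom.setdefault(m.interval.chrom, []).append(m)
    for lst in by_chrom.values():
        lst.sort(key=lambda m: m.interval.start)
    out = []
    for site in sites:
        cand = by_chrom.get(site.chrom, [])
        # narrow with bisect on start coordinates
        starts = [m.interval.start for m in cand]
        lo = np.searchsorted(starts, site.summit - flank - 10_000)
        hi = np.searchsorted(starts, site.summit + flank)
        out.append(attach_best_motif(site, cand[lo:hi], flank))
    return out


def classify_sites_across_celltypes(
    site_sets: Sequence[Sequence[BindingSite]],
) -> "pd.DataFrame":
    """Classify the union of sites by presence/absence across cell types.

    For k cell types each union site receives a pattern like ``"++-"``
    (2^k − 1 non-empty groups); presence means its ±500 bp extent overlaps
    >= 1 bp with a site of that cell type.  Union sites are seeded from each
    cell type's own repertoire in turn (a site already claimed by an earlier
    cell type — extent overlap — is not re-added), matching a prioritised
    ordering: within a group, sites are sorted by the first present cell
    type's intensity, descending.
    """
    import pandas as pd

    if len(site_sets) < 2:
        raise ValueError("need at least two cell types")
    k = len(site_sets)
    union: list[BindingSite] = []
    for sites in site_sets:
        for s in sites:
            if not any(s.extent.overlaps(u.extent) for u in union if u.chrom == s.chrom):
                union.append(s)
    rows = []
    for u in union:
        pattern = ""
        intensities = []
        for sites in site_sets:
            hit = [s for s in sites if s.chrom == u.chrom and s.extent.overlaps(u.extent)]
            pattern += "+" if hit else "-"
            intensities.append(max((s.intensity for s in hit), default=np.nan))
        rows.append(
            {
                "chrom": u.chrom,
                "summit": u.summit,
                "pattern": pattern,
                **{f"intensity_{i}": v for i, v in enumerate(intensities)},
            }
        )
    df = pd.DataFrame(rows)
    # prioritised descending-intensity ordering within each group
    sort_cols = [f"intensity_{i}" for i in range(k)]
    df = df.sort_values(
        ["pattern"] + sort_cols, ascending=[True] + [False] * k, na_position="last"
    ).reset_index(drop=True)
    return df


def relative_fluctuation(v1: float, v2: float) -> float:
    """Ratio of the population standard deviation to the mean of a pair.

    For two non-negative values this is ``|v1 - v2| / (v1 + v2)``, a
    scale-invariant dissimilarity in [0, 1].
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("intensities must be non-negative")
    if v1 == 0 and v2 == 0:
        raise ValueError("relative fluctuation undefined for a zero pair")
    return abs(v1 - v2) / (v1 + v2)
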