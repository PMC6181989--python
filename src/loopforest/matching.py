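"""Loop-to-loop matching: both anchors must overlap by >= 1 bp."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import LoopRecord

__all__ = ["LoopIndex", "match_loops"]


class LoopIndex:
    """Per-chromosome vectorised index of reference loops.

    A query loop matches a reference loop when query.anchor1 overlaps
    ref.anchor1 AND query.anchor2 overlaps ref.anchor2 (both by >= 1 bp,
    anchors left-right normalised on both sides).
    """

    def __init__(self, reference: Sequence[LoopRecord]):
        self._by_chrom: dict[str, tuple[np.ndarray, list[LoopRecord]]] = {}
        buf: dict[str, list[LoopRecord]] = {}
        for lp in reference:
            buf.setdefault(lp.chrom, []).append(lp)
        for chrom, loops in buf.items():
            arr = np.array(
                [
                    (l.anchor1.start, l.anchor1.end, l.anchor2.start, l.anchor2.end)
                    for l in loops
                ],
                dtype=np.int64,
            )
            self._by_chrom[chrom] = (arr, loops)

    def matches(self, query: LoopRecord) -> list[LoopRecord]:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        arr, loops = entry
        m = (
            (arr[:, 0] < query.anchor1.end)
            & (arr[:, 1] > query.anchor1.start)
            & (arr[:, 2] < query.anchor2.end)
            & (arr[:, 3] > query.anchor2.start)
        )
        return [loops[i] for i in np.flatnonzero(m)]

    def best_match(self, query: LoopRecord) -> LoopRecord | None:
        """Among all matches, the one with the highest PET count."""
        hits = self.matches(query)
        if not hits:
            return None
        return max(hits, key=lambda l: (l.pet_count if l.pet_count is not None else -1))

    def __contains__(self, query: LoopRecord) -> bool:
        return bool(self.matches(query))


def match_loops(query: LoopRecord, reference: Sequence[LoopRecord] | LoopIndex) -> LoopRecord | None:
    """Best-matching reference loop (highest PET count) or ``None``."""
    index = reference if isinstance(reference, LoopIndex) else LoopIndex(list(reference))
    return index.best_match(query)
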