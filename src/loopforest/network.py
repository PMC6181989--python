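"""The CTCF-mediated interaction network: anchors as nodes, loops as edges.

Anchors overlapping by >= 1 bp are merged transitively into one node; for
genomic intervals this transitive closure is exactly interval merging.
Hubs are the top decile of nodes by degree (distinct neighbours), with ties
broken by CTCF binding intensity.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import GenomicInterval, LoopRecord, merge_intervals

__all__ = [
    "build_graph",
    "identify_hubs",
    "degree_distribution",
    "hub_conservation",
    "export_graph",
]


def build_graph(
    loops: Sequence[LoopRecord],
    intensity_of: Callable[[GenomicInterval], float] | None = None,
) -> nx.Graph:
    """Merge loop anchors into nodes and connect them by loops.

    Node attributes: ``interval`` (the merged anchor region) and
    ``intensity`` (CTCF binding intensity from ``intensity_of``, default 0).
    Parallel loops between the same node pair collapse into one edge with a
    ``multiplicity`` attribute; self-edges (both anchors in one merged node)
    are not created.
    """
    anchors = [a for lp in loops for a in (lp.anchor1, lp.anchor2)]
    graph = nx.Graph()
    if not anchors:
        return graph
    nodes = merge_intervals(anchors)
    starts: dict[str, np.ndarray] = {}
    ids: dict[str, list[int]] = {}
    for i, node in enumerate(nodes):
        ids.setdefault(node.chrom, []).append(i)
    for chrom, idx in ids.items():
        starts[chrom] = np.asarray([nodes[i].start for i in idx])
    for i, node in enumerate(nodes):
        graph.add_node(
            i,
            interval=node,
            intensity=float(intensity_of(node)) if intensity_of else 0.0,
        )

    def node_of(iv: GenomicInterval) -> int:
        j = int(np.searchsorted(starts[iv.chrom], iv.start, side="right")) - 1
        j = max(j, 0)
        node_id = ids[iv.chrom][j]
        if not nodes[node_id].overlaps(iv):  # anchor starts before first node
            node_id = ids[iv.chrom][min(j + 1, len(ids[iv.chrom]) - 1)]
        return node_id

    for lp in loops:
        u, v = node_of(lp.anchor1), node_of(lp.anchor2)
        if u == v:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["multiplicity"] += 1
        else:
            graph.add_edge(u, v, multiplicity=1)
    return graph


def identify_hubs(graph: nx.Graph, top_frac: float = 0.10) -> tuple[list[int], list[int]]:
    """Top and bottom deciles of nodes by (degree desc, intensity desc).

    Degree counts distinct neighbour nodes.  Requires >= 10 nodes so the
    deciles are non-degenerate.
    """
    n = graph.number_of_nodes()
    if n < 10:
        raise ValueError(f"hub analysis needs >= 10 nodes, got {n}")
    ranked = sorted(
        graph.nodes,
        key=lambda u: (-graph.degree(u), -graph.nodes[u]["intensity"]),
    )
    k = int(np.floor(top_frac * n))
    k = max(k, 1)
    return ranked[:k], ranked[-k:]


def degree_distribution(graph: nx.Graph) -> dict[int, int]:
    """Counts per node degree; values sum to the node count."""
    return dict(sorted(Counter(dict(graph.degree).values()).items()))


def _interval_overlap_count(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Number of intervals in ``a`` overlapping >= 1 interval of ``b``."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b) if b else []:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    n = 0
    for iv in a:
        regs = by_chrom.get(iv.chrom, [])
        if any(iv.overlaps(r) for r in regs):
            n += 1
    return n


def hub_conservation(
    anchor_sets: Mapping[str, Sequence[GenomicInterval]],
) -> "pd.DataFrame":
    """Pairwise (and, for three cells, three-way) anchor-sharing fractions.

    For each ordered pair (A, B), the fraction of A's anchors overlapping
    >= 1 bp with an anchor of B.  Apply separately to hub and non-hub anchor
    sets to compare their conservation.
    """
    import pandas as pd

    names = list(anchor_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 cell types")
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            na = len(anchor_sets[a])
            shared = _interval_overlap_count(anchor_sets[a], anchor_sets[b])
            rows.append(
                {"from": a, "to": b, "n": na, "shared": shared,
                 "fraction": shared / na if na else float("nan")}
            )
    if len(names) >= 3:
        first = names[0]
        shared_all = sum(
            1
            for iv in anchor_sets[first]
            if all(
                _interval_overlap_count([iv], anchor_sets[other]) for other in names[1:]
            )
        )
        na = len(anchor_sets[first])
        rows.append(
            {"from": first, "to": "+".join(names[1:]), "n": na, "shared": shared_all,
             "fraction": shared_all / na if na else float("nan")}
        )
    return pd.DataFrame(rows)


def export_graph(graph: nx.Graph, edge_path, node_path) -> None:
    """Plain-text export (edge list + node attributes) for external viewers."""
    with open(node_path, "w") as fh:
        fh.write("node\tchrom\tstart\tend\tdegree\tintensity\n")
        for u in graph.nodes:
            iv = graph.nodes[u]["interval"]
            fh.write(
                f"{u}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{graph.degree(u)}"
                f"\t{graph.nodes[u]['intensity']:.6g}\n"
            )
    with open(edge_path, "w") as fh:
        fh.write("node1\tnode2\tmultiplicity\n")
        for u, v, d in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{d['multiplicity']}\n")
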