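"""Combinatorial invariants of the bare graph entering the null moments.

The variance of every edge-count statistic under random recoloring is
driven by how pairs of edges sit relative to each other: adjacent pairs
(wedges, i.e. copies of P3) versus disjoint pairs (copies of 2K2).  The
isolated-node variance additionally needs, for every non-adjacent node
pair at distance 2, the size of the intersection of their neighborhoods.
All counts are exact Python integers — C(m, 2) overflows fixed-width
arithmetic at social-network scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping

from .graph import ColoredGraph

__all__ = [
    "GraphInvariants",
    "compute_invariants",
    "count_2k2",
    "count_p3",
    "dist2_common_neighbors",
]


@dataclass(frozen=True)
class GraphInvariants:
    n: int
    m: int
    degrees: Mapping[str, int]
    degree_histogram: Mapping[int, int]
    pi3: int
    two_k2: int
    #: unordered non-adjacent pairs with >= 1 common neighbor -> |N(u) ∩ N(v)|
    dist2_common: Mapping[tuple[str, str], int]


def count_p3(graph: ColoredGraph) -> int:
    """Number of (not necessarily induced) P3 subgraphs: Σ_v C(deg v, 2)."""
    return sum(comb(len(nbrs), 2) for nbrs in graph.adjacency.values())


def count_2k2(graph: ColoredGraph) -> int:
    """Number of 2K2 subgraphs (disjoint edge pairs): C(m, 2) − π3."""
    value = comb(graph.m, 2) - count_p3(graph)
    assert value >= 0
    return value


def dist2_common_neighbors(graph: ColoredGraph) -> dict[tuple[str, str], int]:
    """Common-neighbor counts for non-adjacent pairs at distance 2.

    Enumerates wedges around each center (cost Σ deg(v)²) accumulating
    per-pair counts, then discards pairs that are themselves edges.
    """
    counts: dict[tuple[str, str], int] = {}
    for center, nbrs in graph.adjacency.items():
        ordered = sorted(nbrs)
        for a in range(len(ordered)):
            u = ordered[a]
            for b in range(a + 1, len(ordered)):
                v = ordered[b]
                key = (u, v)
                counts[key] = counts.get(key, 0) + 1
    return {
        pair: c for pair, c in counts.items() if not graph.has_edge(*pair)
    }


def compute_invariants(graph: ColoredGraph) -> GraphInvariants:
    degrees = {v: graph.degree(v) for v in graph.nodes}
    hist: dict[int, int] = {}
    for d in degrees.values():
        hist[d] = hist.get(d, 0) + 1
    pi3 = count_p3(graph)
    return GraphInvariants(
        n=graph.n,
        m=graph.m,
        degrees=degrees,
        degree_histogram=hist,
        pi3=pi3,
        two_k2=comb(graph.m, 2) - pi3,
        dist2_common=dist2_common_neighbors(graph),
    )
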