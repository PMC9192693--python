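"""Colored-graph generators for testing and calibration.

Planted-partition graphs give tunable homophily: intra-class node pairs
are joined independently with probability ``p_in``, inter-class pairs
with ``p_out``.  With ``p_in = p_out`` the coloring carries no
structural information, which is exactly the recoloring null — the
calibration fixture.  ``p_in > p_out`` plants homophily, ``p_out >
p_in`` heterophily; both directions are legal.

Also here: a small worked pair of monochromatic graphs with identical
intra-class edge counts but isolated-node counts differing by a factor
of exactly 2, showing that edge density alone does not determine how
*concentrated* homophily is:

    A = K_p + K̄_{2p}          (one clique, 2p isolated nodes)
    B = K_{p−1} + K_{1,p−1} + K̄_p   (clique, star, p isolated nodes)

Both have C(p−1, 2) + (p−1) = C(p, 2) edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ColoredGraph, ColorProfile

__all__ = ["PlantedPartitionSpec", "example1_pair", "planted_partition"]


@dataclass(frozen=True)
class PlantedPartitionSpec:
    profile: ColorProfile
    p_in: float
    p_out: float
    seed: int

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability, got {p}")


def planted_partition(
    spec: PlantedPartitionSpec, *, drop_isolated: bool = False
) -> ColoredGraph:
    """Sample a planted-partition colored graph.

    Node names are ``<label><index>`` per class; isolated nodes are kept
    by default (the null model does not require dropping them).  With
    ``drop_isolated`` a class emptied by the removal raises — re-seed or
    raise the edge probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    prof = spec.profile
    nodes: list[str] = []
    colors: dict[str, str] = {}
    for lab, c in prof.counts:
        for k in range(c):
            name = f"{lab}{k:03d}"
            nodes.append(name)
            colors[name] = lab
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    labels = np.array([colors[v] for v in nodes])
    same = labels[iu] == labels[ju]
    p = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    edges = [(nodes[a], nodes[b]) for a, b in zip(iu[keep], ju[keep])]
    if drop_isolated:
        touched = {w for e in edges for w in e}
        kept = {v: c for v, c in colors.items() if v in touched}
        if set(kept.values()) != set(prof.labels):
            missing = set(prof.labels) - set(kept.values())
            raise ValueError(
                f"isolated-node removal emptied class(es) {sorted(missing)}; "
                "re-seed or increase the edge probabilities"
            )
        return ColoredGraph(tuple(kept), tuple(edges), kept)
    return ColoredGraph(tuple(nodes), tuple(edges), colors)


def example1_pair(p: int, *, color: str = "i") -> tuple[ColoredGraph, ColoredGraph]:
    """The (K_p + K̄_{2p},  K_{p−1} + K_{1,p−1} + K̄_p) pair, monochromatic.

    Equal intra-class edge counts for every p ≥ 2, yet the first graph
    has exactly twice as many isolated nodes as the second.
    """
    if p < 2:
        raise ValueError("need p >= 2")

    def graph(parts: list[list[tuple[str, str]]], nodes: list[str]) -> ColoredGraph:
        colors = {v: color for v in nodes}
        edges = tuple(e for part in parts for e in part)
        return ColoredGraph(tuple(nodes), edges, colors)

    # A: clique on p nodes plus 2p isolated nodes
    a_clique = [f"a{k:02d}" for k in range(p)]
    a_iso = [f"x{k:02d}" for k in range(2 * p)]
    a_edges = [
        (a_clique[i], a_clique[j]) for i in range(p) for j in range(i + 1, p)
    ]
    graph_a = graph([a_edges], a_clique + a_iso)

    # B: clique on p−1 nodes, star K_{1,p−1}, p isolated nodes
    b_clique = [f"b{k:02d}" for k in range(p - 1)]
    hub = "h00"
    leaves = [f"l{k:02d}" for k in range(p - 1)]
    b_iso = [f"y{k:02d}" for k in range(p)]
    b_edges = [
        (b_clique[i], b_clique[j]) for i in range(p - 1) for j in range(i + 1, p - 1)
    ] + [(hub, leaf) for leaf in leaves]
    graph_b = graph([b_edges], b_clique + [hub] + leaves + b_iso)
    return graph_a, graph_b
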