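"""Shared fixtures: small colored graphs and oracle-comparison helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from recolor import (
    ColoredGraph,
    ColorProfile,
    build_colored_graph,
    compute_invariants,
    edge_count_variance,
    enumerate_null,
    expected_edge_count,
    expected_isolated,
    isolated_variance,
)


@pytest.fixture
def path3_split():
    """Path a-b-c colored (1, 2, 1): both edges bichromatic."""
    return build_colored_graph(
        {"a": "1", "b": "2", "c": "1"}, [("a", "b"), ("b", "c")]
    )


@pytest.fixture
def path3_pair():
    """Path a-b-c colored (1, 1, 2): one monochromatic edge."""
    return build_colored_graph(
        {"a": "1", "b": "1", "c": "2"}, [("a", "b"), ("b", "c")]
    )


@pytest.fixture
def triangle():
    return build_colored_graph(
        {"a": "1", "b": "1", "c": "1"}, [("a", "b"), ("b", "c"), ("a", "c")]
    )


def random_graph(n: int, p: float, rng: np.random.Generator) -> ColoredGraph:
    """Erdős–Rényi structure with a throwaway monochromatic coloring."""
    nodes = [f"v{k:02d}" for k in range(n)]
    edges = [
        (nodes[a], nodes[b])
        for a, b in itertools.combinations(range(n), 2)
        if rng.random() < p
    ]
    colors = {v: "0" for v in nodes}
    return ColoredGraph(tuple(nodes), tuple(edges), colors)


def partitions_up_to_3(n: int):
    """Unordered positive partitions of n into at most 3 parts."""
    out = [(n,)]
    for a in range(1, n // 2 + 1):
        out.append((n - a, a))
    for a in range(1, n + 1):
        for b in range(a, (n - a) // 2 + 1):
            c = n - a - b
            if c >= b:
                out.append((c, b, a))
    return out


def make_profile(sizes) -> ColorProfile:
    return ColorProfile.from_mapping({f"c{k}": c for k, c in enumerate(sizes)})


def assert_moments_match_oracle(graph: ColoredGraph, profile: ColorProfile):
    """Exact rational equality of every closed-form moment vs enumeration."""
    null = enumerate_null(graph, profile)
    inv = compute_invariants(graph)
    n, m = graph.n, graph.m
    for (i, j), summary in null.edge_stats.items():
        same = i == j
        c_i = profile[i]
        c_j = 0 if same else profile[j]
        assert expected_edge_count(n, m, c_i, c_j, same_color=same) == summary.mean, (
            f"E[m({i},{j})] mismatch on n={n} m={m} profile={profile.sizes}"
        )
        assert (
            edge_count_variance(n, m, inv.pi3, c_i, c_j, same_color=same)
            == summary.variance
        ), f"var[m({i},{j})] mismatch on n={n} m={m} profile={profile.sizes}"
    for lab, summary in null.iso_stats.items():
        c_i = profile[lab]
        assert expected_isolated(graph, inv, c_i=c_i) == summary.mean, (
            f"E[l({lab})] mismatch on n={n} m={m} profile={profile.sizes}"
        )
        assert isolated_variance(graph, inv, c_i=c_i) == summary.variance, (
            f"var[l({lab})] mismatch on n={n} m={m} profile={profile.sizes}"
        )
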