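"""Ground truth for the analytic moments: enumeration and Monte Carlo.

The null model is the uniform distribution over all colorings of V(G)
with a fixed profile c — there are n!/(c_1!···c_s!) of them.  For tiny
graphs every coloring can be enumerated and the joint distribution of
all edge counts m_{i,j} and isolated counts l_i obtained exactly (in
rational arithmetic); for larger graphs a seeded vectorized sampler
recolors the graph uniformly and reports empirical moments with
standard errors.  The closed-form moments in :mod:`recolor.moments` and
:mod:`recolor.isolation` are validated against both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .graph import ColoredGraph, ColorProfile, profile as _profile

__all__ = [
    "NullDistribution",
    "StatSummary",
    "count_colorings",
    "enumerate_null",
    "monte_carlo_null",
    "sample_coloring",
]

DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class StatSummary:
    mean: Fraction | float
    variance: Fraction | float
    se_mean: Optional[float] = None  # Monte Carlo only
    se_var: Optional[float] = None


@dataclass
class NullDistribution:
    """Null law of (all m_{i,j}, all l_i) for one graph and profile."""

    source: str  # "exact" | "monte_carlo"
    labels: tuple[str, ...]
    edge_stats: dict[tuple[str, str], StatSummary]
    iso_stats: dict[str, StatSummary]
    #: exact mode only: joint pmf keyed by ((m_{i,j} per cell), (l_i per color))
    joint_pmf: Optional[dict[tuple[tuple[int, ...], tuple[int, ...]], Fraction]] = None
    reps: Optional[int] = None
    seed: Optional[int] = None

    @property
    def cell_order(self) -> list[tuple[str, str]]:
        return [
            (self.labels[a], self.labels[b])
            for a in range(len(self.labels))
            for b in range(a, len(self.labels))
        ]

    def edge_pmf(self, i: str, j: str) -> dict[int, Fraction]:
        """Exact marginal pmf of m_{i,j}."""
        if self.joint_pmf is None:
            raise ValueError("marginal pmfs require the exact oracle")
        idx = self.cell_order.index((min(i, j), max(i, j)))
        out: dict[int, Fraction] = {}
        for (cells, _), p in self.joint_pmf.items():
            out[cells[idx]] = out.get(cells[idx], Fraction(0)) + p
        return out

    def iso_pmf(self, i: str) -> dict[int, Fraction]:
        """Exact marginal pmf of l_i."""
        if self.joint_pmf is None:
            raise ValueError("marginal pmfs require the exact oracle")
        idx = self.labels.index(i)
        out: dict[int, Fraction] = {}
        for (_, iso), p in self.joint_pmf.items():
            out[iso[idx]] = out.get(iso[idx], Fraction(0)) + p
        return out


def count_colorings(profile: ColorProfile) -> int:
    """Multinomial coefficient n!/(c_1!···c_s!), exact."""
    out = math.factorial(profile.n)
    for c in profile.sizes:
        out //= math.factorial(c)
    return out


def _index_structure(graph: ColoredGraph):
    pos = {v: k for k, v in enumerate(graph.nodes)}
    edges = [(pos[u], pos[v]) for u, v in graph.edges]
    adj = [[pos[w] for w in graph.adjacency[v]] for v in graph.nodes]
    return edges, adj


def _statistics(codes: Sequence[int], edges, adj, s: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(m_{i,j} per cell in (i<=j) order, l_i per color) for one coloring."""
    cells = [0] * (s * (s + 1) // 2)
    # position of unordered pair (a, b), a <= b, in row-major upper triangle
    offset = [a * s - a * (a - 1) // 2 for a in range(s)]
    for u, v in edges:
        a, b = codes[u], codes[v]
        if a > b:
            a, b = b, a
        cells[offset[a] + b - a] += 1
    iso = [0] * s
    for v, nbrs in enumerate(adj):
        cv = codes[v]
        if all(codes[w] != cv for w in nbrs):
            iso[cv] += 1
    return tuple(cells), tuple(iso)


def enumerate_null(
    graph: ColoredGraph,
    profile: ColorProfile | None = None,
    *,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> NullDistribution:
    """Exact null distribution by enumerating every c-coloring.

    Only the graph *structure* and the profile matter; the graph's own
    coloring is ignored.  Iterates distinct multiset permutations (not
    all n! orderings), so the cost is exactly the multinomial count.
    """
    from sympy.utilities.iterables import multiset_permutations

    prof = profile or _profile(graph)
    if prof.n != graph.n:
        raise ValueError("profile does not sum to the node count")
    total = count_colorings(prof)
    if total > cap:
        raise ValueError(
            f"{total} colorings exceed the enumeration cap ({cap}); "
            "use monte_carlo_null instead"
        )
    edges, adj = _index_structure(graph)
    s = prof.s
    multiset = [k for k, c in enumerate(prof.sizes) for _ in range(c)]
    joint: dict[tuple[tuple[int, ...], tuple[int, ...]], int] = {}
    for codes in multiset_permutations(multiset):
        key = _statistics(codes, edges, adj, s)
        joint[key] = joint.get(key, 0) + 1
    assert sum(joint.values()) == total

    cell_order = [
        (prof.labels[a], prof.labels[b])
        for a in range(s)
        for b in range(a, s)
    ]
    edge_stats = {}
    for idx, pair in enumerate(cell_order):
        tot = sum(cnt * cells[idx] for (cells, _), cnt in joint.items())
        tot2 = sum(cnt * cells[idx] ** 2 for (cells, _), cnt in joint.items())
        mean = Fraction(tot, total)
        edge_stats[pair] = StatSummary(mean=mean, variance=Fraction(tot2, total) - mean**2)
    iso_stats = {}
    for idx, lab in enumerate(prof.labels):
        tot = sum(cnt * iso[idx] for (_, iso), cnt in joint.items())
        tot2 = sum(cnt * iso[idx] ** 2 for (_, iso), cnt in joint.items())
        mean = Fraction(tot, total)
        iso_stats[lab] = StatSummary(mean=mean, variance=Fraction(tot2, total) - mean**2)
    pmf = {key: Fraction(cnt, total) for key, cnt in joint.items()}
    return NullDistribution(
        source="exact",
        labels=prof.labels,
        edge_stats=edge_stats,
        iso_stats=iso_stats,
        joint_pmf=pmf,
    )


def sample_coloring(
    nodes: Sequence[str], profile: ColorProfile, rng: np.random.Generator
) -> dict[str, str]:
    """One uniform c-coloring: an unbiased shuffle of the color multiset."""
    if len(nodes) != profile.n:
        raise ValueError("profile does not sum to the node count")
    multiset = [lab for lab, c in profile.counts for _ in range(c)]
    perm = rng.permutation(len(multiset))
    return {v: multiset[perm[k]] for k, v in enumerate(nodes)}


def monte_carlo_null(
    graph: ColoredGraph,
    profile: ColorProfile | None = None,
    *,
    reps: int,
    seed: int,
) -> NullDistribution:
    """Empirical null moments from ``reps`` uniform recolorings.

    Vectorized: each recoloring costs O(n + m) numpy work.  Standard
    errors accompany each moment — the mean's as s/√R, the variance
    estimator's from the fourth central moment:
    Var(s²) ≈ (m4 − s⁴(R−3)/(R−1))/R.
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    prof = profile or _profile(graph)
    if prof.n != graph.n:
        raise ValueError("profile does not sum to the node count")
    rng = np.random.default_rng(seed)
    eu, ev, _, _ = graph.index_arrays()
    s = prof.s
    n = graph.n
    base = np.repeat(np.arange(s), prof.sizes)
    ncells = s * (s + 1) // 2
    offset = np.array([a * s - a * (a - 1) // 2 for a in range(s)])
    edge_samples = np.empty((reps, ncells), dtype=np.float64)
    iso_samples = np.empty((reps, s), dtype=np.float64)
    for r in range(reps):
        col = base[rng.permutation(n)]
        a = col[eu]
        b = col[ev]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        edge_samples[r] = np.bincount(offset[lo] + hi - lo, minlength=ncells)
        same = lo == hi
        cnt = np.bincount(eu[same], minlength=n) + np.bincount(ev[same], minlength=n)
        iso_samples[r] = np.bincount(col[cnt == 0], minlength=s)

    def summarize(x: np.ndarray) -> StatSummary:
        mean = float(x.mean())
        var = float(x.var(ddof=1))
        centered = x - mean
        m4 = float((centered**4).mean())
        se_var = math.sqrt(
            max(0.0, (m4 - var**2 * (reps - 3) / (reps - 1)) / reps)
        )
        return StatSummary(
            mean=mean,
            variance=var,
            se_mean=math.sqrt(var / reps),
            se_var=se_var,
        )

    cell_order = [
        (prof.labels[a], prof.labels[b]) for a in range(s) for b in range(a, s)
    ]
    edge_stats = {pair: summarize(edge_samples[:, k]) for k, pair in enumerate(cell_order)}
    iso_stats = {lab: summarize(iso_samples[:, k]) for k, lab in enumerate(prof.labels)}
    return NullDistribution(
        source="monte_carlo",
        labels=prof.labels,
        edge_stats=edge_stats,
        iso_stats=iso_stats,
        reps=reps,
        seed=seed,
    )
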