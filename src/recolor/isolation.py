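"""Moments of per-class isolated-node counts under random recoloring.

A node of color ``i`` is *i-isolated* when none of its neighbors has
color ``i`` — in a homophilic network such nodes are rarer than chance.
Writing ``L^i`` for their number under a uniformly random recoloring
with profile ``c``:

    E[L^i]   = (c_i/n) · Σ_v  (n−c_i)^d(v)_ / (n−1)^d(v)_
    var(L^i) = E[L^i](1 − E[L^i])
               + (c_i^2_/n^2_) · Σ_{(u,v): u≠v, uv∉E}  (n−c_i)^b(u,v)_ / (n−2)^b(u,v)_

with ``b(u,v) = |N(u) ∪ N(v)|`` and the pair sum running over *ordered*
non-adjacent pairs (each unordered pair contributes twice).  The
ordered convention is pinned by exact enumeration: on the 3-path with
c_i = 2 the variance is 8/9, which only the ordered sum reproduces.

Note ``E(1 − E)`` is not a Bernoulli variance and may be negative when
E > 1; no clamping is applied — only the total must be ≥ 0.

The naive pair sum costs O(n²) set unions.  The efficient path
regroups it as

    [all ordered pairs, by degree histogram]
    − [ordered adjacent pairs]
    − [ordered distance-2 pairs: correction from b = d(u)+d(v) down to
       d(u)+d(v) − |N(u) ∩ N(v)|]

for a total cost O(Σ deg(v)² + D²) with D the number of distinct
degrees.  Also here: the hypergeometric law of the number of color-i
nodes in a fixed set of t nodes (e.g. a neighborhood).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import pandas as pd

from .graph import ColoredGraph, profile as _profile
from .invariants import GraphInvariants, compute_invariants
from .moments import falling_power, _ratio

__all__ = [
    "IsolationMomentCell",
    "IsolationMomentTable",
    "NeighborColorDistribution",
    "expected_isolated",
    "isolated_variance",
    "isolated_variance_naive",
    "isolation_moment_table",
    "isolation_zscores",
    "neighbor_color_pmf",
    "observed_isolated_counts",
]


def observed_isolated_counts(graph: ColoredGraph) -> dict[str, int]:
    """Observed l_i: color-i nodes with no color-i neighbor, per color."""
    counts = {c: 0 for c in graph.colors}
    g = graph.coloring
    for v in graph.nodes:
        cv = g[v]
        if all(g[w] != cv for w in graph.adjacency[v]):
            counts[cv] += 1
    return counts


@dataclass(frozen=True)
class NeighborColorDistribution:
    """Law of the number of color-i nodes among a fixed t-subset.

    Drawing colors without replacement makes this hypergeometric,
    Hyp(n, c_i, t):  Pr{h} = C(t,h) · c_i^h_ · (n−c_i)^(t−h)_ / n^t_.
    """

    n: int
    c_i: int
    t: int
    pmf: dict[int, Fraction]

    @property
    def support(self) -> range:
        return range(max(0, self.t - (self.n - self.c_i)), min(self.t, self.c_i) + 1)


def neighbor_color_pmf(n: int, c_i: int, t: int) -> NeighborColorDistribution:
    if not 1 <= c_i <= n:
        raise ValueError("need 1 <= c_i <= n")
    if not 0 <= t <= n:
        raise ValueError("need 0 <= t <= n")
    pmf: dict[int, Fraction] = {}
    denom = falling_power(n, t)
    for h in range(max(0, t - (n - c_i)), min(t, c_i) + 1):
        pmf[h] = _ratio(
            math.comb(t, h) * falling_power(c_i, h) * falling_power(n - c_i, t - h),
            denom,
        )
    assert sum(pmf.values()) == 1
    return NeighborColorDistribution(n=n, c_i=c_i, t=t, pmf=pmf)


def _degree_ratio_table(n: int, c_i: int, shift: int, max_r: int) -> list[Fraction]:
    """f(r) = (n−c_i)^r_ / (n−shift)^r_ for r = 0..max_r, iterated products.

    Each new factor is (n−c_i−k)/(n−shift−k); once the numerator factor
    hits zero the value sticks at 0, which covers the 0/0 cases (the
    corresponding configurations are impossible, probability exactly 0).
    """
    vals = [Fraction(1)]
    cur: Fraction | int = Fraction(1)
    dead = False
    for k in range(max_r):
        if not dead:
            num = n - c_i - k
            if num == 0:
                dead = True
            else:
                den = n - shift - k
                if den == 0:
                    raise ZeroDivisionError(
                        f"falling-power ratio undefined at r={k + 1} "
                        f"(n={n}, c_i={c_i}, shift={shift})"
                    )
                cur = cur * Fraction(num, den)
        vals.append(Fraction(0) if dead else cur)
    return vals


def expected_isolated(
    graph: ColoredGraph, invariants: GraphInvariants | None = None, *, c_i: int
) -> Fraction:
    """E[L^i], grouped by degree: one falling-power ratio per distinct degree."""
    inv = invariants or compute_invariants(graph)
    n = inv.n
    if not 1 <= c_i <= n:
        raise ValueError("need 1 <= c_i <= n")
    max_d = max(inv.degree_histogram) if inv.degree_histogram else 0
    f = _degree_ratio_table(n, c_i, 1, max_d)
    total = sum(
        count * f[d] for d, count in inv.degree_histogram.items()
    )
    return Fraction(c_i, n) * total


def isolated_variance(
    graph: ColoredGraph, invariants: GraphInvariants | None = None, *, c_i: int
) -> Fraction:
    """var(L^i) via the histogram/wedge decomposition (see module notes)."""
    inv = invariants or compute_invariants(graph)
    n = inv.n
    if n < 2:
        raise ValueError("need n >= 2")
    expected = expected_isolated(graph, inv, c_i=c_i)
    prefactor = _ratio(falling_power(c_i, 2), falling_power(n, 2))
    if prefactor == 0:  # c_i = 1: the pair sum vanishes
        return expected * (1 - expected)

    degs = inv.degrees
    hist = inv.degree_histogram
    max_b = 2 * max(hist) if hist else 0
    f = _degree_ratio_table(n, c_i, 2, max_b)

    # ordered pairs u != v, any adjacency, b approximated as d(u)+d(v)
    all_pairs = Fraction(0)
    items = list(hist.items())
    for a, (d1, h1) in enumerate(items):
        all_pairs += h1 * (h1 - 1) * f[2 * d1]
        for d2, h2 in items[a + 1 :]:
            all_pairs += 2 * h1 * h2 * f[d1 + d2]

    # remove ordered adjacent pairs
    adjacent = 2 * sum(f[degs[u] + degs[v]] for u, v in graph.edges)

    # distance-2 pairs: replace d(u)+d(v) by the true b = d(u)+d(v)−|N(u)∩N(v)|
    correction = Fraction(0)
    for (u, v), cn in inv.dist2_common.items():
        b = degs[u] + degs[v] - cn
        assert b <= n - 2
        correction += 2 * (f[degs[u] + degs[v]] - f[b])

    pair_sum = all_pairs - adjacent - correction
    var = expected * (1 - expected) + prefactor * pair_sum
    assert var >= 0
    return var


def isolated_variance_naive(graph: ColoredGraph, *, c_i: int) -> Fraction:
    """Reference var(L^i): explicit ordered-pair loop with set unions."""
    n = graph.n
    expected = expected_isolated(graph, c_i=c_i)
    prefactor = _ratio(falling_power(c_i, 2), falling_power(n, 2))
    pair_sum = Fraction(0)
    nodes = graph.nodes
    for u in nodes:
        for v in nodes:
            if u == v or graph.has_edge(u, v):
                continue
            b = len(graph.adjacency[u] | graph.adjacency[v])
            pair_sum += _ratio(falling_power(n - c_i, b), falling_power(n - 2, b))
    return expected * (1 - expected) + prefactor * pair_sum


@dataclass
class IsolationMomentCell:
    observed: int
    expected: Fraction
    variance: Fraction
    zscore: Optional[float] = None


@dataclass
class IsolationMomentTable:
    labels: tuple[str, ...]
    cells: dict[str, IsolationMomentCell] = field(default_factory=dict)

    def zscore_vector(self) -> pd.Series:
        return pd.Series(
            {
                lab: (c.zscore if c.zscore is not None else float("nan"))
                for lab, c in self.cells.items()
            },
            name="z0",
        ).reindex(list(self.labels))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lab in self.labels:
            cell = self.cells[lab]
            rows.append(
                {
                    "color": lab,
                    "observed": cell.observed,
                    "expected": float(cell.expected),
                    "variance": float(cell.variance),
                    "zscore": float("nan") if cell.zscore is None else cell.zscore,
                    "defined": cell.zscore is not None,
                }
            )
        return pd.DataFrame(rows)


def isolation_moment_table(
    graph: ColoredGraph, invariants: GraphInvariants | None = None
) -> IsolationMomentTable:
    inv = invariants or compute_invariants(graph)
    prof = _profile(graph)
    observed = observed_isolated_counts(graph)
    table = IsolationMomentTable(labels=prof.labels)
    for lab in prof.labels:
        c_i = prof[lab]
        expected = expected_isolated(graph, inv, c_i=c_i)
        variance = isolated_variance(graph, inv, c_i=c_i)
        cell = IsolationMomentCell(
            observed=observed[lab], expected=expected, variance=variance
        )
        if variance > 0:
            cell.zscore = float(observed[lab] - expected) / math.sqrt(variance)
        table.cells[lab] = cell
    return table


def isolation_zscores(graph: ColoredGraph) -> pd.Series:
    """z0 vector: z0[i] = (l_i − E[L^i]) / sqrt(var L^i), NaN when var = 0."""
    return isolation_moment_table(graph).zscore_vector()
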