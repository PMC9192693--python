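"""First and second moments of intra/inter-class edge counts under recoloring.

Under a uniformly random coloring with fixed profile ``c``, the number
``M^{i,j}`` of edges whose endpoints get colors ``{i, j}`` is a sum of
exchangeable edge indicators.  Because colors are drawn *without
replacement*, ordinary powers are replaced by falling powers
``a^r_ = a(a−1)...(a−r+1)`` throughout:

    E[M^{i,i}] = m · c_i^2_ / n^2_
    E[M^{i,j}] = 2m · c_i c_j / n^2_            (i ≠ j)

and the variance picks up covariances between edge pairs, which depend
on the graph only through the wedge count π3 (adjacent pairs) and the
disjoint-pair count C(m,2) − π3:

    σ²_{i,i} = m̄(1 − m̄) + 2{ (c_i^3_/n^3_ − c_i^4_/n^4_) π3
                              + (c_i^4_/n^4_) C(m,2) }

with the analogous mixed-color bracket for i ≠ j.  Everything is
evaluated in exact rational arithmetic and converted to float only when
a z-score is formed; this keeps σ² = 0 cases exact and avoids the
catastrophic cancellation that the m̄² terms would cause in floating
point on million-edge networks.

z-scores standardize the observed counts:  Z[i,j] = (m_{i,j} − m̄)/σ.
Cells with σ = 0 (e.g. a singleton color class, or a monochromatic
graph) are *undefined*, represented as NaN and flagged — they are never
silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Optional

import pandas as pd

from .graph import ColoredGraph, ColorProfile, profile as _profile

__all__ = [
    "EdgeMomentCell",
    "EdgeMomentTable",
    "edge_count_variance",
    "edge_count_variance_via_covariances",
    "edge_moment_table",
    "edge_zscore_matrix",
    "expected_edge_count",
    "falling_power",
    "homophily_ratios",
    "observed_edge_counts",
]


def falling_power(a: int, r: int) -> int:
    """Falling r-th power a^r_ = a(a−1)...(a−r+1), with a^0_ = 1."""
    if r < 0:
        raise ValueError("falling power needs r >= 0")
    out = 1
    for k in range(r):
        out *= a - k
        if out == 0:
            return 0
    return out


def _ratio(num: int, den: int) -> Fraction:
    # 0/0 cases arise when an impossible event (more distinct nodes than n)
    # would carry coefficient 0 anyway; they are exactly 0.
    if num == 0:
        return Fraction(0)
    return Fraction(num, den)


def _check_pair(n: int, c_i: int, c_j: int, same_color: bool) -> None:
    if n < 2:
        raise ValueError("need n >= 2")
    if c_i < 1 or (not same_color and c_j < 1):
        raise ValueError("color classes must be nonempty")
    if same_color:
        if c_i > n:
            raise ValueError("c_i exceeds n")
    elif c_i + c_j > n:
        raise ValueError("c_i + c_j exceeds n")


def expected_edge_count(
    n: int, m: int, c_i: int, c_j: int = 0, *, same_color: bool
) -> Fraction:
    """E[M^{i,i}] = m·c_i^2_/n^2_ or E[M^{i,j}] = 2m·c_i·c_j/n^2_."""
    _check_pair(n, c_i, c_j, same_color)
    if same_color:
        return m * _ratio(falling_power(c_i, 2), falling_power(n, 2))
    return 2 * m * _ratio(c_i * c_j, falling_power(n, 2))


def edge_count_variance(
    n: int, m: int, pi3: int, c_i: int, c_j: int = 0, *, same_color: bool
) -> Fraction:
    """Variance of M^{i,i} / M^{i,j}, exactly as the closed form states."""
    _check_pair(n, c_i, c_j, same_color)
    if not 0 <= pi3 <= comb(m, 2):
        raise ValueError("pi3 must lie in [0, C(m,2)]")
    mbar = expected_edge_count(n, m, c_i, c_j, same_color=same_color)
    if same_color:
        r3 = _ratio(falling_power(c_i, 3), falling_power(n, 3))
        r4 = _ratio(falling_power(c_i, 4), falling_power(n, 4))
        bracket = (r3 - r4) * pi3 + r4 * comb(m, 2)
    else:
        r3 = _ratio(
            c_i * falling_power(c_j, 2) + falling_power(c_i, 2) * c_j,
            falling_power(n, 3),
        )
        r4 = 4 * _ratio(
            falling_power(c_i, 2) * falling_power(c_j, 2), falling_power(n, 4)
        )
        bracket = (r3 - r4) * pi3 + r4 * comb(m, 2)
    return mbar * (1 - mbar) + 2 * bracket


def edge_count_variance_via_covariances(
    n: int, m: int, pi3: int, c_i: int, c_j: int = 0, *, same_color: bool
) -> Fraction:
    """Same variance assembled as Σ var + 2·Σ cov over edge pairs.

    var(M) = m·p(1−p) + 2[π3·(p_adj − p²) + (C(m,2) − π3)·(p_disj − p²)]
    where p, p_adj, p_disj are the probabilities that one edge, a wedge,
    and a disjoint edge pair are fully (i,j)-colored.  Algebraically
    identical to :func:`edge_count_variance`; kept as an independent
    transcription guard.
    """
    _check_pair(n, c_i, c_j, same_color)
    two_k2 = comb(m, 2) - pi3
    if same_color:
        p = _ratio(falling_power(c_i, 2), falling_power(n, 2))
        p_adj = _ratio(falling_power(c_i, 3), falling_power(n, 3))
        p_disj = _ratio(falling_power(c_i, 4), falling_power(n, 4))
    else:
        p = 2 * _ratio(c_i * c_j, falling_power(n, 2))
        p_adj = _ratio(
            c_i * falling_power(c_j, 2) + falling_power(c_i, 2) * c_j,
            falling_power(n, 3),
        )
        p_disj = 4 * _ratio(
            falling_power(c_i, 2) * falling_power(c_j, 2), falling_power(n, 4)
        )
    return m * p * (1 - p) + 2 * (pi3 * (p_adj - p * p) + two_k2 * (p_disj - p * p))


def observed_edge_counts(graph: ColoredGraph) -> dict[tuple[str, str], int]:
    """Observed m_{i,j} on unordered color pairs (i ≤ j), single edge pass."""
    labels = graph.colors
    counts = {
        (i, j): 0 for a, i in enumerate(labels) for j in labels[a:]
    }
    g = graph.coloring
    for u, v in graph.edges:
        i, j = sorted((g[u], g[v]))
        counts[(i, j)] += 1
    return counts


@dataclass
class EdgeMomentCell:
    observed: int
    expected: Fraction
    variance: Fraction
    ratio: Optional[float] = None  # ω_i on the diagonal, η_{i,j} off it
    zscore: Optional[float] = None


@dataclass
class EdgeMomentTable:
    """Observed/expected/variance (and derived ratio, z) per color pair."""

    labels: tuple[str, ...]
    cells: dict[tuple[str, str], EdgeMomentCell] = field(default_factory=dict)

    def zscore_matrix(self) -> pd.DataFrame:
        """Symmetric s×s z-score matrix; undefined entries are NaN."""
        z = pd.DataFrame(
            float("nan"), index=list(self.labels), columns=list(self.labels)
        )
        for (i, j), cell in self.cells.items():
            val = cell.zscore if cell.zscore is not None else float("nan")
            z.loc[i, j] = val
            z.loc[j, i] = val
        return z

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (i, j), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "color_i": i,
                    "color_j": j,
                    "observed": cell.observed,
                    "expected": float(cell.expected),
                    "variance": float(cell.variance),
                    "ratio": float("nan") if cell.ratio is None else cell.ratio,
                    "zscore": float("nan") if cell.zscore is None else cell.zscore,
                    "defined": cell.zscore is not None,
                }
            )
        return pd.DataFrame(rows)


def edge_moment_table(
    graph: ColoredGraph, *, pi3: int | None = None
) -> EdgeMomentTable:
    """Full moment table for a colored graph: one cell per color pair i ≤ j."""
    if pi3 is None:
        from .invariants import count_p3

        pi3 = count_p3(graph)
    prof: ColorProfile = _profile(graph)
    n, m = graph.n, graph.m
    observed = observed_edge_counts(graph)
    table = EdgeMomentTable(labels=prof.labels)
    for (i, j), obs in observed.items():
        same = i == j
        c_i, c_j = prof[i], (0 if same else prof[j])
        expected = expected_edge_count(n, m, c_i, c_j, same_color=same)
        variance = edge_count_variance(n, m, pi3, c_i, c_j, same_color=same)
        cell = EdgeMomentCell(observed=obs, expected=expected, variance=variance)
        if variance > 0:
            # exact rational difference first, then one float division
            cell.zscore = float(obs - expected) / math.sqrt(variance)
        table.cells[(i, j)] = cell
    homophily_ratios(table)
    return table


def homophily_ratios(table: EdgeMomentTable) -> EdgeMomentTable:
    """Fill ω_i = m_{i,i}/m̄_{i,i} and η_{i,j} = m_{i,j}/m̄_{i,j} in place.

    Cells with expected 0 (degenerate classes, c_i = 1 on the diagonal)
    stay undefined — undefined is a value here, not an error.
    """
    for cell in table.cells.values():
        if cell.expected > 0:
            cell.ratio = cell.observed / float(cell.expected)
        else:
            cell.ratio = None
    return table


def edge_zscore_matrix(graph: ColoredGraph) -> pd.DataFrame:
    """Symmetric s×s matrix of edge-count z-scores, NaN where σ = 0."""
    return edge_moment_table(graph).zscore_matrix()
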