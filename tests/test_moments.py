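"""Closed-form edge-count moments, ratios and z-scores."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recolor import (
    build_colored_graph,
    edge_count_variance,
    edge_moment_table,
    edge_zscore_matrix,
    expected_edge_count,
    falling_power,
    observed_edge_counts,
)
from recolor.graph import ColoredGraph
from recolor.moments import edge_count_variance_via_covariances

from conftest import make_profile, random_graph


class TestFallingPower:
    @pytest.mark.parametrize(
        "a,r,out", [(5, 2, 20), (3, 0, 1), (2, 4, 0), (10, 3, 720), (0, 1, 0)]
    )
    def test_examples(self, a, r, out):
        assert falling_power(a, r) == out

    @settings(max_examples=50, derandomize=True)
    @given(a=st.integers(0, 30), r=st.integers(0, 10))
    def test_recurrence(self, a, r):
        assert falling_power(a, r + 1) == falling_power(a, r) * (a - r)


class TestObservedCounts:
    def test_bichromatic_path(self, path3_split):
        assert observed_edge_counts(path3_split) == {
            ("1", "1"): 0, ("1", "2"): 2, ("2", "2"): 0
        }

    def test_mixed_path(self, path3_pair):
        counts = observed_edge_counts(path3_pair)
        assert counts[("1", "1")] == 1 and counts[("1", "2")] == 1

    def test_monochromatic(self, triangle):
        assert observed_edge_counts(triangle) == {("1", "1"): 3}


class TestClosedForms:
    """Frozen values from exhaustive enumeration of the 3 colorings of a
    3-path with profile (2, 1): m_11 takes values {1, 0, 1}, m_12 {1, 2, 1}."""

    def test_expected_same_color(self):
        assert expected_edge_count(3, 2, 2, same_color=True) == Fraction(2, 3)

    def test_expected_mixed(self):
        assert expected_edge_count(3, 2, 2, 1, same_color=False) == Fraction(4, 3)

    def test_singleton_class_degenerate(self):
        assert expected_edge_count(5, 4, 1, same_color=True) == 0
        assert edge_count_variance(5, 4, 3, 1, same_color=True) == 0

    def test_variance_same_color(self):
        assert edge_count_variance(3, 2, 1, 2, same_color=True) == Fraction(2, 9)

    def test_variance_mixed(self):
        assert edge_count_variance(3, 2, 1, 2, 1, same_color=False) == Fraction(2, 9)

    def test_full_class_is_constant(self):
        # c_i = n: every coloring is the constant one, M == m surely
        assert edge_count_variance(6, 7, 4, 6, same_color=True) == 0

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            expected_edge_count(3, 2, 2, 2, same_color=False)  # c_i + c_j > n
        with pytest.raises(ValueError):
            edge_count_variance(4, 3, 99, 2, same_color=True)  # pi3 > C(m,2)


@pytest.mark.parametrize("seed", range(10))
def test_printed_form_equals_covariance_decomposition(seed):
    """The closed form and the Σvar + 2Σcov assembly are the same rational."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    m = int(rng.integers(1, n * (n - 1) // 2 + 1))
    pi3 = int(rng.integers(0, math.comb(m, 2) + 1))
    c_i = int(rng.integers(1, n))
    assert edge_count_variance(
        n, m, pi3, c_i, same_color=True
    ) == edge_count_variance_via_covariances(n, m, pi3, c_i, same_color=True)
    c_j = int(rng.integers(1, n - c_i + 1))
    assert edge_count_variance(
        n, m, pi3, c_i, c_j, same_color=False
    ) == edge_count_variance_via_covariances(n, m, pi3, c_i, c_j, same_color=False)


@settings(max_examples=40, derandomize=True)
@given(
    n=st.integers(2, 60),
    m=st.integers(0, 200),
    seed=st.integers(0, 10**6),
    s=st.integers(1, 5),
)
def test_expected_counts_conserve_m(n, m, seed, s):
    """Σ_{i≤j} m̄_{i,j} = m exactly, for any profile: the falling-power
    identity Σ c_i^2_ + 2 Σ_{i<j} c_i c_j = n^2_ in disguise."""
    if s > n:
        s = n
    rng = np.random.default_rng(seed)
    cuts = sorted(rng.choice(np.arange(1, n), size=s - 1, replace=False)) if s > 1 else []
    sizes = np.diff([0, *cuts, n]).tolist()
    total = Fraction(0)
    for a in range(s):
        total += expected_edge_count(n, m, sizes[a], same_color=True)
        for b in range(a + 1, s):
            total += expected_edge_count(n, m, sizes[a], sizes[b], same_color=False)
    assert total == m


class TestZScoreMatrix:
    def test_monochromatic_is_undefined(self, triangle):
        Z = edge_zscore_matrix(triangle)
        assert Z.shape == (1, 1) and math.isnan(Z.iloc[0, 0])

    def test_path_values(self, path3_pair):
        Z = edge_zscore_matrix(path3_pair)
        assert Z.loc["1", "1"] == pytest.approx(math.sqrt(0.5))
        assert Z.loc["1", "2"] == pytest.approx(-math.sqrt(0.5))
        assert math.isnan(Z.loc["2", "2"])  # c_2 = 1 is degenerate

    def test_symmetry_and_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        g = random_graph(15, 0.3, rng)
        colors = {v: f"c{k % 3}" for k, v in enumerate(g.nodes)}
        g = ColoredGraph(g.nodes, g.edges, colors)
        Z = edge_zscore_matrix(g)
        assert np.allclose(Z.values, Z.values.T, equal_nan=True)
        # relabel colors: the matrix must follow the relabeling
        perm = {"c0": "q2", "c1": "q0", "c2": "q1"}
        g2 = ColoredGraph(g.nodes, g.edges, {v: perm[c] for v, c in colors.items()})
        Z2 = edge_zscore_matrix(g2)
        for i in Z.index:
            for j in Z.columns:
                a, b = Z.loc[i, j], Z2.loc[perm[i], perm[j]]
                assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_ratios(self, triangle):
        table = edge_moment_table(triangle)
        assert table.cells[("1", "1")].ratio == pytest.approx(1.0)

    def test_degenerate_ratio_is_undefined(self, path3_pair):
        table = edge_moment_table(path3_pair)
        assert table.cells[("2", "2")].ratio is None


def test_table_sums_match_graph_totals():
    rng = np.random.default_rng(11)
    g = random_graph(20, 0.25, rng)
    colors = {v: f"c{k % 4}" for k, v in enumerate(g.nodes)}
    g = ColoredGraph(g.nodes, g.edges, colors)
    table = edge_moment_table(g)
    assert sum(c.observed for c in table.cells.values()) == g.m
    assert sum(c.expected for c in table.cells.values()) == g.m
    assert all(c.variance >= 0 for c in table.cells.values())
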