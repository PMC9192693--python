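"""U-values, tail bounds, significance calls and the global index."""

import math

import numpy as np
import pandas as pd
import pytest

from recolor import (
    assess,
    build_report,
    global_homophily_index,
    j_lambda,
    multidim_bound,
    q_alpha,
    tail_bound,
    u_values,
)
from recolor.synthetic import PlantedPartitionSpec, planted_partition

from conftest import make_profile


def _zmat(values, labels=None):
    arr = np.array(values, dtype=float)
    labels = labels or [f"c{k}" for k in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


class TestUValues:
    def test_entrywise_square_inverse(self):
        u = u_values(pd.Series([2.0, 10.0]))
        assert u.tolist() == pytest.approx([0.25, 0.01])

    def test_zero_is_undefined(self):
        u = u_values(pd.Series([0.0]))
        assert math.isnan(u.iloc[0])

    def test_clamped_form(self):
        u = u_values(pd.Series([0.0, 0.5, 3.0]), clamp=True)
        assert u.tolist() == pytest.approx([1.0, 1.0, 1 / 9])


class TestTailBound:
    @pytest.mark.parametrize(
        "z,one_sided,out",
        [(3, False, 1 / 9), (3, True, 0.1), (0.5, False, 1.0), (0, False, 1.0),
         (10, False, 0.01), (float("nan"), False, 1.0)],
    )
    def test_values(self, z, one_sided, out):
        assert tail_bound(z, one_sided=one_sided) == pytest.approx(out)


class TestAssess:
    def test_uncorrected_threshold(self):
        Z = _zmat([[5.0, 0.0], [0.0, 1.0]])
        res = assess(Z, alpha=0.05)
        assert res.threshold == pytest.approx(1 / math.sqrt(0.05))
        assert res.edge_calls.loc["c0", "c0"] == "homophilic"
        assert res.edge_calls.loc["c1", "c1"] == "not-significant"

    def test_bonferroni_diagonal_family(self):
        Z = _zmat([[5.0, 0.0], [0.0, 1.0]])
        res = assess(Z, alpha=0.05, correction="bonferroni", family="diagonal")
        assert res.h == 2
        assert res.threshold == pytest.approx(math.sqrt(2 / 0.05))
        assert res.edge_calls.loc["c0", "c0"] == "not-significant"

    def test_bonferroni_all_family_counts_s_squared(self):
        Z = _zmat([[50.0, 0.0], [0.0, 1.0]])
        res = assess(Z, alpha=0.05, correction="bonferroni", family="all")
        assert res.h == 4
        assert res.edge_calls.loc["c0", "c0"] == "homophilic"

    def test_negative_z_never_significant(self):
        Z = _zmat([[1.0, -8.0], [-8.0, 1.0]])
        res = assess(Z, alpha=0.05)
        assert res.edge_calls.loc["c0", "c1"] == "not-significant"

    def test_offdiagonal_positive_is_heterophilic(self):
        Z = _zmat([[1.0, 9.0], [9.0, 1.0]])
        res = assess(Z, alpha=0.05)
        assert res.edge_calls.loc["c0", "c1"] == "heterophilic"

    def test_undefined_cells_stay_undefined(self):
        Z = _zmat([[float("nan")]])
        res = assess(Z, alpha=0.05)
        assert res.edge_calls.loc["c0", "c0"] == "undefined"

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            assess(_zmat([[1.0]]), alpha=0.0)

    def test_equivalence_with_tail_bound(self):
        """Uncorrected positive call  <=>  two-sided bound ≤ α (for z > 0)."""
        rng = np.random.default_rng(5)
        Z = _zmat(np.diag(rng.normal(0, 5, size=6)))
        alpha = 0.04
        res = assess(Z, alpha=alpha)
        for lab in Z.index:
            z = Z.loc[lab, lab]
            by_call = res.edge_calls.loc[lab, lab] == "homophilic"
            by_bound = z > 0 and tail_bound(z) <= alpha
            assert by_call == by_bound


class TestQAlphaJLambda:
    def test_both_cells_fit(self):
        Z = _zmat([[10.0, 0.0], [0.0, 10.0]])
        q, cells = q_alpha(Z, [("c0", "c0"), ("c1", "c1")], 0.02)
        assert q == 2

    def test_only_one_fits(self):
        Z = _zmat([[10.0, 0.0], [0.0, 10.0]])
        q, cells = q_alpha(Z, [("c0", "c0"), ("c1", "c1")], 0.015)
        assert q == 1 and cells == {("c0", "c0")}  # deterministic tie-break

    def test_alpha_below_min_gives_zero(self):
        Z = _zmat([[10.0]])
        assert q_alpha(Z, [("c0", "c0")], 0.005)[0] == 0

    def test_monotone_in_alpha_and_matches_jlambda(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(2, 3, size=(4, 4))
        Z = _zmat((vals + vals.T) / 2)
        Q = [(f"c{a}", f"c{b}") for a in range(4) for b in range(a, 4)]
        prev = 0
        for alpha in [0.001, 0.01, 0.05, 0.2, 0.9]:
            q, cells = q_alpha(Z, Q, alpha)
            assert q >= prev
            prev = q
            # Q(alpha) is a top-slice of Q by z: some λ reproduces it
            if cells:
                lam = min(Z.loc[i, j] for (i, j) in cells) - 1e-12
                assert cells == j_lambda(Z, lam) & set(Q)

    def test_jlambda_strict(self):
        Z = _zmat([[3.0, 0.0], [0.0, 7.0]])
        assert j_lambda(Z, 5.0) == {("c1", "c1")}
        assert j_lambda(Z, 7.0) == set()
        assert j_lambda(Z, -math.inf) == {
            ("c0", "c0"), ("c0", "c1"), ("c1", "c1")
        }


class TestGlobalIndex:
    @pytest.mark.parametrize(
        "diag,out",
        [((2.0, 2.0), 0.75), ((0.0, 0.0), 0.0), ((1.0,), 0.0)],
    )
    def test_values(self, diag, out):
        Z = _zmat(np.diag(diag))
        assert global_homophily_index(Z) == pytest.approx(out)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 4, size=(5, 5))
        Z = _zmat((vals + vals.T) / 2)
        perm = rng.permutation(5)
        labels = [f"c{k}" for k in perm]
        Zp = pd.DataFrame(Z.values[np.ix_(perm, perm)], index=labels, columns=labels)
        assert global_homophily_index(Zp) == pytest.approx(global_homophily_index(Z))

    def test_undefined_entries_reduce_s(self):
        Z = _zmat([[4.0, 0.0], [0.0, float("nan")]])
        assert global_homophily_index(Z) == pytest.approx(1 - 1 / 16)


class TestMultidimBound:
    @pytest.mark.parametrize(
        "d,t,out", [(3, 3, 1 / 3), (19, math.sqrt(19), 1.0), (1, 10, 0.01)]
    )
    def test_values(self, d, t, out):
        assert multidim_bound(d, t) == pytest.approx(out)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            multidim_bound(0, 1.0)
        with pytest.raises(ValueError):
            multidim_bound(2, 0.0)


def test_full_report_on_homophilic_fixture():
    prof = make_profile((12, 12, 12))
    g = planted_partition(PlantedPartitionSpec(prof, 0.7, 0.05, seed=21))
    report = build_report(g, alpha=0.05)
    assert 0 <= report.global_index <= 1
    assert report.global_index > 0.5  # strongly planted structure
    diag = np.diag(report.Z.values)
    assert (diag > 0).all()
    assert (report.z0.values < 0).all()  # homophily concentrates: few isolated
    assert report.metadata["n"] == 36
    assert set(report.omega.index) == set(prof.labels)
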