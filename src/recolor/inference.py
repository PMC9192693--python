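"""From z-score arrays to statistical statements.

The z-scores are distribution-free: without knowing the null law of a
standardized statistic, Čebyšëv's inequality bounds the probability of
a deviation at least as extreme as z by z⁻² (one-sided refinement:
Cantelli's (1+z²)⁻¹).  We call the entrywise arrays 1/Z² and 1/z0²
*U-value* arrays — upper bounds on the corresponding p-values.

The testing procedure is one-directional: a cell is declared
(homophilic on the diagonal, heterophilic off it) only when its z-score
exceeds 1/√α; negative z-scores, however extreme, are reported but
never declared significant.  Testing many cells at once needs a
family-wise correction; Bonferroni at family size h raises the
threshold to √(h/α).

Two joint summaries complement the per-cell calls: q(α), the largest
number of cells whose summed U-values stay within α, and the
multidimensional Čebyšëv bound d/t² on ‖X‖ for a d-vector of
standardized marginals, which yields the global homophily index

    max{0, 1 − s / ‖diag(Z)‖²}  ∈  [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .graph import ColoredGraph, ColorProfile, profile as _profile

__all__ = [
    "AssessResult",
    "HomophilyReport",
    "assess",
    "build_report",
    "global_homophily_index",
    "j_lambda",
    "multidim_bound",
    "q_alpha",
    "tail_bound",
    "u_values",
]

Cell = tuple[str, str]


def u_values(z, *, clamp: bool = False):
    """Entrywise z⁻² (Čebyšëv p-value bound).

    Undefined or zero z gives a vacuous bound: NaN by default, 1 when
    ``clamp`` is requested (also capping every entry at 1).
    """
    arr = pd.DataFrame(z) if isinstance(z, pd.DataFrame) else pd.Series(z, dtype=float)
    with np.errstate(divide="ignore"):
        u = 1.0 / (arr.astype(float) ** 2)
    if clamp:
        u = u.where(np.isfinite(u), 1.0).clip(upper=1.0)
    else:
        u = u.where(np.isfinite(u))
    return u


def tail_bound(z: float, *, one_sided: bool = False) -> float:
    """Probability bound for a deviation of size z: z⁻² or Cantelli's (1+z²)⁻¹."""
    if math.isnan(z):
        return 1.0
    if one_sided:
        return min(1.0, 1.0 / (1.0 + z * z))
    if z == 0:
        return 1.0
    return min(1.0, 1.0 / (z * z))


def multidim_bound(d: int, t: float) -> float:
    """Čebyšëv-type bound Pr{‖X‖ ≥ t} ≤ d/t² for d standardized marginals."""
    if d < 1:
        raise ValueError("need d >= 1")
    if t <= 0:
        raise ValueError("need t > 0")
    return min(1.0, d / (t * t))


@dataclass(frozen=True)
class AssessResult:
    edge_calls: pd.DataFrame  # s×s labels in {homophilic, heterophilic, not-significant, undefined}
    iso_calls: Optional[pd.Series]
    alpha: float
    correction: str
    h: int
    threshold: float


def _family_size(Z: pd.DataFrame, family) -> int:
    s = Z.shape[0]
    if family == "diagonal":
        return s
    if family == "all":
        # the full s×s matrix counted with symmetric duplicates
        return s * s
    return len(set(family))


def assess(
    Z: pd.DataFrame,
    z0: Optional[pd.Series] = None,
    *,
    alpha: float,
    correction: Literal["none", "bonferroni"] = "none",
    family: Literal["diagonal", "all"] | Iterable[Cell] = "diagonal",
) -> AssessResult:
    """Per-cell significance calls at level ``alpha``.

    A cell is positive iff z ≥ 1/√α (no correction) or z ≥ √(h/α)
    (Bonferroni over a family of h tests, i.e. individual level α/h).
    ``family`` sizes: "diagonal" → h = s; "all" → h = s² (the full
    matrix with its symmetric duplicates); or an explicit cell set.
    Diagonal positives are homophilic, off-diagonal heterophilic;
    σ = 0 cells are undefined.  One-directional by construction:
    negative z is never significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    h = _family_size(Z, family) if correction == "bonferroni" else 1
    threshold = math.sqrt(h / alpha)
    labels = list(Z.index)
    calls = pd.DataFrame("not-significant", index=labels, columns=labels)
    for i in labels:
        for j in labels:
            z = Z.loc[i, j]
            if math.isnan(z):
                calls.loc[i, j] = "undefined"
            elif z >= threshold:
                calls.loc[i, j] = "homophilic" if i == j else "heterophilic"
    iso_calls = None
    if z0 is not None:
        iso_calls = pd.Series(
            [
                "undefined"
                if math.isnan(v)
                else ("significant" if v >= threshold else "not-significant")
                for v in z0
            ],
            index=z0.index,
        )
    return AssessResult(
        edge_calls=calls,
        iso_calls=iso_calls,
        alpha=alpha,
        correction=correction,
        h=h,
        threshold=threshold,
    )


def q_alpha(
    Z: pd.DataFrame, Q: Iterable[Cell], alpha: float
) -> tuple[int, set[Cell]]:
    """Largest Q(α) ⊆ Q with Σ z⁻² ≤ α, greedy by ascending z⁻².

    Greedy inclusion of the smallest U-values maximizes cardinality.
    Cells with z ≤ 0 or undefined carry a vacuous bound (≥ 1) and never
    enter at α < 1.  Ties break by cell label order, so the result is
    deterministic.
    """
    scored = []
    for cell in Q:
        z = Z.loc[cell[0], cell[1]]
        if not math.isnan(z) and z > 0:
            scored.append((1.0 / (z * z), cell))
        else:
            scored.append((math.inf, cell))
    scored.sort(key=lambda t: (t[0], t[1]))
    total = 0.0
    chosen: set[Cell] = set()
    for u, cell in scored:
        if total + u <= alpha:
            total += u
            chosen.add(cell)
        else:
            break
    return len(chosen), chosen


def j_lambda(Z: pd.DataFrame, lam: float) -> set[Cell]:
    """Upper-triangle cells (i ≤ j) with z strictly above λ."""
    labels = list(Z.index)
    out: set[Cell] = set()
    for a, i in enumerate(labels):
        for j in labels[a:]:
            z = Z.loc[i, j]
            if not math.isnan(z) and z > lam:
                out.add((i, j))
    return out


def global_homophily_index(Z: pd.DataFrame) -> float:
    """max{0, 1 − s/‖diag(Z)‖²}: a [0, 1] summary of joint homophily.

    Undefined diagonal entries are excluded and s reduced accordingly.
    """
    diag = np.asarray(np.diag(Z.to_numpy(dtype=float)))
    defined = diag[~np.isnan(diag)]
    s_eff = defined.size
    if s_eff == 0:
        return 0.0
    norm2 = float((defined**2).sum())
    if norm2 == 0:
        return 0.0
    return max(0.0, 1.0 - s_eff / norm2)


@dataclass
class HomophilyReport:
    """Everything the method reports for one colored network."""

    Z: pd.DataFrame
    z0: pd.Series
    U: pd.DataFrame
    u0: pd.Series
    omega: pd.Series  # observed/expected intra-class edge ratios
    eta: pd.DataFrame  # observed/expected inter-class edge ratios (NaN diag)
    calls: AssessResult
    global_index: float
    edge_table: pd.DataFrame
    isolation_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def frame(df):
            return {
                "index": list(df.index),
                "columns": list(df.columns),
                "values": [
                    [None if (isinstance(x, float) and math.isnan(x)) else x for x in row]
                    for row in df.to_numpy().tolist()
                ],
            }

        def series(sr):
            return {
                k: (None if (isinstance(v, float) and math.isnan(v)) else v)
                for k, v in sr.items()
            }

        return {
            "Z": frame(self.Z),
            "z0": series(self.z0),
            "U": frame(self.U),
            "u0": series(self.u0),
            "omega": series(self.omega),
            "eta": frame(self.eta),
            "calls": frame(self.calls.edge_calls),
            "iso_calls": series(self.calls.iso_calls)
            if self.calls.iso_calls is not None
            else None,
            "alpha": self.calls.alpha,
            "correction": self.calls.correction,
            "global_index": self.global_index,
            "metadata": self.metadata,
        }


def build_report(
    graph: ColoredGraph,
    *,
    alpha: float = 0.05,
    correction: Literal["none", "bonferroni"] = "bonferroni",
    family: Literal["diagonal", "all"] | Iterable[Cell] = "diagonal",
    metadata: dict | None = None,
) -> HomophilyReport:
    """Run the full pipeline on one colored graph."""
    from .invariants import compute_invariants
    from .isolation import isolation_moment_table
    from .moments import edge_moment_table

    inv = compute_invariants(graph)
    prof: ColorProfile = _profile(graph)
    etab = edge_moment_table(graph, pi3=inv.pi3)
    itab = isolation_moment_table(graph, inv)
    Z = etab.zscore_matrix()
    z0 = itab.zscore_vector()
    labels = list(prof.labels)
    omega = pd.Series(
        {
            lab: (
                etab.cells[(lab, lab)].ratio
                if etab.cells[(lab, lab)].ratio is not None
                else float("nan")
            )
            for lab in labels
        },
        name="omega",
    )
    eta = pd.DataFrame(float("nan"), index=labels, columns=labels)
    for (i, j), cell in etab.cells.items():
        if i != j and cell.ratio is not None:
            eta.loc[i, j] = cell.ratio
            eta.loc[j, i] = cell.ratio
    calls = assess(Z, z0, alpha=alpha, correction=correction, family=family)
    meta = {
        "n": graph.n,
        "m": graph.m,
        "s": prof.s,
        "profile": dict(prof.counts),
        "pi3": inv.pi3,
        "two_k2": inv.two_k2,
    }
    if metadata:
        meta.update(metadata)
    return HomophilyReport(
        Z=Z,
        z0=z0,
        U=u_values(Z),
        u0=u_values(z0),
        omega=omega,
        eta=eta,
        calls=calls,
        global_index=global_homophily_index(Z),
        edge_table=etab.to_dataframe(),
        isolation_table=itab.to_dataframe(),
        metadata=meta,
    )
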