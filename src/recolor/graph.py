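"""Node-colored simple undirected graphs: data model and text I/O.

A *colored graph* is a pair ``(G, g)`` of a simple undirected graph ``G``
and a surjective map ``g`` from nodes to a finite set of color labels
(protein functional classes, age classes, ...).  The only attribute
information the recoloring null model retains is the *color profile*
``c = (c_1, ..., c_s)`` of class sizes, so both objects are first-class
here.

File conventions follow the two common sources of such data:

* STRING-style protein interaction dumps: a node/color table plus a
  weighted edge list with confidence scores in ``[0, 999]``, thresholded
  at a minimum weight (700 = high confidence);
* Pokec-style social profiles: a directed friendship list symmetrized to
  mutual pairs, plus free-text ages binned into half-open intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ColoredGraph",
    "ColorProfile",
    "DEFAULT_AGE_BINS",
    "DEFAULT_WEIGHT_THRESHOLD",
    "bin_ages",
    "build_colored_graph",
    "profile",
    "read_edge_list",
    "read_node_colors",
    "write_edge_list",
    "write_node_colors",
]

DEFAULT_WEIGHT_THRESHOLD = 700

#: Pokec age classes: label, inclusive lower bound, exclusive upper bound.
DEFAULT_AGE_BINS: tuple[tuple[str, float, float], ...] = (
    ("C", 12, 18),
    ("D", 18, 25),
    ("E", 25, 40),
    ("F", 40, 60),
)

_ISOFORM_SUFFIX = re.compile(r"^(?P<base>.+)_(?P<iso>\d+)$")


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ColorProfile:
    """Class-size vector ``c = (c_1, ..., c_s)``, ordered by color label.

    The profile is the sufficient statistic of the recoloring null model:
    two colorings with the same profile induce the same null distribution
    on every statistic considered here.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("profile must have at least one color class")
        labels = [lab for lab, _ in self.counts]
        if labels != sorted(labels):
            object.__setattr__(self, "counts", tuple(sorted(self.counts)))
        for lab, c in self.counts:
            if c < 1:
                raise ValueError(f"color class {lab!r} is empty (c={c})")

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "ColorProfile":
        return cls(tuple(sorted(counts.items())))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.counts)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.counts)

    @property
    def s(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        return sum(c for _, c in self.counts)

    def __getitem__(self, label: str) -> int:
        for lab, c in self.counts:
            if lab == label:
                return c
        raise KeyError(label)


@dataclass
class ColoredGraph:
    """A simple undirected graph with a total, surjective node coloring.

    Nodes and colors are opaque strings; arrays and tables produced
    downstream are always keyed by label (lexicographic order), never by
    internal index.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    coloring: dict[str, str]
    _adjacency: dict[str, set[str]] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        seen: set[tuple[str, str]] = set()
        canon = []
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has an undeclared endpoint")
            e = _canon(u, v)
            if e in seen:
                raise ValueError(f"duplicate edge {e!r}")
            seen.add(e)
            canon.append(e)
        self.nodes = tuple(sorted(node_set))
        self.edges = tuple(sorted(canon))
        missing = node_set - self.coloring.keys()
        if missing:
            raise ValueError(f"uncolored nodes: {sorted(missing)[:5]}")
        self.coloring = {v: self.coloring[v] for v in self.nodes}
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        self._adjacency = adj

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.coloring.values())))

    def neighbors(self, v: str) -> frozenset[str]:
        return frozenset(self._adjacency[v])

    def degree(self, v: str) -> int:
        return len(self._adjacency[v])

    @property
    def adjacency(self) -> Mapping[str, set[str]]:
        return self._adjacency

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adjacency.get(u, ())

    def index_arrays(self):
        """Dense integer view ``(edge_u, edge_v, color_codes, labels)``.

        Nodes are numbered by sorted label; ``color_codes[k]`` is the
        position of node ``k``'s color in the sorted label list.  Used by
        the vectorized Monte Carlo recoloring path; never exposed in
        reports.
        """
        import numpy as np

        pos = {v: k for k, v in enumerate(self.nodes)}
        labels = self.colors
        cpos = {lab: k for k, lab in enumerate(labels)}
        eu = np.array([pos[u] for u, _ in self.edges], dtype=np.int64)
        ev = np.array([pos[v] for _, v in self.edges], dtype=np.int64)
        codes = np.array([cpos[self.coloring[v]] for v in self.nodes], dtype=np.int64)
        return eu, ev, codes, labels


def profile(graph: ColoredGraph) -> ColorProfile:
    """Color profile of ``graph``, classes ordered lexicographically."""
    counts: dict[str, int] = {}
    for v in graph.nodes:
        counts[graph.coloring[v]] = counts.get(graph.coloring[v], 0) + 1
    return ColorProfile.from_mapping(counts)


# ---------------------------------------------------------------------------
# readers


def _split_rows(path: str | Path, delimiter: str | None) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            rows.append((lineno, [p.strip() for p in parts]))
    return rows


def read_node_colors(
    path: str | Path,
    *,
    delimiter: str | None = None,
    isoform_merge: bool = False,
    merge_map: Mapping[str, str] | None = None,
    fallback: str = "X",
) -> dict[str, str]:
    """Read a two-column node → color table.

    With ``isoform_merge`` on, identifiers differing only by a trailing
    ``_<integer>`` suffix (protein isoforms in STRING node files) collapse
    to the base identifier; when merged isoforms disagree on color the
    merged node falls back to ``fallback``.  ``merge_map`` relabels colors
    afterwards (e.g. the R and S classes folded into X).
    """
    rows = _split_rows(path, delimiter)
    if not rows:
        raise ValueError(f"{path}: empty node-color file")
    colors: dict[str, str] = {}
    from_isoform: set[str] = set()
    merged_conflict: set[str] = set()
    for lineno, parts in rows:
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected node and color, got {parts!r}")
        node, color = parts[0], parts[1]
        is_isoform = False
        if isoform_merge:
            mobj = _ISOFORM_SUFFIX.match(node)
            if mobj:
                node = mobj.group("base")
                is_isoform = True
        if node in colors and colors[node] != color:
            if is_isoform or node in from_isoform:
                merged_conflict.add(node)
            else:
                raise ValueError(
                    f"{path}:{lineno}: node {node!r} recolored "
                    f"{colors[node]!r} -> {color!r}"
                )
        else:
            colors[node] = color
        if is_isoform:
            from_isoform.add(node)
    for node in merged_conflict:
        colors[node] = fallback
    if merge_map:
        colors = {v: merge_map.get(c, c) for v, c in colors.items()}
    return colors


def read_edge_list(
    path: str | Path,
    *,
    delimiter: str | None = None,
    weight_threshold: int | None = DEFAULT_WEIGHT_THRESHOLD,
    directed_mutual: bool = False,
) -> set[tuple[str, str]]:
    """Read an edge list with optional integer weights.

    ``weight_threshold`` keeps rows with weight ≥ threshold (inclusive;
    applied only when a weight column exists; ``None`` disables the
    filter).  With ``directed_mutual`` the input is treated as directed
    and the undirected edge ``{u, v}`` is kept iff both ``(u, v)`` and
    ``(v, u)`` rows survive — mutual-friendship symmetrization.
    Self-loops are dropped; duplicates collapse.
    """
    rows = _split_rows(path, delimiter)
    kept: list[tuple[str, str]] = []
    for lineno, parts in rows:
        if len(parts) < 2 or len(parts) > 3:
            raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}")
        u, v = parts[0], parts[1]
        if len(parts) == 3 and weight_threshold is not None:
            try:
                w = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            if w < weight_threshold:
                continue
        if u == v:
            continue
        kept.append((u, v))
    if directed_mutual:
        arcs = set(kept)
        return {_canon(u, v) for u, v in arcs if (v, u) in arcs}
    return {_canon(u, v) for u, v in kept}


def bin_ages(
    ages: Mapping[str, object],
    *,
    bins: Sequence[tuple[str, float, float]] = DEFAULT_AGE_BINS,
    fallback_label: str = "X",
) -> dict[str, str]:
    """Map free-text ages to class labels over half-open bins ``[lo, hi)``.

    Non-numeric, missing, or out-of-range values get ``fallback_label``
    (users declaring no age, or a patently untrue one).
    """
    ivals = sorted(bins, key=lambda b: b[1])
    for (la, lo_a, hi_a), (lb, lo_b, _) in zip(ivals, ivals[1:]):
        if hi_a > lo_b:
            raise ValueError(f"overlapping age bins {la!r} and {lb!r}")
    for lab, lo, hi in ivals:
        if lo >= hi:
            raise ValueError(f"degenerate age bin {lab!r}: [{lo}, {hi})")
    out: dict[str, str] = {}
    for node, raw in ages.items():
        try:
            value = float(str(raw).strip())
        except (TypeError, ValueError):
            out[node] = fallback_label
            continue
        for lab, lo, hi in ivals:
            if lo <= value < hi:
                out[node] = lab
                break
        else:
            out[node] = fallback_label
    return out


def build_colored_graph(
    colors: Mapping[str, str],
    edges: Iterable[tuple[str, str]],
    *,
    drop_isolated: bool = True,
) -> ColoredGraph:
    """Assemble a :class:`ColoredGraph` from a color map and an edge set.

    Every edge endpoint must be colored.  With ``drop_isolated`` (the
    default) degree-0 nodes are removed before the profile is taken and
    color classes emptied by the removal vanish from the color set; the
    null model itself is agnostic, so the flag may be turned off.
    """
    edge_set = set()
    for u, v in edges:
        if u == v:
            continue
        for w in (u, v):
            if w not in colors:
                raise ValueError(f"edge endpoint {w!r} has no color")
        edge_set.add(_canon(u, v))
    if drop_isolated:
        touched = {w for e in edge_set for w in e}
        kept = {v: c for v, c in colors.items() if v in touched}
    else:
        kept = dict(colors)
    if not kept:
        raise ValueError("graph is empty after isolated-node removal")
    return ColoredGraph(tuple(kept), tuple(edge_set), kept)


# ---------------------------------------------------------------------------
# writers (round-trip with the readers above)


def write_node_colors(graph: ColoredGraph, path: str | Path, *, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in graph.nodes:
            fh.write(f"{v}{delimiter}{graph.coloring[v]}\n")


def write_edge_list(graph: ColoredGraph, path: str | Path, *, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}{delimiter}{v}\n")
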