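# Methods

## The null model

Input is a pair `(G, g)`: a simple undirected graph `G` with `n` nodes
and `m` edges, and a surjective coloring `g` of its nodes with `s`
labels. The null hypothesis keeps `G` fixed and replaces `g` by a
coloring `F` drawn uniformly from the `n!/(c_1!⋯c_s!)` colorings with
the same profile `c = (c_1, …, c_s)`. The profile is the model's
sufficient statistic: any two colorings with equal class sizes induce
the same null law on every statistic computed here. Colors are assigned
without replacement, so node-color indicators are exchangeable but not
independent; ordinary powers in binomial-style formulas become falling
powers `a^r_ = a(a−1)⋯(a−r+1)`, and the number of color-`i` nodes in any
fixed `t`-subset (e.g. a neighborhood) is hypergeometric `Hyp(n, c_i, t)`.

## Moments

*Edge counts.* `M^{i,j}` is a sum of edge indicators; its mean needs
only `n`, `m`, `c`. The variance adds covariances over edge pairs, which
come in exactly two geometries: pairs sharing a node (wedges, counted by
`π3 = Σ_v C(deg v, 2)`) and disjoint pairs (counted by `C(m,2) − π3`).
The implementation evaluates the closed form exactly as stated and,
independently, as the covariance decomposition
`m·p(1−p) + 2[π3(p_adj − p²) + (C(m,2) − π3)(p_disj − p²)]`; a test
asserts the two agree on random parameter draws, guarding against
transcription errors in either form.

*Isolated nodes.* `E[L^i]` groups nodes by degree, costing one
falling-power ratio per distinct degree. The variance pair sum runs over
**ordered** non-adjacent pairs `(u, v)` — each unordered pair counts
twice. The summation convention is not self-evident from the formula's
notation; it is pinned by the enumeration oracle (the 3-path with
`c_i = 2` has variance 8/9 only under the ordered convention). The sum
is regrouped as: all ordered pairs by degree histogram, minus adjacent
pairs, minus a distance-2 correction that replaces `deg u + deg v` by
the true `b(u,v) = deg u + deg v − |N(u) ∩ N(v)|`; total cost
`O(Σ deg(v)² + D²)` with `D` distinct degrees. A naive `O(n²)`
set-union reference implementation is kept and tested equal. Note
`E(1−E)` is not a Bernoulli variance and may be negative when `E > 1`;
it is deliberately not clamped — only the assembled variance is asserted
nonnegative.

## Numerical choices

All moments are computed in exact rational arithmetic (`fractions`),
converted to float only when a z-score is formed. This makes `σ² = 0`
cases exact (no spurious near-zero divisions) and avoids catastrophic
cancellation in `m̄(1 − m̄)` when `m̄` is of order `m`. Falling-power
ratios are iterated products of factors `(c − k)/(n − k)`; once a
numerator factor hits zero the product sticks at zero, which also
resolves the formally 0/0 terms attached to impossible configurations
(e.g. four distinct nodes in a 3-node graph — always with coefficient
zero). Cells with `σ = 0` (singleton classes, monochromatic graphs,
`c_i = n`) produce *undefined* z-scores, carried as NaN with an explicit
flag; they are reported, excluded from declarations, and never coerced
to 0.

## Inference

Čebyšëv's inequality bounds the p-value of an observed deviation by
`z⁻²` (the U-value); Cantelli's one-sided `(1 + z²)⁻¹` is available by
flag, but the two-sided form is the default. Declaration is
one-directional: only large **positive** z triggers a homophilic
(diagonal) or heterophilic (off-diagonal) call; extreme negative scores
remain descriptive. Bonferroni correction uses threshold `√(h/α)` with
`h` the family size. The conventional diagonal threshold `s/√α`
corresponds to counting the full matrix, `h = s²` (family `"all"`);
testing only the `s` diagonal cells gives the less conservative
`√(s/α)` (family `"diagonal"`, the default). Both are exposed because
the two conventions coexist in practice and differ by a factor `√s`.
`q(α)` (largest cell set with summed U-values within α) is built
greedily by ascending U-value, which maximizes cardinality; ties break
by label order for determinism. The global index
`max{0, 1 − s/‖diag(Z)‖²}` derives from the `d/t²` multidimensional
Čebyšëv bound; undefined diagonal entries are excluded with `s` reduced
accordingly.

## Oracles

Two independent ground truths validate every closed form. The exact
oracle enumerates all colorings (distinct multiset permutations, capped
at 10⁶) and produces rational moments and the joint pmf of all
`m_{i,j}` and `l_i`; the central correctness suite asserts *exact*
equality of analytic and enumerated moments on every graph with 2–5
nodes crossed with every class-size vector with ≤ 3 classes, plus 200
random 6–7-node graphs. Profiles are taken up to label permutation —
the moments depend on the sizes only, and permutation equivariance of
the z-matrix is tested separately. One-node graphs are outside the
contract (`n ≥ 2` precondition; the pair probabilities divide by
`n(n−1)`). The Monte Carlo oracle recolors vectorized (`O(n+m)` numpy
work per replicate) and reports means/variances with standard errors
(the variance estimator's SE from the fourth central moment);
agreement is required within 4 SE.

## Synthetic data

The planted-partition generator draws intra-class pairs with `p_in` and
inter-class pairs with `p_out`, independently. `p_in = p_out` realizes
the null exactly (the coloring is uninformative given the graph) and is
used for calibration: at α = 0.05 over 500 replicates (profile
(15, 15, 15), p = 0.12) the declaration rate stays below α — in fact
far below, since Čebyšëv bounds are conservative. Power is checked on a
`p_in` grid 0.05→0.4 at `p_out = 0.05` (profile (20, 20), 100
replicates per point): mean diagonal z increases strictly. Monte Carlo
consistency uses `n = 150`, profile (60, 50, 40), `p_in = 0.08`,
`p_out = 0.04`, 10⁴ recolorings — sizes chosen so the full joint check
runs in seconds while every cell keeps non-degenerate variance.
Independent-edge sampling does not emulate degree heterogeneity,
clustering or weight structure of real PPI or social networks; passing
these tests certifies the correctness and calibration of the
*statistics under the stated null*, not distributional realism of the
generator.

The worked monochromatic pair (`K_p + K̄_2p` vs
`K_{p−1} + K_{1,p−1} + K̄_p`) has equal intra-class edge counts for
every `p ≥ 2` (`C(p−1,2) + (p−1) = C(p,2)`) while the first graph has
exactly twice as many isolated nodes for `p ≥ 3` — the motivating
example for tracking `l_i` alongside edge density. The two constructions
have 3p and 3p−1 nodes as literally defined; the comparison is made on
the induced monochromatic subgraphs (edge and isolated-node counts), not
on density ratios of an ambient graph.

## Preprocessing conventions

STRING-style inputs: confidence weights in [0, 999] thresholded at a
minimum of 700 (read as inclusive, ≥ 700 — configurable, since "minimum
weight 700" admits either reading); protein isoforms (identifiers
differing only by a trailing `_<int>`) optionally merged, with
conflicting class annotations resolved to the fallback class "X"; a
color merge map (e.g. R→X, S→X) applied afterwards. Pokec-style inputs:
directed friendship lists symmetrized to mutual pairs; free-text ages
binned into [12,18), [18,25), [25,40), [40,60) with everything else —
missing, non-numeric, or implausible — in class "X". Isolated nodes are
dropped by default after assembly (classes emptied by the removal
vanish); the null model itself does not require this, so it is a flag.

## Limitations

- U-values are upper bounds, often loose; the method is conservative by
  construction, more so under Bonferroni.
- Covariances *between* cells of the z-matrix (and between `L^i` and
  `M^{i,i}`) are not modeled; joint statements rely on union bounds.
- Exact enumeration is capped (default 10⁶ colorings); beyond it only
  Monte Carlo validation is offered.
- The exact-rational isolated-node variance is designed for graphs up to
  ~10⁵ edges on commodity hardware; the edge z-scores scale much
  further (`O(n + m)`).
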