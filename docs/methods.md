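# Methods

## Edge-confidence model

The package treats a PPI network as an undirected simple graph whose edges
carry a confidence in [0, 1] assembled from two independent signals.

**Topology (resource allocation).** For an edge {i, j}, every common
neighbor u distributes a unit resource equally among its closed
neighborhood N(u) = {u} ∪ neighbors(u), so the edge collects
Σ 1/|N(u)| = Σ 1/(deg(u)+1) over u ∈ N(i) ∩ N(j).  We apply the closed
convention throughout: the endpoints i and j belong to the intersection of
their own closed neighborhoods, contributing 1/(deg(i)+1) + 1/(deg(j)+1).
This has two consequences that motivated the choice, both implemented and
unit-tested:

* an edge inside a k-clique scores exactly 1 for every k, so cliques of
  different sizes are commensurate rather than small cliques being
  systematically down-weighted;
* a bridge edge whose endpoints share no partners still scores positively
  (an isolated edge scores exactly 1), reflecting that such an edge is the
  sole conduit between its two neighborhoods.

The third-party-only (open) variant remains available via
`include_endpoints=False` on `compute_wra` and `build_weighted_network`.

The raw index can exceed 1 only on edges embedded in unusually dense
overlapping neighborhoods.  We finalize it by *saturation*, W_N =
min(WRA, 1), rather than by min–max rescaling: a global min–max makes
every weight depend on the single most extreme edge in the network, so one
dense overlap would compress all clique edges below the core-density
threshold.  Saturation keeps the scale absolute (clique ⇒ 1) and is stable
under graph perturbation.

**Co-expression.** The second signal is the exact sample Pearson
correlation of the two genes' expression profiles (length-T vectors,
T ≥ 2).  Edges with negative correlation are removed from the network
before any topology is measured — anticorrelated expression argues against
a physical interaction — while a correlation of exactly 0 is kept (absence
of correlation is not negative evidence).  Pairs with a gene missing from
the expression data, or with a zero-variance profile, get an undefined
(NaN) correlation: such edges are retained and their expression term
contributes 0 to the blend, so they fall back on topological evidence
alone.

**Blend.** W = α·W_p + (1−α)·W_N per edge, followed by a min–max
normalization of the blended map to [0, 1].  α = 0.3 by default, weighting
topology more than expression.  α = 0 reproduces the saturated-RA-only
map and α = 1 the expression-only map exactly.  The final min–max treats a
spread below 1e-12 (relative) as constant and maps everything to 1;
without this guard, floating-point noise at the last ulp of an otherwise
constant map would be amplified to the full unit interval.

## Complex detection

Detection follows the core–attachment view: a complex is a dense stable
core plus peripheral proteins that bind it.

**Core search.** Admissibility of a vertex set C is defined by two
constraints on the induced weighted subgraph: weighted density
2m/(|C|(|C|−1)) ≥ λ, where m is the sum of internal edge weights, and hop
diameter ≤ δ (longest unweighted shortest path; a disconnected induced
subgraph has infinite diameter).  Seeds are visited in decreasing
weighted-degree order; a seed and its heaviest neighbor form the initial
pair, and the set repeatedly absorbs the adjacent node that maximizes the
resulting density, as long as both constraints continue to hold.  The
candidate is kept when it reaches `min_core_size`.  Nodes already covered
by an accepted core are skipped as seeds; all ties (seed order, neighbor
choice, growth choice) break lexicographically by node ID, making the
search fully deterministic.  The greedy procedure is not exhaustive: it
can miss an admissible subgraph whose density profile dips during growth.

**Second-order expansion.** Candidates for attachment are all nodes within
two hops of a core member.  A candidate joins when its total edge weight
into the core is at least `attach_ratio` times the core's average internal
weighted degree (and is positive) — a weighted analogue of the classical
"connected to more than half the core" rule.  All candidates are judged
against the original core in a single round, so the outcome does not
depend on evaluation order and never removes members.

**Deduplication.** Expanded clusters are processed in decreasing size;
a cluster is dropped when its neighborhood affinity
NA(A, B) = |A∩B|²/(|A||B|) with an already-kept cluster reaches
`dedup_na`.  Exact duplicates (NA = 1) always collapse; the larger of two
near-duplicates survives.

### Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.3 | expression share of the blended edge weight |
| `lam` | 0.7 | weighted-density floor for cores |
| `delta` | 2 | hop-diameter cap for cores |
| `min_core_size` | 3 | smallest reported core (at size 2 the density floor reduces to a single edge weight and loses meaning; configurable down to 2) |
| `attach_ratio` | 0.5 | attachment threshold as a fraction of the core's average internal weighted degree |
| `dedup_na` | 0.8 | affinity above which two clusters count as duplicates |
| `t` | 0.2 | neighborhood-affinity threshold for precision+/recall+ |

λ = 0.7 and δ = 2 are the conventional settings for density/diameter
constrained complex search; α = 0.3 is the reference operating point of
the weighting scheme.

## Evaluation

All measures derive from the overlap table T_ij = |R_i ∩ P_j| between n
benchmark complexes and m predictions.  SN = Σ_i max_j T_ij / Σ_i |R_i|,
PPV = Σ_j max_i T_ij / Σ_ij T_ij, ACC = √(SN·PPV).  Jaccard-based
precision/recall/f-measure use a strict J > 0.5 match; the plus variants
use an inclusive NA ≥ t match.  MMR is the optimal one-to-one assignment
on the NA table (solved exactly as a rectangular linear assignment
problem) divided by n.  FRM is the fraction of benchmark complexes with a
prediction at NA ≥ 0.25.  SEP co-normalizes each overlap by its row and
column sums, sep_ij = (T_ij/Σ_j'T_ij')·(T_ij/Σ_i'T_i'j), and takes the
geometric mean of the grand total averaged per benchmark complex and per
prediction.  Composites: F_MMR = MMR + f-measure+ and CS = MMR + FRM +
SEP + ACC + f-measure.  Every ratio with a zero denominator is 0.  Note
that PPV and SEP reach 1 for a perfect prediction only when the benchmark
complexes are mutually disjoint; with shared proteins the off-diagonal
overlaps inflate their denominators by construction.

## Synthetic benchmark

The generator plants `n_complexes` disjoint complexes with sizes uniform
in `size_range`; within-complex edges appear with probability `p_in` and
every other pair with `p_out`.  Each complex's induced subgraph is redrawn
(up to 1000 attempts) until it is connected with diameter ≤ 2, so perfect
recovery under the default constraints is attainable and recovery tests
are well-posed.  Expression profiles follow the co-expression assumption:
each complex has a latent sinusoid with three periods across the T = 36
time points (a metabolic-cycle-like design) and random phase, standardized
to unit variance; members observe √ρ·latent + √(1−ρ)·noise plus
additive observation noise (`noise_sd`), giving an expected within-complex
correlation of ρ/(1+noise_sd²).  Background nodes (default 40, ≈ 25 % of
the network) receive independent profiles.  Everything derives from a
single integer seed.

`perturb` models interaction noise: it removes `round(remove_frac·|E|)`
edges uniformly and adds `round(add_frac·|E|)` uniformly chosen non-edges,
leaving the node set unchanged.

What the generator does **not** emulate: overlapping complexes, scale-free
or duplication–divergence global topology, missing expression values,
condition-dependent (dynamic) complexes, and systematic (non-uniform)
false-positive structure in the interaction data.  Passing recovery tests
therefore demonstrates correctness of the pipeline's mechanics under the
co-expression model, not performance on real screens.

A consequence of the clean expression model is worth stating: with ρ = 0.8
over 36 time points, pairwise correlation separates within-complex from
background pairs almost perfectly, so the expression-only ablation
(`ra_enabled=False`) is already near ceiling on this benchmark and graph
perturbation — which degrades only the topological channel — cannot make
the blended weighting outperform it.  The topology channel's value on real
data, where co-expression evidence is far weaker and noisier, is outside
what this benchmark can demonstrate; `scripts/acceptance.py` reports both
ablation arms so the comparison is explicit.

## Numerical and degenerate-input conventions

* Min–max normalization with a relative spread ≤ 1e-12 yields all ones.
* Weighted density requires ≥ 2 members; diameter of a singleton is 0 and
  of a disconnected set ∞.
* Duplicate edges on input collapse to the maximum weight; self-loops are
  dropped with a logged count.
* Duplicate complexes are permitted in read files (flagged), and empty
  benchmark or prediction sets are an error for every metric.
* All orderings that could affect output (seed order, growth ties,
  deduplication among equal sizes) are resolved lexicographically, so a
  given input and parameter set always produces bit-identical output.
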