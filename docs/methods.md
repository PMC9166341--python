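# Methods

This note records the modeling assumptions, parameter conventions,
numerical choices and known limitations of `connectogen`. It documents
what the code does and why; every number quoted here is computed by the
test suite or by `scripts/acceptance.py`.

## Wiring models

Networks grow by sequential stochastic edge addition from an (optionally
seeded, by default empty) adjacency matrix. At each iteration every
unconnected pair receives a score θ_ij; the pair is drawn with
probability θ_ij / Σθ (inverse-CDF sampling over lexicographically
ordered candidates, one uniform variate per edge, so runs are bit-exact
given a seed); topology terms are recomputed after every accepted edge.
Six formulations are supported: `spatial` (pure exponential distance
rule), `multiplicative`, `additive` (normalized cost and value compete
through a weight α), `additive-nogamma` (γ fixed at 1), `physio`
(constraint matrix only) and `spatial-physio` (additive with a
constraint in place of topology).

Conventions that the literature on this model family leaves open, fixed
here:

- **Distance penalty sign.** η is stored as a magnitude and applied as
  exp(−η D); a "stronger penalty" always means larger η. Search ranges
  treat the coefficient interval as [0, 2] per mm.
- **Additive normalization.** The maxima normalizing the two additive
  terms are taken over the *current candidate set* (pairs not yet
  connected), refreshed at every iteration.
- **ε-protection.** ε = 10⁻⁶ is added to the topology term before
  exponentiation in both the multiplicative and additive forms, so
  negative γ never divides by zero. If the raw topology term is
  identically zero over candidates (e.g. any degree-based term on an
  empty network), the normalized topology contribution is defined as 0
  rather than 0/0 — the model then behaves as a pure distance rule for
  that iteration.
- **Power-law kernel.** (D + ε)^−η is offered only for the
  multiplicative form. Growth variants require the exponential kernel: a
  power law is scale-invariant, so a uniformly expanding geometry would
  not change selection probabilities at all.
- **"-avg" terms** are arithmetic means (c_i + c_j)/2, (d_i + d_j)/2.
- **Matching index** is |N_i\j ∩ N_j\i| / |N_i\j ∪ N_j\i| with 0/0 := 0
  (isolated or exclusively mutually-connected nodes share nothing).
- **Clustering** of nodes with degree < 2 is 0. **Betweenness** is the
  unnormalized, unweighted node betweenness with endpoints excluded,
  each unordered pair counted once (computed by igraph; validated
  against exhaustive shortest-path enumeration in the tests). Any fixed
  convention works here because model and data are always compared under
  the same one.

Growth variants take an ordered distance sequence D(t) and add
quota(t) = ⌊E·t/T⌋ − ⌊E·(t−1)/T⌋ edges under each geometry — a constant
formation rate, the simplest defensible schedule. Quotas sum to E and
differ by at most 1 across stages.

For speed, the topology term is maintained incrementally during growth:
adding edge (a, b) only changes term entries for pairs involving a, b
(degree-, matching- and common-neighbor-based terms) plus the common
neighbors of a and b (clustering terms, whose triangle counts change).
The property suite verifies the incremental matrix equals a full
recompute for all 12 terms along random growth trajectories.

## Physiological constraints

Similarity matrices enter the models as strictly positive constraint
matrices: `uCGE`/`MPC` are shifted by +1; `cCGE` first subtracts an
exponential distance trend r(D) = p1·exp(−p2·D) + p3 fitted to the data
by least squares (initialized at p1 = range(S), p2 = 1/median(D),
p3 = min(S), with p2 bounded positive). Because residuals can undershoot
−1, values that remain non-positive after the shift are floored at 10⁻⁶
and counted in a warning log. A fit whose amplitude is ~0 (no decay
present) is reported as an error carrying the best iterate, since its
length scale is unidentified.

MPC is the partial correlation of regional depth-intensity profiles
controlling the cortex-wide mean profile. Note a finite-sample property
verified in the tests: when the control profile is the *empirical* mean
of R regions, two regions that are pure noise around the mean have
expected partial correlation ≈ −1/(R−1), not 0; the bias vanishes as R
grows. Zero-variance profiles and profiles perfectly correlated with the
mean are rejected by name.

## Evaluation

Topological fit is max(KS) over degree, clustering, betweenness and
edge-length distributions; the edge-length sample of each network is the
evaluation-geometry distances at its edges. For growth models the
evaluation geometry is the final-stage (adult) matrix — the comparison
target is the adult network — but the evaluation matrix is an explicit
argument so alternatives are testable. When several measures attain the
maximum, the reported determinant follows the fixed priority degree <
clustering < betweenness < edge length. Topography is the Spearman
correlation of nodal property maps; a constant nodal vector yields NaN
(undefined), deliberately never 0. Isolated nodes get mean connection
distance 0 by convention. Paired model comparisons use two-sided
Wilcoxon signed-rank tests with Bonferroni correction; the exact null
distribution is used for n ≤ 25 with no zero differences (the default
normal approximation is badly sized exactly in the tied-difference cases
these comparisons produce).

## Parameter optimization

The search samples `points_per_round` parameter vectors per round
(default 2000, five rounds = 10,000 total). Round 1 is uniform on the
box. Each later round treats every previously evaluated point as a
Voronoi site, selects cells with probability ∝ fit^(−b) (fits floored at
10⁻⁶; b = 0, 0.5, 1.0, 1.5, 2.0 across rounds) and draws new points
uniformly within chosen cells. The tessellation is frozen during a
round: new points join it only at the next round.

Cell-uniform draws use rejection with nearest-site membership, with
sites compared in per-axis min-max standardized coordinates (by the box
bounds) so heterogeneous ranges (γ spanning hundreds for CGE models) do
not dominate the metric. Proposals are drawn inside an axis-aligned
cover of the chosen cell obtained by linear programming over the
halfspace constraints of the nearest sites; the cover is a relaxation,
so accepted draws remain exactly cell-uniform, while the acceptance rate
stays bounded as refinement makes the best cells small. The cover LP is
solved in site-centered, neighbor-scaled coordinates — at late-round
refinement scales a raw-coordinate formulation loses the cell geometry
to the solver's absolute feasibility tolerance. An objective failure on
a point is recorded with the worst fit (1.0) and the sweep continues;
likewise, a cell that defeats rejection sampling (vanishing volume) is
logged and another cell is drawn by the same weights, with one uniform
box draw as the final fallback. Default parameter boxes: η-coefficient [0, 2] per mm,
γ [−8, 8], α [0, 8]; the γ-free additive variant uses α ∈ [0, 0.05] for
clustering/degree terms whose raw scale would otherwise swamp the
distance term; constraint models use γ ∈ [−50, 250] (CGE) or [0, 50]
(MPC).

A topography scan over retained trace networks (maximum Spearman degree
correlation) is reporting-only, never an optimization target.

## Cross-validation

F_CV for held-out subject s: for each other subject's optimized
parameters, run the model `repeats` times (default 20) at s's edge count
and geometry, average the max(KS) fits over repeats, then average the
N−1 per-source means. Run seeds derive from (master seed, held-out id,
source id, repeat), where ids are stable subject identifiers — so F_CV
is invariant to cohort ordering and safe to parallelize. One shared
geometry serves the cohort by default (a common template parcellation);
per-subject geometry is accepted.

## Interior wiring costs

The mesh pipeline approximates fiber distances through the interior of
a closed cortical surface:

1. **Decimation** to 15% of the original vertex count (default) by
   quadric edge collapse with link-condition and normal-flip guards.
   Costs are computed on bounding-box-normalized coordinates quantized
   to a 10⁻⁹ grid, which makes the collapse sequence independent of
   global scale — so scaling a mesh by s scales every output distance by
   exactly s (when the offset depth is scaled along, as it is a length).
   Volume is preserved to within 3% on the sphere fixture.
2. **Inward offset**: one point per vertex, 0.1 mm (default) along the
   inward vertex normal; points that land outside thin geometry fall
   back to halved depths, logged, and error out if they cannot be placed
   inside (ray-parity containment test).
3. **Visibility graph**: a segment-triangle (Möller–Trumbore) test over
   every point pair against every face. Hits within 10⁻⁹ × bounding-box
   diagonal of either endpoint are ignored (offset points sit strictly
   off the surface, so closer contacts can only be numerical grazing),
   and barycentric coordinates carry a 10⁻⁸ overlap so crossings exactly
   on a shared triangle edge cannot slip between the two incident faces.
   No face is excluded outright: a segment can genuinely exit through a
   face adjacent to its own source vertex (this occurs at the cap rims
   of the bent-tube fixture), and the endpoint tolerance alone separates
   that case from grazing.
4. **Dijkstra** over the visibility graph gives all-pairs interior
   distances (disconnected graphs are an error naming component sizes —
   usually a sign of over-aggressive decimation); region distances are
   means over vertex pairs, diagonal 0.

These distances are lower bounds on true fiber lengths: the surface
alone does not encode ventricles or other obstacles, and decimation
smooths concavities.

## Synthetic data

The generators provide every input class with known ground truth:

- **Growing geometry**: n nodes quasi-uniform on a sphere or ellipsoid
  (Fibonacci lattice — deterministic base; optional seeded jitter in
  mm), scaled along a strictly increasing path. Defaults: 19 stages and
  a final/initial scale ratio of 1.74, mirroring the ~74% growth in
  maximum interregional distance reported for fetal-to-adult cortical
  templates; the ratio is configurable because that figure describes one
  template set, not a law. Base scale 40 mm puts adult-stage distances
  in a brain-like range. With zero jitter, D(t) is an exact rescaling of
  D(1).
- **Truth networks** wrap the growth engine with a replay record
  (spec, params, E, seed) sufficient to regenerate them bit-exactly.
- **CGE-like similarity**: S = clip(p1·e^(−p2·D) + p3 + f_i + f_j + ε,
  −1, 1), defaults (1.12, 0.012/mm, −0.29) from published exponential
  fits of cortical CGE. The nodal field f (sd 0.05) is the simplest
  structured fluctuation that gives similarity-constrained models
  something beyond pure distance to exploit; pairwise noise sd 0.05.
  Clipped entries are counted and reported.
- **Depth profiles**: convex mixtures of smooth archetype curves
  (low-order Fourier series) plus noise; regions sharing an archetype
  have high profile covariance.
- **Fixture meshes**: icosphere (convex — every interior pair visible),
  a capped tube swept along a half-circle arc (cross-bend pairs must
  detour), and a dumbbell of revolution (narrow neck), all watertight
  with Euler characteristic 2 by construction.

What passing tests on these synthetics do and do not show: they verify
the machinery — exact edge counts, reduction identities, oracle-level
agreement of every statistic, recoverability of a planted wiring rule
at realistic n — but synthetic geometries are smooth and symmetric,
synthetic CGE has a single global decay, and truth networks come from
the model family itself. Performance rankings on real connectomes, where
none of these hold, are an empirical question the package enables but
cannot settle.

## Problem sizes

Default study sizes used by the test suite and acceptance script were
chosen to exercise every code path at realistic dimensionality while
keeping a full run on a single core comfortable: rule recovery at
n = 60 nodes, E = 250 edges, 5 growth stages with 1000-point search
budgets; cohorts of 4–6 subjects at n = 18–40; decay recovery at n = 90
(matching the parcellation size the CGE literature uses); meshes of
128–642 vertices. The optimizer's published-scale budget (5 × 2000) is
the package default for real analyses.

## Known limitations

- Binary networks only; no weighted edge formation, no pruning or
  overgrowth dynamics, no heterochronous (region-ordered) growth.
- The distance-decay correction for cCGE assumes a single global
  exponential trend.
- Interior distances ignore volumetric obstacles.
- The Voronoi search is a global heuristic: it carries no convergence
  guarantee, only the measured competence on known objectives.
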