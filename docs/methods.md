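# Methods

## Bipartite representation and projections

A complexome is a bipartite graph: complex nodes, protein nodes, and an
edge wherever a protein is a component of a complex. Membership records
carry a role — *core* (stable skeleton) or *attachment* (promiscuous
seasoning) — and an optional stoichiometric count `copies` (default 1,
so the stoichiometry matrix S coincides with the binary indicator U;
public complexome catalogues rarely publish counts). Role filters
(`all`, `core_only`, `attachment_only`) restrict the edge set; nodes
isolated by a filter are dropped from the graph but reported, so degree
averages are taken over participating nodes — the convention under
which "average core-protein degree" is meaningful.

The one-mode projections are weighted: two proteins are linked by the
number of complexes they share, two complexes by the number of proteins
they share (computed by `networkx`'s shared-neighbor projection and
checked in tests against a brute-force pair scan). A node's *strength*
is the sum of its incident weights. Projections carry no self-loops:
under set semantics a protein cannot share a complex with itself.
Rankings break ties lexicographically on node id — any other order
would be arbitrary.

## Degree-distribution fits

Empirical degree distributions are summarized by the cumulative tail
P(k) = Σ_{k'≥k} p(k'), which is again exponential when p is exponential
and again a power law when p is one. Family comparison is ordinary
least squares on log P against k (exponential) or log k (power law),
with the sum of squared log-residuals as the goodness score — the
simplest reproducible criterion equivalent to the straight-line test on
semi-log vs log-log axes. An optional `tail_cut` excludes the largest
degrees, where finite-size effects bend any empirical tail. No
maximum-likelihood power-law machinery is attempted; the question the
fit answers is only *which family is closer*.

## Generating-function prediction for projected degrees

For an uncorrelated bipartite graph, let G_p(x) generate the protein
membership-count distribution and let E(x) = G_q'(x)/G_q'(1) generate
the *excess* size of a complex reached along a random edge (size-biased
choice of complex, minus the arriving protein). Each of a protein's d
complexes contributes an independent excess draw, so the projected
degree is generated by the composition G_p(E(x)). We evaluate it as a
series: the excess pmf e(t) ∝ (t+1)·q(t+1), its convolution powers
accumulated degree-by-degree, truncated at `k_max` (default 512) and
renormalized, with a warning reporting any truncated mass above 1e−6.
The prediction counts shared partners with multiplicity; at the edge
densities used here the distinction from distinct-neighbor degree is
negligible, and the simulation check below uses plain degrees.

The cross-check simulates a bipartite configuration model. Because the
configuration model is defined by a *prescribed* degree sequence, the
default sequence realizes the expected count of each degree
(largest-remainder rounding of N·p(k)); sampled i.i.d. sequences are
available as an option. The test fixture uses exponential pmfs with
scales k₀ = 1.0 (protein memberships, min 1) and k₀ = 1.5 (complex
sizes, min 2) at N = 2,000 proteins: small supports keep the empirical
pmf of a single graph sharp enough that total-variation agreement below
0.05 reflects the theory rather than sampling luck, while the composed
distribution still spans two decades for the log-linear tail check.

## Abundance estimation

With known positive abundances p_i for the protein set K (restricted to
core memberships — attachments are shared too promiscuously and would
inflate the estimate), copy numbers minimize the total leftover

    DA = Σ_{i∈K} (p_i − Σ_j S_ij c_j)   s.t.   Σ_j S_ij c_j ≤ p_i,  c_j ≥ 0.

Under the availability constraint every leftover term is nonnegative,
so DA is simultaneously the L1 deviation from the ideal balance
p = S c. Minimizing DA is equivalent to maximizing total usage
Σ_{i∈K}(Sc)_i, solved with HiGHS via `scipy.optimize.linprog`. Copy
numbers are continuous reals — abundances are in arbitrary units and
the problem is a plain LP, not an integer program. Conditions (rich
YEPD vs minimal SD media) are independent LPs; nothing couples them.

Degenerate details are made explicit rather than hidden:

* complexes with no constraining protein (no core member in K) are
  *undetermined*: assigned c = 0 and flagged;
* the LP optimum need not be unique; `compute_intervals=True` re-solves
  min/max c_j on the optimal face, exposing per-complex ranges;
* proteins with unknown or zero measured abundance are outside K —
  they impose no constraint and receive imputations p̂_i = Σ_j S_ij c_j
  instead (flagged `undetermined` when every containing complex is);
* feasibility is verified post-hoc to 1e−8 rather than trusted.

Condition-dependent ratios c_SD/c_YEPD are aggregated per functional
category (codes truncated to a hierarchy depth); a complex with
functions in several categories counts in each, complexes with
denominator below 1e−9 are excluded and counted, and the ratio classes
are >1.2 (up), <0.8 (down), and the inclusive middle band.

## Function assignment

Both roles enter the covering constraint: allowing every alternative
assignment makes a function that is *still* forced genuinely certain.
The global problem decomposes into one minimum set cover per function
(the constraint couples nothing across functions); each instance is
solved to proven optimality with `scipy.optimize.milp` (HiGHS, zero MIP
gap, deterministic given the fixed lexicographic variable order). The
alternative objective minimizes the number of *newly annotated core
proteins* dragged in by the chosen complexes, with ties broken by fewer
complexes — encoded as one weighted objective, protein weight
(n_candidates + 1) so a single new protein outweighs any complex count.

An assignment (j, k) is high-confidence iff complex j lies in every
optimal cover of k, decided exactly: re-solve with Fc_jk forced to 0;
if the optimum degrades (or the instance becomes infeasible), j is
essential. Only complexes in the reported optimum need testing — any
other complex is already absent from one optimum. Covering is
re-verified on every reported solution instead of trusting the solver.

Re-substitution predicts (i, k) when protein i is a core member of an
assigned complex and lacked annotation k — main biological functions
are executed through core membership, so attachments do not inherit.
Each prediction records its source complexes, and `trace_function_
source` lists the donor proteins (annotated members of the assigned
complex), so every predicted function has an auditable provenance
chain.

## Validation

Protein-level hold-out. For abundance: the LP is solved with test
abundances masked, test proteins are imputed, and the relative
deviation α = |p̂ − p|/p is ranked and compared with a random-pairing
null (imputed values permuted across test proteins; default 200
replicates, per-rank mean and central 95% band). For functions: test
annotations are masked entirely, the cover pipeline reruns on training
annotations, and predictions for test proteins are scored by the
fraction of predicted pairs present in the held-out truth and the
fraction of predicted-for proteins with ≥1 correct function, for raw
and HC outcomes, always serialized with numerator/denominator counts.
Split sizes round half-away-from-zero; masked inputs are hashed into
report metadata so masking hygiene is checkable. HC metrics are not
asserted to dominate raw ones — only the set inclusion HC ⊆ raw is an
invariant.

## Synthetic data

The generator emulates the study conditions the package targets.
Defaults mirror the published yeast complexome statistics: 491
complexes, 1,491 proteins, mean complex size 13.41, mean membership
4.42 (these two are mutually consistent: 491·13.41 ≈ 1491·4.42), 325
function codes. Complex sizes (min 2) and membership counts (min 1)
are truncated geometric — the discrete analogue of the exponential
form observed in the data; wiring is a bipartite configuration model
with parallel edges repaired by random swaps (bounded retries, error
advising a parameter change on failure). Each complex labels a
`core_fraction` of members core, at least one — cores form each
complex's skeleton. Copy numbers are log-normal (median e⁷ ≈ 1100
arbitrary units, σ = 1.2, spanning the orders of magnitude of measured
yeast abundances) with a per-complex log-normal condition ratio
(σ = 0.3); protein abundances are the planted ideal plus *nonnegative*
exponential surplus (mean 10% of the ideal) — negative noise would
make the planted truth infeasible under the availability constraint,
which the generator guarantees by construction. Functions are planted
on complexes (2 each), copied to core proteins, then thinned at a 20%
dropout rate to create unknowns.

What the generator does not emulate: the socio-affinity scoring and
isoform clustering that produced the real catalogue, correlated
measurement error between conditions, degree–degree correlations, and
biologically structured (non-random) annotation sharing across
complexes. Passing tests therefore demonstrate correctness of the
optimization and inference machinery under the stated generative
assumptions, not performance on any particular experimental dataset.

## Problem sizes and numerical choices

Unit and property tests run on complexomes of 30–500 complexes; the
acceptance script runs the full default scale (491/1,491/325) plus a
2,000-protein configuration model, completing in seconds. Oracle
comparisons use exhaustive enumeration (set covers up to 15 candidate
complexes) and brute-force grids (LPs up to 4 complexes, grid step
0.01–0.02 with the tolerance implied by one grid step of total usage).
LP feasibility tolerance is 1e−8; MIP instances require a zero
optimality gap; pmf normalization tolerance is 1e−9; ratio-table
denominators below 1e−9 are treated as zero. Hold-out splits, null
replicates, and the generator are all driven by explicit integer seeds
and are fully deterministic.

## Known limitations

* Stoichiometries default to 0/1 membership; `copies > 1` is supported
  end to end but untested against any real stoichiometry source.
* The LP reports one optimal vertex; interval probing is opt-in and
  costs one LP pair per complex.
* The generating-function prediction ignores degree–degree correlation
  and counts shared partners with multiplicity; both approximations
  degrade for dense graphs (mean membership ≫ 1 and large complexes).
* Function codes are atomic labels during optimization; the dotted
  hierarchy is used only for reporting categories.
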