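# Methods

## The statistical model

The package estimates a partial-correlation network over 17 mixed-type
health variables. For data matrix X (n × p) with sample covariance S
(n − 1 denominator), the edge weight between variables i and j is

    Rp_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj),   Omega = S^-1,

which equals the correlation of the residuals of i and j after OLS
regression on the remaining p − 2 columns (the test suite verifies the
two formulations agree to 1e-8). Categorical variables (sex, marital
status, social position, hypertension) enter as their numeric codes, so
the matrix is a single Pearson-type mixed matrix; polychoric or
polyserial alternatives are deliberately out of scope. A covariance
whose smallest eigenvalue is below 1e-10 of its largest is treated as
singular and the offending (collinear or constant) columns are named in
the error.

Significance of each Rp uses the classical t transform with the
conditioning set counted in the degrees of freedom:

    t = Rp * sqrt((n - k - 2) / (1 - Rp^2)),   df = n - k - 2,  k = p - 2.

At the reference design (n = 188, p = 17) this gives df = 171. The
two-sided p-values are compared strictly against the edge screen
alpha = 0.25 (default): only pairs with p < alpha become edges, with no
multiple-testing correction. This is a deliberately liberal screen whose
purpose is pruning near-zero weights, not error control; under global
independence it retains ~25% of the 136 pairs, and the acceptance suite
checks this calibration empirically (1000 replicates at n = 188). All
17 nodes remain in the graph even when isolated.

## Graph statistics and their conventions

All path-based metrics use the unweighted topology of the pruned graph
(each retained edge counts distance 1). This convention is pinned by
internal-coherence checks: in a 17-node graph, a node with 9 direct
neighbours and the remaining 7 nodes at distance 2 must score closeness
16/23 = 0.6957 and harmonic closeness 12.5/16 = 0.78125, matching the
values a Gephi analysis of such a configuration reports.

* Closeness: (n − 1) / sum of distances to reachable targets; 0 for an
  isolated node.
* Harmonic closeness: mean reciprocal distance with 1/inf = 0, robust to
  disconnection.
* Betweenness: raw (unnormalised) Brandes accumulation over unordered
  pairs with fractional credit for tied shortest paths.
* Eigenvector centrality: leading eigenvector of the absolute-weight
  adjacency, power iteration with a unit diagonal shift (removes the
  period-2 oscillation on bipartite components), tolerance 1e-10,
  rescaled so the maximum score is 1. Absolute weights keep the matrix
  non-negative, as Perron–Frobenius requires; a flag switches to unit
  weights.
* HITS: on an undirected graph the hub/authority fixed point is the same
  Perron eigenvector under L2 normalisation, so hub = authority
  entrywise; the package computes it directly rather than iterating on
  A^T A = A^2, whose dominant eigenspace is degenerate on bipartite
  components. A general A^T A routine is retained for directed input.
* Local clustering: 2T / (k(k − 1)) with T the edges among neighbours;
  0 for degree < 2.
* Global: density = edges / C(n, 2); diameter = maximum eccentricity in
  the largest connected component; average path length over connected
  ordered pairs, with a connectivity flag when pairs were excluded.

Community detection is two-phase Louvain (local moving until no gain
exceeds 1e-10, then aggregation) maximising Newman–Girvan modularity on
absolute edge weights, resolution 1.0 by default. Signed-modularity
variants are out of scope: a negative partial correlation still marks a
conditional dependence, and magnitude is what binds modules here. Node
visiting order is shuffled by a seeded generator, so a fixed seed gives
a fixed partition; community ids are renumbered by descending size with
ties broken by the smallest member index. Exhaustive partition
enumeration on graphs of <= 8 nodes bounds the Louvain optimum in tests.

## The synthetic cohort generator

The generator emulates a cohort of 188 young adults with overweight or
obesity measured on the 17 study variables. A latent multivariate normal
with unit variances carries the dependence structure; each column is then
mapped to its native marginal:

* continuous variables by the affine map mean + sd * z, with draws for
  strictly positive quantities floored at 1% of the mean (flooring
  rather than resampling keeps the generator a pure deterministic map of
  the seed);
* binary/ordinal variables by thresholding at the normal quantiles of
  the cumulative level frequencies (codings: sex 0 = man / 1 = woman;
  hypertension 0/1; marital and social position 0/1/2). Frequencies are
  stored as exact count fractions of the 188-participant cohort
  (81/188 women, 48/188 hypertensive, 148/35/5 marital, 71/62/55 social)
  so probability vectors sum to one exactly.

The latent correlation is a three-block design — glycemic
(insulin, glucose, HOMA-IR), lipid (total cholesterol, TAG) and a
psychosocial block with everything else — parameterised by a single
within-block and a single between-block correlation. Defaults are 0.6
within and 0.05 between: strong enough that the glycemic and lipid
blocks form detectable modules, weak enough across blocks that the
remaining structure stays diffuse, which is the qualitative pattern the
method is meant to resolve. Positive definiteness is checked by Cholesky
before sampling, never assumed.

The published cohort descriptives contain an internal inconsistency: the
reported insulin (2.54 uIU/mL) and glucose (147.80 mg/dL) means imply
HOMA-IR = 2.54 x 147.80 / 405 = 0.93, an order of magnitude below the
reported HOMA-IR mean of 10.69 — most plausibly a unit discrepancy in
insulin reporting. The generator therefore exposes `homa_mode`:
`"formula"` (default) overwrites the HOMA column row-wise with
insulin x glucose / 405, keeping the table internally consistent;
`"sampled"` draws HOMA from its own published moments, matching the
printed marginal but breaking the formula. Neither resolves the
discrepancy; both are documented choices.

What the generator does **not** emulate: skewness and zero-inflation of
real biomarker and questionnaire distributions, heteroscedasticity,
age/sex interactions, measurement error structure, or any particular
observed edge list. Passing tests therefore demonstrate correctness of
the estimation and graph machinery under a known truth, not fidelity of
any particular published network topology, which cannot be reconstructed
without the raw data.

## Numerical and design choices

* BMI classification assigns the boundary values by WHO convention
  (25 -> overweight, 30 -> obesity); below 25 is labelled out of range,
  reflecting the cohort inclusion criterion.
* Edge selection is strictly `<` at the threshold; a pair whose p-value
  equals alpha exactly is excluded (tested).
* Reports round to 4 decimals; all file writers use fixed float formats
  and sorted keys so identical configs reproduce byte-identical outputs.
* A single run-level seed drives both cohort generation and Louvain.
* GEXF/GraphML exports store the node's measurement dimension and the
  edge sign as attributes (edge colour is a viewer concern); GEXF weight
  carries |Rp| since the format requires positive weights, GraphML
  carries the signed Rp.
* Problem sizes in the test and acceptance suites: moment-recovery at
  n = 1e5, structure-recovery at n = 1e4, screen calibration with 1000
  replicates at n = 188, planted-block recovery over 50 seeds at
  n = 5000, exhaustive oracles at <= 8–13 nodes. These sizes make the
  Monte-Carlo error comfortably smaller than the tolerances they are
  checked against while keeping the full suite to a few seconds.

## Known limitations

* Pearson-based partial correlations on coded ordinal data understate
  associations relative to polychoric approaches.
* The p < 0.25 screen controls nothing; retained edges are hypotheses,
  not discoveries.
* Louvain is a greedy heuristic: partitions are seed-dependent on
  near-degenerate modularity landscapes (the exhaustive-oracle tests
  bound, but do not eliminate, this).
* The unweighted-distance convention discards weight information in
  path-based metrics; this mirrors the target analysis software's
  behaviour rather than a methodological preference.
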