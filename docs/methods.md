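# Methods

## Model and pipeline

A regulatory network is a directed graph from regulators to targets;
roles are degree-derived (out-degree ≥ 1 makes a node a regulator), so
a regulated transcription factor holds both roles. The partnership
(co-regulation) network is the undirected projection onto regulator
pairs sharing at least one target, filtered against a null model:

- **Null model.** Degree-preserving randomization by attempted double
  edge swaps: pick two edges (r1,t1), (r2,t2), rewire to (r1,t2),
  (r2,t1), reject swaps that would duplicate an edge or create a
  self-edge absent from the input. The proposal is symmetric and the
  chain connects the fixed-margin space, so sampled networks are
  uniform given enough attempts. The attempt budget is
  `ceil(swap_factor × |E|)` with `swap_factor = 10` by default —
  enough mixing for the network sizes here while staying linear in the
  edge count. The randomization literature names the constraint (fixed
  in/out degrees), not an algorithm; attempted-swap MCMC is the
  standard, degree-exact, memory-light choice.
- **Ensemble statistics.** `ensemble_size` independent randomizations
  (default 1,000; the built-in study conditions use 100 for speed —
  the per-pair null mean stabilizes well before that for these
  network sizes) give per-pair mean μ and SD σ of the shared-target
  count. SDs use the population convention (ddof = 0). Pairs never
  co-targeting in the real network or any replicate are not stored;
  no partnership edge can exist for them.
- **Edge retention.** `CC = x/μ > 1` by default. μ = 0 with x ≥ 1
  yields CC = +∞ and the edge is kept: sharing more than an
  unattainable null maximally satisfies "more frequent than random".
  The z-variant keeps `(x−μ)/σ > 0` (identical ordering to CC > 1
  whenever σ > 0; with σ = 0 the sign of x − μ decides), and
  `filter='none'` keeps every co-targeting pair. The target-level dual
  network (targets sharing a regulator) is built unfiltered; the null
  filter applies only at the regulator level.

## Scaling fits

Fits use the raw per-regulator scatter — one (k, f) point per
regulator, partner-less regulators included at f = 0 — matching how
the relationship is usually plotted, not binned means.

- **Linear:** OLS of f on k (scipy linregress); a constant response is
  the slope-zero degenerate with R² = 0.
- **Exponential saturation:** bounded nonlinear least squares of
  `a(1 − e^{−bk})` with a, b ≥ 0, initialized at `a₀ = 1.05·max f` and
  b₀ from the through-origin regression of `−ln(1 − f/a₀)` on k;
  tolerance 1e−8 on relative parameter change, ≤ 500 residual
  evaluations. The plateau search is capped at `10·max f`: in the
  near-linear regime (bk ≪ 1 across the observed range) only the
  product a·b is identifiable and the unbounded likelihood ridge runs
  to a = ∞; the cap makes the fit well-posed there without moving
  interior optima (b compensates along the ridge, so the fitted curve
  and R² are unaffected).
- **R²** is 1 − SS_res/SS_tot about the mean of f for both families;
  for the nonlinear family it can be negative and is reported as-is.
  Preference goes to the larger R²; ties within 1e−12 go to the linear
  family (fewer effective shape parameters).
- **Power-law diagnostic:** OLS of log₁₀ P(k) on log₁₀ k over support
  points with k ≥ 1, P(k) > 0 — the conventional R² log–log
  regression, deliberately not a maximum-likelihood (Clauset-style)
  fit, because the quantity of interest is how badly the log–log line
  fits a homogeneous degree distribution.
- **Operon recalibration** replaces each target endpoint by its operon
  (unmapped genes are singletons) and collapses parallel edges;
  partners come from the gene-level partnership network, targets are
  recounted at operon resolution. A regulator's operon-level
  out-degree never exceeds its gene-level one.
- **Down-sampling controls** remove a fraction of nodes (from the full
  node set, regulators and targets alike — per-role counts are logged)
  or edges, uniformly, in independent trials.

## Explanatory models

**Random acquisition.** With m potential partner regulators, a target
pool of size N and n targets per regulator on average, a regulator
acquiring targets uniformly at random gains partners at rate
`df/dk = (n/N)(m − f)`, giving `f(k) = m(1 − e^{−(n/N)k})`. The
Monte-Carlo oracle simulates a focal regulator joining m background
regulators whose regulon sizes are Poisson(n): Poisson sizes make
`1 − e^{−nk/N}` the *exact* per-partner overlap probability (the
probability generating function of the Poisson turns the
without-replacement factor `(1 − k/N)^K` into `e^{−nk/N}` in
expectation), up to a O(nk²/N²) distinctness correction. The focal
regulator is additional to the m background regulators — the new
regulator joining an existing network — so the simulated plateau is
exactly m and the simulation serves as a brute-force check of the
closed form in the dilute regime (nm ≪ N); the systematic negative
bias outside that regime is the model's stated assumption failing, not
a bug.

**Generative growth.** Starting from one TF regulating one TG, each of
10,000 iterations draws one move: add a (edgeless) TF or TG, duplicate
a node with each role-relevant edge inherited independently at rate
0.30 (out-edges for TFs, in-edges for TGs; a dual-role node duplicates
per its selected role), convert a TF into a regulated TF-TG (it keeps
its out-edges and stays eligible for TF moves), add a uniform (TF, TG)
non-edge (rejection-sampled, self-edges excluded), delete a uniform
edge, or delete a uniform node with its edges. Moves with no legal
action are skipped and counted, so `iterations` is an exact, auditable
move budget. The default move probabilities (add_tg .126, dup_tg .100,
add_tf .009, dup_tf .009, tf_to_tg .002, add_edge .674, del_edge .060,
del_node .020) were set by a birth/death budget so a default run lands
near the output scale of curated transcriptional networks — about
1.6×10² TFs regulating 2×10³ TGs with mean regulons of a few tens of
genes, dense enough for co-regulation to be measurable; they are
configurable and not calibrated to any single species.

## Synthetic study conditions

The generators emulate the statistical shape of curated regulatory
datasets, not any species' biology (no TF families, no tissue or
condition specificity, no true operon annotations):

- **Heavy-tailed panel** (saturation replication): 157 regulators over
  a 4,410-target pool — curated yeast-network scale — with power-law
  out-degrees (γ = 1.4, giving ≈ 10⁴ interactions and the
  inhomogeneous regulator connectivity of real networks). Twenty seeds
  per panel, null ensembles of 100.
- **Operon panel** (bacterial linear-regime effect): 400 regulators
  binding 1,000 operons, power-law regulon sizes (γ = 2.0) truncated
  at 80 operons — real regulons are bounded far below the genome — and
  geometric operon sizes with mean 3, the skewed
  many-singletons/few-large shape of bacterial genomes. These
  conditions keep every regulator in the bk ≪ 1 regime where the
  saturation curve's first-order expansion is a line: at gene
  resolution the two fits are statistically indistinguishable, while
  recounting targets as operons removes the operon-size noise in k and
  recovers the exponential fit's edge. The large regulator count
  stabilizes the per-seed R² comparison, which is a small-margin
  diagnostic.
- **Saturation scatter:** y = a(1 − e^{−bx}) plus Gaussian noise,
  truncated at 0 (partner counts are nonnegative).

All generators are bit-reproducible for a fixed seed; pipeline runs
fan a single master seed into per-stage sub-seeds (recorded in the run
manifest) via numpy `SeedSequence` spawning.

What passing these panels shows — and does not. They demonstrate that
the pipeline detects saturation when target-pool exhaustion generates
it, that the operon effect appears under neutral operon grouping, and
that the fits and null model behave as specified. They cannot certify
curation biases, condition-specific regulation, or incompleteness
patterns of real datasets; the down-sampling controls probe
incompleteness only in the uniform-removal sense.

## Numerical and degenerate-input choices

- Duplicate edge-list lines collapse to one edge with a logged
  warning; a line with fewer than two fields is a parse error naming
  the line; empty input is an error.
- Self-edges (a regulator listed as its own target) are retained as
  ordinary edges; randomization never introduces one unless the input
  had some.
- Networks whose margins force a unique edge set (e.g. complete
  bipartite blocks) pass through randomization unchanged, so their
  pairs have CC = 1 exactly and the CC > 1 filter empties them.
- `downsample(fraction=0)` returns exact copies; a trial that removes
  every edge logs a warning and still returns the (empty) network.
- Degenerate fit inputs raise a typed `FitError` (fewer than 3 points,
  zero variance in k, all-zero f, non-convergence with the last
  iterate attached); the pipeline records these per-analysis errors in
  its manifest instead of aborting, so toy inputs still complete
  end-to-end.

## Known limitations

- The swap-chain mixing budget (10|E| attempts) is a practical
  default, verified against exhaustive enumeration only on small
  instances; extremely constrained margins may mix slower.
- The `add_edge` growth move is rejection-sampled with a bounded
  number of tries, so in near-complete networks it can skip although a
  non-edge exists; skip counts make this visible in the audit.
- The closed-form acquisition curve is a large-pool approximation; the
  package reports the simulation's standard errors so the regime of
  validity is always visible.
- R² comparison between a 2-parameter linear and a 2-parameter
  saturating family involves no complexity penalty; in the deep linear
  regime the preference is intentionally reported as a near-tie rather
  than adjudicated.
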