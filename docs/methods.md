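# Methods

## Model

`moanet` models how a drug's molecular perturbation travels through a signed
human protein network to a phenotype. The network is a directed graph whose
edges carry a curated *sign* (activation +1 / inhibition −1) and a fitted
*weight* ω ∈ [−1, +1]. Drug-target proteins (the *stimulus*) are clamped at
+1 (activated) or −1 (inhibited); every other protein's signal is

    x_i = tanh( Σ_{edges l: j→i} ω_l · x_j ),

so signals live in [−1, +1] and a node with no upstream input stays at 0
("neutral"). A phenotype is defined molecularly by an *effector set*: a map
from proteins to the active/inactive state they hold in that clinical
condition. A *mechanism of action* (MoA) is one weight assignment together
with its propagated signal vector and the fraction of node *restrictions*
(required active/inactive states) it satisfies.

The package samples an ensemble of MoAs by independent stochastic fits,
stratifies it by response intensity per phenotype, compares strata
geometrically and extracts proteins whose signals discriminate the strata —
candidate biomarkers for which ensemble members ("prototype patients")
respond one way rather than another.

### Propagation scheme

Real protein networks are cyclic, so the perceptron-like evaluation is run
as a damped synchronous fixed-point iteration

    x ← (1 − d) · tanh(Wx) + d · x,      d = 0.5,

with stimulus nodes re-clamped each sweep. On a DAG this reduces to layered
feed-forward evaluation. Convergence is declared on the *undamped* residual
`max_i |tanh((Wx)_i) − x_i| < tol` (default 1e−6), so a converged state is a
genuine fixed point of the plain update at tolerance. The default iteration
cap is 500: on the default 300-node instance the slowest spectral mode
contracts at roughly 0.96 per sweep, and ~320 sweeps are needed to reach
1e−6 from a cold start. Unreachable nodes remain exactly 0.

### Restriction accuracy

A restriction (p, s) is satisfied iff `sign(x_p) = s` and `|x_p| ≥ 0.05`.
The magnitude floor (`min_magnitude`) makes "active" numerically meaningful;
0.05 is far above propagation error (1e−6) and far below typical planted
signal magnitudes. The same floor is used by the synthetic generator when
choosing effector candidates, so planted states are never artifacts of
numerical noise.

### Weight fitting (simulated annealing)

Weights are constrained by default to the half-interval matching the edge
sign (ω ∈ [0, 1] for activating, [−1, 0] for inhibiting edges); a
`sign_constrained=False` switch frees them, since curated signs could in
principle be contradicted by context. Moves perturb one uniformly chosen
edge weight by a Gaussian step (sd = `move_scale` = 0.4), clipped to its
interval; acceptance is Metropolis on the scalar score

    score = accuracy + 0.01 · mean_e(s_e · x_e),

where the secondary term (mean restriction-aligned magnitude) is kept below
one accuracy step for any restriction set smaller than 100 entries — it only
breaks plateaus and ties. Best-so-far tracking is lexicographic in
(accuracy, aligned magnitude), so the reported trace is non-decreasing.

Schedule defaults: initial temperature 0.05 (≈ 1.7 accuracy steps for a
35-restriction set), geometric cooling ×0.9 over 60 temperature levels, 120
moves per level (7 200 evaluations ≈ 12 sweeps per edge on the default
instance). During the search, propagation runs warm-started from the current
accepted state at a loosened tolerance (`search_tol` = 1e−3) — a single-edge
move barely shifts the fixed point, and accuracy decisions at the 0.05
magnitude floor are insensitive to 1e−3 signal error. The final reported MoA
is always re-propagated cold at the full tolerance, so the published
ensemble does not depend on the warm-start trajectory. All randomness flows
from one `numpy` Generator per run seed; ensembles use consecutive seeds
`base_seed … base_seed + n_runs − 1` and are reproducible independent of
execution order.

Ensemble selection keeps the K = 200 most accurate MoAs with accuracy
≥ 0.8 (both published values), sorting by accuracy descending with seed
ascending as the tie-break.

## Synthetic study conditions

No real curated protein network, proprietary effector catalogue or
expression-derived restriction list is redistributable, so the generator
emulates them with a known ground truth:

* **Network** — Barabási–Albert preferential attachment (default n = 300,
  m = 2 → 596 edges), each edge oriented uniformly at random; signs are
  inhibiting with probability 0.3, roughly the inhibition fraction seen in
  curated signed interaction resources.
* **Planted truth** — weights drawn with magnitude U(0.3, 1) on the
  sign-respecting interval; signals are the propagation fixed point of the
  clamped stimulus (2 hub targets with random ±1 states). A minority of
  draws put the damped dynamics on an oscillatory attractor with no fixed
  point at tolerance; such draws are rejected and redrawn from the same
  stream, so the planted truth is always a genuine fixed point and remains
  a pure function of the seed.
* **Effectors** — 15 indication + 15 adverse-event proteins drawn from
  nodes reachable from the stimulus with |signal| ≥ 0.05. Effector sets
  store the *disease* state, i.e. the **negated** planted response sign: the
  planted drug response reverts every effector, matching the pharmacological
  reading that a drug inverts its indication's molecular states. The two
  sets may overlap.
* **Restrictions** — the response targets at the indication effectors
  (tag `effector`) plus 20 additional reachable node states (tag
  `expression`), each independently sign-flipped with probability
  `restriction_noise` (default 0: noise-free, so the planted weights satisfy
  all 35 restrictions exactly).

What the toy deliberately does not emulate: tissue specificity, realistic
degree mixing, edge-level restrictions, quantitative dosage. Passing tests
therefore certify the machinery (propagation, optimisation, statistics,
geometry), not any clinical claim about real networks.

## Stratification

TSignal is the signed projection P = (1/|E|) Σ_e state_e · x_e ∈ [−1, 1]
(+1 = the MoA reproduces every effector state, −1 = it reverts all of them).
Intensity is role-oriented: −P for the indication (reversion strength), +P
for an adverse event (induction strength). The ensemble is ranked by
intensity (ties broken by MoA seed) and the top/bottom ⌊K/4⌋ become the
extreme groups — labelled *Low*-disease for the indication's top block
(little residual disease) and *High* for the adverse event's top block.
Middle quartiles keep a `Mid` label so intersections remain well defined.
Whether the published projection averaged raw or state-weighted effector
signals is not recoverable; the state-weighted projection is used because
one formula then reproduces both quartile interpretations, and the choice is
recorded in output metadata.

## Group geometry

Groups of MoAs are compared as point sets over the full protein coordinate
list (a config switch restricts to an effector subset). The set distance is
the Dubuisson–Jain *modified Hausdorff distance*, their recommended
max-of-mean-nearest-neighbour variant; it is symmetric and zero only for
pointwise-coinciding sets but deliberately **not** a metric (no triangle
inequality — asserted, not assumed, in the tests). Within-group spread is
the mean distance to the centroid. The group dendrogram is plain UPGMA
implemented locally so distance ties break lexicographically on leaf names
(scipy's linkage is used as an oracle in tests, not in the path). The MoA
map is classical Torgerson MDS: double-centred squared distances,
eigendecomposition, axes by decreasing eigenvalue, each axis's sign fixed so
its first nonzero loading is positive. Zero eigenvalues yield zero
coordinates (collinear clouds embed flat); an axis that would need a
negative eigenvalue raises an error listing the spectrum. Coordinates and
trees are emitted as TSV/Newick text; plotting stays outside the core.

## Biomarkers

*Best-classifier proteins* are ranked by the leave-one-out accuracy of an
optimal single-threshold rule on each protein's signals (ties: smallest
threshold, "A if above" orientation preferred; a protein constant across
both groups scores 0.5 by convention; accuracies below chance are flipped
with their orientation). Protein *pairs* as axis-aligned two-threshold
conjunctions are available behind a flag (quadratic cost). The published
strategy is described only as "Data-Science"; the threshold stump is the
simplest faithful reading of classifying by one protein (or pair).

Candidates are then tested with the two-sided Mann–Whitney U (exact null
when both groups ≤ 8 without ties, tie-corrected normal approximation
otherwise, no continuity correction), adjusted with Benjamini–Hochberg
(configurable: none/BH/Bonferroni — the published table says only
"adjusted"), and kept when adjusted p < 0.01 **and** the group means have
strictly opposite signs. α is applied to adjusted values (the stricter
reading). The report's strength column is |mean_A · mean_B|; the packaged
reference table's printed strength column follows some other, unstated
formula and is therefore carried as read-only data and never recomputed.
The packaged table also backs an exact acceptance anchor: pushing its 30
rows through the filter keeps all 30 and partitions them 16/14, with 15 and
12 rows respectively flagged as adverse-event best classifiers.

A generic over-representation utility (one-sided Fisher exact per
user-supplied GMT gene set, BH adjustment, log10 odds ratio with Haldane
0.5 correction) supports downstream functional reading; no ontology is
bundled.

## Proximity cross-check

As an independent line of evidence, every protein is scored by random walk
with restart (restart 0.15, uniform over seeds, teleport from dangling
nodes; power iteration to 1e−12 in L1) on the *unweighted, undirected*
skeleton — a generic proximity scorer, deliberately not a replication of any
specific web service's algorithm. Per seed set (drug targets, indication
effectors, adverse-event effectors) the top 2% of nodes are cut (ties by
protein id; seeds retained with a warning if the cut would drop them),
unioned, and intersected with the biomarker list; enrichment is
hypergeometric against the network as background.

## Problem sizes and determinism

The shipped analysis and the acceptance script use the default toy scale:
300 nodes, 240 annealing runs, K = 200 selected MoAs (the published
ensemble size), 20 seeds for the recovery check — minutes on one CPU.
Every stochastic stage is a pure function of its seed; `run_all` writes a
manifest (config hash, seeds, versions) and identical configs produce
byte-identical artifacts.

## Known limitations

* Signals are qualitative; no dosage or expression magnitudes enter the
  model.
* The annealing objective counts general (`expression`) and specific
  (`effector`) restrictions equally; the weighting the original study used
  is not recoverable.
* The toy network's solution landscape is far smaller than a curated human
  protein network's; published headline counts that depend on the
  proprietary inputs (e.g. numbers of differential classifiers per
  phenotype) are not reproduction targets, only the published reference
  table's internal counts are.
* The toy landscape is largely *sign-stable*: ensemble strata differ in
  signal magnitude much more often than in sign, so the opposite-sign
  filter typically leaves very few (often zero) differential biomarkers on
  the default instance even when ~10 proteins are significant at adjusted
  p < 0.01. The filter's partition/annotation logic is exercised exactly by
  the packaged reference table instead.
* MHD is not a metric; the dendrogram over MHD values is a summary, not an
  embedding-consistent hierarchy.
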