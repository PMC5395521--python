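# Methods

This note documents the models implemented in `simboost`, the choices made
where the design was genuinely open, the synthetic data the tests run on, and
the limits of what those tests demonstrate.

## Problem setting

The input is a triple (M, D, T): a partially observed real-valued affinity
matrix over drugs × targets, and two square symmetric similarity matrices in
[0, 1] with unit diagonal (in practice: structure-fingerprint similarities for
compounds, normalized Smith–Waterman scores for proteins). Affinities are on a
log scale (pK_d, pK_i, or negated-and-shifted KIBA scores), so larger always
means stronger binding. The goal is to predict unobserved cells of M and to
attach a confidence measure to each prediction.

## Value transforms

* `kd_to_pkd`: K_d in nM → pK_d = −log10(K_d/1e9). The 10,000 nM
  "no-binding-detected" assay ceiling maps to pK_d = 5, producing the
  characteristic spike at 5 in dissociation-constant panels.
* `kiba_transform`: v → −v + max(observed values). KIBA scores decrease with
  binding strength; negation reorients them and the max-shift puts the
  transformed minimum at exactly 0. Under this reading the customary raw-score
  cutoff of 3.0 becomes 12.1 on the transformed scale as a rigid shift. The
  shift can be passed explicitly, which makes the transform an involution and
  lets callers undo it.
* `binarize`: threshold with the boundary counted as binding under both
  directions (`≥` for log-scale affinities, `≤` for raw KIBA scores).
  Binarization exists only for evaluation; training is always on continuous
  values.

## Feature engineering

Per pair (d_i, t_j), five fixed-length blocks are concatenated: Type 1 of the
drug, Type 1 of the target, Type 2 of the drug, Type 2 of the target, Type 3
of the pair. Defaults: similarity-graph threshold 0.5, k = 5 nearest
neighbours, 10 histogram bins, factorization rank 10. None of these have
canonical values in the read-across literature; all are exposed in
configuration.

Decisions worth recording:

* `ave.sim` and `hist.sim` include the self-similarity entry (a constant
  contribution identical for every entity; dropping it would only shift the
  feature).
* The k-nearest neighbours of a node are its *graph* neighbours (similarity
  strictly above the threshold) ranked by similarity, ties broken by ascending
  id. Entities with fewer than k neighbours pad `k.sim` with zeros; the
  neighbour-feature averages use only the neighbours that exist, and are NaN
  for isolated nodes.
* Betweenness and closeness use unweighted (hop-count) shortest paths on both
  the similarity graphs and the bipartite affinity graph; eigenvector
  centrality and PageRank use the edge weights (similarity or affinity) as
  adjacency weights. The centrality literature defines the hop-based variants
  as the default, and hop counts are invariant to the affinity scale.
* Eigenvector centrality is computed by power iteration on A + cI with
  c = max weighted degree: the shift leaves eigenvectors unchanged but makes
  the principal eigenvalue strictly dominant, which plain power iteration
  lacks on bipartite graphs (their spectra are symmetric about zero). On
  disconnected graphs the score is computed on the largest component and is
  zero elsewhere, since the principal eigenvector is not unique across
  components. Tolerance 1e−8, hard iteration cap, convergence failure is an
  error naming the component.
* Undefined statistics (no observations, no qualifying neighbour) are NaN —
  the native missing marker that gradient-boosted trees route by learned
  default directions. Imputing a constant would inject a fake affinity.
* All features derive from the training observations, D and T only. The test
  suite asserts bitwise equality of all features and factor matrices after
  tampering with every held-out affinity.

## Matrix factorization

Plain SGD on the regularized squared error over observed cells, no bias
terms. Factors are initialised N(0, 0.1/√k); cells are visited in a seeded
shuffled order; the per-cell update is `p += η(e·q − λp)`, `q += η(e·p − λq)`
(the ½-scaled gradient, constant absorbed into the learning rate η). The
regularized objective is recorded per epoch; a non-finite objective raises an
error suggesting a smaller learning rate. Defaults: rank 10, λ = 0.01,
η = 0.01, 100 epochs. On noiseless data of known rank the factorization
recovers held-out cells essentially exactly (the suite checks RMSE < 0.05 on
a rank-3, 50%-observed 100×50 matrix; typical error is below 1e−6). The inner
loop is JIT-compiled with numba. Cold entities keep their initialised factor
columns, preserving the feature-length contract.

## Gradient boosting

`SimBoostRegressor` delegates tree construction to xgboost under the squared
loss with Ω(f) = γT + ½λΣw². The estimator pins one thread and a fixed seed,
making training reproducible; the base score is the label mean. Defaults:
500 rounds, learning rate 0.05, max depth 4, subsample 0.8, colsample 0.8,
λ = 1, γ = 0. Depth 6 with full sampling — a common default — measurably
overfits at the training sizes used here (a few thousand pairs) and was
rejected after held-out comparisons; the regularized setting won on every
seed inspected.

### Quantile loss

The pinball loss implemented is

    l(y, u) = α(y − u)      if y > u
              (1 − α)(u − y) if y < u

with gradient dl/du = −α·I(y>u) + (1−α)·I(y<u) and the second-order term
fixed to 1 (the loss is piecewise linear). Note the sign convention: the
boosting library expects gradients of the loss with respect to the
prediction, which is the negative of the ascent direction on (y − u) often
written in derivations; a finite-difference check over random (y, u, α)
triples is the source of truth and part of the acceptance suite. The
affinity-weighted variant multiplies loss and gradient by y (labels must be
non-negative); the second-order term stays 1, the weight lives in the
gradient only.

`SimBoostQuantRegressor` trains the ensemble twice, at α and 1 − α; the
interval is [min, max] of the two outputs (rare quantile crossings are
repaired by sorting and their frequency recorded in `crossing_rate_`), the
point prediction is the midpoint. Quantile ensembles default to shallower,
subsampled, shorter configurations (depth 2, subsample 0.7, 300 rounds):
deeper quantile models memorise the training-set quantiles — training
exceedance stays calibrated while held-out interval coverage collapses
towards 0.35 — whereas the shallow setting keeps held-out coverage near
nominal.

Two properties of the weighted loss deserve emphasis. First, weighting by y
tilts *both* quantiles toward high-affinity pairs, so the weighted interval is
not calibrated for marginal coverage (measured ≈ 0.65 at α = 0.1 versus
≈ 0.77 for the plain pinball interval under the conditions below). It is a
prioritisation device — sharpest where affinities are high — not a coverage
device. Coverage checks therefore use the unweighted interval; the weighted
variant's coverage is reported alongside as a diagnostic. Second, interval
width behaves as an applicability-domain signal: per-target mean width falls
with the number of observations available for the target.

## Evaluation protocol

* RMSE; concordance index over all label-distinct pairs with prediction ties
  counting ½ (label ties are excluded from the denominator; the
  implementation is an exact chunked enumeration, checked against a brute-
  force double loop); AUC by tie-corrected rank statistic and AUPR by
  step-wise precision–recall integration (average precision — trapezoidal
  interpolation overestimates PR area). Binarization of the *true* labels
  happens at evaluation time only.
* Folds: per target, observed cells are shuffled and dealt round-robin from a
  random offset, so any target with ≥ 2 cells spans ≥ 2 folds; global fold
  sizes are then balanced by moves that preserve the constraint (max–min gap
  ≤ 1). A config switch additionally enforces the drug-side constraint.
* `cross_validate` rebuilds factorization and features per fold from training
  cells only, pools each repetition's held-out predictions before computing
  metrics (one value per metric per repetition), and reports mean ± sd over
  repetitions. The MF baseline reuses the factorization fitted for the
  Type-3 features of that fold.

## Synthetic data

`generate_dataset` emulates the structure of kinase-panel benchmarks. For
latent vectors u, v (cluster centroid + jitter) and main effects a_i, b_j:

    true(i, j) = baseline + a_i + b_j + softplus(u·v) + w·sin(u·v)
                 + idiosyncratic terms

* Main effects (sd 0.5) emulate promiscuous targets and sticky compounds —
  the dominant signal in real panels, which the `ave.val` features read off
  directly.
* softplus gives the long right tail above the non-binding baseline (5.0 on a
  pK-like scale); `sin` (weight 1.0) adds non-linear interaction signal.
* The idiosyncratic terms (weight 0.4 per side) are random per-target and
  per-drug loadings on the partner's latent vector, independent of D and T:
  entity-specific binding quirks that similarity cannot predict and that are
  learnable only from the entity's own observations. They make sparsely
  observed entities genuinely harder to predict — the premise behind interval
  widths shrinking with observation count.
* The observation mask combines a global density with log-normal per-entity
  propensities (sd 0.8 by default), giving the long-tailed per-entity
  observation counts real panels show; probabilities are renormalised after
  clipping so the realised density matches the nominal one, and entities are
  topped up to ≥ 2 observations (real benchmarks guarantee minimum coverage
  by filtering), which keeps the fold constraint feasible.
* D and T are cosine similarities of the latent vectors mapped from [−1, 1]
  to [0, 1] by (s+1)/2; observed values add Gaussian noise (sd 0.3 log
  units). One `numpy.random.default_rng(seed)` stream drives everything;
  fixed seed ⇒ bitwise-identical output.

Defaults (100 drugs × 60 targets, density 0.25) represent a small sparse
panel in the regime where read-across matters; the protocol-scale experiments
in the acceptance script use 150 × 100 at density 0.2 with propensity sd 1.2,
which leaves ≥ 2000 training cells per fold split. These sizes are the
package's desk-scale choice; the real benchmarks are one to two orders of
magnitude larger.

What the generator does **not** emulate: assay heterogeneity across
K_d/K_i/IC50 sources (the data-integration problem), measurement censoring at
detection limits, non-Gaussian error, and similarity matrices estimated with
error. Passing tests on this generator show the pipeline's mechanics and
qualitative behaviour (boosted read-across beats the bilinear baseline in the
sparse regime; interval width tracks information), not performance on any
real panel.

## Numerical and degenerate-input choices

* Similarity matrices: asymmetry ≤ 1e−8 is averaged away, larger asymmetry is
  an error; values outside [0, 1] by more than 1e−8 are an error, never
  clipped silently.
* Similarity-graph edges require similarity strictly greater than the
  threshold; isolated nodes are retained.
* Neighbour ties everywhere break by ascending entity id (determinism).
* `concordance_index` is undefined (error) when all labels are equal; AUC/AUPR
  require both classes.
* Quantile crossing is repaired by sorting the two model outputs per pair.
* CLI exit codes: 0 success, 1 usage/config, 2 data, 3 numerical failure.

## Known limitations

* The affinity-weighted interval trades coverage for sharpness on strong
  binders (see above); users who need calibrated intervals should set
  `weighted=False`.
* Interval coverage is near, but systematically below, the nominal 1 − 2α,
  because quantile regression captures conditional label spread, not the
  model's own generalization error; at desk-scale training sizes that
  epistemic component is visible (~0.75–0.79 observed at nominal 0.80).
* The MF feature extractor and the MF baseline share one fit per fold — by
  design (the baseline is exactly the Type-3 feature source), but it means
  baseline quality is tied to the feature configuration.
* Betweenness on large dense graphs is the slowest pipeline step; the
  implementation targets panels of a few hundred entities per side.
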