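# Methods

This note documents the statistical model behind `vcforge`, the defaults
and the numerical choices, and what the synthetic-data experiments do and
do not demonstrate.

## Model

A longitudinal cohort is modelled as a discrete Bayesian network
G = (V, E) whose nodes are (variable group, visit) pairs. The joint
factorizes as ∏_v p(X_v | X_pa(v)). Time is unfolded *explicitly*: each
visit gets its own copy of every longitudinal group with its own
conditional distribution, rather than the stationary first-order unfolding
of a dynamic Bayesian network. Patients' transition distributions in a
progressing disease change between visits, so parameter tying across time
slices would be a misspecification; the price is more parameters, which is
why groups are aggregated before learning.

### Missingness

Three mechanisms matter in study data: MCAR (ignorable), MAR (predictable
from observed data) and MNAR (depends on the unobserved value itself, e.g.
drop-out through symptom worsening). MNAR requires modelling the
missingness. Each (group, visit) block that exhibits missing values gets a
binary auxiliary node: 0 iff the *entire* block is absent for a patient.
Aux nodes are structural: the search may never add or remove their edges —
each aux node is clamped as a parent of its group node at the same visit
and of the same group's aux node at the next visit, and nothing else. The
whole-block rule is a deliberate choice: the distinction worth modelling is
*systematic* absence (drop-out, skipped assessment); a partially observed
block (some features present) is treated as ordinary scattered missingness
and left to imputation. Scattered cells are completed with missForest:
initialise with column mean/mode, loop over columns in increasing
missingness order refitting a random forest per column, stop when the
convergence statistic (normalised squared change for continuous columns,
category-flip fraction for categorical ones) first increases, and return
the state of the previous sweep. Imputation runs jointly over the full
wide table — all visits as predictors — so late-visit values can inform
early-visit gaps and vice versa. Defaults: 100 trees, at most 10 sweeps.
Observed cells are never altered (asserted at runtime).

### Aggregation

One sparse autoencoder per multi-feature (group, visit) block compresses
the block to a module score (default latent dimension q = 1, so each group
maps to a single network node; configurable). The encoder is
x̃ = s(Wx + b), the decoder z = s′(W′x̃ + b′), trained by Adam on
MSE + l2·‖W‖² with dropout applied to the *input* layer — the sparsity
device: each gradient step sees a random subset of inputs, discouraging
reliance on any single feature. Continuous inputs are z-scored with
training statistics (stored for encode/decode at simulation time).
Hyperparameters (one- or two-layer encoder, sigmoid/relu, dropout
{0.2, 0.5}, l2 {1e-4, 1e-3}) are selected on a held-out 20 % split by
reconstruction MSE. Single-feature blocks bypass the autoencoder
(identity): there is nothing to compress and degenerate training is
avoided. The networks are tiny (tens of inputs), so training is plain
numpy with manual backprop; determinism follows from the seed.

Input influence uses the Gedeon measure: per neuron,
P_ij = |w_ij| / Σ_p |w_pj|; across layers, P_ik = Σ_r P_ir · P_rk (sum of
path products). Each layer's matrix is column-stochastic, hence so is the
product: influences are non-negative and sum to one per latent output.
Influence is computed on the encoder stack only — the quantity of interest
is how inputs drive the module score.

### Discretization

Structure search needs closed-form marginal likelihoods, so module scores
(and continuous statics) are discretized. Two modes, chosen per run:

* **supervised** — when a clinically meaningful per-patient label exists
  (e.g. baseline diagnosis), a depth-limited univariate CART tree is fit
  to (score → label) and its thresholds become cut points. Defaults:
  at most 4 levels, minimum leaf 5 % of n. Constant inputs yield one
  level; a single label class falls back to the unsupervised mode with a
  warning.
* **unsupervised** — univariate Gaussian mixtures with 1..5 components,
  selected by BIC; values map to their maximum-responsibility component,
  levels ordered by component mean. Responsibility assignment (rather
  than fixed cut points) handles overlapping components.

Applying a map clamps out-of-range values to the boundary levels and
passes missing values through. Cut-point maps are monotone by
construction.

### Structure and parameters

Class-level rules (the prior knowledge layer) expand into a node-level
edge blacklist/whitelist. The shipped default rule set encodes:
demographics may influence but never be influenced; imaging features
relate only to each other; diagnosis depends on cognition, never the
reverse; everything not forbidden is allowed. Two structural families are
always added: no edge points backwards in time, and aux nodes carry only
their fixed wiring. The expansion is deterministic, and blacklist and
whitelist are disjoint by construction.

The structure score is a decomposable Bayesian-Dirichlet marginal
likelihood with a uniform pseudo-count α per CPT cell (equivalent sample
size α·∏levels per family), matching the parameter estimator
θ = (count + α)/(N + α·L); unobserved parent configurations therefore give
uniform rows. Default α = 1. Search is local over add/delete/reverse
moves with family-score caching; hill climbing restarts from random
constraint-respecting DAGs (default 50 restarts), tabu search keeps a
move-reversal tabu list (length 10). Both accept only score-improving
moves — the decomposable score makes each step's gain exact, and a
post-hoc assertion verifies every output respects the constraints. Score
ties break on lexicographic edge order, making results reproducible.
Algorithms are ranked by k-fold (default 10) cross-validated negated
held-out log-likelihood; edge confidence is the relative frequency over
bootstrap resamples of patients (default B = 1000).

### Simulation, filtering, interventions

Virtual patients are ancestral samples: nodes in topological order,
children conditioned on drawn parent values. Because model misfit or
unobserved confounding can make some draws unrealistic, every batch is
scored by the conservative filter: a bagged ensemble of class-weighted
decision trees (default 500) trained real-vs-virtual, with the real class
weighted 100:1 in the split criterion and leaf values. A virtual patient's
confidence is its **out-of-bag** probability of class real — trees that
memorised the patient do not vote, which is also what R's `predict(rf)`
reports for training rows; in-sample scoring with fully grown trees would
be pure memorisation. Patients below the 50 % threshold are rejected and
sampling repeats (default at most 50 rounds) until the target size is
reached. The 100:1 weight implements the asymmetry of the problem:
misclassifying a real patient as virtual is the serious error, so the
filter only discards virtual patients with essentially no real support.

Interventions follow Pearl: do(X_k = x) is conditioning in the *mutilated*
network with all edges into X_k removed. Targets become roots, so logic
sampling (forward sampling with rejection of evidence-inconsistent draws)
needs no rejection for pure do-interventions; per-patient target vectors
(e.g. cognition scores shifted towards a healthy median and re-encoded
through the trained autoencoder) are supported by pinning the target
column. Plain conditioning — a different operation, which does propagate
to ancestors — is available separately via rejection sampling.

### Evaluation

The headline similarity metric is the standardized partial AUC of a
real-vs-virtual random forest, restricted to sensitivity ≥ 0.9 for the
real class: the region where real patients are nearly always detected,
because misclassifying a virtual patient as real is the lesser error. The
raw partial area A (trapezoidal, specificity integrated over sensitivity)
is standardized as ½·(1 + (A − A_min)/(A_max − A_min)) with
A_max = 1 − s₀ and A_min = ½(1 − s₀)² (the chance diagonal over the same
region), so 0.5 is chance. The statistic is assessed over repeated
stratified k-fold cross-validation (default 10×10). Univariate similarity
uses per-variable 2×L χ² homogeneity tests, BH-corrected (the correction
method is configurable). Per-patient confidence scores are exported as
data; visualisation is left to downstream tools.

## Synthetic ground truth

`synthgen` generates cohorts with exactly the structure the model assumes:
discrete latent group scores under a known forward-in-time DAG (temporal
backbone g@t → g@t+1 plus random cross-group edges, CPT entries kept in
[0.05, 0.95] so no relation is deterministic), continuous emissions
x = loading·(level − centre) + N(0, σ) with loadings U(0.5, 1.5) of random
sign and σ = 0.5, and monotone MNAR drop-out: from the second visit on, a
still-observed block drops with hazard
strength · sigmoid(1.5·(level − centre)) — worse scores mean higher
drop-out — and stays dropped afterwards. Latents are generated directly as
discrete levels so that the fitted network's estimand is exactly defined;
the continuous emissions exist to exercise imputation, autoencoding and
discretization. Three levels per node is the default, matching the
few-level discretizations the method produces on real data.

What passing tests on this generator shows: the machinery is correct —
samplers match enumeration oracles, estimators recover known parameters
and structures, the filter and metrics behave as claimed under the model's
own assumptions. What it does not show: robustness to real-data features
the generator lacks — non-monotone missingness, heavy-tailed or
multimodal emissions within a group, measurement batch effects, model-class
violations beyond finite-sample error.

## Experiment sizes

The packaged experiments run at desk scale, chosen once: chance-level
discriminability uses one cohort of n = 600 (4 groups × 6 features × 3
visits) split in halves under 10×10-fold CV; the conservative-filter
comparison averages 10 seeds at n = 600 with k = 5 × 2 repeats per
comparison and VC size 600; structure recovery bootstraps B = 200
replicates at n = 400 on a cross-visit-only graph (within-visit edges are
orientation-ambiguous within the Markov equivalence class, so their
bootstrap frequency splits between directions — a property of
identifiability, not of the learner); parameter recovery uses a binary
chain with CPT probabilities in [0.3, 0.7] at n = 2000, where every parent
configuration is well populated and the 0.05 recovery tolerance is
attainable. Evaluation forests default to 100 trees; filter ensembles
to 500.

## Known limitations

* Group definitions and constraint rules must be supplied; the package
  does not infer them.
* q > 1 module scores produce multiple columns per group, but the shipped
  constraint expansion assumes one node per (group, visit).
* The conservative filter offers no formal re-identification guarantee;
  privacy-preserving training of the autoencoders is out of scope.
* Hybrid continuous/discrete (conditional-Gaussian) networks are not
  implemented; discretization is the supported path.
* Constraint-based and hybrid structure-learning algorithms (MMHC,
  RSMAX2, MMPC, SI-HITON-PC) are not shipped; score-based hill climbing
  and tabu search are.
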