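# Methods

This note documents the models, conventions, and numerical choices behind
`impactnet`, in enough detail to reimplement the pipeline or to judge what
its tests do and do not demonstrate.

## 1. Efficiency metrics (`netcore`)

A connectome is a weighted, symmetric, zero-diagonal matrix over n
parcellated regions; weights carry volume-normalized streamline-count
semantics and are required to be nonnegative.

**Weight-to-length mapping.** Shortest-path computation needs lengths, not
affinities.  A present edge of weight w is assigned length w_max / w, where
w_max is the matrix maximum (or an explicitly supplied normalization weight
— see lesioning below).  This is the reciprocal convention of the standard
connectivity toolboxes, applied after normalizing by the maximum so that all
lengths are ≥ 1.  Consequences:

* global efficiency is invariant to uniform rescaling of all weights;
* the idealized network — every possible edge present at the normalization
  weight — has all pairwise distances exactly 1, so E(G_ideal) = 1 and
  GE = E(G) ∈ [0, 1], with GE = 1 exactly for a uniform complete graph.

All-pairs shortest paths are computed with Dijkstra's algorithm
(`scipy.sparse.csgraph.shortest_path`); zero entries denote absent edges.
Unreachable pairs have infinite distance and contribute 1/∞ = 0 to the
efficiency sum — disconnected inputs (routine in lesioned networks) are
therefore valid, never errors.  Floating-point ties between path lengths are
irrelevant: only the lengths enter the metric.

**Local efficiency** of a node is the raw efficiency of the subgraph induced
by its neighbors (the node excluded), normalized by that subgraph's own
maximum weight; nodes with fewer than two neighbors score 0.

A `binarize` helper replaces every present edge with unit weight for
analyses that prefer binary topology; the default everywhere is weighted.

## 2. Lesion simulation and importance ranking (`lesion`)

Deleting a node set removes its rows and columns; surviving region ids are
preserved (never reindexed) for traceability.  The importance of a deletion
is

    ΔGE = (GE_intact − GE_lesioned) / GE_intact.

Two conventions deserve emphasis because "normalized change" admits
alternatives:

* **Node count:** the lesioned network's efficiency uses its *own* node
  count n − k in the 1/(n(n−1)) prefactor — the lesioned network is the
  network whose efficiency is being measured.
* **Length normalization:** the lesioned network's lengths are computed with
  the *intact* network's maximum weight, so ΔGE reflects lost communication
  rather than a change of units when the strongest edge happens to be
  deleted.

ΔGE is signed: 1 means total disconnection, and negative values occur
legitimately (removing an isolated region raises average efficiency).

**Sweeps** enumerate every k-subset in lexicographic region-id order for
k ∈ {1, 2, 3}: 129, 8256, and 349504 deletions at the 129-region scale.
Every region appears in exactly C(n−1, k−1) subsets (128 for pairs, 8128
for triples).  Triple sweeps over more than 60 regions must be requested
explicitly (`allow_large=True` / `--full-scale`); a full 129-region triple
sweep is ~350k Dijkstra evaluations and is the one deliberately expensive
operation in the package.

**Rank aggregation.** For k = 1 a region's score is its own ΔGE.  For
k ∈ {2, 3} each combination receives a rank r (1 = largest ΔGE; ties broken
by lexicographic subset order) and a weight; a region's score is the sum of
the weights of the combinations containing it, divided by its appearance
count.  The default weight is the linear reverse rank w(r) = C(n,k) − r + 1.
This is an interpretive choice — rank-weighted aggregation can be defined
several ways — so the weight function is pluggable (`inverse_rank` = 1/r and
a `top_decile` indicator ship as alternatives), and the package's own
consistency test checks that single- and pair-deletion rankings agree
(Spearman ρ ≥ 0.8 on hub-planted networks), which is the property that makes
the aggregation scheme's details immaterial in practice.

Cohort importance averages per-region ΔGE (k = 1) or per-subject aggregate
scores (k > 1) across subjects.  Everywhere in the package, ranks 1..n are
assigned in decreasing score order with ties broken by ascending region id.

## 3. Strain analytics (`strain`)

**Percentile convention.** rMPS and MPS95 are 95th percentiles of
element-strain samples.  The package uses linear interpolation between
closest ranks (numpy's default); FE post-processors differ on this, so the
method is a parameter.

**Strain ranking.** Regions are scored by their mean rMPS over concussive
cases only (median available by flag); non-concussive cases never influence
the ranking.

**Group tests.** Concussive vs non-concussive comparisons use the two-sided
Wilcoxon rank-sum test with midranks for ties.  When the smaller group has
at most 8 observations and there are no ties, the p-value comes from the
exact Mann–Whitney null distribution; otherwise from a tie-corrected normal
approximation with continuity correction (a dead-center statistic therefore
gives p = 1 exactly).  Per-region tests over the atlas are Bonferroni
corrected at α/n (α = 0.05, n = the region count by default, both
configurable); the four kinematic peaks and MPS95 are tested uncorrected.

**Ranking correlation.** The strain and network rankings are compared by
Pearson correlation of their score vectors (default) or rank vectors
(Spearman-style), with the two-sided p from the t transform.  Both views are
reported by the pipeline since the underlying question — do the two schemes
pick the same regions — does not dictate a scale.

## 4. Risk model (`riskmodel`)

Binary concussion outcomes are modeled with logistic regression
(scikit-learn's LBFGS implementation).  Predictors are standardized
internally; coefficients are reported on the original scale.  An unpenalized
maximum-likelihood fit is attempted first; if it fails to converge or shows
the runaway standardized coefficients characteristic of complete separation
(|β| > 30, odds ratios beyond e³⁰), the model is refit with a small ridge
penalty (10⁻⁴ on standardized coefficients) and flagged.  Small,
well-separated impact datasets make this path routine rather than
exceptional.

**Cross-validation.** Leave-one-out: each case is predicted by a model
trained on the other N − 1.  Folds whose training set contains one class
predict the training class rate — counted, never fatal, so a 53-fold run
always completes.  Reported per predictor set:

* accuracy, sensitivity, specificity at a 0.5 threshold on out-of-fold
  probabilities (the threshold is a convention; the probabilities are
  retained in the report for any other choice);
* AUC of the pooled out-of-fold probabilities ("testing AUC"), via the
  Mann–Whitney midrank formulation P(s⁺ > s⁻) + ½P(s⁺ = s⁻);
* the mean training-fold AUC.

**Known limitation — pooled LOOCV AUC under the null.**  Pooling
leave-one-out scores into a single ROC is the natural reading of "AUC for
the testing set using the probability scores", and on informative
predictors it behaves well.  On *uninformative* predictors it is
systematically pessimistic: holding out a positive case lowers its training
fold's class rate and pulls the fitted coefficients away from it, so its
own out-of-fold score drops by O(1/N) relative to a held-out negative.  In
the extreme (a constant predictor) the pooled scores are exactly the fold
prevalences and the AUC collapses to 0; for noise predictors it centers
around ~0.3–0.45 rather than 0.5, with heavy-tailed predictors worst.  The
test suite asserts this real behavior rather than an idealized 0.5, and the
null-calibration claims of the pipeline rest on the accuracy metric (which
does converge to the majority-class rate) rather than on the pooled AUC.
Per-fold-averaged or leave-pair-out AUC estimators avoid the artifact at
substantially higher cost and are out of scope here.

**Predictor-set evaluation.** The number of predictors is capped by the
events-per-variable rule (⌊events/5⌋ = 4 at 20 concussive events).
Incremental sets take the top-k regions of a ranking strictly in rank order
(region-id tie-break); univariate baselines cover the four kinematic peaks
and MPS95.  Per-subject evaluation repeats the top-k analysis under each
subject's own ΔGE ranking and reports the accuracy spread across
connectomes — the quantity that makes individual brain architecture a
visible factor in predicted risk.

## 5. Synthetic data (`synthdata`)

The generator emulates the statistical structure the analysis needs, with
planted ground truth for recovery testing.  All generators are
deterministic: same arguments and seed, bit-identical output.  Randomness
everywhere flows from explicit seeds through `numpy.random.default_rng`
streams derived per stage and per subject; there is no global random state.

**Atlas.** n regions (default 129) split ~3:1 cortical:subcortical across
two hemispheres, with names drawn from common parcel vocabulary.  Network
hubs (default 10) are planted among subcortical regions and high-strain
regions (default 10) among cortical ones, disjoint by default — mirroring
the empirical pattern that impact strain concentrates in lateral cortex
while communication bottlenecks sit in subcortex.

**Connectome.** A modular random graph (4 index-based modules) whose
intra-module edges are `intra_module_bias` (default 2) times more likely
than inter-module edges, with the inter-module probability solved so the
expected non-hub density equals `density` (default 0.15).  Edge weights are
log-normal (σ = 0.5), emulating volume-normalized streamline counts, whose
empirical distributions are heavy-tailed and positive.  Planted hubs attach
with `hub_weight_boost`-fold probability *and* carry `hub_weight_boost`-fold
weights (default 3): degree and strength together are what make a node's
deletion expensive for global efficiency, and a pure weight boost without
degree elevation does not produce the hub-dominance the analysis studies.
Graphs are rejection-sampled until connected (bounded attempts, then a
generation error reporting the count); intact networks must be connected so
that ΔGE is interpretable, while lesioned networks may disconnect freely.

**Cohort.** One base connectome per seed, perturbed per subject by
mean-one multiplicative log-normal edge noise with log-sd
`between_subject_noise` (default 0.3).  Zero noise reproduces the base
exactly; between-subject edge variability grows monotonically with the
knob.

**Impacts.** A single latent severity per case drives everything: with
s = exp(δ·[concussive] + ε), ε ~ N(0, 0.35²) and δ = ln(shift), each of the
four kinematic peaks is scale·s·exp(noise) and the strain field is
profile·s·exp(noise) per region.  The concussive severity multiplier
`concussion_strain_shift` (default 1.5) thus makes kinematics and strain
stochastically larger in concussive cases through one knob, and shift = 1
is an exact null in which outcome labels are independent of every
observable.  The region profile is static per dataset: log-normal
(σ = 0.15) around a 0.15 strain scale, with planted high-strain regions
elevated 2-fold.  Element strain is emulated by 200 gamma draws per region
(shape 6, scaled to the region mean); rMPS is the region-wise 95th
percentile and MPS95 the 95th percentile of the pooled sample — the
percentile operation applied to an explicit element sample rather than an
FE mesh.

The per-channel noise σₙ is derived in closed form from the requested
kinematics–strain coupling ρ (default 0.83): with
v = 0.35² + f(1−f)·ln(shift)² the latent log-variance including the
concussive/non-concussive mixture term, σₙ² = ln(1 + (eᵛ − 1)/ρ) − v, which
targets the raw-scale Pearson correlation between two log-normal
observables sharing the latent.  Measured at n = 500 cases this yields
sample correlations of 0.82 ± 0.02 against the 0.83 request.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: real parcel geometry and volumes (weights are
log-normal, not derived from tract counts over anatomy), spatially
correlated strain fields (regions are conditionally independent given
severity), distance-dependent connection probability, hemispheric
asymmetries, and any within-subject relationship between a subject's
connectome and the impacts (impacts and connectomes are independent, as in
the motivating study design, where the impacted players and the imaged
subjects are different people).  Recovery and calibration results
demonstrate that the *pipeline* behaves correctly on data with the assumed
structure, not that the assumed structure is the true structure of NFL
impacts or DSI connectomes.

## 6. Pipeline, configuration, determinism (`pipeline`, `cli`)

`RunConfig` is a flat key=value record (losslessly serialized beside every
run); its hash, excluding the output location, stamps every output table
together with the seed.  `run_pipeline` executes generate → efficiency
metrics → per-subject deletion sweeps → cohort importance → strain ranking
→ ranking correlation → group tests → predictor-set evaluation under both
rankings → per-subject evaluation, writing TSV/JSON artifacts and a
structured log with stage timings.  A stage failure aborts with the stage
name after writing a partial manifest.  Reruns of an identical
configuration reproduce every numeric output byte for byte (the manifest
and log contain wall-clock timings and are the only exceptions).  If the
configured predictor count exceeds the events-per-variable cap for the
configured event count, the pipeline clamps to the cap and logs it; the
library call itself treats the same condition as an error.

Default configuration is the study's native scale with single-node sweeps;
pair sweeps are opt-in per run and triple sweeps at full scale additionally
require `--full-scale`.

## 7. Problem sizes used by the test and acceptance runs

Chosen to exercise every claim at meaningful scale while keeping a desk-run
footprint: oracle equivalence on exhaustively enumerable graphs (≤ 8
nodes); planted-structure recovery at full 129-region scale with 5-subject
cohorts, averaged over 10 seeds; null calibration with 15 seeds of 53-case
datasets at 129 regions; rank-sum type-I error at 1000 replicates;
logistic parameter recovery at n = 2000; end-to-end determinism at 24
regions with k ∈ {1, 2}.  The acceptance script runs the native-scale study
(30 subjects, single-node sweeps) in about two minutes on one CPU.
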