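# impactnet

Concussion risk prediction at the intersection of impact biomechanics and
brain-network analysis.

Finite-element (FE) head models estimate where the brain deforms during an
impact; graph theory on diffusion-imaging connectomes tells us which brain
regions matter most for network communication.  `impactnet` implements an
analysis pipeline that joins the two: it ranks parcellated brain regions by
the strain they experience in concussive impacts, ranks them independently
by how much their *in-silico* deletion degrades the connectome's global
efficiency, compares the two rankings, and asks which family of regional
predictors better separates concussive from non-concussive impacts under
leave-one-out cross-validated logistic regression.

Because the real inputs of such studies — reconstructed professional-football
impact kinematics run through an FE model, and diffusion spectrum imaging
connectomes — are not publicly distributable, the package ships a fully
seeded synthetic-data generator that emulates their statistical structure at
native scale (a 129-region parcellation, 30-subject connectome cohort, 53
impacts of which 20 are concussive) with known planted ground truth, so that
every step of the pipeline can be tested for recovery, calibration, and
determinism.

The intended audience is researchers in injury biomechanics and network
neuroscience who want a tested, reproducible reference implementation of
this analysis to run on their own connectome matrices and regional strain
tables (both are plain TSV).

## The quantities at the core

**Global efficiency.** For a weighted network G with n nodes and shortest
path lengths d(i, j),

    E(G)  = 1 / (n (n − 1)) · Σ_{i≠j} 1 / d(i, j),      GE(G) = E(G) / E(G_ideal)

where G_ideal has every possible edge present.  Stronger connections are
shorter: an edge of weight w has length w_max / w, so all lengths are ≥ 1,
E(G_ideal) = 1, and GE ∈ [0, 1].  Unreachable pairs contribute 0.

**Lesion importance.** Deleting a node set S and all its connections changes
efficiency by

    ΔGE(S) = (GE_intact − GE_lesioned) / GE_intact,

computed for every single node, every pair (C(129,2) = 8256 deletions), and
every triple (C(129,3) = 349504 deletions).  For multi-node deletions each
combination is ranked by ΔGE and a region's importance is its
reverse-rank-weighted appearance total, normalized by how often it appears
(128 per region for pairs, 8128 for triples).

**Strain metrics.** rMPS is a region's 95th-percentile maximum principal
strain during an impact; MPS95 is the 95th percentile over the whole brain.
Regions are ranked by mean rMPS over concussive impacts.

**Prediction.** Concussion likelihood is modeled by logistic regression on
at most 4 predictors (5 events per variable with 20 concussive events),
evaluated with leave-one-out cross-validation: accuracy, sensitivity and
specificity at a 0.5 threshold on out-of-fold probabilities, the AUC of the
pooled out-of-fold probabilities, and the mean training-fold AUC.

## Worked example

```python
from impactnet import (gen_atlas, gen_cohort, gen_impacts, make_ground_truth,
                       cohort_importance, sweep, rank_by_strain,
                       ranking_correlation, evaluate_predictor_sets)

atlas = gen_atlas(n_regions=129, n_hubs=10, n_strain_regions=10, seed=7)
truth = make_ground_truth(atlas, seed=7)
cohort = gen_cohort(atlas, n_subjects=5, between_subject_noise=0.3, seed=7)
impacts = gen_impacts(atlas, n_cases=53, n_concussive=20, truth=truth, seed=7)

dge = cohort_importance([sweep(c, 1) for c in cohort])      # network ranking
strain = rank_by_strain(impacts, atlas.region_ids)          # strain ranking
rho, p = ranking_correlation(strain, dge)
print(f"high-dGE regions (top 5): {dge.top(5)}")
print(f"high-rMPS regions (top 5): {strain.top(5)}")
print(f"strain vs network ranking: rho = {rho:.3f}, p = {p:.3f}")
```

prints

```
high-dGE regions (top 5): [54, 124, 60, 95, 90]
high-rMPS regions (top 5): [107, 20, 81, 123, 99]
strain vs network ranking: rho = -0.094, p = 0.287
```

The two rankings recover the planted structure — regions 54, 124, 60, 95, 90
are planted subcortical hubs and 107, 20, 81, 123, 99 planted cortical
high-strain regions — and are uncorrelated with each other: the regions that
deform most are not the regions whose loss most degrades communication.
Feeding both rankings into the cross-validated risk model,

```python
for r in evaluate_predictor_sets(impacts, strain, max_k=4):
    print(r.predictor_set, f"accuracy={r.accuracy:.2f}", f"AUC={r.auc_testing:.2f}")
```

yields (univariate kinematic/MPS95 baselines first, then incremental top-k
rMPS sets)

```
('peak_lin_vel',) accuracy=0.75 AUC=0.79
('peak_ang_vel',) accuracy=0.70 AUC=0.77
('peak_lin_acc',) accuracy=0.58 AUC=0.70
('peak_ang_acc',) accuracy=0.74 AUC=0.78
('mps95',) accuracy=0.72 AUC=0.78
('rmps[107]',) accuracy=0.70 AUC=0.75
('rmps[107]', 'rmps[20]') accuracy=0.72 AUC=0.75
('rmps[107]', 'rmps[20]', 'rmps[81]') accuracy=0.70 AUC=0.77
('rmps[107]', 'rmps[20]', 'rmps[81]', 'rmps[123]') accuracy=0.70 AUC=0.75
```

— strain-based regional predictors are about as accurate as whole-brain
MPS95 and peak kinematics, the study's central comparison.

## Command line

The same pipeline is scriptable from a shell:

```
impactnet generate --n-regions 129 --n-subjects 30 --n-cases 53 \
    --n-concussive 20 --seed 1 --out-dir data/
impactnet lesion-sweep --in data/connectomes/subject_00.tsv --k 1 --out s0.tsv
impactnet rank --sweeps sweeps/ --out importance.tsv
impactnet strain-rank --impacts data/impacts.tsv --out strain_rank.tsv
impactnet group-tests --impacts data/impacts.tsv --out tests.tsv
impactnet correlate --a strain_rank.tsv --b importance.tsv --out corr.json
impactnet predict --impacts data/impacts.tsv --ranking strain_rank.tsv \
    --max-k 4 --out report.json
impactnet run --seed 11 --out-dir runs/demo    # the whole thing, end to end
```

`impactnet run` writes every table (TSV) and report (JSON) plus the resolved
configuration; rerunning the same configuration reproduces all numeric
outputs byte for byte.

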