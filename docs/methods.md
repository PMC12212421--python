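# Methods

This note documents the models and procedures implemented in `hnmil`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic validation does and does not show.

## Synthetic phantom cohorts

Each patient is a 3D voxel grid in Hounsfield units (default 96×96×40 voxels
at 1×1×3 mm — anisotropic, as routine CT is) containing:

- a soft-tissue body ellipsoid (~40 HU) in an air background (~−1000 HU);
- a flat high-density couch slab (250 HU) along the posterior edge,
  deliberately disconnected from the body so that threshold-plus-largest-
  component body masking is genuinely exercised;
- an ellipsoidal GTVp (~60 HU) with per-axis radius jitter, radius drawn
  from 8–22 mm, and additive Gaussian intensity noise whose standard
  deviation ("heterogeneity", 5–30 HU) is the texture signal.

**Risk model.** The latent log-hazard is a linear combination of z-scored
log tumor volume, z-scored heterogeneity, and the centered N stage, with
default coefficients `{volume: 0.8, texture: 0.8, n_stage: 0.25}`. N stage is
drawn from a cumulative-logit model whose location increases with the
volume/texture risk, so nodal stage is both an outcome correlate and a
clinical covariate, as in real registries. Event times for each endpoint are
exponential with rate `h0 · exp(latent_risk)` (`h0` = 0.009/month, giving a
~20–25% 2-year event rate at the defaults, comparable to published HNSCC
registry OS event fractions), with independent exponential censoring at
0.004/month; this is the simplest generator whose Cox hazard ratios are
recoverable by construction. Persistent disease is an independent Bernoulli
flag (p = 0.05). Clinical covariates (age, sex, T stage, HPV status,
chemotherapy) are drawn correlated with the latent risk — HPV positivity is
more likely at low risk, matching its favorable prognosis — and are deleted
completely at random (p = 0.05 per value) to exercise imputation.

**Dichotomization.** Events at or before 24 months are positive; event-free
follow-up reaching 24 months is negative; event-free follow-up ending earlier
is excluded as lost to follow-up; an event recorded at time zero is excluded
as ambiguous; persistent disease excludes a patient from the LRC endpoint
only. Only these adjudication rules are implemented; other forms of
ambiguous endpoint data have no analogue in the generator.

**What the phantoms do not emulate:** real anatomy and organ texture, scanner
and reconstruction effects, contrast phases, multi-lesion disease,
non-proportional hazards, and informative censoring. Passing the recovery
tests therefore shows that the *pipeline* can extract a planted
volume/texture risk signal under its own assumptions — not that any
particular AUROC would be attained on clinical data.

## CT preprocessing

Body masking thresholds at −500 HU, keeps the largest connected component,
fills holes, and replaces everything outside (couch, air) with −1024 HU.
Volumes are resampled to 1 mm isotropic (CT trilinear, mask nearest-neighbor).
The 2D route windows to soft tissue (level 50 HU / width 120 HU, rescaled to
[0, 1]) and takes one 224×224 crop per mask-positive slice per requested
view, centered on the in-plane projection of the GTVp center of mass
(rounded half-up) and zero-padded at borders. The 3D route rescales
[−1024, 2048] HU to [0, 1] and samples one hundred 50³ subvolumes with
centers from N(centroid, 16·I), rounded to voxel indices and *clamped* (not
rejected) at boundaries so that exactly n instances are always produced.
Axial is the last array axis; masks are {0,1}.

## Feature extraction and augmentation

An extractor is anything exposing `input_kind`, `embedding_dim`, and a
deterministic `map(array) → vector`; an adapter for a real frozen backbone
would own its model-specific input normalization behind this contract. The
bundled toy extractor summarizes an instance on a coarse grid (16×16 for
patches, 8×8×8 for subvolumes) with two channels — local mean and local
standard deviation — then applies a fixed seeded Gaussian projection and
tanh. The second-moment channel is essential: it is what lets intra-tumor
intensity variance (the texture signal) reach the embedding; a mean-only
coarsening is nearly blind to it.

Each instance gets one augmented twin at extraction time (rotation uniform in
[0°, 10°], bilinear with zero fill; Gaussian blur σ = 1 px with probability
½ — σ chosen as a standard mild-blur default), mirroring an
extract-once/train-many workflow with precomputed augmented features. The
augmentation is drawn once per instance, not re-drawn per epoch, because
features are precomputed; the training loop then chooses between the plain
and augmented matrix per bag per epoch.

## MIL model and training protocol

The classifier is a pre-norm transformer encoder (default 2 layers, 8 heads,
model dim 512 — the experiment pipeline uses a smaller 64-dim / 4-head
configuration appropriate to toy embeddings) with no positional encoding, so
bags are sets and predictions are exactly permutation-invariant. Attention
pooling computes one logit per token from its layer-normalized value; softmax
weights (reported per patient, summing to 1) pool the tokens, and a sigmoid
head scores the bag. Forward and backward passes are hand-written NumPy;
the test suite checks every parameter's gradient against central finite
differences.

Training: weighted BCE with inverse-class-proportion weights computed on the
training fold; Adam (β₁ = 0.95) with cosine annealing from 1e-3 to zero over
the scheduled epochs; default 64 epochs with early-stopping patience 15
(the pipeline's synthetic experiments use 10 epochs, which suffices at this
problem size); per-epoch per-bag coin flips (p = ½) between plain and
augmented features; gradient accumulation over minibatches of bags (default
8 in the pipeline), equivalent to padded batching for a mean loss; holdout
evaluation and checkpointing on plain features only. The recorded protocol
value of 1e-4 for a "maximum allowed" learning rate is kept in the
configuration as provenance (`lr_max_recorded`) but the schedule anneals
from the initial rate: the two stated values are mutually inconsistent, and
at small epoch budgets a 1e-4 peak leaves the model untrained.

Cross-validation is class-stratified 5-fold (seeded, default 1337). The
deployed model is the fold whose holdout AUROC is closest to the CV median
(ties to the lowest fold id). Training-cohort MIL scores used downstream —
the median stratification cutoff, the multivariate log-odds-ratio analysis,
and fitting the multimodal fusion — are *out-of-fold* scores (each patient
scored by the fold that held it out): the deployed model has trained on 4/5
of the cohort and its in-sample scores are optimistic to the point of
quasi-separation. Test cohorts are always scored by the deployed model.

## Radiomics

Features are computed from the base image inside the GTVp, as a documented
IBSI-style subset (no parity with any particular extraction tool is
claimed): morphology (volume as voxel count × voxel volume; surface area by
exposed-face counting; sphericity `(36πV²)^⅓ / A`; maximum 3D diameter as
the largest pairwise distance between boundary-voxel centers, via the convex
hull), first-order statistics (mean, variance, skewness, excess kurtosis,
energy, fixed-bin-width histogram entropy with 25 HU bins anchored at
multiples of the bin width, 10th/90th percentiles, min, max), and GLCM
texture (32 equal-width levels over the in-mask range; symmetric normalized
co-occurrence aggregated over the 13 unique 3D direction offsets at distance
1, out-of-mask neighbors skipped; contrast, correlation, joint entropy,
dissimilarity, homogeneity). Degenerate conventions: constant regions have
zero variance/entropy/skewness, GLCM contrast 0 and correlation defined
as 1.

Selection chain, in order: (1) drop near-zero-variance features; (2)
z-score; (3) average-linkage hierarchical clustering on distance
1 − |Spearman ρ|, cut at 0.20; (4) one representative per cluster — the
member with the highest mean |Spearman ρ| to its co-members (absolute
values; ties broken alphabetically); (5) mRMR in the difference (MID) form —
relevance is |point-biserial correlation with the label|, redundancy the
mean |Spearman ρ| with already-selected features; (6) keep
k = ⌊n_minority/10⌋, minimum 1. The classifier is an unpenalized logistic
regression on z-scores whose standardization parameters are learned on the
training cohort and frozen for deployment.

## Clinical and multimodal models

Missing clinical values are imputed with training-set means (numeric) or
modes (categorical, deterministic tie-break), frozen for test cohorts.
T/N stage enter as ordinal integers by default (dummy coding available);
HPV is dummy-coded against a "negative" reference; the non-HPV-positive
subgroup keeps negative *and* unknown patients. The baseline is a logistic
regression with balanced class weights (the n/(2·n_c) convention); the
multimodal model appends the MIL score as one numeric covariate. The
multivariate log-odds-ratio report comes from an unpenalized fit with Wald
95% intervals; rank-deficient designs and (quasi-)separation are flagged
rather than silently reported.

## Statistics

- AUROC is the Mann–Whitney concordance probability with ties counted ½.
- CIs are percentile intervals from 1000 class-stratified bootstraps
  (resampling within each class, preserving counts).
- Model comparison: paired score-permutation test — under the null of
  exchangeable models each patient's two scores are swapped independently
  with probability ½; the p-value uses the +1 finite-resampling correction,
  two-sided by default.
- Stratification: the cutoff is the training-cohort median score; scores
  strictly above it are high-risk (ties to low-risk). Separation is
  assessed by the logrank test and a univariate Cox fit of the high-risk
  indicator (Efron tie handling; HR > 1 means more events in the high-risk
  arm). A split leaving one group empty or only one group with events is
  flagged degenerate and reported without HR/logrank values.
- Correlations with clinical factors: Spearman ρ for ordinal/numeric
  variables (age, T, N), point-biserial for binary ones (sex, chemotherapy,
  HPV-positive indicator); constant variables are flagged.
- Multiplicity: Benjamini–Hochberg step-up adjustment over each comparison
  family.

## Orchestration and reproducibility

One global experiment seed fans out to per-stage seeds through SHA-256
(`stage_seed(seed, stage_name)`, truncated below 2³¹), so stages can be
re-run in isolation and two runs of the same configuration produce
byte-identical reports. The experiment report carries provenance (seed,
stage seeds, cohort sizes, mode, embedding dimension).

## Problem sizes used in validation

The test suite and the acceptance script validate at deliberately desk-scale
sizes chosen as the smallest at which each property is stable: signal
recovery on 300 training / 200 test phantoms with 128-dimensional toy
embeddings and 10 training epochs; calibration and coverage checks over
100–500 simulated replicates; exhaustive oracles at n ≤ 20. The full suite
and the acceptance run each complete in a few minutes on one CPU.

## Known limitations

The MIL transformer's exact topology (dimensions, pooling variant) is a
declared default, not a community standard; the radiomics set is a subset of
the IBSI families (no GLRLM/GLSZM/NGTDM, no filtered-image or peritumoral
features); the permutation scheme for comparing models admits variants and
the implemented per-patient swap is one documented choice; bootstrap CIs are
percentile, not BCa; and all empirical performance statements in this
repository are about synthetic phantoms, not clinical cohorts.
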