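# Methods

This note documents the modelling choices behind `somdbn`: the pipeline's
stages and their assumptions, the defaults and why they are set where they
are, what the synthetic-data generators do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Problem setting and assumptions

The target data are small clinical screening tables: hundreds of records,
fewer than a dozen continuous measurements, a binary outcome, and
substantial missingness encoded as physiologically impossible zeros
(serum insulin, skinfold thickness, diastolic blood pressure, plasma
glucose, BMI). The pipeline assumes:

* **Missingness is MCAR** (mask independent of values). Under MCAR,
  observed-cell column means are unbiased and the mean-anchored SVD
  imputation below is consistent. Under informative missingness (e.g.
  sicker patients skipping a measurement) the imputed values and the
  downstream classifier would both be biased; nothing in the pipeline
  detects or corrects this.
* **The cohort is heterogeneous**: records fall into latent subgroups
  (clusters), and the outcome's relationship to the measurements may
  differ between subgroups. This is why clustering precedes both
  imputation and classification, and why each cluster gets its own
  imputation statistics, feature subset and classifiers.
* **Within a subgroup, the measurements are approximately low-rank**:
  a few latent physiological factors plus noise. This justifies rank-d
  truncated-SVD completion with small d.

## Pipeline stages

### Zeros-as-missing masking

`mask_zeros_as_missing` sets mask bits where designated columns equal 0;
values are never rewritten, so the operation is idempotent and the raw
table remains inspectable. The default column set is
{glucose, blood pressure, skinfold, insulin, BMI}; a pregnancy count of
zero is a valid value and is never masked.

### Normalization

Columns are z-scored with observed-cell statistics: B̄_j and σ_j (sample
SD, divisor m_obs − 1) over unmasked cells, missing z-scores set to 0 —
i.e. missing values start at the column mean. A constant observed column
gets σ_j := 1 (logged), making its z-scores 0 rather than undefined.

### SVD imputation

One cycle is: z-score → best rank-d approximation Z_d (truncated SVD) →
replace each missing cell with B̄_j + σ_j (Z_d)_ij. A single cycle cannot
exploit structure at the missing cells themselves, so `impute` iterates
the cycle to a fixed point, refilling missing cells with their current
predictions each time. Two numerical points:

* **Column statistics are recomputed from the refilled matrix each
  cycle.** Centering a rank-r matrix by anything outside its row space
  adds a rank; with statistics frozen at observed-cell values the
  z-score matrix of a planted rank-2 matrix is generically rank 3 and a
  d = 2 truncation has an error floor (masked-cell RMSE ≈ 0.06 on the
  planted fixture). With the EM-style recomputation the same fixture is
  recovered to ≈ 1e-9.
* **Deterministic SVD signs**: each left singular vector's
  largest-magnitude entry is made positive, so repeated runs are
  bit-identical.

Defaults: d = 2, tol = 1e-4 on the maximum absolute change at a missing
cell (original units), max_iter = 100. Non-convergence returns the last
iterate with a flagged log entry; on noisy data the trailing changes are
typically far below the data scale.

Out-of-sample completion (scoring a new record) does not refit anything:
the record's rank-d coefficients are estimated by least squares on its
*observed* coordinates in the stored basis V_d, and missing coordinates
are reconstructed from those coefficients. This is the exact conditional
completion in the stored basis; iterating a plain projection instead
converges to the same fixed point but more slowly.

In the pipeline, each cluster's basis is estimated on a trimmed core:
records whose per-observed-coordinate z-distance exceeds 2.5× the cluster
median are excluded from basis estimation (not from classification). A
handful of boundary records from a neighbouring cluster sit roughly one
centre-separation away and would otherwise dominate the scatter and
hijack the rank-2 basis (measured on the planted fixture: masked-cell
RMSE 2.3 with strays in, 0.37 with the trim).

### PCA denoising

Hand-rolled on the thin SVD of the centred matrix (no external
dependency in the fitted path). Default: the smallest number of
components explaining ≥ 90 % of variance, feeding the SOM only; the
classifiers always see the original feature space. PCA can be disabled
(`use_pca=False`), in which case the SOM runs on the z-scores directly.
Component signs follow the same largest-entry-positive convention.

### SOM clustering

Canonical online Kohonen training: Gaussian neighborhood on lattice
coordinates, exponential decay of learning rate (0.5 → 0.01) and radius
(max(rows, cols)/2 → 0.3) over 200 epochs, seeded shuffle per epoch.
Clusters are identified with map units (2×3 grid → six clusters); there
is no secondary agglomeration of units. Two schedule choices matter and
were set empirically on the planted-cluster fixture:

* **Final radius 0.3** (not 0.5): with the larger final radius, adjacent
  units keep pulling on each other strongly enough that on ~20 % of
  seeds the map ends with a dead unit and one unit covering two planted
  clusters; quantization error shows the defect directly.
* **200 epochs** (not 100), for the same reason.

Map quality: quantization error (mean record–BMU distance) and
topographic error (fraction of records whose two best units are not
8-neighborhood adjacent; defined as 0 for a 1×1 grid).
`select_grid_size` scans candidate grids and picks the lowest
quantization error with topographic error as tie-break.

BMU ties are broken toward the lowest unit index, making degenerate
inputs deterministic.

### Stepwise discriminant feature selection

Backward elimination on Wilks' lambda Λ = det(W)/det(T) (within-group /
total scatter). The partial F for removing one feature from a p+1-feature
subset with two groups is F = (n − 2 − p)(Λ_without/Λ_with − 1), with
p-value from F(1, n − 2 − p). The stay level defaults to α = 0.15, the
conventional stay threshold for stepwise discriminant procedures. At
least one feature is always retained so downstream classifiers stay
well-posed. Removing the only feature compares against the empty model
(Λ = 1), which reduces the single-feature F to the squared pooled
two-sample t — used as an exact cross-check in the tests. A
zero-variance feature is defined to have F = 0, p = 1 (it cannot
discriminate); determinants with such a feature present are otherwise
singular and raise.

Boundary semantics: features are removed while their p-value exceeds α,
so α → 0⁺ strips the set down to one feature and α → 1 keeps everything.

### DBN classifiers

Bernoulli–Bernoulli RBMs on features min–max-scaled to [0, 1] (per
cluster; scaler stored with the model; out-of-range prediction inputs
are clipped). Pretraining: CD-1 with learning rate 0.1 and momentum 0.5,
batch size 100 (clamped to the cluster size with a warning), 200 epochs.
The stack (two hidden layers, 16 and 8 units by default) is unrolled
into a feed-forward logistic network topped by a logistic classification
layer and fine-tuned by mini-batch backpropagation on the cross-entropy.

Optimization choices, set after the plain small-init recipe measurably
failed on this problem scale:

* **RBM weights initialize at Glorot scale √(2/(I+J))**, not 0.01. With
  near-zero weights, hidden activations are ≈ 0.5 everywhere, the
  unrolled network starts on the symmetric plateau, and 200 epochs of
  fine-tuning end at chance accuracy even on linearly separable data.
* **Fine-tuning uses momentum 0.9 with a Glorot-initialized top layer**;
  learning rate 0.5 standalone, 0.2 inside the pipeline (0.5 oscillates
  on some ~90-record clusters). Plain gradient descent at small rates
  does not leave the plateau within the epoch budget.
* **Stall-detecting restarts**: per subnetwork the pipeline trains up to
  `finetune_restarts` (default 2) independent (pretrain, fine-tune)
  pairs — an unlucky pretraining draw can leave a stack that stalls at
  the base rate for the entire run — keeps the lowest final training
  loss, and retries (bounded at restarts + 4) while the best final loss
  is not below 0.8× the best constant predictor's cross-entropy.

Classification is one-vs-rest: one single-logistic-output DBN per class
per cluster, label = argmax of the two subnetwork scores, exact ties to
class 0. A two-output-unit variant is selectable
(`subnetwork_outputs=2`). Clusters with fewer than 20 training records,
or without both classes represented, use a global fallback DBN trained
on all records; 20 is the smallest size at which batch training and the
F-tests behave.

### Ensemble orchestration

`DiabetesEnsemble.fit()` runs, on training data only: mask → normalize →
PCA → SOM train/assign → per-cluster imputation → per-cluster selection →
per-cluster subnetworks → global fallback. Every fitted artifact
(normalization parameters, PCA loadings, SOM weights, per-cluster
imputation statistics and basis, feature subsets, scalers, network
weights, seeds) lives on the returned `EnsembleResults`, which is
JSON-serializable and sufficient to reproduce predictions bit-for-bit.
Prediction never refits: records are z-scored and routed to their BMU,
completed from the stored cluster statistics, restricted to the stored
subset, scaled and scored. Fit-time stages see exactly the completion a
scored record gets, so training and serving cannot drift apart.

Holdout evaluation uses a stratified split (default 70/30, master seed
42); `accuracy_over_seeds` repeats generate → split → fit → evaluate over
replicate seeds.

## Synthetic data

`generate_low_rank` plants B = L R + noise (i.i.d. standard normal
factors) with a uniform MCAR mask, refusing masks that leave a column
with < 2 observed cells. The truth object stores the pre-masking values
at masked positions.

`generate_clustered_classes` is the pipeline's end-to-end test bed. It
plants, per cluster: an isotropic Gaussian centre (centres rescaled so
the minimum pairwise distance equals `separation`, default 10), a
rank-2 factor structure (scale `factor_sd` = 2) plus isotropic noise
(`noise_sd` = 0.3), so each cluster's submatrix is strongly low-rank —
the regime the imputer targets, and the regime in which a masked cell's
class-relevant content is recoverable from the other columns. Labels
follow a steep logistic link (sharpness 25) on a score over
`n_informative` = 3 designated features, with the score direction
flipping sign between even and odd clusters — so clustering genuinely
carries label information and a single global model cannot match the
per-cluster rules. The intercept is set so the marginal positive rate
matches `class_balance` (default 268/768, the screening cohort's rate).
The sharpness default makes the planted rule nearly deterministic
(irreducible error ≈ 2 %): a verification fixture should fail because an
implementation is wrong, not because its labels are noisy — with softer
labels (sharpness 8–10) even an oracle logistic regression fitted per
true cluster to the uncorrupted values cannot exceed ~0.90 holdout
accuracy at this sample size, leaving no margin to attribute failures.

What the generator does *not* emulate: realistic marginal distributions
(values can be negative; units are arbitrary), correlated or informative
missingness, measurement heteroscedasticity, label noise that depends on
the features, or cluster-size imbalance beyond multinomial sampling.
Passing the end-to-end checks therefore demonstrates that the machinery
is correct and that the method's premises help when they hold — not that
the pipeline reaches any particular accuracy on real cohorts.

`generate_pima_like_cohort` is a synthetic stand-in for the public
screening cohort, for exercising the data-description path: it plants
exactly 768 records, 268 cases / 500 controls, the published per-column
zero-sentinel counts (glucose 5, blood pressure 35, skinfold 227,
insulin 374, BMI 27) and the published mean ± SD per column (pregnancy
count 3.84 ± 3.36, etc.). Skewed nonnegative measurements use
standardized exponential deviates so the exact moment match cannot
produce negative values; diabetic records get standardized-unit shifts
on glucose, insulin, BMI, age and pregnancy count before the moment
match so the outcome carries a realistic signal. It emulates the
published *description* of the cohort, not the joint distribution of the
real measurements.

## Known limitations

* The rank-d basis of a cluster is estimated from at most a few hundred
  records; with more than ~40 % missingness in a column the basis and
  the completion degrade together, and below d + 2 records the cluster
  falls back to column-mean imputation.
* Sigmoid networks of this size cannot represent razor-thin decision
  boundaries on [0, 1]-scaled inputs within a 200-epoch budget (the
  required first-layer weight magnitudes are of order 100); on fixtures
  with near-deterministic labels an occasional cluster/seed draw
  remains at its base rate even after restarts. Reference
  implementations (a scikit-learn MLP with logistic activations and
  several thousand Adam iterations) fail on the same draws, while only a
  near-unregularized linear model solves them.
* Backward selection at α = 0.15 on ~90-record clusters has appreciable
  selection variance; an informative feature is occasionally dropped in
  favour of a correlated proxy.
* CD-1's update direction approximates the likelihood gradient only for
  moderate weights and non-degenerate gradients; the agreement checks
  condition on |∇| ≥ 0.5 because the angle of a vanishing gradient is
  meaningless.
* One-vs-rest coordination trains the two subnetworks independently;
  their scores are not calibrated against each other beyond the shared
  data.

## Problem sizes used in the checks

The end-to-end verification runs the full pipeline and both ablations on
m = 800 records (six planted clusters, 20 % missingness in the five
maskable columns) over ten replicate seeds — about four minutes on one
CPU; the enumeration, identity and brute-force oracles all run on
problem sizes where the exact computation is instant (RBMs with ≤ 8
units, matrices of a few thousand cells, 10⁴-query BMU scans).
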