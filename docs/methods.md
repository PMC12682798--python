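# Methods

`gradconn` re-implements, as a tested pipeline, an analysis that links
macroscale structural-connectome gradients measured in infancy to cognitive
outcome scores (IQ) measured years later: gradient extraction by diffusion-map
embedding, cross-subject alignment, scanner harmonization, a spectral
graph-convolutional regressor with a paired-difference loss, repeated
cross-validated evaluation with permutation significance, and gradient-based
regional relevance maps. Because the underlying MRI cohort is not distributed
with the package, every stage is exercised on a synthetic cohort generator
whose structure mirrors the statistical assumptions of the analysis. This note
records the models, the parameters that matter, and the design decisions taken
where the protocol left room.

## Connectome preprocessing

A structural connectome (SC) is a square nonnegative region-by-region matrix of
streamline counts (148 regions in the default bilateral parcellation, half per
hemisphere). Raw counts are symmetrized as the arithmetic mean of the matrix
and its transpose (the mean, rather than the sum, is a fixed point on already
symmetric input), diagonals are zeroed (tractography self-loops carry no
meaning), and the matrix is scaled so the strictly-lower-triangular entries sum
to 1. Normalization is idempotent and ratio-preserving; a matrix with no
off-diagonal mass is rejected rather than silently passed through.

## Gradients

Connectivity profiles (matrix rows) are compared by cosine similarity after
per-row sparsification: the smallest `row_sparsity` fraction of entries in each
row is zeroed (default 0.9, i.e. each region keeps its strongest decile of
connections; deterministic tie-break by column). Cosine of nonnegative vectors
gives a symmetric affinity in [0, 1] with unit diagonal.

The diffusion-map embedding uses anisotropic normalization with exponent
alpha = 0.5: K = D^-a W D^-a, then the row-stochastic operator P = D_K^-1 K.
P is eigendecomposed through its symmetric conjugate D_K^1/2 P D_K^-1/2 for
numerical stability and the eigenvectors back-transformed. The trivial
constant eigenvector (eigenvalue 1) is discarded; the next `n_components`
(default 10) eigenvectors, scaled by lambda/(1 - lambda) (diffusion time 0, the
automatic multi-scale weighting) or lambda^t for t > 0, are the gradients.
An eigenvalue's share of the retained non-trivial total is its explanation
ratio. alpha, the diffusion time and the sparsity level are declared package
defaults (the conventions of the widely used gradient toolboxes), not values
fixed by the protocol, and are recorded in output metadata.

Eigenvector sign and rotation are not identified, so each subject's gradient
matrix is aligned to a reference template by orthogonal Procrustes rotation
(no scaling or translation). The template is either supplied externally —
for prediction it is built from an independent reference set of 10 subjects, so
no information flows between cross-validation folds through the template — or
computed by generalized Procrustes analysis (iterated align-and-average;
convergence tolerance 1e-7 in Frobenius norm, cap 500 iterations, warning and
best iterate on non-convergence). Template column signs are fixed so each
column's largest-magnitude entry is positive. Hemisphere-specific gradients are
computed on the within-hemisphere principal submatrices (interhemispheric
connections excluded), with the right hemisphere Procrustes-aligned to the left
when the hemispheres have equal region counts.

## Harmonization

Scanner batch effects are removed by parametric empirical-Bayes location/scale
adjustment (ComBat). Features are standardized by their covariate-adjusted
grand mean and pooled variance from a full-rank design (batch one-hot plus
covariates; collinear covariates are rejected by name); per-batch location and
scale effects are shrunk toward normal and inverse-gamma priors with the
standard iterative update (convergence 1e-4, cap 100 iterations); the batch
effects are then removed and the covariate and grand-mean structure restored.
The implementation is cross-checked in the test suite against the Bioconductor
reference (`sva::ComBat`) to 1e-4 on a shared fixture. Covariates follow the
study protocol: gestational age at birth, sex, and the two head-motion
surrogates (number of DWIs with large translation, number of excluded DWIs).
All gradient components are harmonized jointly as one feature matrix.

Two cross-validation modes exist: `combined` fits ComBat on the combined
train+test data of each fold (the study protocol, chosen there because ~10
test subjects per fold are too few for reliable scanner-effect estimation) and
`train_only` fits on the training folds only and applies the model to the test
fold (the leakage-free best practice). The harness records a `leakage_free`
provenance flag.

## The graph-convolutional regressor

Each subject is a graph: nodes are regions, the adjacency is the subject's own
normalized SC matrix, and node features are the subject's first
`n_input_gradients` aligned gradients (default 2: the principal and secondary
gradients). The normalized Laplacian L = I - D^-1/2 A D^-1/2 (spectrum in
[0, 2]; lambda_max computed exactly by a symmetric eigensolver, no
lambda_max ~ 2 shortcut) is rescaled to Ltilde = 2 L / lambda_max - I
(spectrum in [-1, 1]). Two graph-convolution layers apply order-K Chebyshev
filters,

    H^(l+1) = relu( sum_{k=0..K} T_k(Ltilde) H^(l) W_k^(l) ),   K = 3,

with hidden widths (16, 16); node features are then flattened — preserving
region identity, which the regional relevance maps require — and passed through
an MLP (one hidden layer of 64 rectified units) to a linear scalar output.
Targets are IQ scores mapped to [0, 1] by (IQ - 50)/100; predictions are
clipped to [0, 1] only for reporting, as a squashing output head would distort
the difference structure the loss works on.

The objective is

    L = sum_i (y_i - f_i)^2
        + w_siamese * sum_{i != j} [ (y_i - y_j) - (f_i - f_j) ]^2,

with w_siamese = 10 and pairs taken over all ordered pairs within each
minibatch. The paired term preserves inter-subject heterogeneity; it is
invariant to a constant shift of all predictions and vanishes exactly when the
residual is constant (closed form 2 n sum(e^2) - 2 (sum e)^2, verified against
the double loop).

Training is Adam at initial learning rate 0.005 for exactly 300 epochs,
minibatch 10, no early stopping, final-epoch parameters. Two numerical choices
are package decisions documented here because the level of the predictions is
only weakly constrained (the dominant paired term is shift-invariant):

* the learning rate follows a cosine decay from the initial rate to zero, so
  the final-epoch iterate — which the protocol evaluates — is a settled one;
* the output bias is initialized at the training-target mean.

Without these, the per-fold prediction level wanders by several IQ points
(fold-offset SD ~7, as large as the within-fold prediction spread), which
scrambles ranks when out-of-fold predictions are pooled across the 10 folds.
A constant learning rate remains available (`lr_schedule="constant"`).

No autodiff engine is used: the backward pass is written out analytically
(Clenshaw-style adjoint of the Chebyshev propagation). Parameter and input
gradients are validated against central finite differences in the test suite
(1e-4 relative). Training arithmetic is float32 for speed; gradient-based
attribution and all gradient checks recompute in float64. Weight
initialization is scaled uniform fan-in; everything downstream of the seed
(initialization and epoch shuffling) is deterministic, and reruns with the same
seed are bit-identical.

Feature normalization: gradient components are z-scored separately per
hemisphere. Both readings of that operation are implemented: per-subject
across regions (`within_subject`), and per-feature across subjects
(`across_subjects`). The pipeline default is `across_subjects`: it is an
affine per-feature map that preserves between-subject regional structure,
whereas within-subject scaling removes each subject's hemisphere-level
information — on synthetic cohorts it demonstrably discards most of the
planted signal. In the leakage-free mode the standardization statistics come
from the training fold only.

## Evaluation

10-fold cross-validation repeated (default 10 times) with shuffled balanced
folds, deterministic from a master seed. Within each repetition the
out-of-fold predictions are pooled across the 10 folds and MAE (on the IQ
scale), Spearman's rho and Pearson's r are computed once per repetition;
summaries are mean ± SD across repetitions. Pooling is what makes the naive
mean-predictor baseline's correlation defined at all (its predictions are
constant within a fold but fold means differ) — and typically slightly
negative, as a train-mean predictor anti-tracks the held-out fold mean.

Significance uses a one-sided permutation test for positive association:
the predictions are shuffled (default 10,000 times), p = (1 + #{null >=
observed}) / (1 + n_perm); when n! <= n_perm the permutations are enumerated
exhaustively and the p-value is exact. Sidedness is a package decision (the
alternative of interest is predictive signal).

## Attribution

Saliency is |df/dx| at the subject's input; integrated gradients (IG)
averages df/dx along the straight path from a baseline to the input (midpoint
Riemann rule, default 50 steps) and multiplies by (x - baseline), so the
attributions sum to f(x) - f(baseline) (completeness; verified to 1e-3
relative at 200 steps). The IG baseline is all-zero features — the natural
origin for unitless embedding coordinates. Regional maps are produced by
averaging attribution across subjects, model fits and folds; because signed
relevance values are ambiguous for unitless coordinates, aggregation defaults
to magnitude mode (absolute value before averaging, components summed after),
with signed mode available. The top regions are the ceil(5% of N) largest
aggregated weights (ties broken by region id), and the consistent set across
target outcomes is their intersection.

One caveat: an isolated region (zero-degree node) is rejected when the
Laplacian is built, and the T_0 = I filter term feeds each region's own feature
into its node output regardless of connectivity — so "zero connectivity implies
zero saliency" does not hold verbatim. The corresponding exact property holds
for IG with the zero baseline (a region whose features equal the baseline gets
exactly zero attribution), and saliency contributions flowing through the graph
vanish as incident weights shrink (as sqrt of the weight, via the degree
normalization); both forms are tested.

## The synthetic cohort generator

The generator produces what the analysis assumes, not what a scanner produces:

* **Connectomes.** Regions carry a 1-D anterior-posterior (A-P) coordinate per
  hemisphere. Expected within-hemisphere weight decays exponentially with A-P
  distance (decay length 0.4 in normalized units); between hemispheres a weak
  flat background (0.1 of the intra scale) is augmented by homotopic
  ("callosal") connections between mirror regions whose strength peaks (0.9)
  for centrally located regions (Gaussian profile, width 0.12). The localized
  homotopic structure matters: it keeps the sparsified affinity graph connected
  while leaving interhemispheric affinity weak, so the group principal gradient
  separates the hemispheres and the secondary gradient tracks the A-P axis —
  the two axes the analysis expects — and the hemisphere-masked principal
  gradient correlates |rho| > 0.9 with the planted A-P coordinate.
* **Subject variability.** Multiplicative lognormal noise with two parts:
  a smooth per-subject regional field over the A-P axis (three cosine modes
  per hemisphere, mode m amplitude 0.25/m) entering as exp(f_i + f_j), and
  i.i.d. symmetric edge noise (sigma 0.2). The smooth field encodes spatially
  coherent individual differences — the component of real inter-subject
  variation a learner can generalize from at cohort sample sizes; with purely
  independent edge noise the planted signal is present but unlearnable at
  n = 92 (an oracle given the relevant regions reaches rho ~ 0.6 while any
  blind learner stays near 0). Noise draws are consumed identically regardless
  of the sigma settings, so cohorts with different noise levels stay paired.
* **Scanner effect.** Two batches in a 67/33 split (62/30 at n = 92). The
  minority batch's interhemispheric block is scaled by 1.2 — a structural
  perturbation that propagates into the gradients, where ComBat can act on it.
  (A uniform multiplicative effect would be cancelled by the normalization and
  the cosine kernel; a feature-space shift would never reach a pipeline that
  recomputes gradients from connectomes. The feature-space location/scale
  effect is still available as `add_batch_effects` and is what the
  harmonization oracle tests use.)
* **Outcome.** IQ = 100 + 15 (sqrt(es) * signal + sqrt(1 - es) * eps), with
  eps standard normal, effect size es = 0.35, and signal the standardized mean
  gradient value over 5 planted left-hemisphere regions (evenly spread along
  the A-P axis). The signal is read from the A-P gradient component of the
  *clean* (pre-scanner-effect) connectomes: the hemisphere-separation
  component is nearly constant within a hemisphere by construction, so the
  within-hemisphere regional structure the outcome couples to lives on the A-P
  component; and planting on clean connectomes makes the scanner effect a
  nuisance rather than part of the signal. corr(signal, IQ) = sqrt(0.35) ~ 0.59
  is the generator's ceiling for any predictor.
* **Covariates** (sex, gestational age, age at scan ~12.95 ± 0.94 months,
  motion counts) are drawn with realistic marginals and carry no planted effect
  on IQ; ComBat protects them, nothing in the pipeline uses them otherwise.

Ground truth (relevant regions, planted signal) is stored in a sidecar the
pipeline never reads; only recovery tests consume it.

What passing tests do and do not show: the generator plants a linear,
regionally sparse signal on smooth low-rank subject variation. Recovery of
that signal end-to-end demonstrates that the pipeline is wired correctly, that
harmonization, alignment and normalization preserve between-subject structure,
and that the regressor can exploit it; it does not show that real infant
connectomes carry such a signal, nor calibrate the effect size of biology
(the planted 0.35 is a test condition, not an estimate).

## Problem sizes and runtime choices

The end-to-end verification (the acceptance script's headline target and the
corresponding suite test) uses the full data scale of the emulated study —
n = 92 subjects, 148 regions, 300 epochs, 10-fold cross-validation with the
stated hyperparameters — with repetition counts chosen for desk-scale runtime:
the script averages 2 repetitions for each of five cohort seeds, and the suite
test 2 repetitions for each of two seeds. Training-behavior property tests
(determinism, null behavior, planted-signal fitting) run on small graphs
(16-40 regions), where a 300-epoch fit takes milliseconds. Measured at full
protocol (5 seeds x 3 repetitions) the mean pooled out-of-fold Spearman
correlation is 0.270; at the script's 5 x 2 it is 0.274.

## Known limitations

* The generator's geometry is a 1-D chain per hemisphere; real parcellations
  have 2-D cortical adjacency, long-range association bundles and
  lobe/network structure that are not modeled.
* The smooth subject field makes regional signals partially collinear with
  global modes, so attribution localization is evaluated on field-free
  cohorts; on default cohorts relevance maps are spatially smeared by
  construction.
* ComBat assumes feature-specific batch effects drawn from its priors; with an
  identical shift planted across all features, empirical-Bayes shrinkage
  leaves a residual at the sampling-error scale (visible in tests as a ~0.05 SD
  bound rather than exact removal).
* The permutation test treats subjects as exchangeable (no family structure or
  site stratification in the null).
* Predictions, like the emulated protocol's, are evaluated at the final epoch
  of a fixed-length run; there is no model selection, so reported correlations
  are conservative with respect to tuning but sensitive to the training-noise
  choices documented above.
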