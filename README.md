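# gradconn

Structural connectome gradients and graph-convolutional prediction of
early-childhood cognitive outcomes.

`gradconn` is for researchers who work with region-by-region structural
connectivity matrices (streamline counts from diffusion-MRI tractography) and
want to (a) summarize each subject's connectome as a small set of continuous
spatial *gradients*, and (b) test whether those gradients, measured in
infancy, predict cognitive scores (IQ) assessed years later. The package
implements the full analysis as a reusable, tested pipeline and ships a
synthetic cohort generator so every stage runs and is verified without any
imaging data.

## What it computes

**Gradients.** A subject's connectome `A` (symmetrized, normalized so the
strictly-lower-triangular entries sum to 1) is converted to an affinity matrix
by row-sparsified cosine similarity, `W[i,j] = cos(v_i, v_j)`, and embedded by
diffusion maps: eigenvectors of the Markov operator built from
`K = D^-1/2 W D^-1/2` (anisotropic normalization, alpha = 0.5), with the
trivial constant eigenvector discarded. Column k of the embedding is the k-th
gradient; its eigenvalue share is the *explanation ratio*. Subjects are
aligned to a reference template by orthogonal Procrustes rotation, and scanner
batch effects are removed from the gradient features by parametric
empirical-Bayes ComBat with covariates protected.

**Prediction.** A Chebyshev spectral graph-convolutional network regresses IQ
on the per-region gradient features, using each subject's own connectome as
the graph:

    H^(l+1) = relu( sum_{k=0..K} T_k(L~) H^(l) W_k^(l) ),
    L~ = 2L/lambda_max - I,   L = I - D^-1/2 A D^-1/2,   K = 3,

followed by a flattened-readout MLP. The loss is a weighted sum of squared
error and a paired inter-subject ("Siamese") term,
`sum_{i!=j} [(y_i - y_j) - (f_i - f_j)]^2` (weight 10), which preserves
between-subject heterogeneity. Evaluation is repeated 10-fold cross-validation
with out-of-fold predictions pooled per repetition (MAE on the IQ scale,
Spearman's rho, Pearson's r), a naive train-mean baseline, and permutation
tests for significance. Regional relevance maps come from saliency and
integrated gradients, magnitude-averaged across subjects and folds, with the
top-5% consistently selected regions reported.

The backward pass of the network is written analytically in numpy (no autodiff
framework) and is validated against finite differences in the test suite.

## Worked example

```python
import numpy as np
from gradconn import (
    SimulationConfig, GCNConfig, EmbeddingConfig, simulate_cohort,
    make_cv_plan, run_cv, naive_cv, permutation_pvalue,
    cosine_affinity, diffusion_map,
)

cohort = simulate_cohort(SimulationConfig(), seed=0)   # 92 subjects, 148 regions
gs = diffusion_map(cosine_affinity(cohort.connectomes[0], EmbeddingConfig()))
print(np.round(gs.explanation_ratio[:3], 2))

plan = make_cv_plan(cohort.n_subjects, k=10, n_repetitions=1, master_seed=0)
predictions, summary = run_cv(cohort, GCNConfig(), plan)
_, naive = naive_cv(cohort.iq, plan)
p = permutation_pvalue(predictions.predicted, predictions.observed,
                       n_perm=10_000, seed=0)
```

Output (a couple of minutes on one CPU):

```
cohort: 92 subjects, 148 regions, scanner batches {'scanner_A': 62, 'scanner_B': 30}
IQ: mean 99.8, SD 14.8
subject 0 explanation ratios: [0.19 0.18 0.18]
GCN   MAE 12.51  Spearman 0.190  Pearson 0.215
naive MAE 11.18  Spearman -0.293
permutation p-value: 0.0318
```

Reading the numbers: the generated cohort matches the instrument distribution
(IQ mean 100, SD 15) and the 67/33 two-scanner split. The cross-validated GCN
recovers a positive rank correlation between predicted and observed IQ
(rho = 0.19 in this single repetition; the planted signal carries 35% of the
IQ variance, so the ceiling for any predictor is rho ~ 0.59), significant
under a 10,000-shuffle permutation test (p = 0.032). The naive baseline, which
predicts each fold's training mean, has competitive MAE but *negative* pooled
correlation — the characteristic signature of a constant-per-fold predictor —
which is exactly why correlation rather than MAE separates predictive models
from trivial ones here.

A thin CLI mirrors the library:
`gradconn simulate | gradients | harmonize | train | evaluate | attribute`.

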