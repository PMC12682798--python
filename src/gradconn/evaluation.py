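"""Repeated k-fold cross-validated prediction, metrics and permutation tests.

The protocol: 10-fold cross-validation repeated 10 times with different
shuffled splits. Within each repetition, out-of-fold predictions are pooled
across the 10 folds and the metrics (MAE on the IQ scale, Spearman's rho,
Pearson's r) are computed once per repetition; the summary is mean +/- SD
across repetitions. Pooling is also what makes the naive mean-predictor
baseline's correlation defined (fold means differ), and typically negative.

Within each fold, gradients are aligned to the external reference template
(computed from independent subjects, so no leakage through the template), and
ComBat is applied either to the combined train+test data of the fold (the
study protocol, ``combat_mode='combined'``) or to the training data only with
the fitted model applied to the test fold (``'train_only'``, the leakage-free
best practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .embedding import EmbeddingConfig, cosine_affinity, diffusion_map, procrustes_align
from .gcn import (
    GCNConfig,
    inverse_minmax_iq,
    minmax_iq,
    precompute_graphs,
    zscore_by_hemisphere,
)
from .harmonization import ComBat
from .simulate import SyntheticCohort

__all__ = [
    "CVPlan",
    "MetricsSummary",
    "make_cv_plan",
    "metrics",
    "permutation_pvalue",
    "naive_baseline",
    "run_cv",
    "naive_cv",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for repeated k-fold CV, deterministic from a master seed."""

    n_subjects: int
    k: int
    n_repetitions: int
    seeds: tuple[int, ...]
    folds: tuple[tuple[int, ...], ...]  # per repetition: fold index per subject

    def fold_indices(self, repetition: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        assignment = np.asarray(self.folds[repetition])
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        return train, test


def make_cv_plan(n: int, k: int = 10, n_repetitions: int = 10, master_seed: int = 0) -> CVPlan:
    """Balanced shuffled folds per repetition (fold sizes differ by at most 1)."""
    if k > n:
        raise EvaluationError(f"k = {k} folds but only n = {n} subjects")
    rng = np.random.default_rng(master_seed)
    seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=n_repetitions))
    folds = []
    for seed in seeds:
        assignment = np.empty(n, dtype=int)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(splitter.split(np.arange(n))):
            assignment[test_idx] = fold
        folds.append(tuple(int(a) for a in assignment))
    return CVPlan(n_subjects=n, k=k, n_repetitions=n_repetitions, seeds=seeds, folds=tuple(folds))


def metrics(pred, obs) -> tuple[float, float, float]:
    """(MAE, Spearman rho, Pearson r) between predictions and observations."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or pred.size < 3:
        raise EvaluationError("metrics need equal-length vectors with >= 3 entries")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    mae = float(np.mean(np.abs(pred - obs)))
    rho = float(stats.spearmanr(pred, obs).statistic)
    r = float(stats.pearsonr(pred, obs).statistic)
    return mae, rho, r


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def permutation_pvalue(
    pred,
    obs,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "spearman",
) -> float:
    """One-sided permutation p-value for positive predicted-observed association.

    The statistic is the correlation between predictions and observations; the
    null is generated by shuffling the predictions. Sampled mode uses the
    add-one estimate p = (1 + #{null >= observed}) / (1 + n_perm). When n! <=
    n_perm the permutations are enumerated exhaustively and the p-value is the
    exact proportion #{null >= observed} / n!.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    n = pred.size
    if obs.size != n or n < 3:
        raise EvaluationError("permutation test needs equal-length vectors, n >= 3")
    if statistic == "spearman":
        a, b = _rank(pred), _rank(obs)
    elif statistic == "pearson":
        a, b = pred, obs
    else:
        raise EvaluationError(f"unknown statistic {statistic!r}")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    observed = float(a @ b) / n
    if math.factorial(n) <= n_perm:
        total = math.factorial(n)
        count = 0
        for perm in iter_permutations(range(n)):
            if float(a[list(perm)] @ b) / n >= observed - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null = (a[perms] @ b) / n
    count = int(np.sum(null >= observed - 1e-12))
    return (1 + count) / (1 + n_perm)


def naive_baseline(train_targets, test_size: int) -> np.ndarray:
    """Constant prediction equal to the training-set mean."""
    train_targets = np.asarray(train_targets, dtype=float)
    if train_targets.size == 0:
        raise EvaluationError("naive baseline needs non-empty training targets")
    return np.full(test_size, train_targets.mean())


@dataclass
class MetricsSummary:
    """Per-repetition pooled metrics and their mean +/- SD across repetitions."""

    per_repetition: pd.DataFrame  # columns: repetition, mae, spearman, pearson, r2
    provenance: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        return {c: float(self.per_repetition[c].mean()) for c in ("mae", "spearman", "pearson", "r2")}

    @property
    def sd(self) -> dict:
        return {c: float(self.per_repetition[c].std(ddof=1)) for c in ("mae", "spearman", "pearson", "r2")}


_COVARIATE_COLUMNS = (
    "gestational_age_weeks",
    "sex_male",
    "n_large_translation_dwi",
    "n_excluded_dwi",
)


def _summarize(rows: list[dict], provenance: dict) -> tuple[pd.DataFrame, MetricsSummary]:
    predictions = pd.DataFrame(rows)
    per_rep = []
    for rep, grp in predictions.groupby("repetition"):
        mae, rho, r = metrics(grp["predicted"], grp["observed"])
        per_rep.append(
            {"repetition": rep, "mae": mae, "spearman": rho, "pearson": r, "r2": r * r}
        )
    summary = MetricsSummary(per_repetition=pd.DataFrame(per_rep), provenance=provenance)
    return predictions, summary


def run_cv(
    cohort: SyntheticCohort,
    config: GCNConfig | None = None,
    plan: CVPlan | None = None,
    *,
    combat_mode: str = "combined",
    embedding: EmbeddingConfig | None = None,
    n_input_gradients: int = 2,
    harmonize: bool = True,
    zscore_scope: str = "across_subjects",
) -> tuple[pd.DataFrame, MetricsSummary]:
    """Full cross-validated gradient -> GCN prediction pipeline on a cohort.

    Steps per fold: gradients aligned to the cohort's external template (the
    alignment does not depend on the fold split, so it is computed once);
    ComBat per ``combat_mode``; within-subject per-hemisphere z-scoring;
    min-max target normalization; GCN training on the train folds; prediction
    of the held-out fold. Out-of-fold predictions are pooled per repetition
    and metrics computed once per repetition.
    """
    if combat_mode not in {"combined", "train_only"}:
        raise EvaluationError(f"unknown combat_mode {combat_mode!r}")
    config = config or GCNConfig()
    plan = plan or make_cv_plan(cohort.n_subjects, 10, 10, 0)
    if embedding is None:
        # default to the settings the cohort's template was built with
        embedding = EmbeddingConfig(
            n_components=cohort.config.n_components,
            row_sparsity=cohort.config.row_sparsity,
        )
    if plan.n_subjects != cohort.n_subjects:
        raise EvaluationError("CV plan does not match the cohort size")

    # gradients aligned to the external reference (template from independent
    # subjects; identical across folds by construction)
    sets = [
        procrustes_align(
            diffusion_map(cosine_affinity(c, embedding), embedding), cohort.template
        )[0]
        for c in cohort.connectomes
    ]
    features = np.stack([g.vectors[:, :n_input_gradients] for g in sets])
    n, nreg, d = features.shape
    flat = features.reshape(n, nreg * d)
    graphs = precompute_graphs(np.stack([c.values for c in cohort.connectomes]))
    hemis = np.asarray(cohort.parcellation.hemisphere)
    covariates = cohort.covariates[list(_COVARIATE_COLUMNS)].to_numpy(dtype=float)
    batch = cohort.batch
    y01 = minmax_iq(cohort.iq)

    combined_adjusted = None
    if harmonize and combat_mode == "combined":
        model = ComBat().fit(flat, batch=batch, covariates=covariates)
        combined_adjusted = model.transform(flat, batch=batch, covariates=covariates)

    rows: list[dict] = []
    rng = np.random.default_rng(int(np.asarray(plan.seeds).sum()) % (2**31 - 1))
    fold_seeds = rng.integers(0, 2**31 - 1, size=(plan.n_repetitions, plan.k))
    for rep in range(plan.n_repetitions):
        for fold in range(plan.k):
            train_idx, test_idx = plan.fold_indices(rep, fold)
            if harmonize:
                if combat_mode == "combined":
                    adjusted = combined_adjusted
                else:
                    model = ComBat().fit(
                        flat[train_idx],
                        batch=batch[train_idx],
                        covariates=covariates[train_idx],
                    )
                    adjusted = np.empty_like(flat)
                    adjusted[train_idx] = model.transform(
                        flat[train_idx], batch=batch[train_idx], covariates=covariates[train_idx]
                    )
                    adjusted[test_idx] = model.transform(
                        flat[test_idx], batch=batch[test_idx], covariates=covariates[test_idx]
                    )
            else:
                adjusted = flat
            cube = adjusted.reshape(n, nreg, d)
            if zscore_scope == "across_subjects" and combat_mode == "train_only":
                # leakage-free mode: standardize with training-fold statistics
                x = zscore_by_hemisphere(
                    cube, hemis, scope=zscore_scope, reference=cube[train_idx]
                )
            else:
                x = zscore_by_hemisphere(cube, hemis, scope=zscore_scope)
            est = config.make_estimator(seed=int(fold_seeds[rep, fold]))
            est.fit(x[train_idx], y01[train_idx], adjacency=graphs.take(train_idx))
            raw = est.predict(x[test_idx], adjacency=graphs.take(test_idx))
            pred_iq = inverse_minmax_iq(np.clip(raw, 0.0, 1.0))
            for i, subj in enumerate(test_idx):
                rows.append(
                    {
                        "subject_id": cohort.covariates["subject_id"].iloc[subj],
                        "repetition": rep,
                        "fold": fold,
                        "predicted": float(pred_iq[i]),
                        "observed": float(cohort.iq[subj]),
                    }
                )
    provenance = {
        "combat_mode": combat_mode if harmonize else "off",
        "template_source": "external_reference",
        "leakage_free": (not harmonize) or combat_mode == "train_only",
        "n_input_gradients": n_input_gradients,
        "zscore_scope": zscore_scope,
    }
    return _summarize(rows, provenance)


def naive_cv(
    targets: np.ndarray, plan: CVPlan
) -> tuple[pd.DataFrame, MetricsSummary]:
    """Mean-predictor baseline run through the identical pooling protocol."""
    targets = np.asarray(targets, dtype=float)
    rows = []
    for rep in range(plan.n_repetitions):
        for fold in range(plan.k):
            train_idx, test_idx = plan.fold_indices(rep, fold)
            preds = naive_baseline(targets[train_idx], test_idx.size)
            for i, subj in enumerate(test_idx):
                rows.append(
                    {
                        "subject_id": f"subject_{subj}",
                        "repetition": rep,
                        "fold": fold,
                        "predicted": float(preds[i]),
                        "observed": float(targets[subj]),
                    }
                )
    return _summarize(rows, {"model": "naive_mean"})
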