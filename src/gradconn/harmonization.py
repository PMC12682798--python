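"""ComBat batch harmonization (parametric empirical Bayes location/scale model).

Removes additive (location) and multiplicative (scale) scanner/batch effects
from feature matrices while preserving covariate effects. Features are first
standardized by their covariate-adjusted grand mean and pooled variance; batch
location and scale effects are then estimated per batch x feature and shrunk
toward parametric priors (normal for location, inverse-gamma for scale) with the
standard iterative empirical-Bayes update; finally the batch effects are removed
and the covariate plus grand-mean structure is restored.

The estimator follows the fit/transform convention so a model fit on one set of
subjects can be applied to held-out subjects from the same batches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ComBat", "combat_fit", "combat_apply"]


class HarmonizationError(ValueError):
    pass


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else delta_hat.var()
    if s2 == 0:
        return 2.0
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else delta_hat.var()
    if s2 == 0:
        return m
    return (m * s2 + m**3) / s2


def _as_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise HarmonizationError(
            f"covariate rows ({cov.shape[0]}) do not match samples ({n})"
        )
    return cov


class ComBat(BaseEstimator, TransformerMixin):
    """Empirical-Bayes location/scale batch-effect removal.

    Parameters
    ----------
    eb_tol : convergence threshold for the iterative EB update
        (max absolute change in the shrunken estimates).
    eb_max_iter : iteration cap for the EB update.

    Fitted attributes
    -----------------
    batches_ : batch labels seen during fit.
    grand_mean_ : per-feature covariate-free grand mean (batch-size weighted).
    beta_cov_ : per-feature covariate coefficients (protected structure).
    pooled_var_ : per-feature pooled variance used for standardization.
    gamma_star_, delta2_star_ : EB-shrunken per-batch location and scale
        effects in standardized units (delta2 strictly positive).
    """

    def __init__(self, eb_tol: float = 1e-4, eb_max_iter: int = 100):
        self.eb_tol = eb_tol
        self.eb_max_iter = eb_max_iter

    def fit(self, X, y=None, *, batch, covariates=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise HarmonizationError("features must be a 2-D samples x features array")
        n, n_feat = X.shape
        batch = np.asarray(batch)
        if batch.shape[0] != n:
            raise HarmonizationError("batch labels do not match the number of samples")
        self.batches_, batch_idx = np.unique(batch, return_inverse=True)
        n_batches = self.batches_.size
        if n_batches < 2:
            raise HarmonizationError("ComBat requires at least 2 batches")
        counts = np.bincount(batch_idx, minlength=n_batches)
        singletons = self.batches_[counts < 2]
        if singletons.size:
            raise HarmonizationError(
                f"batches with fewer than 2 samples cannot be harmonized: {list(singletons)}"
            )
        cov = _as_design(covariates, n)
        self._cov_names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"cov_{j}" for j in range(cov.shape[1])]
        )

        # full design: batch one-hot plus covariates
        onehot = np.eye(n_batches)[batch_idx]
        design = np.hstack([onehot, cov])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            bad = self._collinear_columns(design, n_batches)
            raise HarmonizationError(
                f"rank-deficient design (rank {rank} < {design.shape[1]}); "
                f"collinear covariate columns: {bad}"
            )
        b_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
        weights = counts / n
        self.grand_mean_ = weights @ b_hat[:n_batches]
        self.beta_cov_ = b_hat[n_batches:]
        fitted = design @ b_hat
        self.pooled_var_ = ((X - fitted) ** 2).mean(axis=0)
        self.pooled_var_ = np.maximum(self.pooled_var_, 1e-12)

        stand_mean = self.grand_mean_[None, :] + cov @ self.beta_cov_
        z = (X - stand_mean) / np.sqrt(self.pooled_var_)[None, :]

        gamma_hat = np.empty((n_batches, n_feat))
        delta2_hat = np.empty((n_batches, n_feat))
        for b in range(n_batches):
            zb = z[batch_idx == b]
            gamma_hat[b] = zb.mean(axis=0)
            delta2_hat[b] = zb.var(axis=0, ddof=1)
        delta2_hat = np.maximum(delta2_hat, 1e-12)
        self.gamma_hat_ = gamma_hat
        self.delta2_hat_ = delta2_hat

        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        self.eb_n_iter_ = np.zeros(n_batches, dtype=int)
        for b in range(n_batches):
            gamma_star[b], delta2_star[b], self.eb_n_iter_[b] = self._eb_shrink(
                z[batch_idx == b], gamma_hat[b], delta2_hat[b]
            )
        self.gamma_star_ = gamma_star
        self.delta2_star_ = delta2_star
        return self

    def _collinear_columns(self, design: np.ndarray, n_batches: int) -> list[str]:
        names = [f"batch[{b}]" for b in self.batches_] + self._cov_names
        bad = []
        base_rank = 0
        kept: list[int] = []
        for j in range(design.shape[1]):
            r = np.linalg.matrix_rank(design[:, kept + [j]])
            if r > base_rank:
                base_rank = r
                kept.append(j)
            else:
                bad.append(names[j])
        return bad

    def _eb_shrink(self, zb, gamma_hat_b, delta2_hat_b):
        """Iterative parametric EB update for one batch (normal / inverse-gamma)."""
        nb = zb.shape[0]
        g_bar = gamma_hat_b.mean()
        t2 = gamma_hat_b.var(ddof=1) if gamma_hat_b.size > 1 else max(gamma_hat_b.var(), 1e-12)
        t2 = max(t2, 1e-12)
        a = _aprior(delta2_hat_b)
        b = _bprior(delta2_hat_b)
        gamma = gamma_hat_b.copy()
        delta2 = delta2_hat_b.copy()
        n_iter = 0
        for n_iter in range(1, self.eb_max_iter + 1):
            gamma_new = (nb * t2 * gamma_hat_b + delta2 * g_bar) / (nb * t2 + delta2)
            sum2 = ((zb - gamma_new[None, :]) ** 2).sum(axis=0)
            delta2_new = (0.5 * sum2 + b) / (nb / 2.0 + a - 1.0)
            delta2_new = np.maximum(delta2_new, 1e-12)
            change = max(
                np.abs(gamma_new - gamma).max(), np.abs(delta2_new - delta2).max()
            )
            gamma, delta2 = gamma_new, delta2_new
            if change < self.eb_tol:
                break
        return gamma, delta2, n_iter

    def transform(self, X, *, batch, covariates=None):
        """Remove batch effects; restore covariate and grand-mean structure."""
        if not hasattr(self, "gamma_star_"):
            raise HarmonizationError("ComBat model is not fitted")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        batch = np.asarray(batch)
        unseen = np.setdiff1d(np.unique(batch), self.batches_)
        if unseen.size:
            raise HarmonizationError(f"unseen batch labels: {list(unseen)}")
        lookup = {lab: i for i, lab in enumerate(self.batches_)}
        batch_idx = np.array([lookup[lab] for lab in batch])
        cov = _as_design(covariates, n)
        if cov.shape[1] != self.beta_cov_.shape[0]:
            raise HarmonizationError(
                f"expected {self.beta_cov_.shape[0]} covariates, got {cov.shape[1]}"
            )
        stand_mean = self.grand_mean_[None, :] + cov @ self.beta_cov_
        z = (X - stand_mean) / np.sqrt(self.pooled_var_)[None, :]
        z_adj = (z - self.gamma_star_[batch_idx]) / np.sqrt(self.delta2_star_[batch_idx])
        return z_adj * np.sqrt(self.pooled_var_)[None, :] + stand_mean

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, **fit_params)
        return self.transform(
            X, batch=fit_params["batch"], covariates=fit_params.get("covariates")
        )


def combat_fit(features, batch, covariates=None, **kwargs) -> ComBat:
    """Fit a ComBat model on a samples x features matrix."""
    return ComBat(**kwargs).fit(features, batch=batch, covariates=covariates)


def combat_apply(model: ComBat, features, batch, covariates=None) -> np.ndarray:
    """Apply a fitted ComBat model to (possibly held-out) samples."""
    return model.transform(features, batch=batch, covariates=covariates)
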