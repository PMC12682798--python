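"""Connectome gradients: cosine affinity, diffusion-map embedding, alignment.

A connectome gradient is a low-dimensional axis of continuous variation in
regional connectivity profiles. It is obtained by (1) converting the SC matrix
into an affinity matrix via row-wise cosine similarity (after per-row
sparsification), (2) eigendecomposing the diffusion operator built from that
affinity (diffusion map embedding), and (3) aligning each subject's gradients to
a common reference template with an orthogonal Procrustes rotation, which
resolves the sign/rotation indeterminacy of eigenvectors.

The diffusion operator uses anisotropic normalization with exponent ``alpha``
(default 0.5) and, at diffusion time 0, the automatic multi-scale weighting
lambda/(1-lambda) of the non-trivial eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin

from .connectome import ConnectomeMatrix

__all__ = [
    "EmbeddingConfig",
    "AffinityMatrix",
    "GradientSet",
    "GradientTemplate",
    "AlignmentTransform",
    "cosine_affinity",
    "diffusion_map",
    "explanation_ratio",
    "procrustes_align",
    "build_template",
    "hemispheric_gradients",
    "DiffusionGradients",
]


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the affinity construction and diffusion-map embedding.

    n_components : number of non-trivial gradients retained (default 10).
    row_sparsity : fraction of the smallest entries zeroed per row before the
        cosine similarity (default 0.9, i.e. keep the top 10% per row).
    alpha : anisotropic diffusion exponent in [0, 1] (default 0.5).
    diffusion_time : t >= 0; 0 selects the automatic multi-scale weighting
        lambda/(1-lambda).
    """

    n_components: int = 10
    row_sparsity: float = 0.9
    alpha: float = 0.5
    diffusion_time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise EmbeddingError("n_components must be >= 1")
        if not 0.0 <= self.row_sparsity < 1.0:
            raise EmbeddingError("row_sparsity must be in [0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise EmbeddingError("alpha must be in [0, 1]")
        if self.diffusion_time < 0:
            raise EmbeddingError("diffusion_time must be >= 0")


@dataclass
class AffinityMatrix:
    """Symmetric cosine-similarity affinity; entries in [0, 1], unit diagonal."""

    values: np.ndarray
    source_subject: str = ""


@dataclass
class GradientSet:
    """Per-subject embedding: region x component vectors plus spectrum.

    Column k of ``vectors`` is the (k+1)-th gradient; column 0 is the principal
    gradient. ``eigenvalues`` are the non-trivial eigenvalues sorted descending,
    and ``explanation_ratio[k] = eigenvalues[k] / eigenvalues.sum()`` over the
    retained components.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    explanation_ratio: np.ndarray
    aligned: bool = False
    subject_id: str = ""

    @property
    def n_components(self) -> int:
        return self.vectors.shape[1]


@dataclass
class GradientTemplate:
    """Reference gradient basis used to align subjects; records provenance."""

    vectors: np.ndarray
    provenance: tuple[str, ...] = ()


@dataclass
class AlignmentTransform:
    """Orthogonal rotation (possibly with reflection) from Procrustes alignment."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if np.abs(r.T @ r - np.eye(r.shape[1])).max() > 1e-8:
            raise EmbeddingError("alignment transform is not orthogonal")
        self.rotation = r


def _as_values(conn) -> tuple[np.ndarray, str]:
    if isinstance(conn, ConnectomeMatrix):
        return conn.values, conn.subject_id
    if isinstance(conn, AffinityMatrix):
        return conn.values, conn.source_subject
    return np.asarray(conn, dtype=float), ""


def cosine_affinity(conn, config: EmbeddingConfig | None = None) -> AffinityMatrix:
    """Row-sparsified cosine similarity of connectivity profiles.

    Per row, the smallest ``row_sparsity`` fraction of entries is zeroed
    (deterministic tie-break by column index), then W[i, j] is the cosine of
    rows i and j. Nonnegative rows give entries in [0, 1]; the diagonal is 1.
    Raises naming the region if a row is entirely zero after sparsification.
    """
    config = config or EmbeddingConfig()
    values, subject = _as_values(conn)
    n = values.shape[0]
    rows = values.copy()
    n_zero = int(config.row_sparsity * n)
    if n_zero > 0:
        # argsort with stable kind gives a deterministic set of zeroed entries
        order = np.argsort(rows, axis=1, kind="stable")
        zero_idx = order[:, :n_zero]
        np.put_along_axis(rows, zero_idx, 0.0, axis=1)
    norms = np.linalg.norm(rows, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        if isinstance(conn, ConnectomeMatrix):
            names = [conn.parcellation.region_ids[i] for i in dead]
        else:
            names = [str(i) for i in dead]
        raise EmbeddingError(
            f"degenerate regions with all-zero connectivity after sparsification: {names}"
        )
    w = (rows @ rows.T) / np.outer(norms, norms)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return AffinityMatrix(values=w, source_subject=subject)


def _fix_column_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    out = vectors.copy()
    idx = np.abs(out).argmax(axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


def diffusion_map(affinity, config: EmbeddingConfig | None = None) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Builds K = D^-alpha W D^-alpha, the row-stochastic P = D_K^-1 K, and
    eigendecomposes P through its symmetric conjugate
    D_K^1/2 P D_K^-1/2 for numerical stability. The trivial constant
    eigenvector (eigenvalue 1) is discarded; the next ``n_components``
    eigenvectors, scaled by lambda/(1-lambda) (t = 0) or lambda^t, are the
    gradients. Eigenvalues are reported post-discard, sorted descending.
    """
    config = config or EmbeddingConfig()
    w, subject = _as_values(affinity)
    n = w.shape[0]
    if w.shape[0] != w.shape[1]:
        raise EmbeddingError("affinity must be square")
    if np.abs(w - w.T).max() > 1e-10:
        raise EmbeddingError("affinity must be symmetric")
    if np.any(w < 0):
        raise EmbeddingError("affinity must be nonnegative")
    n_comp, _ = connected_components(w > 0, directed=False)
    if n_comp != 1:
        raise EmbeddingError(
            f"affinity graph is disconnected ({n_comp} components); "
            "gradients are only defined on a connected graph"
        )
    if config.n_components >= n:
        raise EmbeddingError("n_components must be smaller than the number of regions")

    d = w.sum(axis=1)
    if config.alpha > 0:
        k = w / np.outer(d**config.alpha, d**config.alpha)
    else:
        k = w.copy()
    dk = k.sum(axis=1)
    sq = np.sqrt(dk)
    m = k / np.outer(sq, sq)  # symmetric conjugate of the Markov operator
    evals, evecs = linalg.eigh(m)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # discard the trivial eigenvector (eigenvalue 1, constant after back-transform)
    lam = evals[1:]
    n_pos = int(np.sum(lam > 1e-12))
    if config.n_components > n_pos:
        raise EmbeddingError(
            f"requested {config.n_components} components but only {n_pos} positive "
            "non-trivial eigenvalues are available"
        )
    lam = lam[: config.n_components]
    psi = evecs[:, 1 : config.n_components + 1] / sq[:, None]
    # normalize like the trivial eigenvector so coordinates are comparable
    psi = psi / (evecs[:, 0] / sq).mean()
    if config.diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    else:
        scale = lam**config.diffusion_time
    vectors = _fix_column_signs(psi * scale)
    return GradientSet(
        vectors=vectors,
        eigenvalues=lam,
        explanation_ratio=explanation_ratio(lam),
        aligned=False,
        subject_id=subject,
    )


def explanation_ratio(eigenvalues) -> np.ndarray:
    """Each retained non-trivial eigenvalue's share of their total.

    Accepts a GradientSet or an eigenvalue sequence; ratios sum to 1 over the
    retained set and are invariant to rescaling of the eigenvalues.
    """
    if isinstance(eigenvalues, GradientSet):
        eigenvalues = eigenvalues.eigenvalues
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise EmbeddingError("empty eigenvalue list")
    if np.any(lam <= 0):
        raise EmbeddingError("eigenvalues must be positive")
    return lam / lam.sum()


def procrustes_align(
    source: GradientSet | np.ndarray, template: GradientTemplate | np.ndarray
) -> tuple[GradientSet, AlignmentTransform]:
    """Orthogonal Procrustes rotation of a gradient set onto a template.

    Finds orthogonal R (rotation or reflection; no scaling, no translation)
    minimizing ||source @ R - template||_F and returns the rotated set with its
    transform.
    """
    src = source.vectors if isinstance(source, GradientSet) else np.asarray(source, float)
    tgt = template.vectors if isinstance(template, GradientTemplate) else np.asarray(template, float)
    if src.shape != tgt.shape:
        raise EmbeddingError(f"shape mismatch: source {src.shape} vs template {tgt.shape}")
    r, _ = linalg.orthogonal_procrustes(src, tgt)
    aligned = src @ r
    transform = AlignmentTransform(rotation=r)
    if isinstance(source, GradientSet):
        out = replace(source, vectors=aligned, aligned=True)
    else:
        out = GradientSet(
            vectors=aligned,
            eigenvalues=np.array([]),
            explanation_ratio=np.array([]),
            aligned=True,
        )
    return out, transform


def build_template(
    gradient_sets: list[GradientSet],
    tol: float = 1e-7,
    max_iter: int = 500,
) -> GradientTemplate:
    """Generalized Procrustes mean of several gradient sets.

    Initializes the template with the first subject's gradients, then
    iterates { align every set to the template; template <- mean of aligned
    sets } until the template moves less than ``tol`` in Frobenius norm or
    ``max_iter`` is reached (warning, best iterate returned). Template column
    signs are fixed so each column's largest-magnitude entry is positive.
    """
    if len(gradient_sets) < 2:
        raise EmbeddingError("template construction needs at least 2 gradient sets")
    mats = [gs.vectors if isinstance(gs, GradientSet) else np.asarray(gs, float) for gs in gradient_sets]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise EmbeddingError(f"gradient sets have differing shapes: {shapes}")
    template = mats[0].copy()
    converged = False
    for _ in range(max_iter):
        aligned = []
        for m in mats:
            r, _ = linalg.orthogonal_procrustes(m, template)
            aligned.append(m @ r)
        new = np.mean(aligned, axis=0)
        if np.linalg.norm(new - template) < tol:
            template = new
            converged = True
            break
        template = new
    if not converged:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    provenance = tuple(
        gs.subject_id if isinstance(gs, GradientSet) else "" for gs in gradient_sets
    )
    return GradientTemplate(vectors=_fix_column_signs(template), provenance=provenance)


def hemispheric_gradients(
    conn: ConnectomeMatrix, config: EmbeddingConfig | None = None
) -> tuple[GradientSet, GradientSet]:
    """Per-hemisphere gradients with the right hemisphere aligned to the left.

    Interhemispheric connections are excluded (principal submatrices per
    hemisphere) before embedding. If the hemispheres have unequal region
    counts, alignment is skipped with a warning and both raw sets returned.
    """
    from .connectome import mask_interhemispheric

    config = config or EmbeddingConfig()
    left_c, right_c = mask_interhemispheric(conn)
    left = diffusion_map(cosine_affinity(left_c, config), config)
    right = diffusion_map(cosine_affinity(right_c, config), config)
    if left_c.n_regions != right_c.n_regions:
        warnings.warn(
            "hemispheres have unequal region counts; right-to-left alignment skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return left, right
    right_aligned, _ = procrustes_align(right, GradientTemplate(vectors=left.vectors))
    return left, right_aligned


class DiffusionGradients(BaseEstimator, TransformerMixin):
    """Diffusion-map gradient extraction for a cohort of connectomes.

    A scikit-learn-style transformer: ``fit`` computes per-subject gradients
    and (unless an external template is supplied) a generalized-Procrustes
    template from them; ``transform`` returns template-aligned gradients
    stacked as an array of shape (n_subjects, n_regions, n_components).

    Parameters mirror :class:`EmbeddingConfig`. ``template`` may be a
    GradientTemplate built from an independent reference set, in which case
    subjects are aligned to it directly (the protocol used for prediction,
    avoiding train/test leakage through the template).
    """

    def __init__(
        self,
        n_components: int = 10,
        row_sparsity: float = 0.9,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        template: GradientTemplate | None = None,
    ):
        self.n_components = n_components
        self.row_sparsity = row_sparsity
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.template = template

    def _config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            n_components=self.n_components,
            row_sparsity=self.row_sparsity,
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
        )

    def fit(self, X, y=None):
        config = self._config()
        self.gradients_ = [diffusion_map(cosine_affinity(c, config), config) for c in X]
        self.eigenvalues_ = np.array([g.eigenvalues for g in self.gradients_])
        self.explanation_ratios_ = np.array([g.explanation_ratio for g in self.gradients_])
        if self.template is not None:
            self.template_ = self.template
        else:
            self.template_ = build_template(self.gradients_)
        return self

    def transform(self, X):
        config = self._config()
        out = []
        for c in X:
            gs = diffusion_map(cosine_affinity(c, config), config)
            aligned, _ = procrustes_align(gs, self.template_)
            out.append(aligned.vectors)
        return np.stack(out)

    def fit_transform(self, X, y=None):
        self.fit(X)
        out = []
        for gs in self.gradients_:
            aligned, _ = procrustes_align(gs, self.template_)
            out.append(aligned.vectors)
        return np.stack(out)
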