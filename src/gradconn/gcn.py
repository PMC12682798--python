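"""Chebyshev spectral graph-convolutional regression with a Siamese paired loss.

The model predicts a scalar (min-max-normalized IQ) from per-region gradient
features, using each subject's own structural connectome as the graph. Two
graph-convolution layers apply K-order Chebyshev polynomial filters of the
scaled normalized Laplacian,

    H^(l+1) = relu( sum_{k=0..K} T_k(Ltilde) H^(l) W_k^(l) ),

with T_0 = I, T_1 = Ltilde, T_k = 2 Ltilde T_{k-1} - T_{k-2} and
Ltilde = 2 L / lambda_max - I for L = I - D^{-1/2} A D^{-1/2}. Node features are
then flattened (preserving region identity, which the regional relevance maps
require) and passed through a small MLP with a linear output head.

The training objective is the weighted sum of a squared-error term and a paired
inter-subject difference ("Siamese") term,

    L = sum_i (y_i - f_i)^2
        + w_siamese * sum_{i != j} [ (y_i - y_j) - (f_i - f_j) ]^2,

which penalizes discrepancies between inter-subject differences of predictions
and of targets; it is invariant to a constant shift of the predictions and
discourages collapse to the group mean.

Because no autodiff engine is used, the backward pass is written by hand; it is
validated against central finite differences in the test suite. Optimization is
plain Adam, full number of epochs, no early stopping, final-epoch parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .connectome import ConnectomeMatrix

__all__ = [
    "GraphOperator",
    "GCNConfig",
    "TrainingBatch",
    "build_graph_operator",
    "chebyshev_features",
    "chebyshev_basis",
    "siamese_loss",
    "total_loss",
    "zscore_by_hemisphere",
    "minmax_iq",
    "inverse_minmax_iq",
    "ChebNetRegressor",
    "PrecomputedGraphs",
    "precompute_graphs",
    "train_model",
]

IQ_MIN, IQ_MAX = 50.0, 150.0


class GCNError(ValueError):
    pass


@dataclass
class GraphOperator:
    """Normalized-Laplacian operators of one subject's connectome graph.

    laplacian L = I - D^-1/2 A D^-1/2 has spectrum in [0, 2]; the scaled
    version Ltilde = 2 L / lambda_max - I has spectrum in [-1, 1], the domain
    of the Chebyshev polynomials.
    """

    adjacency: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    lambda_max: float
    scaled_laplacian: np.ndarray


def build_graph_operator(adjacency) -> GraphOperator:
    """Build L, lambda_max and Ltilde from a symmetric nonnegative adjacency.

    lambda_max is computed exactly with a symmetric eigensolver (no
    lambda_max ~ 2 approximation). Raises naming the region if any node has
    zero degree.
    """
    if isinstance(adjacency, ConnectomeMatrix):
        region_ids = adjacency.parcellation.region_ids
        a = adjacency.values
    else:
        a = np.asarray(adjacency, dtype=float)
        region_ids = None
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GCNError(f"adjacency must be square, got {a.shape}")
    if np.abs(a - a.T).max(initial=0.0) > 1e-10:
        raise GCNError("adjacency must be symmetric")
    if np.any(a < 0):
        raise GCNError("adjacency must be nonnegative")
    d = a.sum(axis=1)
    dead = np.flatnonzero(d == 0)
    if dead.size:
        names = [region_ids[i] for i in dead] if region_ids else [str(i) for i in dead]
        raise GCNError(f"isolated nodes with zero degree: {names}")
    inv_sqrt = 1.0 / np.sqrt(d)
    lap = np.eye(a.shape[0]) - a * np.outer(inv_sqrt, inv_sqrt)
    lam_max = float(linalg.eigh(lap, eigvals_only=True, subset_by_index=[a.shape[0] - 1, a.shape[0] - 1])[0])
    scaled = 2.0 * lap / lam_max - np.eye(a.shape[0])
    return GraphOperator(
        adjacency=a, degree=d, laplacian=lap, lambda_max=lam_max, scaled_laplacian=scaled
    )


def chebyshev_features(op, h: np.ndarray, K: int) -> list[np.ndarray]:
    """[T_0 H, ..., T_K H] via the three-term Chebyshev recursion."""
    lt = op.scaled_laplacian if isinstance(op, GraphOperator) else np.asarray(op, float)
    h = np.asarray(h, dtype=float)
    if K < 0:
        raise GCNError("Chebyshev order K must be >= 0")
    out = [h]
    if K >= 1:
        out.append(lt @ h)
    for _ in range(2, K + 1):
        out.append(2.0 * (lt @ out[-1]) - out[-2])
    return out


def chebyshev_basis(scaled_laplacian: np.ndarray, K: int) -> np.ndarray:
    """Stacked polynomials [T_0; T_1; ...; T_K] of shape ((K+1) N, N)."""
    n = scaled_laplacian.shape[0]
    mats = chebyshev_features(scaled_laplacian, np.eye(n), K)
    return np.concatenate(mats, axis=0)


def siamese_loss(y, f) -> float:
    """Sum over ordered pairs i != j of [(y_i - y_j) - (f_i - f_j)]^2.

    Shift-invariant: adding a constant to every prediction leaves it
    unchanged; zero iff the residual f - y is constant. Computed in closed
    form (2 n sum(e^2) - 2 (sum e)^2 for e = f - y), which equals the double
    loop over ordered pairs.
    """
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.shape != f.shape:
        raise GCNError("targets and predictions must have equal length")
    if y.size < 2:
        warnings.warn("Siamese loss of fewer than 2 subjects is defined as 0", stacklevel=2)
        return 0.0
    e = f - y
    return float(2.0 * e.size * (e**2).sum() - 2.0 * e.sum() ** 2)


def total_loss(y, f, w_siamese: float) -> float:
    """Sum of squared errors plus w_siamese times the Siamese pair loss."""
    if w_siamese < 0:
        raise GCNError("w_siamese must be nonnegative")
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    mse = float(((y - f) ** 2).sum())
    return mse + w_siamese * (siamese_loss(y, f) if y.size >= 2 else 0.0)


def _loss_grad(y: np.ndarray, f: np.ndarray, w: float) -> np.ndarray:
    """d total_loss / d f for one (mini)batch."""
    e = f - y
    g = 2.0 * e
    if e.size >= 2 and w > 0:
        g = g + w * (4.0 * e.size * e - 4.0 * e.sum())
    return g


def zscore_by_hemisphere(
    features: np.ndarray,
    hemisphere,
    scope: str = "within_subject",
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Standardize each gradient component separately for each hemisphere.

    ``features`` is (n_regions, d) or (n_subjects, n_regions, d). Two scopes:

    * ``within_subject`` — for every subject and component, L-hemisphere
      entries are scaled to mean 0 / SD 1 over the L regions, likewise R.
      Normalizes each subject's gradient range but removes any per-subject
      hemisphere-level information.
    * ``across_subjects`` — each region x component feature is standardized
      over subjects (an affine per-feature map), preserving all
      between-subject regional structure. ``reference`` may supply the array
      the means/SDs are computed from (e.g. the training fold, to keep test
      subjects out of the statistics).

    Raises on zero variance in the standardizing dimension.
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    hemisphere = np.asarray(hemisphere)
    for label in ("L", "R"):
        if not np.any(hemisphere == label):
            raise GCNError(f"hemisphere {label!r} has no regions")
    if scope == "within_subject":
        out = x.copy()
        for label in ("L", "R"):
            idx = np.flatnonzero(hemisphere == label)
            block = x[:, idx, :]
            mu = block.mean(axis=1, keepdims=True)
            sd = block.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                raise GCNError(
                    f"zero within-hemisphere variance in hemisphere {label!r}"
                )
            out[:, idx, :] = (block - mu) / sd
        return out[0] if single else out
    if scope == "across_subjects":
        ref = x if reference is None else np.asarray(reference, dtype=float)
        mu = ref.mean(axis=0)
        sd = ref.std(axis=0)
        if np.any(sd == 0):
            raise GCNError("zero across-subject variance in some feature")
        out = (x - mu) / sd
        return out[0] if single else out
    raise GCNError(f"unknown z-score scope {scope!r}")


def minmax_iq(scores) -> np.ndarray:
    """Map IQ to [0, 1] with 50 -> 0 and 150 -> 1 (linear outside, with warning)."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise GCNError("IQ scores must be finite")
    if np.any((s < IQ_MIN) | (s > IQ_MAX)):
        warnings.warn("IQ scores outside [50, 150] pass through linearly", stacklevel=2)
    return (s - IQ_MIN) / (IQ_MAX - IQ_MIN)


def inverse_minmax_iq(targets) -> np.ndarray:
    """Exact inverse of :func:`minmax_iq`."""
    return np.asarray(targets, dtype=float) * (IQ_MAX - IQ_MIN) + IQ_MIN


@dataclass(frozen=True)
class GCNConfig:
    """Bundle of model and training hyperparameters.

    Defaults follow the study protocol: Chebyshev order K = 3, Siamese weight
    10, Adam with learning rate 0.005, 300 epochs, minibatch size 10, model
    taken at the final epoch. Hidden widths are kept small for ~90-subject
    cohorts.
    """

    K: int = 3
    layer_widths: tuple[int, ...] = (16, 16)
    mlp_widths: tuple[int, ...] = (64,)
    activation: str = "relu"
    learning_rate: float = 0.005
    lr_schedule: str = "cosine"
    epochs: int = 300
    batch_size: int = 10
    w_siamese: float = 10.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise GCNError("K must be >= 1")
        if any(wd < 1 for wd in self.layer_widths) or any(wd < 1 for wd in self.mlp_widths):
            raise GCNError("layer widths must be positive")
        if self.activation != "relu":
            raise GCNError("only the rectifier activation is supported")
        if self.w_siamese < 0:
            raise GCNError("w_siamese must be nonnegative")

    def make_estimator(self, seed: int | None = None) -> "ChebNetRegressor":
        return ChebNetRegressor(
            K=self.K,
            hidden=self.layer_widths,
            mlp_hidden=self.mlp_widths,
            learning_rate=self.learning_rate,
            lr_schedule=self.lr_schedule,
            epochs=self.epochs,
            batch_size=self.batch_size,
            w_siamese=self.w_siamese,
            random_state=self.seed if seed is None else seed,
            dtype=self.dtype,
        )


@dataclass
class TrainingBatch:
    """Per-subject inputs for training: gradient features, adjacency, target."""

    x: np.ndarray  # (n, N, d)
    adjacency: np.ndarray  # (n, N, N)
    y: np.ndarray  # (n,) in [0, 1]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.ndim != 3 or self.adjacency.ndim != 3:
            raise GCNError("x must be (n, N, d) and adjacency (n, N, N)")
        if not (self.x.shape[0] == self.adjacency.shape[0] == self.y.shape[0]):
            raise GCNError("inconsistent subject counts")
        if self.x.shape[1] != self.adjacency.shape[1]:
            raise GCNError("x and adjacency disagree on the number of regions")


@dataclass
class PrecomputedGraphs:
    """Scaled Laplacians of a cohort, reusable across folds and repetitions.

    Building the graph operator (an exact eigensolve per subject) is the only
    per-subject setup cost of the GCN; cross-validation re-fits the model many
    times on overlapping subject sets, so the harness computes these once.
    """

    scaled_laplacians: np.ndarray  # (n, N, N), float64

    def __len__(self) -> int:
        return self.scaled_laplacians.shape[0]

    def take(self, idx) -> "PrecomputedGraphs":
        return PrecomputedGraphs(scaled_laplacians=self.scaled_laplacians[idx])


def precompute_graphs(adjacency) -> PrecomputedGraphs:
    """Build per-subject scaled Laplacians from stacked adjacency matrices."""
    adjacency = np.asarray(adjacency, dtype=float)
    lts = np.stack(
        [build_graph_operator(a).scaled_laplacian for a in adjacency]
    )
    return PrecomputedGraphs(scaled_laplacians=lts)


def _propagate(lt: np.ndarray, h: np.ndarray, K: int) -> np.ndarray:
    """Concatenated Chebyshev features [T_0 H | ... | T_K H], (B, N, (K+1) c)."""
    outs = [h]
    if K >= 1:
        outs.append(lt @ h)
    for _ in range(2, K + 1):
        outs.append(2.0 * (lt @ outs[-1]) - outs[-2])
    return np.concatenate(outs, axis=-1)


def _propagate_adjoint(lt: np.ndarray, g: np.ndarray, K: int, c: int) -> np.ndarray:
    """sum_k T_k(Ltilde) G_k for G_k the k-th block of g, via Clenshaw recursion.

    This is the adjoint of :func:`_propagate` (each T_k is symmetric), used in
    the backward pass.
    """
    blocks = [g[..., k * c : (k + 1) * c] for k in range(K + 1)]
    if K == 0:
        return blocks[0]
    b1 = blocks[K]
    b2 = np.zeros_like(b1)
    for k in range(K - 1, 0, -1):
        b1, b2 = blocks[k] + 2.0 * (lt @ b1) - b2, b1
    return blocks[0] + lt @ b1 - b2


class ChebNetRegressor(BaseEstimator, RegressorMixin):
    """Chebyshev spectral GCN regressor with the MSE + Siamese objective.

    scikit-learn-style estimator. ``fit(X, y, adjacency=...)`` takes gradient
    features X of shape (n_subjects, n_regions, d), targets y in [0, 1] and a
    per-subject adjacency array (n_subjects, n_regions, n_regions); each
    subject is processed with the graph operator of its own connectome.
    ``predict`` returns raw outputs on the normalized target scale (the output
    head is linear; clip to [0, 1] for reporting).

    Fully deterministic given ``random_state``: weight initialization (scaled
    uniform fan-in) and epoch shuffling share one seeded generator.
    """

    def __init__(
        self,
        K: int = 3,
        hidden: tuple[int, ...] = (16, 16),
        mlp_hidden: tuple[int, ...] = (64,),
        learning_rate: float = 0.005,
        lr_schedule: str = "cosine",
        epochs: int = 300,
        batch_size: int = 10,
        w_siamese: float = 10.0,
        random_state: int = 0,
        dtype: str = "float32",
    ):
        self.K = K
        self.hidden = hidden
        self.mlp_hidden = mlp_hidden
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.w_siamese = w_siamese
        self.random_state = random_state
        self.dtype = dtype

    # ------------------------------------------------------------------ setup

    def _np_dtype(self):
        return np.dtype(self.dtype)

    def _prepare_graphs(self, adjacency, dtype=None) -> np.ndarray:
        """Per-subject scaled Laplacians (n, N, N) in the working dtype."""
        if isinstance(adjacency, PrecomputedGraphs):
            lts = adjacency.scaled_laplacians
        else:
            lts = precompute_graphs(adjacency).scaled_laplacians
        return np.ascontiguousarray(lts, dtype=dtype or self._np_dtype())

    def _init_params(self, n_regions: int, d_in: int, rng: np.random.Generator) -> dict:
        dt = self._np_dtype()

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(dt)

        params: dict[str, np.ndarray] = {}
        prev = d_in
        for l, width in enumerate(self.hidden):
            fan = (self.K + 1) * prev
            params[f"gcn_W{l}"] = uniform((fan, width), fan)
            prev = width
        prev = n_regions * prev  # flattened readout
        for l, width in enumerate(list(self.mlp_hidden) + [1]):
            params[f"mlp_W{l}"] = uniform((prev, width), prev)
            params[f"mlp_b{l}"] = np.zeros(width, dtype=dt)
            prev = width
        return params

    # ---------------------------------------------------------------- forward

    def _forward(self, params: dict, lt: np.ndarray, u0: np.ndarray, cache: bool = False):
        """Batched forward pass. Returns predictions (and cache for backward).

        ``lt`` holds the per-subject scaled Laplacians (b, N, N); ``u0`` the
        precomputed Chebyshev-propagated input features (b, N, (K+1) d).
        """
        b, nreg, _ = u0.shape
        caches: dict = {"z_gcn": [], "u": [u0]}
        h = None
        u = u0
        for l in range(len(self.hidden)):
            z = u @ params[f"gcn_W{l}"]
            h = np.maximum(z, 0.0)
            if cache:
                caches["z_gcn"].append(z)
            if l + 1 < len(self.hidden):
                u = _propagate(lt, h, self.K)
                if cache:
                    caches["u"].append(u)
        flat = h.reshape(b, -1)
        acts = [flat]
        pre = []
        a = flat
        n_mlp = len(self.mlp_hidden) + 1
        for l in range(n_mlp):
            z = a @ params[f"mlp_W{l}"] + params[f"mlp_b{l}"]
            pre.append(z)
            a = np.maximum(z, 0.0) if l + 1 < n_mlp else z  # linear output head
            acts.append(a)
        caches["mlp_pre"] = pre
        caches["mlp_act"] = acts
        f = a[:, 0]
        return (f, caches) if cache else f

    def _backward(
        self,
        params: dict,
        lt: np.ndarray,
        caches: dict,
        df: np.ndarray,
        want_input_grad: bool = False,
        out_grads: dict | None = None,
    ):
        """Gradients of the scalar objective wrt parameters (and inputs).

        ``out_grads`` may hold preallocated arrays (views into the optimizer
        blob) that the weight gradients are written into.
        """
        b = df.shape[0]
        nreg = caches["u"][0].shape[1]
        grads = out_grads if out_grads is not None else {}

        def put(key, compute_into):
            if out_grads is None:
                grads[key] = compute_into(None)
            else:
                compute_into(grads[key])

        n_mlp = len(self.mlp_hidden) + 1
        da = df[:, None]  # grad wrt final activation (linear head)
        for l in reversed(range(n_mlp)):
            z = caches["mlp_pre"][l]
            dz = da if l + 1 == n_mlp else da * (z > 0)
            a_prev = caches["mlp_act"][l]
            put(f"mlp_W{l}", lambda out: np.matmul(a_prev.T, dz, out=out))
            put(f"mlp_b{l}", lambda out: np.sum(dz, axis=0, out=out))
            da = dz @ params[f"mlp_W{l}"].T
        dh = da.reshape(b, nreg, -1)
        for l in reversed(range(len(self.hidden))):
            z = caches["z_gcn"][l]
            dz = dh * (z > 0)
            u = caches["u"][l]
            m = u.shape[-1]
            c = dz.shape[-1]
            uf = np.ascontiguousarray(u).reshape(b * nreg, m)
            zf = np.ascontiguousarray(dz).reshape(b * nreg, c)
            put(f"gcn_W{l}", lambda out: np.matmul(uf.T, zf, out=out))
            if l == 0 and not want_input_grad:
                break
            du = dz @ params[f"gcn_W{l}"].T  # (b, N, (K+1) c_prev)
            c_prev = du.shape[-1] // (self.K + 1)
            back = _propagate_adjoint(lt, du, self.K, c_prev)
            if l == 0:
                return grads, back  # gradient wrt raw input features
            dh = back
        return grads, None

    # -------------------------------------------------------------------- fit

    def fit(self, X, y, *, adjacency):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if x.ndim != 3 or x.shape[0] != y.shape[0]:
            raise GCNError("X must be (n, N, d) with one target per subject")
        n, nreg, d_in = x.shape
        if n < 2:
            raise GCNError("training requires at least 2 subjects")
        dt = self._np_dtype()
        rng = np.random.default_rng(self.random_state)
        lt = self._prepare_graphs(adjacency)
        if lt.shape[0] != n or lt.shape[1] != nreg:
            raise GCNError("adjacency does not match the feature array")
        u0 = _propagate(lt, np.ascontiguousarray(x, dtype=dt), self.K)
        yv = y.astype(dt)
        params = self._init_params(nreg, d_in, rng)
        # anchor the output level at the training-target mean; the loss's
        # dominant Siamese term is shift-invariant, so the level is otherwise
        # only weakly constrained
        last = len(self.mlp_hidden)
        params[f"mlp_b{last}"][:] = dt.type(yv.mean())
        # flatten parameters into one blob so the Adam update is a handful of
        # vectorized ops; the dict values become views into the blob
        sizes = {k: v.size for k, v in params.items()}
        shapes = {k: v.shape for k, v in params.items()}
        blob = np.concatenate([params[k].ravel() for k in params])
        offsets = {}
        pos = 0
        for k in params:
            offsets[k] = (pos, pos + sizes[k])
            params[k] = blob[pos : pos + sizes[k]].reshape(shapes[k])
            pos += sizes[k]
        mom = np.zeros_like(blob)
        vel = np.zeros_like(blob)
        gblob = np.empty_like(blob)
        tmp = np.empty_like(blob)
        gviews = {
            k: gblob[lo:hi].reshape(shapes[k]) for k, (lo, hi) in offsets.items()
        }
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        bs = min(self.batch_size, n)
        if self.lr_schedule not in {"constant", "cosine"}:
            raise GCNError(f"unknown lr_schedule {self.lr_schedule!r}")
        self.loss_history_ = []
        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                # anneal from the initial rate to 0; final-epoch evaluation
                # relies on the late-training iterates being settled
                lr_now = self.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / self.epochs)
                )
            else:
                lr_now = self.learning_rate
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                ltb = lt[idx]
                f, caches = self._forward(params, ltb, u0[idx], cache=True)
                e = f - yv[idx]
                loss = float((e**2).sum())
                if idx.size >= 2:
                    loss += self.w_siamese * float(
                        2.0 * idx.size * (e**2).sum() - 2.0 * e.sum() ** 2
                    )
                epoch_loss += loss
                df = _loss_grad(yv[idx], f, self.w_siamese).astype(dt)
                self._backward(params, ltb, caches, df, out_grads=gviews)
                step += 1
                lr1 = dt.type(lr_now / (1.0 - beta1**step))
                inv_bc2 = dt.type(1.0 / (1.0 - beta2**step))
                # allocation-free Adam update on the flat parameter blob
                mom *= dt.type(beta1)
                np.multiply(gblob, dt.type(1 - beta1), out=tmp)
                mom += tmp
                vel *= dt.type(beta2)
                np.square(gblob, out=tmp)
                tmp *= dt.type(1 - beta2)
                vel += tmp
                np.multiply(vel, inv_bc2, out=tmp)
                np.sqrt(tmp, out=tmp)
                tmp += dt.type(eps)
                np.divide(mom, tmp, out=tmp)
                tmp *= lr1
                blob -= tmp
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "consider lowering the learning rate"
                )
            self.loss_history_.append(epoch_loss)
            if epoch == 0:
                self.train_loss_first_epoch_ = total_loss(
                    yv, self._forward(params, lt, u0), self.w_siamese
                )
        self.params_ = params
        self.n_features_in_ = d_in
        self.n_regions_ = nreg
        self.train_loss_final_ = total_loss(yv, self._forward(params, lt, u0), self.w_siamese)
        return self

    # ---------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise GCNError("model is not fitted")

    def predict(self, X, *, adjacency):
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.n_regions_ or x.shape[2] != self.n_features_in_:
            raise GCNError(
                f"expected features of shape (n, {self.n_regions_}, {self.n_features_in_})"
            )
        lt = self._prepare_graphs(adjacency)
        u0 = _propagate(lt, np.ascontiguousarray(x, dtype=self._np_dtype()), self.K)
        return np.asarray(self._forward(self.params_, lt, u0), dtype=float)

    def _f64_setup(self, X, adjacency):
        x = np.asarray(X, dtype=np.float64)
        params = {k: v.astype(np.float64) for k, v in self.params_.items()}
        lt = self._prepare_graphs(adjacency, dtype=np.float64)
        u0 = _propagate(lt, x, self.K)
        return params, lt, u0

    def input_gradients(self, X, *, adjacency) -> np.ndarray:
        """d f / d x per subject, shape (n, N, d), computed in float64.

        Used by the attribution methods; the float64 recomputation makes the
        finite-difference and completeness oracles meaningful regardless of
        the training dtype.
        """
        self._check_fitted()
        params, lt, u0 = self._f64_setup(X, adjacency)
        f, caches = self._forward(params, lt, u0, cache=True)
        df = np.ones_like(f)
        _, dx = self._backward(params, lt, caches, df, want_input_grad=True)
        return dx

    def decision_function_f64(self, X, *, adjacency) -> np.ndarray:
        """Float64 forward pass (reference path shared with attribution)."""
        self._check_fitted()
        params, lt, u0 = self._f64_setup(X, adjacency)
        return self._forward(params, lt, u0)

    # ------------------------------------------------------------ checkpoints

    def save(self, path) -> None:
        """Deterministic single-file checkpoint (weights + configuration)."""
        self._check_fitted()
        import json

        config = json.dumps(self.get_params())
        np.savez(
            path,
            __config__=np.frombuffer(config.encode(), dtype=np.uint8),
            __n_regions__=np.array([self.n_regions_]),
            __n_features__=np.array([self.n_features_in_]),
            **self.params_,
        )

    @classmethod
    def load(cls, path) -> "ChebNetRegressor":
        import json

        with np.load(path) as payload:
            config = json.loads(bytes(payload["__config__"]).decode())
            config["hidden"] = tuple(config["hidden"])
            config["mlp_hidden"] = tuple(config["mlp_hidden"])
            est = cls(**config)
            est.params_ = {
                k: payload[k] for k in payload.files if not k.startswith("__")
            }
            est.n_regions_ = int(payload["__n_regions__"][0])
            est.n_features_in_ = int(payload["__n_features__"][0])
        return est


def train_model(batch: TrainingBatch, config: GCNConfig) -> ChebNetRegressor:
    """Train a ChebNetRegressor on a full training batch per the configuration."""
    est = config.make_estimator()
    est.fit(batch.x, batch.y, adjacency=batch.adjacency)
    return est
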