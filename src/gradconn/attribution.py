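"""Regional relevance maps: saliency and integrated gradients.

Both methods attribute a trained model's prediction to its per-region,
per-component input gradient features. Saliency is the absolute input gradient
|df/dx| at the subject's input; integrated gradients (IG) averages the gradient
along the straight path from a baseline to the input (midpoint Riemann rule)
and multiplies by (x - baseline), which makes the attributions satisfy the
completeness axiom: they sum to f(x) - f(baseline).

Signed relevance values are ambiguous to interpret for unitless embedding
coordinates, so regional aggregation defaults to magnitude mode (absolute value
before averaging, components summed afterwards); the signed maps remain
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelevanceMap",
    "saliency",
    "integrated_gradients",
    "aggregate_relevance",
    "top_fraction_regions",
    "consistent_regions",
]


class AttributionError(ValueError):
    pass


@dataclass
class RelevanceMap:
    """Per-region attribution weights with method tag and provenance.

    ``weights`` is one value per region; ``components`` keeps the per-input-
    component attribution. ``provenance`` records what was averaged (subjects,
    folds, repetitions, aggregation mode).
    """

    region_ids: tuple[str, ...]
    weights: np.ndarray
    components: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.weights.shape[0] != len(self.region_ids):
            raise AttributionError("weights do not match the region set")
        if not np.all(np.isfinite(self.weights)):
            raise AttributionError("relevance weights must be finite")


def saliency(model, X, *, adjacency) -> np.ndarray:
    """Absolute input gradients |df/dx|, shape (n_subjects, N, d)."""
    return np.abs(model.input_gradients(X, adjacency=adjacency))


def integrated_gradients(
    model, X, *, adjacency, baseline=None, steps: int = 50
) -> np.ndarray:
    """Signed integrated-gradients attributions, shape (n_subjects, N, d).

    IG_i = (x_i - b_i) * mean over the path b -> x of df/dx_i, with the path
    sampled at midpoints (alpha = (s + 0.5)/steps). The default baseline is
    all-zero features, the natural origin for unitless embedding coordinates.
    """
    if steps < 1:
        raise AttributionError("steps must be >= 1")
    x = np.asarray(X, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(x)
    else:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != x.shape:
            raise AttributionError("baseline must match the input shape")
    diff = x - baseline
    acc = np.zeros_like(x)
    for s in range(steps):
        alpha = (s + 0.5) / steps
        acc += model.input_gradients(baseline + alpha * diff, adjacency=adjacency)
    return diff * (acc / steps)


def aggregate_relevance(
    maps,
    *,
    region_ids=None,
    method: str = "",
    mode: str = "magnitude",
    provenance: dict | None = None,
) -> RelevanceMap:
    """Average attribution maps across subjects/folds into one regional map.

    ``maps`` is an iterable of (N, d) arrays (or RelevanceMap component
    arrays). In magnitude mode (default) absolute values are taken before
    averaging and components are summed after; in signed mode raw values are
    averaged and components summed with sign.
    """
    if mode not in {"magnitude", "signed"}:
        raise AttributionError(f"unknown aggregation mode {mode!r}")
    arrays = []
    for m in maps:
        if isinstance(m, RelevanceMap):
            if region_ids is not None and tuple(m.region_ids) != tuple(region_ids):
                raise AttributionError("relevance maps have mismatched region sets")
            region_ids = m.region_ids
            if not method:
                method = m.method
            arrays.append(m.components)
        else:
            arrays.append(np.asarray(m, dtype=float))
    if not arrays:
        raise AttributionError("no maps to aggregate")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise AttributionError(f"maps have differing shapes: {shapes}")
    stack = np.stack(arrays)
    if mode == "magnitude":
        stack = np.abs(stack)
    comp = stack.mean(axis=0)
    weights = comp.sum(axis=1)
    n = comp.shape[0]
    if region_ids is None:
        region_ids = tuple(f"region_{i:04d}" for i in range(n))
    prov = dict(provenance or {})
    prov.update({"n_maps": len(arrays), "mode": mode})
    return RelevanceMap(
        region_ids=tuple(region_ids),
        weights=weights,
        components=comp,
        method=method or "unknown",
        provenance=prov,
    )


def top_fraction_regions(rmap: RelevanceMap, fraction: float = 0.05) -> list[str]:
    """The ceil(fraction * N) regions with largest absolute weight.

    Deterministic tie-break: equal weights are ordered by region id.
    """
    if not 0.0 < fraction <= 1.0:
        raise AttributionError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(rmap.region_ids))
    order = sorted(
        range(len(rmap.region_ids)),
        key=lambda i: (-abs(rmap.weights[i]), rmap.region_ids[i]),
    )
    return [rmap.region_ids[i] for i in order[:n_top]]


def consistent_regions(subsets) -> list[str]:
    """Sorted intersection of the top-region subsets across target outcomes."""
    subsets = [set(s) for s in subsets]
    if not subsets:
        return []
    common = set.intersection(*subsets)
    return sorted(common)
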