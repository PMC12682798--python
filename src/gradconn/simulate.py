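"""Synthetic cohort generator with the statistical structure the analysis assumes.

Real infant connectome data are not shipped with the package, so every pipeline
stage is exercised on synthetic cohorts that emulate the relevant structure:

* symmetric nonnegative streamline-count connectomes with weak interhemispheric
  blocks and a smooth anterior-posterior (A-P) connectivity decay within each
  hemisphere, so the group principal gradient separates the hemispheres and the
  within-hemisphere gradients track the A-P axis;
* two scanner batches in a 67/33 split with a planted structural scanner effect
  on the minority batch (interhemispheric block scaled), which propagates into
  the gradient features where harmonization can remove it;
* IQ-like outcomes with population mean 100 and SD 15, whose individual
  variation is planted as a function of gradient values in a chosen set of
  "relevant" regions (effect_size = fraction of IQ variance carried by that
  signal). The signal is read from the A-P gradient component: the
  hemisphere-separation component is nearly constant within a hemisphere by
  construction, so the regional structure an outcome can couple to lives on
  the A-P axis.

Edge noise is multiplicative lognormal, keeping counts nonnegative and
heteroscedastic like streamline counts. IQ is planted on gradients of the
*clean* (pre-scanner-effect) connectomes, so the batch effect is a nuisance
variable rather than part of the signal. Ground truth (relevant regions, planted
signal) is stored on the cohort and in a sidecar file that the pipeline never
reads; only recovery tests consume it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    ConnectomeMatrix,
    ParcellationInfo,
    normalize_connectome,
    symmetrize,
    write_connectome,
    write_parcellation,
)
from .embedding import (
    EmbeddingConfig,
    GradientTemplate,
    build_template,
    cosine_affinity,
    diffusion_map,
    procrustes_align,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_connectome",
    "simulate_iq",
    "add_batch_effects",
    "simulate_cohort",
    "write_cohort",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator parameters; defaults are the emulated study conditions.

    n_subjects 92 with a 67/33 two-scanner split, 148 regions (half per
    hemisphere), IQ mean 100 / SD 15, and a planted signal in 5 regions
    carrying 35% of the IQ variance. ``ap_gradient_strength`` is the
    exponential decay length of within-hemisphere connectivity along the
    normalized A-P coordinate; ``edge_noise_sigma`` the lognormal sigma of the
    multiplicative subject edge noise; ``batch_conn_scale`` the structural
    scanner effect (interhemispheric multiplier for the minority batch).
    ``batch_shift``/``batch_scale`` are the feature-space location/scale
    effects used by :func:`add_batch_effects`.
    """

    n_subjects: int = 92
    n_regions: int = 148
    interhemispheric_mean: float = 0.1
    intrahemispheric_mean: float = 1.0
    homotopic_strength: float = 0.9
    homotopic_decay: float = 0.05
    homotopic_width: float = 0.12
    ap_gradient_strength: float = 0.4
    edge_noise_sigma: float = 0.2
    ap_field_sigma: float = 0.25
    ap_field_modes: int = 3
    batch_proportions: tuple[float, float] = (0.67, 0.33)
    batch_labels: tuple[str, str] = ("scanner_A", "scanner_B")
    batch_conn_scale: float = 1.2
    batch_shift: float = 0.5
    batch_scale: float = 1.0
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    relevant_regions: tuple[int, ...] | None = None
    effect_size: float = 0.35
    signal_component: int = 1  # the A-P gradient, which carries the
    # within-hemisphere regional structure the outcome couples to
    n_template_subjects: int = 10
    n_components: int = 10
    row_sparsity: float = 0.9

    def __post_init__(self) -> None:
        if self.n_regions % 2:
            raise SimulationError("n_regions must be even (half per hemisphere)")
        if abs(sum(self.batch_proportions) - 1.0) > 1e-9:
            raise SimulationError("batch proportions must sum to 1")
        if not 0.0 <= self.effect_size < 1.0:
            raise SimulationError("effect_size must be in [0, 1)")
        if self.relevant_regions is None:
            # five left-hemisphere regions spread along the A-P axis
            half = self.n_regions // 2
            picks = np.unique(
                np.round(np.linspace(0.1, 0.9, 5) * (half - 1)).astype(int)
            )
            object.__setattr__(self, "relevant_regions", tuple(int(i) for i in picks))
        bad = [i for i in self.relevant_regions if not 0 <= i < self.n_regions]
        if bad:
            raise SimulationError(f"relevant regions outside the parcellation: {bad}")

    @property
    def parcellation(self) -> ParcellationInfo:
        return ParcellationInfo.bilateral(self.n_regions)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        tuple_fields = {"batch_proportions", "batch_labels", "relevant_regions"}
        kwargs = {
            k: tuple(v) if k in tuple_fields and v is not None else v
            for k, v in payload.items()
        }
        return cls(**kwargs)

    def batch_counts(self) -> tuple[int, int]:
        n_major = int(round(self.batch_proportions[0] * self.n_subjects))
        return n_major, self.n_subjects - n_major


@dataclass
class SyntheticCohort:
    """Full synthetic cohort plus the ground truth used only by recovery tests."""

    connectomes: list[ConnectomeMatrix]
    parcellation: ParcellationInfo
    covariates: pd.DataFrame
    iq: np.ndarray
    template: GradientTemplate
    ground_truth: dict
    config: SimulationConfig

    @property
    def n_subjects(self) -> int:
        return len(self.connectomes)

    @property
    def batch(self) -> np.ndarray:
        return self.covariates["batch"].to_numpy()


def _ap_coordinates(config: SimulationConfig) -> np.ndarray:
    """Normalized anterior-posterior coordinate per region (same per hemisphere)."""
    half = config.n_regions // 2
    pos = np.linspace(0.0, 1.0, half)
    return np.concatenate([pos, pos])


def _expected_matrix(config: SimulationConfig, scanner_effect: bool) -> np.ndarray:
    pos = _ap_coordinates(config)
    half = config.n_regions // 2
    hemi = np.repeat([0, 1], half)
    dist = np.abs(pos[:, None] - pos[None, :])
    intra = config.intrahemispheric_mean * np.exp(-dist / config.ap_gradient_strength)
    # interhemispheric block: weak flat background plus a homotopic (callosal)
    # peak between mirror regions. The callosal strength is region-dependent
    # (Gaussian bump around the mid A-P position): only centrally located
    # regions keep their homotopic edges after row sparsification, which
    # leaves the interhemispheric affinity weak enough for the principal
    # gradient to separate the hemispheres while keeping the affinity graph
    # connected.
    profile = np.exp(-((pos - 0.5) ** 2) / (2.0 * config.homotopic_width**2))
    hom = (
        config.intrahemispheric_mean
        * config.homotopic_strength
        * np.sqrt(np.outer(profile, profile))
        * np.exp(-dist / config.homotopic_decay)
    )
    inter = config.interhemispheric_mean + hom
    if scanner_effect:
        inter = inter * config.batch_conn_scale
    same_hemi = hemi[:, None] == hemi[None, :]
    expected = np.where(same_hemi, intra, inter)
    np.fill_diagonal(expected, 0.0)
    return expected


def simulate_connectome(
    config: SimulationConfig,
    subject_index: int,
    rng: np.random.Generator,
    *,
    scanner_effect: bool = False,
    _noise: np.ndarray | None = None,
) -> ConnectomeMatrix:
    """One subject's symmetrized, normalized streamline-count connectome.

    Expected edge weight decays exponentially with A-P distance within a
    hemisphere and is flat (and weaker) between hemispheres; multiplicative
    lognormal noise individuates subjects. With ``scanner_effect`` the
    interhemispheric block is scaled by ``batch_conn_scale`` (the planted
    scanner artifact).
    """
    expected = _expected_matrix(config, scanner_effect)
    if _noise is None:
        _noise = draw_edge_noise(config, rng)
    raw = expected * _noise
    conn = symmetrize(raw, config.parcellation, subject_id=f"sub-{subject_index:04d}")
    return normalize_connectome(conn)


def draw_edge_noise(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Symmetric multiplicative subject noise: smooth regional field x edge noise.

    Two components, both lognormal so counts stay nonnegative:

    * a smooth per-subject regional field f over the A-P axis (low-order
      cosine modes, independent per hemisphere, mode m amplitude
      ap_field_sigma / m) entering as exp(f_i + f_j) — spatially coherent
      individual differences in regional connectivity, the part of the
      variation a learner can generalize from at cohort sample sizes;
    * i.i.d. symmetric lognormal edge noise with sigma edge_noise_sigma —
      streamline-count measurement noise, localized and unshared.

    Note the generator consumes the same number of random draws regardless of
    the sigmas, so cohorts with different noise settings stay paired.
    """
    n = config.n_regions
    half = n // 2
    pos = np.linspace(0.0, 1.0, half)
    f = np.zeros(n)
    for lo in (0, half):
        for m in range(1, config.ap_field_modes + 1):
            c = rng.normal(0.0, config.ap_field_sigma / m)
            f[lo : lo + half] += c * np.cos(m * np.pi * pos)
    z = rng.normal(size=(n, n))
    z = (z + z.T) / np.sqrt(2.0)  # symmetric, still unit variance
    sigma = config.edge_noise_sigma
    return np.exp(f[:, None] + f[None, :]) * np.exp(sigma * z - sigma**2 / 2.0)


def simulate_iq(
    gradient_features: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """IQ scores planted on the mean gradient value of the relevant regions.

    signal = standardized (across subjects) mean gradient value over the
    relevant regions; IQ = mean + sd * (sqrt(es) * signal + sqrt(1-es) * eps)
    with eps standard normal, so the population mean and SD are the instrument
    values and corr(signal, IQ) = sqrt(effect_size).
    """
    feats = np.asarray(gradient_features, dtype=float)
    if feats.ndim != 2:
        raise SimulationError("gradient features must be (n_subjects, n_regions)")
    if feats.shape[1] != config.n_regions:
        raise SimulationError(
            f"features have {feats.shape[1]} regions, config expects {config.n_regions}"
        )
    raw = feats[:, list(config.relevant_regions)].mean(axis=1)
    sd = raw.std()
    if sd == 0:
        raise SimulationError("planted signal has zero variance across subjects")
    signal = (raw - raw.mean()) / sd
    eps = rng.normal(size=feats.shape[0])
    es = config.effect_size
    return config.iq_mean + config.iq_sd * (
        np.sqrt(es) * signal + np.sqrt(1.0 - es) * eps
    )


def add_batch_effects(
    features: np.ndarray,
    batch,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Feature-space scanner effect: location/scale shift of the minority batch.

    The minority batch's features are scaled by ``batch_scale`` and shifted by
    ``batch_shift`` per-feature standard deviations. Identity when shift is 0
    and scale is 1. This is the planted effect the harmonization oracle tests
    remove; the cohort generator plants its scanner effect structurally in the
    connectomes instead.
    """
    x = np.asarray(features, dtype=float).copy()
    batch = np.asarray(batch)
    labels, counts = np.unique(batch, return_counts=True)
    if labels.size < 2:
        raise SimulationError("batch effects need at least two batches")
    minority = labels[np.argmin(counts)]
    sd = x.std(axis=0)
    mask = batch == minority
    x[mask] = x[mask] * config.batch_scale + config.batch_shift * sd
    return x


def _principal_gradients(
    connectomes, config: SimulationConfig, template: GradientTemplate | None
):
    emb = EmbeddingConfig(
        n_components=config.n_components, row_sparsity=config.row_sparsity
    )
    sets = [diffusion_map(cosine_affinity(c, emb), emb) for c in connectomes]
    if template is None:
        return sets
    aligned = [procrustes_align(g, template)[0] for g in sets]
    return aligned


def simulate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a complete cohort: connectomes, covariates, batches, IQ, template.

    Reproducible from ``seed``. The reference template is built from
    ``n_template_subjects`` additional clean subjects that are not part of the
    cohort, mirroring the independent-reference protocol. Scanner batch labels
    are assigned in the configured proportions (rounded; 92 subjects at 67/33
    give a 62/30 split) and shuffled.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    # independent reference subjects (clean) -> gradient template
    template_sets = []
    for i in range(config.n_template_subjects):
        conn = simulate_connectome(config, 10_000 + i, rng)
        template_sets.extend(_principal_gradients([conn], config, None))
    template = build_template(template_sets)

    # batch assignment: exact rounded proportions, shuffled
    n_major, n_minor = config.batch_counts()
    batch = np.array(
        [config.batch_labels[0]] * n_major + [config.batch_labels[1]] * n_minor
    )
    rng.shuffle(batch)

    clean: list[ConnectomeMatrix] = []
    observed: list[ConnectomeMatrix] = []
    for i in range(config.n_subjects):
        noise = draw_edge_noise(config, rng)
        clean.append(
            simulate_connectome(config, i, rng, scanner_effect=False, _noise=noise)
        )
        affected = batch[i] == config.batch_labels[1]
        observed.append(
            simulate_connectome(config, i, rng, scanner_effect=affected, _noise=noise)
        )

    aligned = _principal_gradients(clean, config, template)
    signal_feats = np.stack(
        [g.vectors[:, config.signal_component] for g in aligned]
    )
    iq = simulate_iq(signal_feats, config, rng)

    n = config.n_subjects
    covariates = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in observed],
            "batch": batch,
            "sex_male": rng.binomial(1, 0.54, size=n),
            "gestational_age_weeks": rng.normal(39.4, 1.6, size=n),
            "age_at_scan_months": rng.normal(12.95, 0.94, size=n),
            "n_large_translation_dwi": rng.poisson(0.32, size=n),
            "n_excluded_dwi": np.minimum(rng.poisson(1.46, size=n), 14),
        }
    )
    raw_signal = signal_feats[:, list(config.relevant_regions)].mean(axis=1)
    ground_truth = {
        "relevant_regions": [
            config.parcellation.region_ids[i] for i in config.relevant_regions
        ],
        "relevant_region_indices": list(config.relevant_regions),
        "effect_size": config.effect_size,
        "signal": ((raw_signal - raw_signal.mean()) / raw_signal.std()).tolist(),
        "seed": seed,
    }
    return SyntheticCohort(
        connectomes=observed,
        parcellation=config.parcellation,
        covariates=covariates,
        iq=iq,
        template=template,
        ground_truth=ground_truth,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort in the text formats the pipeline consumes.

    Connectomes as CSV matrices, parcellation as TSV, covariates + IQ as CSV,
    the template as TSV, and ground truth as a JSON sidecar (never read by the
    pipeline; recovery tests only).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for c in cohort.connectomes:
        write_connectome(c, conn_dir / f"{c.subject_id}.csv")
    write_parcellation(cohort.parcellation, out / "parcellation.tsv")
    table = cohort.covariates.copy()
    table["iq"] = cohort.iq
    table.to_csv(out / "covariates.csv", index=False)
    np.savetxt(out / "template.tsv", cohort.template.vectors, delimiter="\t")
    with open(out / "config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)
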