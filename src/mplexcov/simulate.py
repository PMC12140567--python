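"""Synthetic multi-modal cohorts with known ground truth.

The analysis pipeline studies GROUP-level covariance networks, so the
generator's control knob is the population inter-regional correlation
matrix of each (group, modality): subjects are i.i.d. draws

    Y_subject = b0 + b_age*age + b_sex*sex + b_edu*education
                + noise_sd * MVN(0, R_group_modality)

with age ~ U(50, 80) years, sex ~ Bernoulli(1/2), education ~ U(8, 22)
years. Correlation targets use a two-factor model, which keeps every
target exactly positive semi-definite and mimics the structure of real
covariance networks (a broad global factor plus tighter communities):

* a global factor with node loadings spread around
  sqrt(base_correlation - community_loading**2) — the spread
  (``strength_heterogeneity``, low-discrepancy and deterministic) gives
  nodes distinct strengths so that density thresholding is decided by
  structure rather than ties;
* a community factor with loading ``community_loading`` on ordinary
  nodes and ``hub_loading`` on epicenter nodes, making the epicenter a
  strongly covarying, hub-like module in BOTH groups' background.

The mean off-diagonal background correlation is ~``base_correlation``.
A group difference is planted by shifting the epicenter nodes' community
loading in the affected layer of the second group so that every
epicenter/non-epicenter edge changes by exactly
``epicenter_delta_by_layer[modality]`` (edges within the epicenter
module change more, as both endpoints lose loading). With the default
delta of -0.3 on the FDG layer only, the epicenter's degrees become
layer-imbalanced after thresholding, which lowers its multiplex
participation coefficient in the affected group by a
population-computable amount.

A ``repair_psd`` projection (eigenvalue clipping + rescaling to unit
diagonal) guards arbitrary user configurations; for the default
factor-model targets it is a no-op.

Defaults emulate a dual-layer cortical-thickness / FDG-SUVR design:
plausible intercepts (2.5 mm, 1.5 SUVR), small negative age slopes, and
residual scale 0.15 — the order of regional SDs seen in ROI tables after
surface-based extraction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, synthetic_atlas
from .cohort import CohortTable

logger = logging.getLogger(__name__)

#: (intercept, age, sex, education) slopes per modality
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "CTH": (2.5, -0.010, 0.05, 0.005),
    "FDG": (1.5, -0.005, 0.03, 0.004),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one two-group synthetic cohort."""

    n_per_group: tuple[int, int] = (60, 60)
    n_regions: int = 34
    modalities: tuple[str, ...] = ("CTH", "FDG")
    base_correlation: float = 0.55
    strength_heterogeneity: float = 0.15
    community_loading: float = 0.45
    hub_loading: float = 0.80
    epicenter_nodes: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    epicenter_delta_by_layer: tuple[tuple[str, float], ...] = (("FDG", -0.3),)
    covariate_effects: tuple[tuple[str, tuple[float, float, float, float]], ...] = (
        ("CTH", DEFAULT_COVARIATE_EFFECTS["CTH"]),
        ("FDG", DEFAULT_COVARIATE_EFFECTS["FDG"]),
    )
    noise_sd: float = 0.15
    seed: int = 0
    group_labels: tuple[str, str] = ("control", "patient")

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_correlation < 1.0:
            raise ValueError("base_correlation must lie in [0, 1)")
        if self.community_loading**2 > self.base_correlation:
            raise ValueError(
                "community_loading**2 exceeds base_correlation; the global "
                "factor variance would be negative"
            )
        if not 0.0 <= self.hub_loading < 1.0:
            raise ValueError("hub_loading must lie in [0, 1)")
        for mod, dr in dict(self.epicenter_delta_by_layer).items():
            if mod not in self.modalities:
                raise ValueError(f"delta for unknown modality {mod!r}")
            if abs(dr) >= 1.0:
                raise ValueError("epicenter delta must have |delta| < 1")
        if any(i < 0 or i >= self.n_regions for i in self.epicenter_nodes):
            raise ValueError("epicenter node index out of range")

    @property
    def deltas(self) -> dict[str, float]:
        return dict(self.epicenter_delta_by_layer)

    @property
    def effects(self) -> dict[str, tuple[float, float, float, float]]:
        return dict(self.covariate_effects)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for oracle-style checks."""

    target: dict[tuple[str, str], np.ndarray]  # (group, modality) -> R
    epicenter_nodes: tuple[int, ...]
    epicenter_regions: tuple[str, ...]
    config_hash: str


def repair_psd(R: np.ndarray, clip: float = 1e-8, max_distortion: float = 0.25) -> np.ndarray:
    """Project a symmetric matrix to a unit-diagonal PSD surrogate.

    Eigenvalues below ``clip`` are raised to it and the result is rescaled
    to a unit diagonal (logged when triggered). Raises if the repair moves
    any off-diagonal entry by more than ``max_distortion`` — such a target
    is considered invalid rather than silently replaced. Factor-model
    targets are PSD by construction, so this only acts on hand-crafted
    configurations.
    """
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= clip:
        return R
    logger.warning(
        "PSD repair triggered: clipping min eigenvalue %.2e to %.0e", vals.min(), clip
    )
    fixed = (vecs * np.maximum(vals, clip)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    fixed = (fixed + fixed.T) / 2.0
    worst = float(np.abs(fixed - R).max())
    if worst > max_distortion:
        raise ValueError(
            f"PSD repair tolerance exceeded: an entry moved by {worst:.3f} "
            f"(> {max_distortion}); the requested target is too far from a "
            "valid correlation matrix"
        )
    return fixed


def factor_loadings(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Background (global, community) loading vectors (b, c).

    The global loadings follow a golden-ratio low-discrepancy sequence so
    node strength is spread evenly yet decorrelated from node index; the
    community loading is ``hub_loading`` on epicenter nodes and
    ``community_loading`` elsewhere. Loadings are capped so every node's
    communality stays below 1.
    """
    n = config.n_regions
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    u = np.modf(np.arange(1, n + 1) * phi)[0]
    global_var = config.base_correlation - config.community_loading**2
    b = np.sqrt(global_var) * (1.0 + config.strength_heterogeneity * (u - 0.5))
    c = np.full(n, config.community_loading)
    if config.epicenter_nodes:
        c[list(config.epicenter_nodes)] = config.hub_loading
    b = np.minimum(b, np.sqrt(np.clip(1.0 - c**2 - 0.02, 0.0, 1.0)))
    return b, c


def target_correlation(config: GeneratorConfig, group: str, modality: str) -> np.ndarray:
    """Population correlation matrix for one (group, modality)."""
    b, c = factor_loadings(config)
    c = c.copy()
    if (
        group == config.group_labels[1]
        and modality in config.deltas
        and config.epicenter_nodes
    ):
        dr = config.deltas[modality]
        # shift the epicenter community loading so each epicenter/non-epicenter
        # edge changes by exactly dr
        comm = config.community_loading
        epi = list(config.epicenter_nodes)
        if comm > 0:
            shifted = config.hub_loading + dr / comm
        else:
            shifted = config.hub_loading
        cap = np.sqrt(np.clip(1.0 - b[epi] ** 2 - 0.02, 0.0, 1.0))
        c[epi] = np.clip(shifted, 0.0, cap)
    R = np.outer(b, b) + np.outer(c, c)
    np.fill_diagonal(R, 1.0)
    return repair_psd(R)


def _draw_group(
    config: GeneratorConfig,
    group: str,
    n_subjects: int,
    atlas: RoiAtlas,
    rng: np.random.Generator,
    id_prefix: str,
) -> CohortTable:
    age = rng.uniform(50.0, 80.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    edu = rng.uniform(8.0, 22.0, n_subjects)
    ids = [f"{id_prefix}{i:03d}" for i in range(n_subjects)]
    covariates = pd.DataFrame(
        {"group": group, "age": age, "sex": sex, "education": edu},
        index=pd.Index(ids, name="subject_id"),
    )
    roi = {}
    for mod in config.modalities:
        R = target_correlation(config, group, mod)
        L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
        z = rng.standard_normal((n_subjects, config.n_regions)) @ L.T
        b0, b_age, b_sex, b_edu = config.effects[mod]
        linear = b0 + b_age * age + b_sex * sex + b_edu * edu
        values = linear[:, None] + config.noise_sd * z
        roi[mod] = pd.DataFrame(values, index=covariates.index, columns=list(atlas.regions))
    return CohortTable(
        atlas=atlas, modalities=config.modalities, covariates=covariates, roi=roi
    )


def generate_cohort(
    config: GeneratorConfig, atlas: RoiAtlas | None = None
) -> tuple[dict[str, CohortTable], GroundTruth]:
    """Draw one cohort per group plus the planted ground truth.

    Seed-deterministic: the same config yields bit-identical cohorts.
    """
    if atlas is None:
        atlas = synthetic_atlas(config.n_regions)
    if atlas.n_regions != config.n_regions:
        raise ValueError("atlas size does not match config.n_regions")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.group_labels))
    cohorts = {}
    for (group, n), child in zip(
        zip(config.group_labels, config.n_per_group), children
    ):
        prefix = f"{group[:4]}-"
        cohorts[group] = _draw_group(
            config, group, n, atlas, np.random.default_rng(child), prefix
        )
    truth = GroundTruth(
        target={
            (g, m): target_correlation(config, g, m)
            for g in config.group_labels
            for m in config.modalities
        },
        epicenter_nodes=config.epicenter_nodes,
        epicenter_regions=tuple(atlas.regions[i] for i in config.epicenter_nodes),
        config_hash=config.config_hash(),
    )
    return cohorts, truth


def make_null_pair(
    config: GeneratorConfig, atlas: RoiAtlas | None = None
) -> tuple[CohortTable, CohortTable, GroundTruth]:
    """Two cohorts from the IDENTICAL generator (no planted difference).

    Both pseudo-groups share every population parameter — the epicenter
    effect is stripped — so any detected difference is a false positive.
    Used for type-I-error calibration of the permutation test.
    """
    null_cfg = GeneratorConfig(
        **{
            **config.__dict__,
            "epicenter_delta_by_layer": (),
            "epicenter_nodes": (),
        }
    )
    cohorts, truth = generate_cohort(null_cfg, atlas=atlas)
    a, b = (cohorts[g] for g in null_cfg.group_labels)
    return a, b, truth
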