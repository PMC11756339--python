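"""Synthetic morphometric data with known latent structure.

The generator emulates the statistical shape of a carnivoran-style dataset:
~109 species measured for ~136 linear and angular skeletal traits, a
multiplicative per-specimen size confound on the linear traits, and a 2-D
latent ecological plane carrying group-mean structure for 7 locomotor and 7
dietary regimes. Log linear traits are affine in the latent position plus
noise, then multiplied by a lognormal size factor (which log-shape-ratio
correction cancels exactly); angular traits are affine in the latent position
in degrees. Group means sit on circles in the latent plane so a single
effect-size knob controls separation in units of the within-group SD.

A second generator builds known-truth landscape scenarios: smooth unimodal
performance surfaces (isotropic Gaussian bumps with distinct peaks) plus a
group placed at the argmax of a known weighted combination, so the exhaustive
weight search has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from morphlands.errors import ValidationError
from morphlands.kriging import GridSpec, PerformanceSurface, normalize_surface
from morphlands.optimize import WeightVector
from morphlands.trait_data import ANGULAR, LINEAR, TraitSchema, TraitTable

LOCOMOTOR_REGIMES = (
    "arboreal",
    "cursorial",
    "scansorial",
    "semiaquatic",
    "semifossorial",
    "terrestrial_hunter",
    "terrestrial_nonhunter",
)
DIETARY_REGIMES = (
    "large_prey_hypercarnivory",
    "medium_prey_hypercarnivory",
    "small_prey_hypercarnivory",
    "omnivory",
    "insectivory",
    "aquatic_carnivory",
    "herbivory",
)
FAMILIES = (
    "Felidae",
    "Viverridae",
    "Eupleridae",
    "Herpestidae",
    "Hyaenidae",
    "Canidae",
    "Ursidae",
    "Mephitidae",
    "Mustelidae",
    "Procyonidae",
    "Ailuridae",
    "Nandiniidae",
)

#: Core linear traits referenced by the default proxy registry.
CORE_LINEAR = (
    "jaw_out_lever",
    "temporalis_in_lever",
    "masseter_in_lever",
    "scapula_length",
    "scapula_width",
    "humerus_length",
    "humerus_diameter",
    "humerus_epicondylar_breadth",
    "radius_length",
    "ulna_length",
    "ulna_diameter",
    "olecranon_length",
    "metacarpal3_length",
    "femur_length",
    "femur_diameter",
    "femur_epicondylar_breadth",
    "greater_trochanter_height",
    "tibia_length",
    "tibia_diameter",
    "metatarsal3_length",
    "c3_centrum_width",
    "c3_centrum_height",
    "dt_centrum_width",
    "dt_centrum_height",
    "ml_centrum_width",
    "ml_centrum_height",
)
#: Core angular traits (vertebral joint angles at the three proxy positions).
CORE_ANGULAR = (
    "c3_joint_torsion_angle",
    "c3_joint_verticality_angle",
    "dt_joint_torsion_angle",
    "dt_joint_verticality_angle",
    "ml_joint_torsion_angle",
    "ml_joint_verticality_angle",
)


def default_schema(n_traits: int = 136, n_angular: int = 18) -> TraitSchema:
    """Trait schema with the registry's core traits plus filler traits.

    Fillers stand in for the remaining skeletal measurements (additional
    vertebral positions, skull widths, ...) so the table reaches the target
    dimensionality without every column needing a bespoke proxy.
    """
    n_linear = n_traits - n_angular
    if n_linear < len(CORE_LINEAR) or n_angular < len(CORE_ANGULAR):
        raise ValidationError(
            f"schema needs >= {len(CORE_LINEAR)} linear and >= {len(CORE_ANGULAR)} angular traits"
        )
    kinds: dict[str, str] = {t: LINEAR for t in CORE_LINEAR}
    for i in range(n_linear - len(CORE_LINEAR)):
        kinds[f"extra_linear_{i + 1:03d}"] = LINEAR
    kinds.update({t: ANGULAR for t in CORE_ANGULAR})
    for i in range(n_angular - len(CORE_ANGULAR)):
        kinds[f"extra_angle_{i + 1:02d}"] = ANGULAR
    return TraitSchema(kinds=kinds)


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 109
    n_traits: int = 136
    n_angular: int = 18
    group_effect_size: float = 2.0  # latent-axis separation, within-group SDs
    trait_noise_sd: float = 0.05  # log-scale residual SD of linear traits
    angular_noise_sd: float = 2.0  # degrees
    size_sd: float = 0.3  # log-scale SD of the specimen size factor
    loading_scale: float = 0.15  # log-units of trait response per latent unit
    angular_loading_scale: float = 8.0  # degrees per latent unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValidationError("need at least 3 species")
        if self.n_angular < len(CORE_ANGULAR) or self.n_traits - self.n_angular < len(CORE_LINEAR):
            raise ValidationError("trait counts too small for the core schema")
        for name in ("group_effect_size", "trait_noise_sd", "angular_noise_sd", "size_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n_linear(self) -> int:
        return self.n_traits - self.n_angular


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for recovery tests."""

    latent_positions: np.ndarray  # species x 2
    group_means: dict[str, np.ndarray]  # category -> 2-D point (both axes)
    loading_matrix: np.ndarray  # traits x 2 (response of each trait)
    trait_names: list[str] = field(default_factory=list)
    true_weights: WeightVector | None = None
    true_optimum: np.ndarray | None = None


def _circle_means(n: int, radius: float, phase: float) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n + phase
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def generate_dataset(config: SyntheticConfig) -> tuple[TraitTable, SyntheticTruth]:
    """Draw one synthetic specimen-per-species trait table plus its truth.

    Independent RNG streams drive latent positions, trait noise, and size
    factors, so changing ``size_sd`` alone leaves every other draw — and hence
    the size-corrected table — unchanged.
    """
    schema = default_schema(config.n_traits, config.n_angular)
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_traits, rng_size, rng_struct = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = config.n_species
    loco = [LOCOMOTOR_REGIMES[i % 7] for i in range(n)]
    diet = [DIETARY_REGIMES[(i // 7) % 7] for i in range(n)]
    fam = [FAMILIES[i % len(FAMILIES)] for i in range(n)]

    loco_means = _circle_means(7, config.group_effect_size, phase=0.0)
    diet_means = _circle_means(7, 0.5 * config.group_effect_size, phase=np.pi / 7)
    loco_idx = np.array([LOCOMOTOR_REGIMES.index(g) for g in loco])
    diet_idx = np.array([DIETARY_REGIMES.index(g) for g in diet])
    latent = (
        loco_means[loco_idx]
        + diet_means[diet_idx]
        + rng_latent.normal(0.0, 1.0, size=(n, 2))
    )

    names = schema.trait_names
    lin_names, ang_names = schema.linear_traits, schema.angular_traits
    loadings = pd.DataFrame(0.0, index=names, columns=["lat1", "lat2"])
    loadings.loc[lin_names] = rng_struct.normal(0.0, config.loading_scale, (len(lin_names), 2))
    loadings.loc[ang_names] = rng_struct.normal(
        0.0, config.angular_loading_scale, (len(ang_names), 2)
    )
    log_base = pd.Series(
        rng_struct.uniform(np.log(5.0), np.log(300.0), len(lin_names)), index=lin_names
    )
    ang_base = pd.Series(rng_struct.uniform(60.0, 120.0, len(ang_names)), index=ang_names)

    log_shape = (
        log_base.to_numpy()
        + latent @ loadings.loc[lin_names].to_numpy().T
        + rng_traits.normal(0.0, config.trait_noise_sd, (n, len(lin_names)))
    )
    log_size = rng_size.normal(0.0, config.size_sd, n) if config.size_sd > 0 else np.zeros(n)
    linear = np.exp(log_shape + log_size[:, None])
    angular = (
        ang_base.to_numpy()
        + latent @ loadings.loc[ang_names].to_numpy().T
        + rng_traits.normal(0.0, config.angular_noise_sd, (n, len(ang_names)))
    )
    angular = np.clip(angular, 0.0, np.nextafter(360.0, 0.0))

    traits = pd.DataFrame(
        np.column_stack([linear, angular]),
        columns=lin_names + ang_names,
        index=[f"sp_{i + 1:03d}" for i in range(n)],
    )[names]
    meta = pd.DataFrame(
        {
            "species": [f"Species {i + 1:03d}" for i in range(n)],
            "locomotor": loco,
            "dietary": diet,
            "family": fam,
        },
        index=traits.index,
    )
    table = TraitTable(traits=traits, meta=meta, schema=schema)
    group_means = {f"locomotor:{g}": loco_means[i] for i, g in enumerate(LOCOMOTOR_REGIMES)}
    group_means.update({f"dietary:{g}": diet_means[i] for i, g in enumerate(DIETARY_REGIMES)})
    truth = SyntheticTruth(
        latent_positions=latent,
        group_means=group_means,
        loading_matrix=loadings.to_numpy(),
        trait_names=names,
    )
    return table, truth


def gaussian_bump_surface(
    grid: GridSpec, peak: np.ndarray, width: float, proxy_name: str = ""
) -> PerformanceSurface:
    """Unimodal surface exp(-|x - peak|^2 / (2 width^2)), min-max normalized."""
    nodes = grid.nodes()
    d2 = ((nodes - np.asarray(peak, dtype=float)) ** 2).sum(axis=1)
    raw = np.exp(-d2 / (2.0 * width**2)).reshape(grid.nx, grid.ny)
    return PerformanceSurface(
        proxy_name=proxy_name,
        grid=grid,
        raw_values=raw,
        normalized_values=normalize_surface(raw),
        variogram=None,
    )


def generate_landscape_scenario(
    n_surfaces: int,
    true_weights: WeightVector,
    grid: GridSpec | None = None,
    seed: int = 0,
    n_group_points: int = 5,
) -> tuple[list[PerformanceSurface], np.ndarray, SyntheticTruth]:
    """Known-truth scenario for the weight search.

    Surfaces are Gaussian bumps with distinct peaks spread on a circle inside
    the grid; the group sits (with small jitter) at the argmax of the true
    weighted combination, so optimizing the group's fitness should recover
    ``true_weights`` whenever it is representable at the search increment.
    """
    if len(true_weights) != n_surfaces:
        raise ValidationError(f"{len(true_weights)} weights for {n_surfaces} surfaces")
    if grid is None:
        grid = GridSpec(-1.0, 1.0, -1.0, 1.0, nx=60, ny=60)
    rng = np.random.default_rng(seed)
    span = min(grid.x_max - grid.x_min, grid.y_max - grid.y_min)
    center = np.array([(grid.x_min + grid.x_max) / 2, (grid.y_min + grid.y_max) / 2])
    phase = rng.uniform(0, 2 * np.pi)
    ang = 2 * np.pi * np.arange(n_surfaces) / n_surfaces + phase
    peaks = center + 0.3 * span * np.column_stack([np.cos(ang), np.sin(ang)])
    width = 0.35 * span
    surfaces = [
        gaussian_bump_surface(grid, peaks[i], width, proxy_name=f"F{i + 1}")
        for i in range(n_surfaces)
    ]
    combined = np.tensordot(
        true_weights.weights, np.stack([s.normalized_values for s in surfaces]), axes=1
    )
    flat = int(np.argmax(combined))
    optimum = grid.nodes()[flat]
    jitter = 0.005 * span * rng.standard_normal((n_group_points, 2))
    group_points = optimum + jitter - jitter.mean(axis=0)  # centroid exactly at the argmax
    truth = SyntheticTruth(
        latent_positions=group_points,
        group_means={"group": optimum},
        loading_matrix=np.zeros((0, 2)),
        true_weights=true_weights,
        true_optimum=optimum,
    )
    return surfaces, group_points, truth
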