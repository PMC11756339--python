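"""End-to-end orchestration: traits -> morphospace -> proxies -> surfaces ->
landscapes -> group comparison, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

import morphlands
from morphlands.compare import (
    HYPERGEOMETRIC,
    average_top_weights,
    pairwise_comparison_matrix,
    permutation_manova,
)
from morphlands.errors import DegeneracyError, ValidationError
from morphlands.kriging import GridSpec, VARIOGRAM_FAMILIES, interpolate_surface
from morphlands.morphospace import fit_pca, make_theoretical_grid
from morphlands.optimize import (
    AT_GROUP_MEAN,
    GroupFitnessRanking,
    enumerate_weights,
    optimize_group,
)
from morphlands.proxies import (
    DEFAULT_DROP_LIST,
    compute_proxy_table,
    default_registry,
    drop_proxies,
    grid_shape_table,
    registry_from_yaml,
)
from morphlands.synthetic import SyntheticConfig, generate_dataset
from morphlands.trait_data import log_shape_ratio, read_trait_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run; flags mirror the CLI."""

    trait_csv: str | None = None  # None -> simulate a dataset
    schema_yaml: str | None = None
    registry_yaml: str | None = None  # None -> default 27-proxy registry
    drop_list: tuple[str, ...] = DEFAULT_DROP_LIST
    size_correction: bool = True
    angular_in_pca: bool = True
    grid_nx: int = 50
    grid_ny: int = 50
    grid_pad: float = 0.05
    variogram_families: tuple[str, ...] = VARIOGRAM_FAMILIES
    n_lags: int = 12
    log_skewed_proxies: bool = True  # krige >2-decade positive proxies on log scale
    weight_increment: float = 0.25
    fitness_mode: str = AT_GROUP_MEAN
    top_percentile: float = 5.0
    null_method: str = HYPERGEOMETRIC
    group_axis: str = "locomotor"
    theoretical_grid: tuple[int, int] = (9, 7)
    use_theoretical: bool = False  # krige proxies of grid morphologies, not species
    manova_permutations: int = 999
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    output_dir: str = "morphlands_out"
    write_rankings: int = 1000  # top rows per group written to CSV

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": morphlands.__version__,
        "warnings": warnings,
    }

    # --- stage: ingest -----------------------------------------------------
    if config.trait_csv is None:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        table, _truth = generate_dataset(syn)
        manifest["input"] = {"synthetic": True, "synthetic_seed": syn.seed}
    else:
        if config.schema_yaml is None:
            raise ValidationError("a schema YAML is required with a trait CSV")
        table = read_trait_table(config.trait_csv, config.schema_yaml)
        manifest["input"] = {"synthetic": False, "trait_csv": config.trait_csv}
    manifest["n_specimens"] = table.n_specimens
    manifest["n_traits"] = len(table.trait_names)

    # --- stage: size correction + PCA -------------------------------------
    corrected = log_shape_ratio(table, enabled=config.size_correction)
    if not config.angular_in_pca:
        keep = corrected.schema.linear_traits
        corrected.corrected = corrected.corrected[keep]
    corrected.to_csv(out / "size_corrected.csv")
    space = fit_pca(corrected)
    space.scores_csv(out / "pc_scores.csv")
    space.loadings_csv(out / "pc_loadings.csv")
    manifest["pc12_prop_variance"] = float(space.prop_variance[:2].sum())

    grid_cols, grid_rows = config.theoretical_grid
    theo = make_theoretical_grid(space, grid_cols, grid_rows)
    theo.to_csv(out / "theoretical_grid.csv")
    manifest["n_theoretical_species"] = theo.n_points

    # --- stage: proxies ----------------------------------------------------
    registry = (
        registry_from_yaml(config.registry_yaml) if config.registry_yaml else default_registry()
    )
    if config.use_theoretical:
        shape_table = grid_shape_table(theo, table.schema)
        proxy_points = theo.pc_scores
        proxies = compute_proxy_table(registry, shape_table, index_name="theoretical_species")
    else:
        proxy_points = space.scores.to_numpy()[:, :2]
        proxies = compute_proxy_table(registry, table)
    proxies.values.to_csv(out / "proxy_table.csv")
    manifest["n_proxies_computed"] = len(proxies.proxy_names)
    retained = drop_proxies(proxies, config.drop_list) if config.drop_list else proxies
    manifest["n_proxies_retained"] = len(retained.proxy_names)

    # --- stage: kriged performance surfaces --------------------------------
    grid = GridSpec.from_points(
        proxy_points, nx=config.grid_nx, ny=config.grid_ny, pad=config.grid_pad
    )
    surfaces = []
    log_kriged: list[str] = []
    for name in retained.proxy_names:
        vals = retained.values[name].to_numpy(dtype=float)
        # strictly positive proxies spanning orders of magnitude (second
        # moments of area go as width * height^3) are interpolated on the log
        # scale, the standard variance-stabilizing practice in kriging
        if config.log_skewed_proxies and vals.min() > 0 and vals.max() / vals.min() > 100:
            vals = np.log(vals)
            log_kriged.append(name)
        try:
            surf = interpolate_surface(
                proxy_points,
                vals,
                grid,
                proxy_name=name,
                n_lags=config.n_lags,
                families=config.variogram_families,
            )
        except DegeneracyError as exc:
            warnings.append(f"surface {name} dropped: {exc}")
            continue
        surf.to_long_csv(out / f"surface_{name}.csv")
        surf.variogram_yaml(out / f"variogram_{name}.yaml")
        surfaces.append(surf)
    manifest["n_surfaces"] = len(surfaces)
    manifest["log_scale_surfaces"] = log_kriged
    if len(surfaces) < 1:
        raise DegeneracyError("no non-degenerate performance surfaces")

    # --- stage: weight search per group ------------------------------------
    candidates = enumerate_weights(len(surfaces), config.weight_increment)
    manifest["n_weight_vectors"] = len(candidates)
    if config.group_axis not in ("locomotor", "dietary", "family"):
        raise ValidationError(f"unknown group axis {config.group_axis!r}")
    labels = space.meta[config.group_axis]
    scores12 = space.scores.to_numpy()[:, :2]
    rankings = []
    for group in sorted(labels.unique()):
        pts = scores12[(labels == group).to_numpy()]
        rk = optimize_group(surfaces, candidates, pts, mode=config.fitness_mode, group_label=group)
        top = rk.order[: config.write_rankings]
        sub = GroupFitnessRanking(
            group_label=group,
            weight_vectors=rk.weight_vectors,
            fitness=rk.fitness,
            order=top,
            surface_names=rk.surface_names,
        )
        sub.to_csv(out / f"ranking_{config.group_axis}_{group}.csv")
        rankings.append(rk)
    manifest["groups"] = [r.group_label for r in rankings]
    manifest["w_prime"] = {
        r.group_label: dict(zip([s.proxy_name for s in surfaces], map(float, r.w_prime.weights)))
        for r in rankings
    }
    manifest["w_prime_top_avg"] = {
        r.group_label: dict(
            zip(
                [s.proxy_name for s in surfaces],
                map(float, average_top_weights(r, config.top_percentile)),
            )
        )
        for r in rankings
    }

    # --- stage: comparisons -------------------------------------------------
    if len(rankings) >= 2:
        mat = pairwise_comparison_matrix(
            rankings,
            percentile=config.top_percentile,
            null_method=config.null_method,
            seed=config.seed,
        )
        mat.to_csv(out / f"comparison_{config.group_axis}.csv")
    for axis in ("locomotor", "dietary"):
        res = permutation_manova(
            scores12,
            space.meta[axis],
            n_permutations=config.manova_permutations,
            seed=config.seed,
        )
        res.to_yaml(out / f"manova_{axis}.yaml")
        manifest[f"manova_{axis}"] = {
            "r_squared": float(res.r_squared),
            "f_statistic": float(res.f_statistic),
            "p_value": float(res.p_value),
        }

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
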