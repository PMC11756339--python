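"""Functional-proxy registry and computation.

Functional proxies are morphology-derived indices standing in for performance
traits: lever-arm mechanical advantages in the jaw, elongation and robustness
ratios in the limbs, and stiffness/mobility measures in the vertebral column.
The default registry instantiates 27 proxies — 2 skull, 7 forelimb, 6
hindlimb, and 4 vertebral proxies at each of three joint regions (third
cervical, diaphragmatic thoracic, middle lumbar) — using conventional
ecomorphology formulas. Every formula is overridable via a YAML registry so
the pipeline is not tied to any particular algebra.

Formula kinds
-------------
ratio
    operand1 / operand2 (e.g. mechanical advantage = in-lever / out-lever,
    robustness = midshaft diameter / length).
sum_ratio
    (operand1 + ... + operand_k) / (operand_{k+1} + ... ), with k given by
    ``n_numerator``.
elliptical_second_moment
    (pi/64) * a * b**3 for operands (a, b): the second moment of area of an
    elliptical beam section. Sagittal-plane stiffness lists (width, height);
    the lateral-plane variant lists the swapped order.
angle_passthrough
    the operand angle in degrees, unchanged (joint torsion angle, joint
    verticality).

Ratio-type proxies are dimensionless, so they are computed from raw
(non-size-corrected) traits and are invariant to uniform scaling of their
operands; second-moment proxies computed from shape variables are on a
size-relative scale, which is all the landscape machinery needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from morphlands.errors import SchemaError, ValidationError
from morphlands.morphospace import TheoreticalGrid
from morphlands.trait_data import ANGULAR, LINEAR, TraitSchema, TraitTable

RATIO = "ratio"
SUM_RATIO = "sum_ratio"
SECOND_MOMENT = "elliptical_second_moment"
ANGLE = "angle_passthrough"

#: Vertebral joint regions at which the vertebral proxies are instantiated.
VERTEBRAL_POSITIONS = {
    "c3": "third cervical",
    "dt": "diaphragmatic thoracic",
    "ml": "middle lumbar",
}

#: Proxies removed from landscape analyses by default (surfaces dominated by
#: single-species peaks on the empirical data this pipeline emulates).
DEFAULT_DROP_LIST = ("masMA", "SI", "GI", "TRI")


@dataclass(frozen=True)
class ProxyDefinition:
    name: str
    region: str  # skull | forelimb | hindlimb | vertebral
    formula_kind: str
    operands: tuple[str, ...]
    description: str = ""
    vertebral_position: str | None = None
    n_numerator: int | None = None  # split point for sum_ratio

    def __post_init__(self) -> None:
        if self.formula_kind not in (RATIO, SUM_RATIO, SECOND_MOMENT, ANGLE):
            raise SchemaError(f"proxy {self.name}: unknown formula kind {self.formula_kind!r}")
        n = len(self.operands)
        if self.formula_kind == RATIO and n != 2:
            raise SchemaError(f"proxy {self.name}: ratio needs exactly 2 operands")
        if self.formula_kind == SECOND_MOMENT and n != 2:
            raise SchemaError(f"proxy {self.name}: second moment needs exactly 2 operands")
        if self.formula_kind == ANGLE and n != 1:
            raise SchemaError(f"proxy {self.name}: angle passthrough needs 1 operand")
        if self.formula_kind == SUM_RATIO:
            if self.n_numerator is None or not (0 < self.n_numerator < n):
                raise SchemaError(f"proxy {self.name}: sum_ratio needs a valid n_numerator")


@dataclass
class ProxyTable:
    """Species-by-proxy value matrix (no missing values allowed)."""

    values: pd.DataFrame  # species x proxies

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def proxy_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "species"
        out.to_csv(path)


def default_registry() -> list[ProxyDefinition]:
    """The 27-proxy default registry over the package's core trait names."""
    defs = [
        ProxyDefinition(
            "temMA", "skull", RATIO, ("temporalis_in_lever", "jaw_out_lever"),
            "temporalis mechanical advantage: bite-force transmission from the temporalis",
        ),
        ProxyDefinition(
            "masMA", "skull", RATIO, ("masseter_in_lever", "jaw_out_lever"),
            "masseter mechanical advantage: bite-force transmission from the masseter",
        ),
        ProxyDefinition(
            "SI", "forelimb", RATIO, ("scapula_width", "scapula_length"),
            "scapula index: shoulder-muscle expansion vs. scapular contribution to limb length",
        ),
        ProxyDefinition(
            "BI", "forelimb", RATIO, ("radius_length", "humerus_length"),
            "brachial index: relative distal-element elongation of the forelimb",
        ),
        ProxyDefinition(
            "HRI", "forelimb", RATIO, ("humerus_diameter", "humerus_length"),
            "humeral robustness: resistance to bending and shear",
        ),
        ProxyDefinition(
            "HEI", "forelimb", RATIO, ("humerus_epicondylar_breadth", "humerus_length"),
            "humeral epicondylar index: origin area for forearm flexors/pronators/supinators",
        ),
        ProxyDefinition(
            "OLI", "forelimb", RATIO, ("olecranon_length", "ulna_length"),
            "olecranon length index: triceps mechanical advantage in elbow extension",
        ),
        ProxyDefinition(
            "URI", "forelimb", RATIO, ("ulna_diameter", "ulna_length"),
            "ulnar robustness: resistance to bending and shear, flexor attachment area",
        ),
        ProxyDefinition(
            "MAN", "forelimb", SUM_RATIO,
            ("metacarpal3_length", "humerus_length", "radius_length"),
            "manus proportions: relative hand size vs. proximal forelimb",
            n_numerator=1,
        ),
        ProxyDefinition(
            "CI", "hindlimb", RATIO, ("tibia_length", "femur_length"),
            "crural index: relative distal-element elongation of the hindlimb",
        ),
        ProxyDefinition(
            "FRI", "hindlimb", RATIO, ("femur_diameter", "femur_length"),
            "femoral robustness: resistance to bending and shear",
        ),
        ProxyDefinition(
            "GI", "hindlimb", RATIO, ("greater_trochanter_height", "femur_length"),
            "gluteal index: gluteal mechanical advantage in femoral retraction",
        ),
        ProxyDefinition(
            "FEI", "hindlimb", RATIO, ("femur_epicondylar_breadth", "femur_length"),
            "femoral epicondylar index: origin area for gastrocnemius/soleus",
        ),
        ProxyDefinition(
            "TRI", "hindlimb", RATIO, ("tibia_diameter", "tibia_length"),
            "tibial robustness: resistance to bending and shear",
        ),
        ProxyDefinition(
            "PES", "hindlimb", SUM_RATIO,
            ("metatarsal3_length", "femur_length", "tibia_length"),
            "pes length index: relative hindfoot size vs. proximal hindlimb",
            n_numerator=1,
        ),
    ]
    for pos, pos_name in VERTEBRAL_POSITIONS.items():
        w, h = f"{pos}_centrum_width", f"{pos}_centrum_height"
        defs.extend(
            [
                ProxyDefinition(
                    f"sSMA_{pos}", "vertebral", SECOND_MOMENT, (w, h),
                    f"sagittal second moment of area ({pos_name}): sagittal-plane stiffness",
                    vertebral_position=pos_name,
                ),
                ProxyDefinition(
                    f"lSMA_{pos}", "vertebral", SECOND_MOMENT, (h, w),
                    f"lateral second moment of area ({pos_name}): lateral-plane stiffness",
                    vertebral_position=pos_name,
                ),
                ProxyDefinition(
                    f"JTA_{pos}", "vertebral", ANGLE, (f"{pos}_joint_torsion_angle",),
                    f"joint torsion angle ({pos_name}): range of axial rotation",
                    vertebral_position=pos_name,
                ),
                ProxyDefinition(
                    f"JV_{pos}", "vertebral", ANGLE, (f"{pos}_joint_verticality_angle",),
                    f"joint verticality ({pos_name}): sagittal vs. lateral bending emphasis",
                    vertebral_position=pos_name,
                ),
            ]
        )
    return defs


def registry_from_yaml(path: str | Path) -> list[ProxyDefinition]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for entry in raw["proxies"]:
        defs.append(
            ProxyDefinition(
                name=entry["name"],
                region=entry["region"],
                formula_kind=entry["formula_kind"],
                operands=tuple(entry["operands"]),
                description=entry.get("description", ""),
                vertebral_position=entry.get("vertebral_position"),
                n_numerator=entry.get("n_numerator"),
            )
        )
    return defs


def registry_to_yaml(registry: Sequence[ProxyDefinition], path: str | Path) -> None:
    doc = {"proxies": []}
    for d in registry:
        entry: dict = {
            "name": d.name,
            "region": d.region,
            "formula_kind": d.formula_kind,
            "operands": list(d.operands),
        }
        if d.description:
            entry["description"] = d.description
        if d.vertebral_position:
            entry["vertebral_position"] = d.vertebral_position
        if d.n_numerator is not None:
            entry["n_numerator"] = d.n_numerator
        doc["proxies"].append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _evaluate(defn: ProxyDefinition, cols: list[np.ndarray], context: str) -> np.ndarray:
    if defn.formula_kind == RATIO:
        num, den = cols
    elif defn.formula_kind == SUM_RATIO:
        num = sum(cols[: defn.n_numerator])
        den = sum(cols[defn.n_numerator :])
    elif defn.formula_kind == SECOND_MOMENT:
        a, b = cols
        return (math.pi / 64.0) * a * b**3
    else:  # ANGLE
        return cols[0]
    if np.any(den == 0):
        raise ValidationError(f"proxy {defn.name}: zero denominator ({context})")
    return num / den


def compute_proxy(defn: ProxyDefinition, traits: Mapping[str, float] | pd.Series) -> float:
    """Evaluate one proxy on a single trait vector."""
    try:
        cols = [np.asarray(float(traits[t])) for t in defn.operands]
    except KeyError as exc:
        raise SchemaError(f"proxy {defn.name}: operand trait {exc.args[0]!r} not found") from exc
    return float(_evaluate(defn, cols, "single specimen"))


def compute_proxy_table(
    registry: Sequence[ProxyDefinition],
    table: TraitTable | pd.DataFrame,
    index_name: str = "species",
) -> ProxyTable:
    """Evaluate every registered proxy for every specimen/species.

    Accepts a validated :class:`TraitTable` (proxies are computed from the raw
    measurements; ratios are size-free by construction) or a plain DataFrame
    of trait values such as reconstructed theoretical morphologies.
    """
    if not registry:
        raise ValidationError("proxy registry is empty")
    if isinstance(table, TraitTable):
        df = table.traits
        idx = table.meta["species"]
    else:
        df = table
        idx = df.index
    missing = {t for d in registry for t in d.operands} - set(df.columns)
    if missing:
        raise SchemaError(f"registry operands absent from trait table: {sorted(missing)}")
    out = {}
    for d in registry:
        cols = [df[t].to_numpy(dtype=float) for t in d.operands]
        vals = _evaluate(d, cols, f"{len(df)} specimens")
        if not np.isfinite(vals).all():
            bad = np.flatnonzero(~np.isfinite(vals))[0]
            raise ValidationError(f"proxy {d.name}: non-finite value for {df.index[bad]!r}")
        out[d.name] = vals
    values = pd.DataFrame(out, index=pd.Index(idx, name=index_name))
    return ProxyTable(values=values)


def drop_proxies(table: ProxyTable, names: Iterable[str]) -> ProxyTable:
    """Remove named proxy columns (e.g. the default drop list), keeping order."""
    names = list(names)
    unknown = set(names) - set(table.proxy_names)
    if unknown:
        raise ValidationError(f"cannot drop unknown proxies: {sorted(unknown)}")
    kept = [c for c in table.proxy_names if c not in set(names)]
    if not kept:
        raise ValidationError("dropping all proxies would leave an empty table")
    return ProxyTable(values=table.values[kept].copy())


def grid_shape_table(grid: TheoreticalGrid, schema: TraitSchema) -> pd.DataFrame:
    """Convert reconstructed log-shape ratios to a shape-variable table.

    Linear traits come back as exp(log-shape ratio) — the trait's size-relative
    magnitude — and angular traits pass through, so the proxy registry can be
    evaluated on theoretical morphologies exactly as on real specimens.
    """
    df = grid.reconstructed_traits.copy()
    lin = [t for t in df.columns if schema.kinds.get(t) == LINEAR]
    ang = [t for t in df.columns if schema.kinds.get(t) == ANGULAR]
    df[lin] = np.exp(df[lin].to_numpy(dtype=float))
    df[ang] = df[ang].to_numpy(dtype=float)
    return df
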