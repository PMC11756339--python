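"""Reading, validation, and size correction of specimen trait tables.

A trait table holds one row per specimen (here one adult individual per
species) with positive linear measurements in mm and angular measurements in
degrees, plus ecological labels (locomotor regime, dietary regime, family).

Size correction follows the log-shape-ratio convention: specimen size is the
geometric mean of all linear traits and each linear trait t is replaced by
ln(t / size). Angular traits are dimensionless with respect to size and pass
through unchanged. A consequence used as a validation invariant downstream:
the log-shape ratios of the traits entering the geometric mean sum to zero
for every specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from morphlands.errors import SchemaError, ValidationError

#: Metadata columns expected in a trait CSV, in order.
META_COLUMNS = ("specimen_id", "species", "locomotor", "dietary", "family")

LINEAR = "linear"
ANGULAR = "angular"


@dataclass(frozen=True)
class TraitSchema:
    """Declares each trait's kind (linear/angular) and optional units."""

    kinds: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: k for t, k in self.kinds.items() if k not in (LINEAR, ANGULAR)}
        if bad:
            raise SchemaError(f"unknown trait kinds: {bad}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.kinds)

    @property
    def linear_traits(self) -> list[str]:
        return [t for t, k in self.kinds.items() if k == LINEAR]

    @property
    def angular_traits(self) -> list[str]:
        return [t for t, k in self.kinds.items() if k == ANGULAR]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "traits" not in raw:
            raise SchemaError(f"{path}: expected a mapping with a 'traits' key")
        kinds, units = {}, {}
        for name, entry in raw["traits"].items():
            if isinstance(entry, str):
                kinds[name] = entry
            else:
                kinds[name] = entry.get("kind", LINEAR)
                if "units" in entry:
                    units[name] = entry["units"]
        return cls(kinds=kinds, units=units)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "traits": {
                name: (
                    {"kind": kind, "units": self.units[name]}
                    if name in self.units
                    else kind
                )
                for name, kind in self.kinds.items()
            }
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class TraitTable:
    """Validated specimen-by-trait measurements with ecological labels.

    Attributes
    ----------
    traits : DataFrame
        Specimens (index: specimen_id) by named traits; all values finite,
        linear traits strictly positive, angular traits in [0, 360).
    meta : DataFrame
        Same index; columns species, locomotor, dietary, family.
    schema : TraitSchema
        Kind declaration for every trait column.
    """

    traits: pd.DataFrame
    meta: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(self.schema.trait_names) - set(self.traits.columns)
        if missing:
            raise SchemaError(f"traits declared in schema but absent from table: {sorted(missing)}")
        extra = set(self.traits.columns) - set(self.schema.trait_names)
        if extra:
            raise SchemaError(f"trait columns not declared in schema: {sorted(extra)}")
        if not self.traits.index.equals(self.meta.index):
            raise ValidationError("traits and meta must be indexed by the same specimens")
        for col in ("species", "locomotor", "dietary", "family"):
            if col not in self.meta.columns:
                raise SchemaError(f"missing metadata column {col!r}")
            if self.meta[col].isna().any():
                bad = self.meta.index[self.meta[col].isna()][0]
                raise ValidationError(f"specimen {bad!r}: missing {col} label")
        values = self.traits.to_numpy(dtype=float)
        if np.isnan(values).any():
            spec, trait = self._first_offender(np.isnan(values))
            raise ValidationError(f"specimen {spec!r}: missing value for trait {trait!r}")
        if not np.isfinite(values).all():
            spec, trait = self._first_offender(~np.isfinite(values))
            raise ValidationError(f"specimen {spec!r}: non-finite value for trait {trait!r}")
        lin = self.traits[self.schema.linear_traits].to_numpy(dtype=float)
        if (lin <= 0).any():
            mask = np.zeros_like(values, dtype=bool)
            cols = [self.traits.columns.get_loc(t) for t in self.schema.linear_traits]
            mask[:, cols] = lin <= 0
            spec, trait = self._first_offender(mask)
            raise ValidationError(
                f"specimen {spec!r}: linear trait {trait!r} must be strictly positive"
            )
        ang = self.traits[self.schema.angular_traits].to_numpy(dtype=float)
        if ang.size and ((ang < 0) | (ang >= 360)).any():
            mask = np.zeros_like(values, dtype=bool)
            cols = [self.traits.columns.get_loc(t) for t in self.schema.angular_traits]
            mask[:, cols] = (ang < 0) | (ang >= 360)
            spec, trait = self._first_offender(mask)
            raise ValidationError(
                f"specimen {spec!r}: angular trait {trait!r} must lie in [0, 360)"
            )

    def _first_offender(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.traits.index[i]), str(self.traits.columns[j])

    @property
    def n_specimens(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.traits], axis=1)
        out.index.name = "specimen_id"
        out.to_csv(path)


@dataclass
class SizeCorrectedTable:
    """Log-shape ratios for linear traits, raw angles, and per-specimen size.

    ``corrected`` has the same specimen index and trait column order as the
    source table; ``size`` is the geometric mean of each specimen's linear
    traits (or 1.0 when correction is disabled).
    """

    corrected: pd.DataFrame
    size: pd.Series
    meta: pd.DataFrame
    schema: TraitSchema
    size_corrected: bool = True

    @property
    def trait_names(self) -> list[str]:
        return list(self.corrected.columns)

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.corrected], axis=1)
        out["size"] = self.size
        out.index.name = "specimen_id"
        out.to_csv(path)


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean exp(mean(ln v)) of strictly positive values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of an empty collection is undefined")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValidationError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr))))


def log_shape_ratio(table: TraitTable, enabled: bool = True) -> SizeCorrectedTable:
    """Size-correct a trait table via log-shape ratios.

    Each linear trait t becomes ln(t / size) with size the geometric mean of
    the specimen's linear traits; angular traits pass through unchanged. With
    ``enabled=False`` (the no-size-correction sensitivity variant) linear
    traits become ln(t) and size is recorded as 1, so the downstream PCA still
    operates on a log scale but retains isometric size.
    """
    lin_names = table.schema.linear_traits
    if not lin_names:
        raise ValidationError("size correction requires at least one linear trait")
    corrected = table.traits.astype(float).copy()
    log_lin = np.log(corrected[lin_names].to_numpy())
    if enabled:
        log_size = log_lin.mean(axis=1)
    else:
        log_size = np.zeros(len(corrected))
    corrected[lin_names] = log_lin - log_size[:, None]
    size = pd.Series(np.exp(log_size), index=corrected.index, name="size")
    return SizeCorrectedTable(
        corrected=corrected,
        size=size,
        meta=table.meta.copy(),
        schema=table.schema,
        size_corrected=enabled,
    )


def read_trait_table(
    path: str | Path,
    schema: TraitSchema | Mapping[str, str] | str | Path,
) -> TraitTable:
    """Read a trait CSV (comma-separated, UTF-8, header row) and validate it.

    The CSV must carry the metadata columns ``specimen_id, species, locomotor,
    dietary, family`` followed by one column per declared trait. ``schema``
    may be a :class:`TraitSchema`, a trait-name -> kind mapping, or a path to
    a schema YAML.
    """
    if isinstance(schema, (str, Path)):
        schema = TraitSchema.from_yaml(schema)
    elif not isinstance(schema, TraitSchema):
        schema = TraitSchema(kinds=dict(schema))
    df = pd.read_csv(path, encoding="utf-8")
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["specimen_id"].duplicated().any():
        dup = df["specimen_id"][df["specimen_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate specimen_id {dup!r}")
    df = df.set_index("specimen_id")
    meta = df[list(META_COLUMNS[1:])]
    missing = [t for t in schema.trait_names if t not in df.columns]
    if missing:
        raise SchemaError(f"{path}: trait columns missing from CSV: {missing}")
    traits = df[schema.trait_names].apply(pd.to_numeric, errors="coerce")
    return TraitTable(traits=traits, meta=meta, schema=schema)
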