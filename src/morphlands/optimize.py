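"""Weight enumeration, landscape combination, and group-optimal landscapes.

An adaptive landscape is the convex combination W = sum_n w_n F_n of the
normalized performance surfaces, with the weights w_n >= 0 summing to 1.
Candidate weight vectors are enumerated exhaustively on a simplex lattice
(weights in multiples of a fixed increment); each group's fitness under a
candidate landscape is the landscape height at the group's mean morphospace
position (or, optionally, the mean height over members), and the optimum W'
is the argmax over candidates with a lexicographic tie-break.

Weights are stored internally as integer multiples of the increment so that
every enumerated vector sums to 1 exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from morphlands.errors import ValidationError
from morphlands.kriging import GridSpec, PerformanceSurface

logger = logging.getLogger(__name__)

AT_GROUP_MEAN = "at_group_mean"
MEAN_OVER_MEMBERS = "mean_over_members"


@dataclass(frozen=True)
class WeightVector:
    """Simplex-lattice weight vector: units[i] * increment, sum = 1."""

    units: tuple[int, ...]  # integer multiples of the increment
    increment: float

    def __post_init__(self) -> None:
        m = round(1.0 / self.increment)
        if not math.isclose(m * self.increment, 1.0, rel_tol=0, abs_tol=1e-12):
            raise ValidationError(f"increment {self.increment} does not divide 1")
        if any(u < 0 for u in self.units) or sum(self.units) != m:
            raise ValidationError("weight units must be nonnegative and sum to 1/increment")

    @classmethod
    def from_weights(cls, weights: Sequence[float], increment: float) -> "WeightVector":
        m = round(1.0 / increment)
        units = tuple(int(round(w * m)) for w in weights)
        return cls(units=units, increment=increment)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.units, dtype=float) * self.increment

    def __len__(self) -> int:
        return len(self.units)


@dataclass
class AdaptiveLandscape:
    """Cellwise weighted sum of normalized performance surfaces."""

    weight_vector: WeightVector
    grid: GridSpec
    values: np.ndarray  # (nx, ny)


@dataclass
class GroupFitnessRanking:
    """Every candidate weight vector ranked by a group's fitness."""

    group_label: str
    weight_vectors: list[WeightVector]  # candidate order (enumeration order)
    fitness: np.ndarray  # aligned to weight_vectors
    order: np.ndarray  # candidate indices sorted best-first
    surface_names: list[str] = field(default_factory=list)

    @property
    def w_prime(self) -> WeightVector:
        return self.weight_vectors[int(self.order[0])]

    @property
    def n_candidates(self) -> int:
        return len(self.weight_vectors)

    def to_csv(self, path: str | Path) -> None:
        names = self.surface_names or [f"w{i + 1}" for i in range(len(self.weight_vectors[0]))]
        rows = np.array([self.weight_vectors[i].weights for i in self.order])
        df = pd.DataFrame(rows, columns=names)
        df.insert(0, "rank", np.arange(1, len(self.order) + 1))
        df["fitness"] = self.fitness[self.order]
        df.to_csv(path, index=False)


def enumerate_weights(n_surfaces: int, increment: float = 0.25) -> list[WeightVector]:
    """All weight vectors on the simplex lattice, lexicographically descending.

    Counts follow stars-and-bars: with m = 1/increment units to distribute
    over n surfaces there are C(n + m - 1, m) vectors (27 surfaces at 0.25
    increments give C(30, 4) = 27,405 candidate landscapes).
    """
    if n_surfaces < 1:
        raise ValidationError("need at least one surface")
    m = round(1.0 / increment)
    if m < 1 or not math.isclose(m * increment, 1.0, rel_tol=0, abs_tol=1e-12):
        raise ValidationError(f"1/increment must be a positive integer, got {increment}")
    out: list[WeightVector] = []
    units = [0] * n_surfaces

    def rec(slot: int, remaining: int) -> None:
        if slot == n_surfaces - 1:
            units[slot] = remaining
            out.append(WeightVector(units=tuple(units), increment=increment))
            return
        for u in range(remaining, -1, -1):
            units[slot] = u
            rec(slot + 1, remaining - u)

    rec(0, m)
    return out


def weight_matrix(weight_vectors: Sequence[WeightVector]) -> np.ndarray:
    """Stack candidate weights into a (n_candidates, n_surfaces) float matrix."""
    return np.array([wv.weights for wv in weight_vectors])


def combine_landscape(
    surfaces: Sequence[PerformanceSurface], w: WeightVector
) -> AdaptiveLandscape:
    """W = sum_n w_n F_n over the shared grid of normalized surfaces."""
    if len(surfaces) != len(w):
        raise ValidationError(f"{len(w)} weights for {len(surfaces)} surfaces")
    grid = surfaces[0].grid
    if any(s.grid != grid for s in surfaces[1:]):
        raise ValidationError("all surfaces must share one grid")
    stack = np.stack([s.normalized_values for s in surfaces])
    values = np.tensordot(w.weights, stack, axes=1)
    return AdaptiveLandscape(weight_vector=w, grid=grid, values=values)


def _clamp_points(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    lo = np.array([grid.x_min, grid.y_min])
    hi = np.array([grid.x_max, grid.y_max])
    clamped = np.clip(points, lo, hi)
    if not np.allclose(clamped, points):
        logger.warning("clamped %d points to grid bounds", int((clamped != points).any(axis=1).sum()))
    return clamped


def interpolate_at(grid: GridSpec, values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of gridded values at (clamped) points."""
    points = _clamp_points(np.atleast_2d(np.asarray(points, dtype=float)), grid)
    interp = RegularGridInterpolator((grid.xs, grid.ys), values, method="linear")
    return interp(points)


def group_fitness(
    landscape: AdaptiveLandscape,
    group_points: np.ndarray,
    mode: str = AT_GROUP_MEAN,
) -> float:
    """Height of the landscape for a group of morphospace points.

    ``at_group_mean`` evaluates W at the group centroid; ``mean_over_members``
    averages W over the member positions. Points outside the grid are clamped
    to the boundary with a warning.
    """
    pts = np.atleast_2d(np.asarray(group_points, dtype=float))
    if pts.size == 0:
        raise ValidationError("group has no points")
    if mode == AT_GROUP_MEAN:
        return float(interpolate_at(landscape.grid, landscape.values, pts.mean(axis=0))[0])
    if mode == MEAN_OVER_MEMBERS:
        return float(interpolate_at(landscape.grid, landscape.values, pts).mean())
    raise ValidationError(f"unknown fitness mode {mode!r}")


def optimize_group(
    surfaces: Sequence[PerformanceSurface],
    weight_vectors: Sequence[WeightVector],
    group_points: np.ndarray,
    mode: str = AT_GROUP_MEAN,
    group_label: str = "",
) -> GroupFitnessRanking:
    """Rank every candidate weight vector by the group's fitness.

    Because W is linear in the weights, the fitness of every candidate is the
    dot product of its weight vector with the per-surface fitness of the
    group, so the exhaustive search is a single matrix product rather than
    27,405 grid combinations. Ties rank the lexicographically smaller weight
    vector first.
    """
    if not weight_vectors:
        raise ValidationError("no candidate weight vectors")
    pts = np.atleast_2d(np.asarray(group_points, dtype=float))
    if mode == AT_GROUP_MEAN:
        pts = pts.mean(axis=0, keepdims=True)
    elif mode != MEAN_OVER_MEMBERS:
        raise ValidationError(f"unknown fitness mode {mode!r}")
    per_surface = np.array(
        [interpolate_at(s.grid, s.normalized_values, pts).mean() for s in surfaces]
    )
    W = weight_matrix(weight_vectors)
    if W.shape[1] != len(surfaces):
        raise ValidationError(f"{W.shape[1]}-long weight vectors for {len(surfaces)} surfaces")
    fitness = W @ per_surface
    # best-first; among equal fitness the lexicographically smallest weights
    units = np.array([wv.units for wv in weight_vectors])
    order = np.lexsort(tuple(units[:, i] for i in range(units.shape[1] - 1, -1, -1)) + (-fitness,))
    return GroupFitnessRanking(
        group_label=group_label,
        weight_vectors=list(weight_vectors),
        fitness=fitness,
        order=order,
        surface_names=[s.proxy_name for s in surfaces],
    )
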