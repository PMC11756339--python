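"""Ordinary kriging of functional proxies over the morphospace plane.

Each proxy observed at the species' (PC1, PC2) scores is interpolated onto a
regular grid by ordinary kriging: the best linear unbiased predictor whose
weights sum to one, driven by a semivariogram fitted to the empirical
binned semivariances. The pipeline then min-max normalizes each surface to
[0, 1] so surfaces are commensurate when combined into weighted landscapes.

The semivariogram gamma(h) is half the expected squared difference of field
values at separation h. Three standard isotropic families are supported,
parameterized by nugget (discontinuity at the origin), partial sill
(gamma(inf) - nugget) and range (practical correlation length):

    spherical    gamma = c0 + c * (1.5 u - 0.5 u^3),  u = min(h/a, 1)
    exponential  gamma = c0 + c * (1 - exp(-3 h / a))
    gaussian     gamma = c0 + c * (1 - exp(-3 h^2 / a^2))

The exponential/gaussian ranges use the practical-range convention (95% of
the sill at h = a). Family selection is by pair-count-weighted least squares.

The ordinary-kriging system at a prediction node x0 with samples x_1..x_n is
the augmented linear system

    [ Gamma  1 ] [ lambda ]   [ gamma(x_i, x0) ]
    [ 1^T    0 ] [ mu     ] = [ 1              ]

with Gamma_ij = gamma(|x_i - x_j|) off the diagonal and 0 on it (a point has
zero semivariance with itself); the unit row enforces sum(lambda) = 1, i.e.
unbiasedness. With a zero nugget the predictor interpolates the samples
exactly; a positive nugget filters measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from morphlands.errors import DegeneracyError, ValidationError

logger = logging.getLogger(__name__)

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid over the PC1-PC2 plane."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 50
    ny: int = 50

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError("grid bounds must satisfy min < max on both axes")
        if self.nx < 2 or self.ny < 2:
            raise ValidationError("grid needs at least 2 nodes per axis")

    @classmethod
    def from_points(
        cls, points: np.ndarray, nx: int = 50, ny: int = 50, pad: float = 0.05
    ) -> "GridSpec":
        """Bounding box of the points expanded by ``pad`` per side."""
        pts = np.asarray(points, dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = hi - lo
        return cls(
            x_min=float(lo[0] - pad * span[0]),
            x_max=float(hi[0] + pad * span[0]),
            y_min=float(lo[1] - pad * span[1]),
            y_max=float(hi[1] + pad * span[1]),
            nx=nx,
            ny=ny,
        )

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx)

    @property
    def ys(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny)

    def nodes(self) -> np.ndarray:
        """All nx*ny node coordinates, x-major order."""
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class VariogramModel:
    """Fitted semivariogram: gamma(0) = nugget, gamma(inf) = nugget + sill."""

    family: str
    nugget: float
    partial_sill: float
    range_param: float
    fit_sse: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValidationError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill <= 0 or self.range_param <= 0:
            raise ValidationError("variogram requires nugget >= 0, sill > 0, range > 0")

    def __call__(self, h: np.ndarray | float) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.partial_sill * _structure(self.family, h, self.range_param)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "range": float(self.range_param),
            "fit_sse": float(self.fit_sse),
        }


def _structure(family: str, h: np.ndarray, a: float) -> np.ndarray:
    """Unit-sill correlation structure g(h): g(0)=0, g(inf)=1."""
    if family == "spherical":
        u = np.minimum(h / a, 1.0)
        return 1.5 * u - 0.5 * u**3
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * h / a)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * (h / a) ** 2)
    raise ValidationError(f"unknown variogram family {family!r}")


@dataclass
class PerformanceSurface:
    """A gridded, normalized interpolation of one functional proxy."""

    proxy_name: str
    grid: GridSpec
    raw_values: np.ndarray  # (nx, ny)
    normalized_values: np.ndarray  # (nx, ny), min 0 max 1
    variogram: VariogramModel | None = None
    #: largest |sum(weights) - 1| over prediction nodes (unbiasedness check)
    max_weight_sum_error: float = 0.0

    def to_long_csv(self, path: str | Path) -> None:
        nodes = self.grid.nodes()
        pd.DataFrame(
            {
                "pc1": nodes[:, 0],
                "pc2": nodes[:, 1],
                "raw": self.raw_values.ravel(),
                "normalized": self.normalized_values.ravel(),
            }
        ).to_csv(path, index=False)

    def variogram_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"proxy": self.proxy_name, "variogram": self.variogram.to_dict()}, fh)


def empirical_semivariogram(
    points: np.ndarray, values: np.ndarray, n_lags: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariances.

    Returns (lag bin centers, semivariances, pair counts) over ``n_lags``
    equal-width distance bins spanning (0, max pairwise distance]. Empty bins
    carry NaN semivariance and zero count.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[0] != values.shape[0]:
        raise ValidationError("points must be (n, 2) aligned with values")
    if n_lags < 1:
        raise ValidationError("n_lags must be >= 1")
    d = pdist(points)
    if d.size == 0 or d.max() == 0:
        raise DegeneracyError("all points coincident: no nonzero lags")
    sq_half = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, d.max(), n_lags + 1)
    # right-inclusive bins over (0, max]
    idx = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq_half, minlength=n_lags)
    with np.errstate(invalid="ignore"):
        gammas = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gammas, counts


def fit_variogram(
    lags: np.ndarray,
    gammas: np.ndarray,
    counts: np.ndarray,
    families: Sequence[str] = VARIOGRAM_FAMILIES,
    max_lag_fraction: float = 0.5,
) -> VariogramModel:
    """Fit candidate families by pair-count-weighted least squares.

    Each family's (nugget, partial sill, range) is estimated by bounded
    nonlinear least squares with residuals weighted by sqrt(pair count); the
    family with the lowest weighted SSE wins. Only lags up to
    ``max_lag_fraction`` of the largest lag enter the fit (far bins hold few
    pairs and are dominated by boundary noise). A flat empirical variogram
    collapses to a pure-nugget model (partial sill at its lower bound).
    """
    lags = np.asarray(lags, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ok = (counts > 0) & np.isfinite(gammas)
    if ok.sum() > 3:
        cut = lags <= max_lag_fraction * lags[ok].max()
        if (ok & cut).sum() >= 3:
            ok &= cut
    lags, gammas, counts = lags[ok], gammas[ok], counts[ok]
    if lags.size < 3:
        raise ValidationError("variogram fitting needs >= 3 nonempty lag bins")
    gmax = float(gammas.max())
    if gmax <= 0:
        raise DegeneracyError("zero total variance: flat field has no variogram")
    w = np.sqrt(counts)
    hi_range = 3.0 * float(lags.max())
    lo = [0.0, 1e-10 * gmax, 1e-3 * float(lags.max())]
    hi = [gmax, 2.0 * gmax, hi_range]
    best: VariogramModel | None = None
    for family in families:
        for range0 in (0.3 * lags.max(), lags.max()):
            x0 = np.clip(
                [0.1 * gmax, max(gmax - 0.1 * gmax, lo[1]), range0], lo, hi
            )

            def resid(theta, family=family):
                c0, c, a = theta
                return w * (c0 + c * _structure(family, lags, a) - gammas)

            sol = least_squares(resid, x0, bounds=(lo, hi))
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best.fit_sse:
                c0, c, a = sol.x
                best = VariogramModel(
                    family=family,
                    nugget=float(c0),
                    partial_sill=float(max(c, lo[1])),
                    range_param=float(a),
                    fit_sse=sse,
                )
    # identifiability tie-break: when a pure-nugget model explains the data as
    # well as a structured one, prefer it (flat empirical variogram)
    nugget_level = float(np.average(gammas, weights=counts))
    sse_nugget = float(np.sum((w * (nugget_level - gammas)) ** 2))
    if sse_nugget <= best.fit_sse * (1 + 1e-9) + 1e-12 * gmax**2:
        return VariogramModel(
            family=best.family,
            nugget=nugget_level,
            partial_sill=lo[1],
            range_param=lo[2],
            fit_sse=sse_nugget,
        )
    return best


def _dedupe(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (kriging-matrix singularity guard)."""
    uniq, inv = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    logger.warning("averaging %d duplicate sample locations", len(points) - len(uniq))
    sums = np.bincount(inv, weights=values, minlength=len(uniq))
    cnts = np.bincount(inv, minlength=len(uniq))
    return uniq, sums / cnts


def krige(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    grid: GridSpec,
    proxy_name: str = "",
    normalize: bool = True,
) -> PerformanceSurface:
    """Ordinary-kriging prediction of ``values`` at every grid node.

    Solves the augmented system once via LU factorization and back-solves for
    all nodes simultaneously. Duplicate sample coordinates are averaged first.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    points, values = _dedupe(points, values)
    n = len(points)
    if n < 3:
        raise ValidationError("kriging needs at least 3 samples")
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model(squareform(pdist(points)))
    np.fill_diagonal(A[:n, :n], 0.0)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    nodes = grid.nodes()
    B = np.empty((n + 1, len(nodes)))
    B[:n] = model(cdist(points, nodes))
    B[n] = 1.0
    lam = lu_solve(lu_factor(A), B)
    weight_err = float(np.abs(lam[:n].sum(axis=0) - 1.0).max())
    if weight_err > 1e-6:
        logger.warning("kriging weight sums deviate from 1 by up to %.2e", weight_err)
    raw = (values @ lam[:n]).reshape(grid.nx, grid.ny)
    normalized = normalize_surface(raw) if normalize else raw
    return PerformanceSurface(
        proxy_name=proxy_name,
        grid=grid,
        raw_values=raw,
        normalized_values=normalized,
        variogram=model,
        max_weight_sum_error=weight_err,
    )


def normalize_surface(raw_values: np.ndarray) -> np.ndarray:
    """Min-max rescale grid values to [0, 1]; constant surfaces are degenerate."""
    raw = np.asarray(raw_values, dtype=float)
    if not np.isfinite(raw).all():
        raise ValidationError("surface contains non-finite values")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise DegeneracyError("constant surface cannot be normalized to [0, 1]")
    return (raw - lo) / (hi - lo)


def interpolate_surface(
    points: np.ndarray,
    values: np.ndarray,
    grid: GridSpec,
    proxy_name: str = "",
    n_lags: int = 12,
    families: Sequence[str] = VARIOGRAM_FAMILIES,
) -> PerformanceSurface:
    """Convenience chain: empirical semivariogram -> fit -> krige -> normalize."""
    lags, gammas, counts = empirical_semivariogram(points, values, n_lags=n_lags)
    model = fit_variogram(lags, gammas, counts, families=families)
    return krige(points, values, model, grid, proxy_name=proxy_name)
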