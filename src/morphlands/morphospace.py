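"""Covariance-matrix PCA morphospace and the theoretical-morphology grid.

The morphospace is the PC1-PC2 plane of a PCA on the size-corrected trait
matrix (covariance matrix, n-1 denominator). Theoretical morphologies are
reconstructed at evenly spaced lattice points spanning the observed score
range, with all components beyond the first two held at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from morphlands.errors import DegeneracyError, ValidationError
from morphlands.trait_data import SizeCorrectedTable


@dataclass
class Morphospace:
    """Fitted PCA ordination: means, orthonormal loadings, scores.

    Invariants: loading columns orthonormal; eigenvalues descending;
    ``scores == (X - means) @ loadings``.
    """

    trait_names: list[str]
    trait_means: np.ndarray
    loadings: np.ndarray  # traits x components, orthonormal columns
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # specimens x components
    prop_variance: np.ndarray
    meta: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project(self, trait_vector: pd.Series | np.ndarray) -> np.ndarray:
        """Project a trait vector into PC space: (v - means) @ loadings."""
        if isinstance(trait_vector, pd.Series):
            missing = set(self.trait_names) - set(trait_vector.index)
            if missing:
                raise ValidationError(f"trait vector missing traits: {sorted(missing)}")
            v = trait_vector[self.trait_names].to_numpy(dtype=float)
        else:
            v = np.asarray(trait_vector, dtype=float)
            if v.shape[-1] != len(self.trait_names):
                raise ValidationError(
                    f"expected {len(self.trait_names)} traits, got {v.shape[-1]}"
                )
        return (v - self.trait_means) @ self.loadings

    def reconstruct_traits(self, pc1: float, pc2: float) -> pd.Series:
        """Trait vector at (pc1, pc2) with all higher components at zero."""
        if self.n_components < 2:
            raise DegeneracyError("reconstruction needs at least two components")
        v = self.trait_means + pc1 * self.loadings[:, 0] + pc2 * self.loadings[:, 1]
        return pd.Series(v, index=self.trait_names)

    def scores_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.scores], axis=1)
        out.index.name = "specimen_id"
        out.to_csv(path)

    def loadings_csv(self, path: str | Path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        pd.DataFrame(self.loadings, index=self.trait_names, columns=cols).to_csv(path)


@dataclass
class TheoreticalGrid:
    """Evenly spaced lattice of theoretical morphologies in the PC1-PC2 plane."""

    grid_shape: tuple[int, int]  # (ncols along PC1, nrows along PC2)
    pc_scores: np.ndarray  # points x 2
    reconstructed_traits: pd.DataFrame  # points x traits

    @property
    def n_points(self) -> int:
        return self.pc_scores.shape[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.reconstructed_traits.copy()
        out.insert(0, "pc2", self.pc_scores[:, 1])
        out.insert(0, "pc1", self.pc_scores[:, 0])
        out.to_csv(path, index=False)


def fit_pca(data: SizeCorrectedTable) -> Morphospace:
    """Eigendecompose the sample covariance of the size-corrected matrix.

    Components are ordered by descending eigenvalue; each loading column is
    oriented so its largest-magnitude entry is positive, making fits
    deterministic. The number of retained components is min(n-1, p).
    """
    X = data.corrected.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValidationError(f"PCA needs >=3 specimens and >=2 traits, got {n}x{p}")
    means = X.mean(axis=0)
    Xc = X - means
    total_var = float((Xc**2).sum() / (n - 1))
    if total_var <= 0:
        raise DegeneracyError("all specimens identical: covariance matrix is zero")
    # SVD route: numerically stabler than forming the p x p covariance.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    k = min(n - 1, p)
    eigenvalues, loadings = eigenvalues[:k], Vt[:k].T
    # deterministic sign: largest-|.| entry of each column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    cols = [f"PC{i + 1}" for i in range(k)]
    return Morphospace(
        trait_names=list(data.corrected.columns),
        trait_means=means,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=pd.DataFrame(scores, index=data.corrected.index, columns=cols),
        prop_variance=eigenvalues / eigenvalues.sum(),
        meta=data.meta.copy(),
    )


def make_theoretical_grid(
    morphospace: Morphospace, ncols: int = 9, nrows: int = 7
) -> TheoreticalGrid:
    """Lattice of ncols x nrows theoretical species spanning the observed
    PC1/PC2 score range exactly (no padding), traits reconstructed per node.

    With a single column (or row) the lattice collapses to the midpoint of
    the corresponding axis range.
    """
    if ncols < 1 or nrows < 1:
        raise ValidationError("grid dimensions must be >= 1")
    if morphospace.n_components < 2:
        raise DegeneracyError("theoretical grid needs at least two components")
    s = morphospace.scores.to_numpy()
    lo1, hi1 = float(s[:, 0].min()), float(s[:, 0].max())
    lo2, hi2 = float(s[:, 1].min()), float(s[:, 1].max())
    xs = np.linspace(lo1, hi1, ncols) if ncols > 1 else np.array([(lo1 + hi1) / 2])
    ys = np.linspace(lo2, hi2, nrows) if nrows > 1 else np.array([(lo2 + hi2) / 2])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    recon = (
        morphospace.trait_means
        + pts[:, [0]] * morphospace.loadings[:, 0]
        + pts[:, [1]] * morphospace.loadings[:, 1]
    )
    traits = pd.DataFrame(recon, columns=morphospace.trait_names)
    return TheoreticalGrid(grid_shape=(ncols, nrows), pc_scores=pts, reconstructed_traits=traits)
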