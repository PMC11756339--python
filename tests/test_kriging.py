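import numpy as np
import pytest

from morphlands import (
    GridSpec,
    VariogramModel,
    empirical_semivariogram,
    fit_variogram,
    krige,
    normalize_surface,
)
from morphlands.errors import DegeneracyError, ValidationError
from morphlands.kriging import _structure


def dense_ok_solve(points, values, model, targets):
    """Independent ordinary-kriging oracle: explicit loops, one solve per node."""
    n = len(points)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                A[i, j] = model(np.linalg.norm(points[i] - points[j]))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    preds = []
    for t in np.atleast_2d(targets):
        b = np.empty(n + 1)
        for i in range(n):
            b[i] = model(np.linalg.norm(points[i] - t))
        b[n] = 1.0
        lam = np.linalg.solve(A, b)
        assert abs(lam[:n].sum() - 1.0) < 1e-8
        preds.append(float(lam[:n] @ values))
    return np.array(preds)


class TestEmpiricalSemivariogram:
    def test_constant_field_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (20, 2))
        lags, gammas, counts = empirical_semivariogram(pts, np.full(20, 3.0), n_lags=5)
        assert np.nanmax(gammas) == 0.0
        assert counts.sum() == 20 * 19 // 2

    def test_two_points_single_bin(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        lags, gammas, counts = empirical_semivariogram(pts, np.array([0.0, 2.0]), n_lags=1)
        assert gammas[0] == pytest.approx(2.0)  # 0.5 * (2)^2
        assert counts[0] == 1

    def test_iid_large_lag_sill(self):
        """For spatially independent values the semivariance plateaus at sigma^2."""
        rng = np.random.default_rng(42)
        sigma = 1.7
        pts = rng.uniform(0, 10, (400, 2))
        vals = rng.normal(0, sigma, 400)
        lags, gammas, counts = empirical_semivariogram(pts, vals, n_lags=8)
        heavy = counts > 1000
        assert np.allclose(gammas[heavy], sigma**2, rtol=0.15)

    def test_coincident_points_error(self):
        with pytest.raises(DegeneracyError):
            empirical_semivariogram(np.zeros((4, 2)), np.arange(4.0))


class TestFitVariogram:
    def test_generative_recovery_spherical(self):
        """Fields simulated from a known spherical model are recovered within 25%.

        The empirical semivariogram of a single Gaussian-field realization is
        noisy enough that the three families are barely distinguishable, so
        the oracle averages the binned semivariances over a few independent
        realizations at the same 400 sample locations before fitting.
        """
        rng = np.random.default_rng(3)
        true = VariogramModel("spherical", nugget=0.0, partial_sill=2.0, range_param=3.0)
        pts = rng.uniform(0, 10, (400, 2))
        from scipy.spatial.distance import squareform, pdist

        gamma = true(squareform(pdist(pts)))
        np.fill_diagonal(gamma, 0.0)
        sill = true.nugget + true.partial_sill
        cov = sill - gamma
        acc = np.zeros(15)
        for _ in range(6):
            vals = rng.multivariate_normal(np.zeros(400), cov, method="cholesky")
            lags, gammas, counts = empirical_semivariogram(pts, vals, n_lags=15)
            acc += gammas
        model = fit_variogram(lags, acc / 6, counts)
        assert model.family == "spherical"
        fitted_sill = model.nugget + model.partial_sill
        assert fitted_sill == pytest.approx(sill, rel=0.25)
        assert model.range_param == pytest.approx(true.range_param, rel=0.25)

    def test_flat_variogram_pure_nugget(self):
        lags = np.array([1.0, 2.0, 3.0, 4.0])
        gammas = np.full(4, 0.8)
        model = fit_variogram(lags, gammas, np.full(4, 50))
        assert model.nugget + model.partial_sill * 0 == pytest.approx(0.8, abs=0.05)
        assert model.partial_sill < 0.05

    def test_sse_beats_brute_force_grid(self):
        """The WLS optimum is at least as good as any coarse grid triple."""
        rng = np.random.default_rng(9)
        lags = np.linspace(0.5, 8, 12)
        gammas = 0.3 + 1.5 * _structure("exponential", lags, 3.0) + rng.normal(0, 0.05, 12)
        counts = np.full(12, 30.0)
        model = fit_variogram(lags, gammas, counts, families=["exponential"])
        w = np.sqrt(counts)
        best_grid = np.inf
        for c0 in np.linspace(0, 1, 6):
            for c in np.linspace(0.2, 3, 8):
                for a in np.linspace(0.5, 10, 10):
                    sse = np.sum((w * (c0 + c * _structure("exponential", lags, a) - gammas)) ** 2)
                    best_grid = min(best_grid, sse)
        assert model.fit_sse <= best_grid + 1e-9

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegeneracyError):
            fit_variogram(np.array([1.0, 2, 3]), np.zeros(3), np.full(3, 10))


class TestKrige:
    @pytest.fixture
    def lattice(self):
        xs = np.linspace(0, 1, 5)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    @pytest.fixture
    def model(self):
        return VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_param=0.8)

    def test_constant_field_reproduced(self, lattice, model, unit_grid):
        surf = krige(lattice, np.full(25, 4.2), model, unit_grid, normalize=False)
        assert np.allclose(surf.raw_values, 4.2, atol=1e-8)
        assert surf.max_weight_sum_error < 1e-8

    def test_exact_interpolation_zero_nugget(self, lattice, model):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 25)
        grid = GridSpec(0, 1, 0, 1, nx=5, ny=5)  # nodes coincide with samples
        surf = krige(lattice, vals, model, grid, normalize=False)
        assert np.allclose(surf.raw_values.ravel(), vals, atol=1e-8)

    def test_matches_dense_solve_oracle(self, lattice, model):
        """LU-based vectorized solve equals an independently coded dense solve."""
        rng = np.random.default_rng(2)
        vals = np.sin(3 * lattice[:, 0]) + rng.normal(0, 0.1, 25)
        grid = GridSpec(0, 1, 0, 1, nx=4, ny=3)
        surf = krige(lattice, vals, model, grid, normalize=False)
        oracle = dense_ok_solve(lattice, vals, model, grid.nodes())
        assert np.allclose(surf.raw_values.ravel(), oracle, atol=1e-8)

    def test_shift_invariance(self, lattice, model, unit_grid):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 25)
        s0 = krige(lattice, vals, model, unit_grid, normalize=False)
        s1 = krige(lattice, vals + 10.0, model, unit_grid, normalize=False)
        assert np.allclose(s1.raw_values, s0.raw_values + 10.0, atol=1e-8)

    def test_duplicate_points_averaged(self, model, unit_grid):
        pts = np.array([[0.2, 0.2], [0.2, 0.2], [0.8, 0.3], [0.4, 0.9]])
        vals = np.array([1.0, 3.0, 5.0, 7.0])
        surf = krige(pts, vals, model, unit_grid, normalize=False)
        dedup = krige(pts[1:], np.array([2.0, 5.0, 7.0]), model, unit_grid, normalize=False)
        assert np.allclose(surf.raw_values, dedup.raw_values)

    def test_monotone_proxy_yields_monotone_surface(self, lattice, model):
        """A smooth increasing function of PC1 krigs to rows increasing in PC1."""
        vals = 2.0 * lattice[:, 0] + 0.5
        grid = GridSpec(0, 1, 0, 1, nx=15, ny=7)
        surf = krige(lattice, vals, model, grid, normalize=False)
        assert (np.diff(surf.raw_values, axis=0) > -1e-6).all()


class TestNormalizeSurface:
    def test_basic(self):
        assert normalize_surface(np.array([2.0, 4.0, 6.0])).tolist() == [0.0, 0.5, 1.0]

    def test_affine_invariance_and_idempotence(self):
        rng = np.random.default_rng(6)
        raw = rng.normal(size=(8, 8))
        norm = normalize_surface(raw)
        assert np.allclose(normalize_surface(3.5 * raw + 2.0), norm)
        assert np.allclose(normalize_surface(norm), norm)
        assert norm.min() == 0.0 and norm.max() == 1.0

    def test_constant_degenerate(self):
        with pytest.raises(DegeneracyError):
            normalize_surface(np.ones((4, 4)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            normalize_surface(np.array([1.0, np.nan]))
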