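"""Maximum-entropy reweighting: entropy, chi-square, the dual minimizer
against a brute-force simplex oracle, theta scanning, and the
phi_eff-based force-field-error conversion."""

import numpy as np
import pytest

import sasbme as sb
from sasbme.bme import _as_simplex
from sasbme.scattering import ScatteringCurve


def tiny_instance(rng, n=None, m=None):
    """Random small reweighting problem (frames x points)."""
    n = n or int(rng.integers(2, 5))
    m = m or int(rng.integers(1, 4))
    mat = rng.normal(0.0, 1.0, (n, m))
    q = np.linspace(0.01, 0.1, m)
    data = ScatteringCurve(
        q=q, I=rng.normal(0.0, 1.0, m), sigma=rng.uniform(0.5, 1.5, m)
    )
    w0 = rng.dirichlet(np.ones(n))
    return mat, data, w0


def objective_on_grid(theta, w0, mat, data, step):
    """Dense simplex grid search oracle: enumerate weight vectors at the
    given resolution and return (best L, best w)."""
    n = len(w0)
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if n == 2:
        w1 = ticks
        grid = np.column_stack([1.0 - w1, w1])
    elif n == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        keep = a + b <= 1.0 + 1e-12
        grid = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    else:
        a, b, c = np.meshgrid(ticks, ticks, ticks, indexing="ij")
        keep = a + b + c <= 1.0 + 1e-12
        grid = np.column_stack(
            [a[keep], b[keep], c[keep], 1.0 - a[keep] - b[keep] - c[keep]]
        )
    grid = np.clip(grid, 0.0, 1.0)
    res = (grid @ mat - data.I) / data.sigma
    chi2 = (res**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(grid > 0, np.log(np.where(grid > 0, grid, 1.0) / w0), 0.0)
    entropy = -(grid * logs).sum(axis=1)
    L = chi2 / 2 - theta * entropy
    best = int(np.argmin(L))
    return float(L[best]), grid[best]


def snap_to_grid(w, step):
    """Nearest simplex grid point (coordinates multiples of step)."""
    snapped = np.round(np.asarray(w) / step) * step
    snapped = np.clip(snapped, 0.0, 1.0)
    deficit = round((1.0 - snapped.sum()) / step)
    # distribute the rounding deficit one tick at a time, largest coords first
    order = np.argsort(-snapped)
    tick = step if deficit > 0 else -step
    for k in range(abs(int(deficit))):
        i = order[k % len(order)]
        snapped[i] = np.clip(snapped[i] + tick, 0.0, 1.0)
    return snapped


def L_of(theta, w, w0, mat, data):
    chi2 = sb.chi2_of_weights(w, mat, data)
    return chi2 / 2 - theta * sb.relative_entropy(w, w0)


class TestRelativeEntropy:
    def test_identical_measures_zero(self):
        w = np.array([0.2, 0.3, 0.5])
        assert sb.relative_entropy(w, w) == 0.0

    def test_single_frame_collapse(self):
        s = sb.relative_entropy(np.array([1.0, 0, 0]), np.full(3, 1 / 3))
        assert s == pytest.approx(-np.log(3), abs=1e-12)
        assert sb.phi_eff(s) == pytest.approx(1 / 3, abs=1e-12)

    def test_support_violation_rejected(self):
        with pytest.raises(ValueError, match="support"):
            sb.relative_entropy(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    def test_entropy_nonpositive_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            assert sb.relative_entropy(rng.dirichlet(np.ones(n)),
                                       rng.dirichlet(np.ones(n))) <= 1e-12


class TestChi2OfWeights:
    def test_single_residual(self):
        data = ScatteringCurve(q=np.array([0.1]), I=np.array([1.0]), sigma=np.array([1.0]))
        assert sb.chi2_of_weights(np.array([1.0]), np.array([[2.0]]), data) == 1.0

    def test_delta_weights_give_single_frame_chi2(self):
        rng = np.random.default_rng(1)
        mat, data, _ = tiny_instance(rng, n=3, m=3)
        w = np.array([0.0, 1.0, 0.0])
        expected = float(np.sum(((mat[1] - data.I) / data.sigma) ** 2))
        assert sb.chi2_of_weights(w, mat, data) == pytest.approx(expected)

    def test_average_hits_datum(self):
        data = ScatteringCurve(q=np.array([0.1]), I=np.array([1.0]), sigma=np.array([1.0]))
        mat = np.array([[0.0], [2.0]])
        assert sb.chi2_of_weights(np.array([0.5, 0.5]), mat, data) == 0.0

    def test_multi_dataset_additivity(self):
        rng = np.random.default_rng(2)
        mat1, data1, w0 = tiny_instance(rng, n=3, m=3)
        mat2, data2, _ = tiny_instance(rng, n=3, m=2)
        combined = sb.chi2_of_weights(w0, [mat1, mat2], [data1, data2])
        assert combined == pytest.approx(
            sb.chi2_of_weights(w0, mat1, data1) + sb.chi2_of_weights(w0, mat2, data2)
        )


class TestBMEMinimize:
    def test_entropy_dominated_limit_returns_prior(self):
        rng = np.random.default_rng(3)
        mat, data, w0 = tiny_instance(rng, n=4, m=3)
        r = sb.bme_minimize(1e9, w0, mat, data, K=0)
        assert np.max(np.abs(r.weights - w0)) < 1e-6

    def test_two_frame_oracle(self):
        data = ScatteringCurve(q=np.array([0.1]), I=np.array([0.5]), sigma=np.array([1.0]))
        mat = np.array([[0.0], [2.0]])
        w0 = np.array([0.5, 0.5])
        r = sb.bme_minimize(1.0, w0, mat, data, K=0)
        _, w_grid = objective_on_grid(1.0, w0, mat, data, step=1e-5)
        assert np.max(np.abs(r.weights - w_grid)) < 1e-4

    def test_matches_grid_search_on_random_instances(self):
        """The dual solver attains the simplex minimum of L on 50 random
        tiny problems, within the grid's discretization bound.  The bound
        is exact: snapping the solver optimum onto the grid gives a grid
        point whose L the grid minimum cannot exceed, so L_grid - L_solver
        is at most the snapping penalty."""
        rng = np.random.default_rng(4)
        steps = {2: 1e-3, 3: 1e-3, 4: 5e-3}
        for _ in range(50):
            mat, data, w0 = tiny_instance(rng)
            theta = float(10 ** rng.uniform(-1, 2))
            r = sb.bme_minimize(theta, w0, mat, data, K=0)
            step = steps[len(w0)]
            L_solver = L_of(theta, r.weights, w0, mat, data)
            L_grid, _ = objective_on_grid(theta, w0, mat, data, step)
            assert L_solver <= L_grid + 1e-9        # never worse than the grid
            w_snap = snap_to_grid(r.weights, step)
            L_snap = L_of(theta, w_snap, w0, mat, data)
            assert L_grid - L_solver <= (L_snap - L_solver) + 1e-9

    def test_result_internal_consistency(self):
        rng = np.random.default_rng(5)
        mat, data, w0 = tiny_instance(rng, n=4, m=3)
        r = sb.bme_minimize(5.0, w0, mat, data, K=0)
        assert sb.chi2_of_weights(r.weights, mat, data) == pytest.approx(r.chi2, abs=1e-8)
        assert np.exp(r.S) == pytest.approx(r.phi_eff, abs=1e-10)
        assert r.S <= 1e-12

    def test_perfect_prior_keeps_high_phi_eff(self):
        """When the prior average already fits the data, reweighting at
        moderate theta leaves essentially all frames in play."""
        rng = np.random.default_rng(6)
        mat = rng.normal(0.0, 1.0, (20, 5))
        w0 = np.full(20, 0.05)
        q = np.linspace(0.01, 0.05, 5)
        data = ScatteringCurve(q=q, I=w0 @ mat, sigma=np.full(5, 1.0))
        r = sb.bme_minimize(100.0, w0, mat, data, K=0)
        assert r.phi_eff > 0.99

    def test_invalid_theta_rejected(self):
        rng = np.random.default_rng(7)
        mat, data, w0 = tiny_instance(rng, n=3, m=2)
        with pytest.raises(ValueError):
            sb.bme_minimize(0.0, w0, mat, data)


class TestThetaScan:
    def test_path_monotonicity(self):
        """Along a decreasing theta grid, chi2_r never increases and
        phi_eff never increases (regularization-path monotonicity),
        across 20 random instances."""
        rng = np.random.default_rng(8)
        grid = np.logspace(3, -1, 12)
        for _ in range(20):
            mat, data, w0 = tiny_instance(rng, n=4, m=3)
            scan = sb.theta_scan(grid, w0, mat, data, K=0)
            chi2_r = scan.table["chi2_r"].to_numpy()
            phi = scan.table["phi_eff"].to_numpy()
            assert np.all(np.diff(chi2_r) <= 1e-8)
            assert np.all(np.diff(phi) <= 1e-8)

    def test_flat_curve_selects_largest_theta(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(0.0, 1.0, (10, 4))
        w0 = np.full(10, 0.1)
        q = np.linspace(0.01, 0.04, 4)
        data = ScatteringCurve(q=q, I=w0 @ mat, sigma=np.full(4, 2.0))
        scan = sb.theta_scan(np.logspace(4, 0, 10), w0, mat, data, K=0)
        assert scan.theta_selected == scan.table["theta"].iloc[0]
        assert scan.selection_method.startswith("flat")

    def test_recovery_fixture_reaches_good_fit(self, recovery_fixture):
        """On the known-truth weight-recovery problem the selected theta
        fits the data to chi2_r <= 1.2."""
        data, matrix, w0, _ = recovery_fixture
        scan = sb.theta_scan(sb.default_theta_grid(1.0, 1e5, 25), w0, matrix, data)
        assert scan.selected.chi2_r <= 1.2

    def test_grid_validation(self):
        rng = np.random.default_rng(10)
        mat, data, w0 = tiny_instance(rng, n=3, m=2)
        with pytest.raises(ValueError):
            sb.theta_scan(np.array([1.0, 10.0, 100.0]), w0, mat, data)  # increasing
        with pytest.raises(ValueError):
            sb.theta_scan(np.array([10.0, 1.0]), w0, mat, data)  # too short


class TestForceFieldError:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.004, 5.5), (0.56, 0.6), (0.36, 1.0)],
    )
    def test_printed_conversions(self, phi, expected):
        """-ln(phi_eff) reproduces the published kBT error estimates at
        the corresponding effective frame fractions."""
        assert round(sb.forcefield_error(phi), 1) == expected

    def test_identical_ensembles_zero(self):
        assert sb.forcefield_error(1.0) == 0.0

    @pytest.mark.parametrize("phi", [0.0, -0.1, 1.1])
    def test_domain_checked(self, phi):
        with pytest.raises(ValueError):
            sb.forcefield_error(phi)


def test_simplex_validation_helper():
    with pytest.raises(ValueError):
        _as_simplex(np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        _as_simplex(np.array([1.5, -0.5]))
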