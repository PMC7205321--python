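"""Forward model: Debye intensities, smearing, nuisance fits, p(r), Guinier."""

import numpy as np
import pytest

import sasbme as sb
from sasbme.scattering import (
    DegenerateFitError,
    GuinierError,
    ScatteringCurve,
    SmearingGridError,
)

Q = np.linspace(0.01, 0.5, 40)


def random_frame(rng, n=20, spread=15.0):
    return rng.normal(0.0, spread, (n, 3)), rng.normal(0.0, 1.0, n)


class TestDebye:
    def test_single_bead_flat_unity(self):
        c = sb.debye_curve(np.zeros((1, 3)), np.array([1.0]), Q)
        assert np.allclose(c.I, 1.0)

    def test_two_beads_forward_limit_is_total_contrast_squared(self):
        coords = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        c = sb.debye_curve(coords, np.array([1.0, 1.0]), np.array([1e-6]))
        assert c.I[0] == pytest.approx(4.0, rel=1e-6)

    def test_two_beads_at_qr_pi_leaves_self_terms(self):
        coords = np.array([[0.0, 0, 0], [np.pi, 0, 0]])
        c = sb.debye_curve(coords, np.array([1.0, 1.0]), np.array([1.0]))
        assert c.I[0] == pytest.approx(2.0, abs=1e-12)

    def test_q_zero_rejected(self):
        with pytest.raises(ValueError):
            sb.debye_curve(np.zeros((1, 3)), np.array([1.0]), np.array([0.0, 0.1]))

    def test_histogram_path_matches_reference(self):
        """Accelerated histogram Debye agrees with the O(n^2) sum to 1e-6
        relative on 50 random 20-bead frames with signed contrasts."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            coords, db = random_frame(rng)
            ref = sb.debye_curve(coords, db, Q).I
            fast = sb.debye_curve_hist(coords, db, Q).I
            scale = np.maximum(np.abs(ref), 1e-3 * np.abs(ref).max())
            assert np.max(np.abs(fast - ref) / scale) < 1e-6

    def test_forward_scattering_identity(self):
        rng = np.random.default_rng(3)
        coords, db = random_frame(rng)
        c = sb.debye_curve(coords, db, np.array([1e-7]))
        assert c.I[0] == pytest.approx(np.sum(db) ** 2, rel=1e-6)


class TestEnsembleAverage:
    def test_delta_weights_select_single_frame(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(5, len(Q)))
        w = np.zeros(5)
        w[0] = 1.0
        avg = sb.ensemble_average_curve(mat, w, Q)
        assert np.array_equal(avg.I, mat[0])

    def test_identical_frames_idempotent(self):
        mat = np.tile(np.exp(-Q), (4, 1))
        avg = sb.ensemble_average_curve(mat, np.full(4, 0.25), Q)
        assert np.allclose(avg.I, mat[0])

    def test_convex_combination_bounded_by_frames(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(8, len(Q)))
        w = rng.dirichlet(np.ones(8))
        avg = sb.ensemble_average_curve(mat, w, Q)
        assert np.all(avg.I <= mat.max(axis=0) + 1e-12)
        assert np.all(avg.I >= mat.min(axis=0) - 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sb.ensemble_average_curve(np.ones((3, len(Q))), np.full(4, 0.25), Q)


class TestSmearing:
    def setup_method(self):
        self.q = np.linspace(0.01, 0.4, 400)

    def test_zero_width_is_identity(self):
        model = ScatteringCurve(q=self.q, I=np.exp(-self.q**2 * 100))
        out = sb.smear_curve(model, 0.0)
        assert np.array_equal(out.I, model.I)

    def test_constant_curve_unchanged(self):
        model = ScatteringCurve(q=self.q, I=np.full_like(self.q, 3.7))
        out = sb.smear_curve(model, 0.01)
        assert np.allclose(out.I, 3.7, rtol=1e-12)

    def test_linear_curve_unchanged_in_interior(self):
        """A symmetric kernel has zero first moment, so linear curves
        pass through smearing untouched away from the grid edges."""
        model = ScatteringCurve(q=self.q, I=5.0 * self.q + 0.2)
        out = sb.smear_curve(model, 0.005)
        interior = (self.q > 0.05) & (self.q < 0.35)
        assert np.allclose(out.I[interior], model.I[interior], rtol=1e-8)

    def test_under_resolved_grid_names_offending_point(self):
        coarse = np.linspace(0.01, 0.4, 10)
        model = ScatteringCurve(q=coarse, I=np.ones_like(coarse))
        with pytest.raises(SmearingGridError, match="q ="):
            sb.smear_curve(model, 0.005)

    def test_smearing_broadens_a_peak(self):
        peak = np.exp(-((self.q - 0.2) ** 2) / (2 * 0.005**2))
        model = ScatteringCurve(q=self.q, I=peak)
        out = sb.smear_curve(model, 0.01)
        assert out.I.max() < peak.max() * 0.6


class TestNuisanceFits:
    def test_exact_scale_background_recovery(self):
        model = ScatteringCurve(q=Q, I=np.exp(-Q * 5))
        data = ScatteringCurve(q=Q, I=2.0 * model.I + 3.0, sigma=np.full_like(Q, 0.1))
        p = sb.fit_scale_background(model, data)
        assert p.scale == pytest.approx(2.0, abs=1e-10)
        assert p.background == pytest.approx(3.0, abs=1e-10)

    def test_identity_fit(self):
        model = ScatteringCurve(q=Q, I=np.exp(-Q * 5) + 0.1)
        data = ScatteringCurve(q=Q, I=model.I.copy(), sigma=np.full_like(Q, 0.1))
        p = sb.fit_scale_background(model, data)
        assert p.scale == pytest.approx(1.0, abs=1e-10)
        assert p.background == pytest.approx(0.0, abs=1e-10)

    def test_constant_model_degenerate(self):
        model = ScatteringCurve(q=Q, I=np.full_like(Q, 2.0))
        data = ScatteringCurve(q=Q, I=np.full_like(Q, 5.0), sigma=np.full_like(Q, 0.1))
        with pytest.raises(DegenerateFitError):
            sb.fit_scale_background(model, data)

    def test_wls_unbiased_under_noise(self):
        """Mean fitted scale over 500 noisy replicates sits within three
        standard errors of the generating value."""
        rng = np.random.default_rng(5)
        base = np.exp(-Q * 4)
        sigma = np.full_like(Q, 0.05)
        model = ScatteringCurve(q=Q, I=base)
        scales = np.empty(500)
        for k in range(500):
            noisy = 1.7 * base + 0.4 + rng.normal(0, 1, len(Q)) * sigma
            scales[k] = sb.fit_scale_background(
                model, ScatteringCurve(q=Q, I=noisy, sigma=sigma)
            ).scale
        se = scales.std(ddof=1) / np.sqrt(len(scales))
        assert abs(scales.mean() - 1.7) < 3 * se


class TestChi2Reduced:
    def test_unit_residuals(self):
        q = np.linspace(0.01, 0.1, 10)
        sigma = np.full(10, 0.2)
        data = ScatteringCurve(q=q, I=np.ones(10), sigma=sigma)
        model = ScatteringCurve(q=q, I=np.ones(10) + sigma)
        assert sb.chi2_reduced(model, data, K=2) == pytest.approx(10 / 8)
        assert sb.chi2_reduced(model, data, K=4) == pytest.approx(10 / 6)

    def test_perfect_model_is_zero(self):
        q = np.linspace(0.01, 0.1, 10)
        data = ScatteringCurve(q=q, I=np.ones(10), sigma=np.full(10, 0.2))
        model = ScatteringCurve(q=q, I=np.ones(10))
        assert sb.chi2_reduced(model, data) == 0.0

    def test_too_few_points_rejected(self):
        q = np.array([0.01, 0.02])
        data = ScatteringCurve(q=q, I=np.ones(2), sigma=np.ones(2))
        with pytest.raises(ValueError):
            sb.chi2_reduced(data, data, K=2)


class TestPairDistribution:
    def test_opposite_contrasts_give_negative_peak(self):
        # separation on a bin center so the mass lands in a single bin
        coords = np.array([[0.0, 0, 0], [10.5, 0, 0]])
        pr = sb.pair_distribution(coords, np.array([1.0, -1.0]), bin_width=1.0)
        assert pr.p.sum() == pytest.approx(-2.0)
        assert pr.p.min() == pytest.approx(-2.0)

    def test_positive_contrasts_nonnegative(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 10, (15, 3))
        pr = sb.pair_distribution(coords, np.abs(rng.normal(1, 0.2, 15)))
        assert np.all(pr.p >= 0)

    def test_debye_pr_duality(self):
        """I(q) reconstructed from p(r) via sum p * sinc(q r) + self-term
        agrees with the direct Debye sum to 1% for sub-Angstrom bins."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            coords, db = random_frame(rng)
            pr = sb.pair_distribution(coords, db, bin_width=0.5)
            direct = sb.debye_curve(coords, db, Q).I
            recon = pr.self_term + (np.sinc(np.outer(Q, pr.r) / np.pi) @ pr.p)
            assert np.max(np.abs(recon - direct)) < 0.01 * np.abs(direct).max()

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            sb.pair_distribution(np.zeros((2, 3)), np.ones(2), bin_width=0.0)


class TestGuinier:
    def test_exact_guinier_curve(self):
        q = np.linspace(0.005, 0.2, 100)
        rg_true, i0_true = 25.0, 140.0
        data = ScatteringCurve(q=q, I=i0_true * np.exp(-(q**2) * rg_true**2 / 3))
        rg, i0 = sb.guinier_rg(data)
        assert rg == pytest.approx(rg_true, abs=0.1)
        assert i0 == pytest.approx(i0_true, rel=1e-3)

    def test_bead_sphere_matches_coordinate_rg(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(0, 1, (400, 3))
        coords = 20.0 * coords / np.linalg.norm(coords, axis=1, keepdims=True)
        coords *= rng.uniform(0, 1, (400, 1)) ** (1 / 3)
        db = np.ones(400)
        rg_coord = np.sqrt((np.sum((coords - coords.mean(0)) ** 2, axis=1)).mean())
        q = np.linspace(0.005, 0.1, 60)
        rg, _ = sb.guinier_rg(sb.debye_curve(coords, db, q))
        assert rg == pytest.approx(rg_coord, rel=0.03)

    def test_no_guinier_region_rejected(self):
        q = np.linspace(0.01, 0.1, 20)
        data = ScatteringCurve(q=q, I=1.0 + q)
        with pytest.raises(GuinierError):
            sb.guinier_rg(data)


class TestScatteringCurveValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"q": np.array([0.2, 0.1]), "I": np.ones(2)},
            {"q": np.array([0.0, 0.1]), "I": np.ones(2)},
            {"q": np.array([0.1, 0.2]), "I": np.ones(3)},
            {"q": np.array([0.1, 0.2]), "I": np.ones(2), "sigma": np.zeros(2)},
        ],
    )
    def test_invalid_curves_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScatteringCurve(**kwargs)
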