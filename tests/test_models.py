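"""Analytic models, transit-time maxima, and least-squares fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stedpcf.carpet_io import LineScanCarpet
from stedpcf.correlate import CorrelationCurve
from stedpcf.models import (
    DiffusionModelParams,
    PairModelParams,
    acf_3d,
    estimate_D_from_tau_max,
    fit_correlation,
    fit_sigmoid_profile,
    gaussian_fwhm,
    has_interior_maximum,
    locate_envelope,
    pair_ccf,
    tau_max_2d,
    tau_max_exact,
)

TAU_GRID = np.geomspace(1e-7, 10.0, 10_000)


class TestAcf3d:
    def test_zero_lag_amplitude_is_inverse_N(self):
        p = DiffusionModelParams(N=2.0, D=8.5, w_xy=275, S=5)
        assert acf_3d(0.0, p) == pytest.approx(0.5)

    def test_half_amplitude_at_tau_D_for_large_S(self):
        p = DiffusionModelParams(N=2.0, D=8.5, w_xy=275, S=1e6)
        assert acf_3d(p.tau_D, p) == pytest.approx(0.25, rel=1e-6)

    def test_half_decay_matches_root_finder(self):
        """The lag where G drops to half its zero-lag value agrees with an
        independent root finder applied to the closed form."""
        from scipy.optimize import brentq
        p = DiffusionModelParams(N=2.0, D=20.0, w_xy=110, S=10)
        target = 0.5 * acf_3d(0.0, p)
        root = brentq(lambda t: acf_3d(t, p) - target, 1e-9, 1.0)
        grid = np.geomspace(1e-7, 1.0, 200_000)
        vals = acf_3d(grid, p)
        grid_root = grid[np.argmin(np.abs(vals - target))]
        assert grid_root == pytest.approx(root, rel=1e-3)

    @given(st.floats(0.1, 50), st.floats(50, 400), st.floats(1, 20),
           st.floats(0.5, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonically_decreasing(self, D, w, S, N):
        p = DiffusionModelParams(N=N, D=D, w_xy=w, S=S)
        vals = acf_3d(np.geomspace(1e-6, 1.0, 200), p)
        assert (np.diff(vals) < 0).all()

    def test_rejects_negative_lag_and_params(self):
        p = DiffusionModelParams(N=1, D=1, w_xy=100, S=5)
        with pytest.raises(ValueError):
            acf_3d(-1e-3, p)
        with pytest.raises(ValueError):
            DiffusionModelParams(N=0, D=1, w_xy=100, S=5)


class TestPairCcf:
    def test_reduces_to_acf_at_zero_displacement(self):
        pp = PairModelParams(N=1.5, D=8.5, w_xy=110, S=10, d=0.0)
        dp = DiffusionModelParams(N=1.5, D=8.5, w_xy=110, S=10)
        taus = np.geomspace(1e-6, 1.0, 500)
        np.testing.assert_array_equal(pair_ccf(taus, pp), acf_3d(taus, dp))

    def test_decays_to_zero_at_long_lag(self):
        pp = PairModelParams(N=1.5, D=8.5, w_xy=110, S=10, d=200)
        assert pair_ccf(1e4, pp) < 1e-6

    def test_bell_shape_when_displacement_resolved(self):
        pp = PairModelParams(N=1.0, D=5.0, w_xy=110, S=10, d=200)
        vals = pair_ccf(TAU_GRID, pp)
        i = np.argmax(vals)
        assert 0 < i < TAU_GRID.size - 1  # interior maximum


class TestTauMax:
    def test_maximization_property_on_grid(self):
        pp = PairModelParams(N=1.0, D=5.0, w_xy=110, S=10, d=200)
        tm = tau_max_exact(pp)
        assert pair_ccf(tm, pp) >= pair_ccf(TAU_GRID, pp).max() - 1e-15

    def test_grid_argmax_matches_closed_form(self):
        pp = PairModelParams(N=1.0, D=5.0, w_xy=110, S=10, d=200)
        tm_grid = TAU_GRID[np.argmax(pair_ccf(TAU_GRID, pp))]
        assert tm_grid == pytest.approx(tau_max_exact(pp), rel=2e-3)

    def test_large_S_limit_converges_to_2d_form(self):
        for S, tol in [(100.0, 1e-2), (1000.0, 1e-3)]:
            pp = PairModelParams(N=1.0, D=5.0, w_xy=110, S=S, d=300)
            assert tau_max_exact(pp) == pytest.approx(tau_max_2d(pp), rel=tol)

    def test_doubling_D_halves_tau_m(self):
        p1 = PairModelParams(N=1.0, D=5.0, w_xy=110, S=10, d=200)
        p2 = PairModelParams(N=1.0, D=10.0, w_xy=110, S=10, d=200)
        assert tau_max_exact(p1) == pytest.approx(2 * tau_max_exact(p2), rel=1e-12)
        assert tau_max_2d(p1) == pytest.approx(2 * tau_max_2d(p2), rel=1e-12)

    def test_scale_invariance_of_tau_m(self):
        """Scaling d, w by k and D by k² leaves the maximum lag unchanged."""
        k = 3.0
        p1 = PairModelParams(N=1.0, D=5.0, w_xy=110, S=10, d=300)
        p2 = PairModelParams(N=1.0, D=5.0 * k**2, w_xy=110 * k, S=10, d=300 * k)
        assert tau_max_exact(p1) == pytest.approx(tau_max_exact(p2), rel=1e-12)

    def test_2d_form_approaches_pure_transit_when_w_small(self):
        pp = PairModelParams(N=1.0, D=5.0, w_xy=20, S=10, d=400)
        pure = (0.4**2) / (4 * 5.0)
        assert tau_max_2d(pp) == pytest.approx(pure, rel=0.01)

    def test_no_interior_maximum_raises(self):
        with pytest.raises(ValueError):
            tau_max_exact(PairModelParams(N=1, D=5, w_xy=110, S=10, d=0))
        # d within the PSF: sigmoidal regime
        with pytest.raises(ValueError):
            tau_max_exact(PairModelParams(N=1, D=5, w_xy=275, S=10, d=150))
        with pytest.raises(ValueError):
            tau_max_2d(PairModelParams(N=1, D=5, w_xy=275, S=10, d=150))

    def test_shape_taxonomy_of_three_pixel_distance(self):
        """A 150 nm displacement (3 pixels) is resolved by a 106 nm PSF
        (bell curve) but not by a 275 nm PSF (maximum at shortest lag)."""
        assert has_interior_maximum(
            PairModelParams(N=1, D=8.5, w_xy=106, S=10, d=150))
        assert not has_interior_maximum(
            PairModelParams(N=1, D=8.5, w_xy=275, S=10, d=150))


class TestEstimateD:
    def test_fast_pool_worked_example(self):
        # tau_m = 0.6 ms at d = 200 nm -> ~16.7 um^2/s
        assert estimate_D_from_tau_max(0.6e-3, 200.0) == pytest.approx(
            16.67, abs=0.01)

    def test_slow_pool_worked_example(self):
        assert estimate_D_from_tau_max(2.3e-3, 200.0) == pytest.approx(
            4.35, abs=0.01)

    def test_self_inverse(self):
        D = 10.0
        tau = (0.2**2) / (4 * D)
        assert estimate_D_from_tau_max(tau, 200.0) == pytest.approx(D, rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            estimate_D_from_tau_max(0.0, 200.0)
        with pytest.raises(ValueError):
            estimate_D_from_tau_max(1e-3, -5.0)

    def test_approximation_bias_vs_2d_form(self):
        """Neglecting the PSF size overestimates D by exactly the factor
        1/(1 − (w/d)²): within 10% only for w/d ≲ 0.3, and +43% in the
        w = 110 nm, d = 200 nm regime (where the estimate is read as a
        *local, apparent* diffusion coefficient)."""
        for w, d in [(110, 200), (110, 400), (60, 200), (100, 350)]:
            pp = PairModelParams(N=1, D=7.0, w_xy=w, S=10, d=d)
            tm = tau_max_2d(pp)
            D_est = estimate_D_from_tau_max(tm, d)
            expected_factor = 1.0 / (1.0 - (w / d) ** 2)
            assert D_est / 7.0 == pytest.approx(expected_factor, rel=1e-12)
            if (w / d) ** 2 <= 0.09:
                assert abs(D_est - 7.0) / 7.0 <= 0.10


class TestFitCorrelation:
    @staticmethod
    def synth_curve(params, model="acf_3d", n=80):
        lags = np.geomspace(1.25e-4, 0.5, n)
        vals = (acf_3d(lags, params) if model == "acf_3d"
                else pair_ccf(lags, params))
        return CorrelationCurve(lags=lags, values=vals)

    def test_mode_i_self_inversion(self):
        p = DiffusionModelParams(N=2.0, D=8.5, w_xy=275, S=5)
        r = fit_correlation(self.synth_curve(p), "acf_3d", free=("D", "N"),
                            fixed={"w_xy": 275, "S": 5})
        assert r.converged
        assert r.params["D"] == pytest.approx(8.5, rel=1e-6)
        assert r.params["N"] == pytest.approx(2.0, rel=1e-6)
        assert r.params["w_xy"] == 275  # fixed returned unchanged
        assert set(r.stderr) == {"D", "N"}

    def test_mode_ii_self_inversion(self):
        p = DiffusionModelParams(N=1.2, D=20.0, w_xy=110, S=10)
        r = fit_correlation(self.synth_curve(p), "acf_3d", free=("w_xy", "N"),
                            fixed={"D": 20.0, "S": 10})
        assert r.params["w_xy"] == pytest.approx(110, rel=1e-6)

    def test_mode_iii_pair_model_self_inversion(self):
        p = PairModelParams(N=1.2, D=8.5, w_xy=106, S=10, d=150)
        r = fit_correlation(self.synth_curve(p, "pair_ccf"), "pair_ccf",
                            free=("w_xy", "N"),
                            fixed={"D": 8.5, "S": 10, "d": 150})
        assert r.params["w_xy"] == pytest.approx(106, rel=1e-5)

    def test_unassigned_parameter_raises(self):
        p = DiffusionModelParams(N=2.0, D=8.5, w_xy=275, S=5)
        with pytest.raises(ValueError, match="neither free nor fixed"):
            fit_correlation(self.synth_curve(p), "acf_3d", free=("D",),
                            fixed={"w_xy": 275})

    def test_degenerate_all_zero_curve_raises(self):
        curve = CorrelationCurve(lags=np.geomspace(1e-4, 1, 50),
                                 values=np.zeros(50))
        with pytest.raises(ValueError, match="degenerate"):
            fit_correlation(curve, "acf_3d", free=("D", "N"),
                            fixed={"w_xy": 275, "S": 5})

    def test_too_few_points_raises(self):
        p = DiffusionModelParams(N=2.0, D=8.5, w_xy=275, S=5)
        with pytest.raises(ValueError, match="points"):
            fit_correlation(self.synth_curve(p, n=3), "acf_3d",
                            free=("D", "N"), fixed={"w_xy": 275, "S": 5})


class TestSigmoidFit:
    def test_noiseless_self_inversion(self):
        x = np.arange(64, dtype=float)
        profile = 100.0 + 400.0 / (1.0 + np.exp(-(x - 32.0) / 1.5))
        fit = fit_sigmoid_profile(profile)
        assert fit.A == pytest.approx(100.0, rel=1e-6)
        assert fit.B == pytest.approx(400.0, rel=1e-6)
        assert fit.x0 == pytest.approx(32.0, abs=1e-6)
        assert fit.x_width == pytest.approx(1.5, rel=1e-6)

    def test_poisson_noise_x0_recovery(self):
        """Sub-pixel midpoint recovery under shot noise: mean error over
        100 seeded replicates < 0.2 px at 400-count amplitude."""
        x = np.arange(64, dtype=float)
        truth = 100.0 + 400.0 / (1.0 + np.exp(-(x - 30.4) / 1.5))
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            noisy = rng.poisson(truth).astype(float)
            errs.append(fit_sigmoid_profile(noisy).x0 - 30.4)
        assert np.abs(np.mean(errs)) < 0.05
        assert np.abs(errs).mean() < 0.2

    def test_decreasing_profile_has_negative_amplitude(self):
        x = np.arange(64, dtype=float)
        profile = 500.0 - 400.0 / (1.0 + np.exp(-(x - 32.0) / 2.0))
        fit = fit_sigmoid_profile(profile)
        assert fit.B == pytest.approx(-400.0, rel=1e-5)
        assert fit.x0 == pytest.approx(32.0, abs=1e-5)
        assert fit.x_width > 0

    def test_short_profile_raises(self):
        with pytest.raises(ValueError):
            fit_sigmoid_profile(np.arange(5.0))


def interface_carpet(profile_fn, n_lines=2000, drift_px=0.0, seed=0):
    """Poisson carpet around a (possibly drifting) interface profile."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lines):
        shift = drift_px * i / (n_lines - 1)
        rows.append(rng.poisson(profile_fn(shift)))
    return LineScanCarpet(counts=np.array(rows, dtype=float),
                          line_period=0.125e-3, pixel_size=50e-9)


class TestLocateEnvelope:
    def test_recovers_step_position(self, interface_profiles):
        from tests.conftest import STED_PSF
        from scipy.special import erf

        base = interface_profiles(STED_PSF)

        def prof(shift):
            x = np.arange(64, dtype=float)
            sigma_px = STED_PSF.w_xy / 2.0 / 50.0
            return 100 + 300 * 0.5 * (1 + erf((x - 30.0 - shift) / (sigma_px * np.sqrt(2))))

        carpet = interface_carpet(prof, seed=1)
        summary = locate_envelope(carpet, bin_factor=20)
        assert summary.x0_mean == pytest.approx(30.0, abs=0.5)
        assert summary.n_converged >= 0.5 * summary.n_lines_fit

    def test_sted_interface_narrower_than_confocal(self, interface_profiles):
        from tests.conftest import CONFOCAL_PSF, STED_PSF
        widths = {}
        for name, psf in (("sted", STED_PSF), ("confocal", CONFOCAL_PSF)):
            prof = interface_profiles(psf)
            carpet = interface_carpet(lambda s, p=prof: p, seed=2)
            widths[name] = locate_envelope(carpet, 20).width_mean
        assert widths["sted"] < widths["confocal"]

    def test_drifting_interface_widens_x0_distribution(self, interface_profiles):
        from scipy.special import erf

        def prof(shift):
            x = np.arange(64, dtype=float)
            return 100 + 300 * 0.5 * (1 + erf((x - 30.0 - shift) / 1.5))

        still = locate_envelope(interface_carpet(prof, seed=3), 20)
        drifting = locate_envelope(
            interface_carpet(prof, drift_px=1.0, seed=3), 20)
        assert drifting.x0_sd > still.x0_sd
        assert drifting.x0_sd > 0.2  # ~sd of a uniform 1 px drift


class TestGaussianFwhm:
    def test_exact_gaussian_closed_form(self):
        x = np.linspace(-500, 500, 101)
        profile = 10 + 100 * np.exp(-(x**2) / (2 * 100.0**2))
        assert gaussian_fwhm(profile, x) == pytest.approx(235.48, abs=0.01)

    def test_sted_spot_narrower_than_confocal(self):
        from stedpcf.simulate import PSFModel, simulate_spot_image
        fwhms = {}
        for name, w in (("sted", 110.0), ("confocal", 275.0)):
            img = simulate_spot_image(PSFModel(w_xy=w, S=5), [(1000.0, 1000.0)],
                                      pixel_size=25.0, image_size=80)
            row = img[img.sum(axis=1).argmax()]
            x = (np.arange(80) + 0.5) * 25.0
            fwhms[name] = gaussian_fwhm(row, x)
        assert fwhms["sted"] < fwhms["confocal"]
        # FWHM = 2 sqrt(2 ln 2) * (w/2) ≈ 1.177 w
        assert fwhms["sted"] == pytest.approx(1.1774 * 110 / 2 * 2, rel=0.01)

    def test_two_peak_profile_rejected(self):
        x = np.linspace(-500, 500, 101)
        profile = (np.exp(-((x + 200) ** 2) / (2 * 60.0**2))
                   + np.exp(-((x - 200) ** 2) / (2 * 60.0**2)))
        with pytest.raises(ValueError, match="peaks"):
            gaussian_fwhm(profile, x)
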