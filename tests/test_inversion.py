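"""Tests of peak tracking, lattice/index fitting and the alignment ratio."""

import dataclasses

import numpy as np
import pytest

from colonyoptics import (
    ColonyOpticalParams,
    SpectralMap,
    alignment_ratio,
    fit_lattice_constant,
    fit_refractive_index,
    simulate_spectral_map,
    specular_shift,
    track_diffraction_peaks,
)
from colonyoptics.inversion import DiffractionPeakTrack, FitError
from colonyoptics.optics import detection_angle


def _constructed_map(intensity, wavelengths, angles, theta_illum=-60.0):
    intensity = np.asarray(intensity, float)
    dark = np.abs(np.asarray(angles) - theta_illum) <= 3.0
    intensity[:, dark] = 0.0
    return SpectralMap(
        wavelengths=wavelengths,
        angles=angles,
        intensity=intensity,
        theta_illum=theta_illum,
    )


class TestTracking:
    def test_noiseless_single_order_yields_one_exact_track(
        self, noiseless_single_order_map
    ):
        params, smap = noiseless_single_order_map
        tracks = track_diffraction_peaks(smap)
        assert len(tracks) >= 1
        main = tracks[0]
        # every tracked point obeys the grating equation with the true d
        for lam, theta, _ in main.points:
            pred = detection_angle(params.d, 1, lam, params.theta_illum)
            assert pred != "evanescent"
            assert abs(theta - pred) < 0.1

    def test_pure_noise_map_has_no_tracks(self, rng):
        wl = np.arange(400.0, 601.0, 1.0)
        ang = np.arange(-80.0, 81.0, 1.0)
        noise = rng.uniform(0.0, 1.0, size=(wl.size, ang.size))
        smap = _constructed_map(noise, wl, ang)
        with pytest.warns(UserWarning, match="no diffraction ridge"):
            tracks = track_diffraction_peaks(smap, rel_prominence=0.5)
        assert tracks == []

    def test_two_orders_two_tracks_with_correct_assignment(self):
        p = ColonyOpticalParams(
            d=460.0, noise_sd=0.0, aligned_fraction=1.0, orders=(1, 2)
        )
        smap = simulate_spectral_map(p)
        tracks = track_diffraction_peaks(smap)
        fit = fit_lattice_constant(tracks, theta_illum=p.theta_illum)
        assert set(fit.orders_used) == {1, 2}
        assert fit.d_hat == pytest.approx(460.0, abs=1.0)


class TestLatticeFit:
    @pytest.mark.parametrize("d_true", [395.0, 410.0, 425.0, 450.0, 460.0])
    def test_noiseless_roundtrip_recovers_d(self, d_true):
        """Generator-as-oracle: noiseless simulation inverts to < 1 nm."""
        p = ColonyOpticalParams(
            d=d_true,
            noise_sd=0.0,
            aligned_fraction=1.0,
            lambda_p=578.0 * d_true / 425.0,
        )
        smap = simulate_spectral_map(p)
        fit = fit_lattice_constant(
            track_diffraction_peaks(smap), theta_illum=p.theta_illum
        )
        assert fit.d_hat == pytest.approx(d_true, abs=1.0)
        assert fit.rms_residual_deg < 0.1

    def test_single_point_closed_form(self):
        # lambda / (sin(theta_m) + sin(theta_i)) for one point, m = 1
        lam, theta_det = 548.0, -25.05
        pts = np.array([[lam + i, 0.0, 1.0] for i in range(25)], dtype=float)
        for i in range(25):
            pred = detection_angle(425.0, 1, lam + i, -60.0)
            pts[i, 1] = pred
        track = DiffractionPeakTrack(points=pts)
        fit = fit_lattice_constant([track], theta_illum=-60.0)
        assert fit.d_hat == pytest.approx(425.0, abs=0.1)

    def test_intensity_rescaling_invariance(self, noisy_map):
        params, smap = noisy_map
        fit1 = fit_lattice_constant(
            track_diffraction_peaks(smap), theta_illum=params.theta_illum
        )
        scaled = SpectralMap(
            wavelengths=smap.wavelengths,
            angles=smap.angles,
            intensity=smap.intensity * 37.0,
            theta_illum=smap.theta_illum,
            dark_band_halfwidth=smap.dark_band_halfwidth,
            specular_window=smap.specular_window,
        )
        fit2 = fit_lattice_constant(
            track_diffraction_peaks(scaled), theta_illum=params.theta_illum
        )
        assert fit1.d_hat == pytest.approx(fit2.d_hat, abs=1e-9)

    def test_empty_tracks_raise(self):
        with pytest.raises(FitError):
            fit_lattice_constant([], theta_illum=-60.0)


class TestIndexFit:
    def test_noiseless_roundtrip(self):
        pts = [(th, specular_shift(578.0, 1.4, th)) for th in (15, 30, 45, 60, 75)]
        fit = fit_refractive_index(pts)
        assert fit.n_hat == pytest.approx(1.4, abs=1e-6)
        assert fit.lambda_p_hat == pytest.approx(578.0, abs=1e-3)
        assert not fit.at_upper_bound

    def test_flat_curve_pins_at_upper_bound(self):
        pts = [(th, 578.0) for th in (0, 20, 40, 60)]
        fit = fit_refractive_index(pts)
        assert fit.at_upper_bound
        assert fit.n_hat == pytest.approx(3.0, abs=1e-3)

    def test_noisy_recovery_within_published_band(self):
        """1% noise, 20 seeds: recovered index stays within 1.4 +/- 0.05."""
        n_hats = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = [
                (th, specular_shift(578.0, 1.4, th) * rng.normal(1.0, 0.01))
                for th in (15, 30, 45, 60, 75)
            ]
            n_hats.append(fit_refractive_index(pts).n_hat)
        assert np.mean(n_hats) == pytest.approx(1.4, abs=0.05)

    def test_insufficient_angular_range_rejected(self):
        with pytest.raises(FitError, match="span"):
            fit_refractive_index([(10, 570.0), (15, 565.0), (20, 560.0)])
        with pytest.raises(FitError):
            fit_refractive_index([(60, 450.0)])


class TestAlignmentRatio:
    def test_constructed_arithmetic(self):
        wl = np.arange(500.0, 601.0, 1.0)
        ang = np.arange(-80.0, 81.0, 1.0)
        intensity = np.full((wl.size, ang.size), 1e-4)
        i = int(np.argmin(np.abs(wl - 550.0)))
        j_main = int(np.argmin(np.abs(ang - (-30.0))))
        j_tilt = int(np.argmin(np.abs(ang - 25.0)))
        intensity[i, j_main] = 0.6
        intensity[i, j_tilt] = 0.06
        smap = _constructed_map(intensity, wl, ang)
        res = alignment_ratio(smap)
        assert res.ratio == pytest.approx(10.0)
        assert res.main_peak_angle == -30.0
        assert res.tilted_angle == 25.0
        assert not res.below_noise_floor

    def test_fully_aligned_noiseless_is_capped(self):
        p = ColonyOpticalParams(aligned_fraction=1.0, tilt_sigma=0.0, noise_sd=0.0)
        res = alignment_ratio(simulate_spectral_map(p))
        assert res.below_noise_floor

    def test_monotone_in_aligned_fraction(self):
        ratios = []
        for af in (0.95, 0.8, 0.6, 0.4):
            p = ColonyOpticalParams(aligned_fraction=af, noise_sd=0.02, seed=3)
            ratios.append(alignment_ratio(simulate_spectral_map(p)).ratio)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_window_outside_grid_rejected(self, noisy_map):
        _, smap = noisy_map
        with pytest.raises(ValueError):
            alignment_ratio(smap, window_center=-200.0)
        with pytest.raises(ValueError):
            alignment_ratio(smap, tilt_offset=300.0)
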