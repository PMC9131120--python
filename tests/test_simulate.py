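"""Tests of the synthetic-data generators against their design contracts."""

import numpy as np
import pytest

from colonyoptics import (
    ColonyOpticalParams,
    DomainImageParams,
    MorphometryParams,
    simulate_cell_profiles,
    simulate_domain_image,
    simulate_spectral_map,
)
from colonyoptics.optics import ridge_wavelength


class TestSpectralMap:
    def test_deterministic_given_seed(self):
        p = ColonyOpticalParams(seed=42)
        a = simulate_spectral_map(p)
        b = simulate_spectral_map(p)
        assert np.array_equal(a.intensity, b.intensity)
        c = simulate_spectral_map(ColonyOpticalParams(seed=43))
        assert not np.array_equal(a.intensity, c.intensity)

    def test_invariants(self, noisy_map):
        _, smap = noisy_map
        smap.validate()  # masks, grids, non-negativity
        assert np.all(smap.intensity[:, smap.dark_band_mask()] == 0)

    def test_ridge_satisfies_grating_equation_exactly(self, noiseless_single_order_map):
        """In every angle column the noiseless ridge crest sits at the
        wavelength solving the grating equation for that angle."""
        params, smap = noiseless_single_order_map
        checked = 0
        for j, ang in enumerate(smap.angles):
            if smap.dark_band_mask()[j] or smap.specular_mask()[j]:
                continue
            col = smap.intensity[:, j]
            if col.max() < 0.5:
                continue
            lam_star = ridge_wavelength(params.d, 1, ang, params.theta_illum)
            if not smap.wavelengths[2] < lam_star < smap.wavelengths[-3]:
                continue
            crest = smap.wavelengths[np.argmax(col)]
            assert abs(crest - lam_star) <= 0.5  # grid resolution
            checked += 1
        assert checked > 50

    def test_first_order_ridge_through_known_point(self):
        # d = 425 nm, illumination -60 deg: 548 nm diffracts to ~-25 deg
        p = ColonyOpticalParams(d=425.0, noise_sd=0.0, aligned_fraction=1.0, orders=(1,))
        smap = simulate_spectral_map(p)
        i = int(np.argmin(np.abs(smap.wavelengths - 548.0)))
        j = int(np.argmax(smap.intensity[i, ~smap.specular_mask()]))
        ang = smap.angles[~smap.specular_mask()][j]
        assert ang == pytest.approx(-25.0, abs=1.0)

    def test_no_tilted_intensity_when_fully_aligned(self):
        p = ColonyOpticalParams(
            d=425.0, noise_sd=0.0, aligned_fraction=1.0, tilt_sigma=0.0, orders=(1,)
        )
        smap = simulate_spectral_map(p)
        main_j = int(np.argmin(np.abs(smap.angles - (-30.0))))
        tilted_j = int(np.argmin(np.abs(smap.angles - 25.0)))
        main = smap.intensity[:, main_j].max()
        tilted = smap.intensity[:, tilted_j].max()
        assert tilted < 1e-3 * main

    def test_peak_positions_converge_under_grid_refinement(self):
        p = ColonyOpticalParams(d=425.0, noise_sd=0.0, aligned_fraction=1.0, orders=(1,))
        crests = []
        for step in (1.0, 0.25):
            wl = np.arange(360.0, 801.0, step)
            smap = simulate_spectral_map(p, wavelengths=wl)
            j = int(np.argmin(np.abs(smap.angles - (-30.0))))
            crests.append(wl[np.argmax(smap.intensity[:, j])])
        assert abs(crests[0] - crests[1]) <= 0.5

    def test_all_orders_evanescent_warns(self):
        p = ColonyOpticalParams(d=425.0, noise_sd=0.0, orders=(3,), aligned_fraction=1.0)
        wl = np.arange(700.0, 801.0, 1.0)
        with pytest.warns(UserWarning, match="specular"):
            smap = simulate_spectral_map(p, wavelengths=wl)
        # only the specular band (and its angular tails) remains
        outside = ~(smap.specular_mask() | smap.dark_band_mask())
        assert smap.intensity[:, outside].max() < 1e-3 * smap.intensity.max()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ColonyOpticalParams(aligned_fraction=1.2)
        with pytest.raises(ValueError):
            ColonyOpticalParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            ColonyOpticalParams(n_avg=0.8)


class TestCellProfiles:
    def test_zero_variation_gives_constant_diameters(self):
        p = MorphometryParams(
            n_cells=5, sd_diameter_between=0.0, sd_diameter_within=0.0, seed=0
        )
        for prof in simulate_cell_profiles(p):
            assert np.all(prof.diameters_nm == p.mean_diameter)

    def test_sampling_interval_and_count(self):
        p = MorphometryParams(n_cells=30, sd_length=0.0, mean_length=3.2, seed=2)
        for prof in simulate_cell_profiles(p):
            assert prof.spacing_nm == p.sampling_interval
            assert prof.n_samples >= 10  # 3.2 um at 300 nm -> 11 samples

    def test_mean_diameter_recovered_within_three_se(self):
        p = MorphometryParams(n_cells=40, seed=7)
        profiles = simulate_cell_profiles(p)
        means = [np.mean(prof.diameters_nm) for prof in profiles]
        se = p.sd_diameter_between / np.sqrt(p.n_cells)
        assert abs(np.mean(means) - p.mean_diameter) < 3.5 * se

    def test_deterministic(self):
        a = simulate_cell_profiles(MorphometryParams(seed=3))
        b = simulate_cell_profiles(MorphometryParams(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x.diameters_nm, y.diameters_nm)

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            MorphometryParams(mean_diameter=-5)
        with pytest.raises(ValueError):
            MorphometryParams(n_cells=0)


class TestDomainImage:
    def test_single_domain_is_pure_sinusoid(self):
        p = DomainImageParams(
            image_size=128,
            pixel_pitch=30.0,
            mean_domain_size=1e7,  # one domain fills the frame
            lattice_period=480.0,
            noise_sd=0.0,
            domain_contrast=0.0,
            seed=0,
        )
        img = simulate_domain_image(p)
        assert img.meta["n_domains"] == 1
        # a single off-centre conjugate pair dominates the 2-D spectrum
        # (spectral leakage from the random stripe orientation aside)
        f = np.fft.fft2(img.pixels - img.pixels.mean())
        power = np.abs(f) ** 2
        iy, ix = np.unravel_index(np.argmax(power), power.shape)
        assert (iy, ix) != (0, 0)
        fr = np.hypot(np.fft.fftfreq(128)[iy], np.fft.fftfreq(128)[ix])
        assert fr == pytest.approx(30.0 / 480.0, abs=1.5 / 128)
        top2 = np.sort(power.ravel())[-2:].sum()
        assert top2 > 0.5 * power.sum()

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            simulate_domain_image(
                DomainImageParams(pixel_pitch=30.0, lattice_period=50.0)
            )

    def test_deterministic(self):
        p = DomainImageParams(image_size=64 + 64, seed=9)
        assert np.array_equal(
            simulate_domain_image(p).pixels, simulate_domain_image(p).pixels
        )
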