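"""Tests of the image preprocessing and radial-PSD analysis."""

import math

import numpy as np
import pytest

from colonyoptics import (
    DomainImage,
    DomainImageParams,
    characteristic_scales,
    mean_radial_psd,
    preprocess,
    radial_psd,
    simulate_domain_image,
)


def _sinusoid(period_px=16, size=256, pitch=30.0):
    yy, xx = np.mgrid[0:size, 0:size]
    return DomainImage(0.5 + 0.45 * np.sin(2 * np.pi * xx / period_px), pitch)


class TestPreprocess:
    def test_clean_image_nearly_unchanged(self):
        img = _sinusoid()
        out = preprocess(img, denoise_strength=0.05)
        change = np.abs(out.pixels - img.pixels).mean() / np.ptp(img.pixels)
        assert change < 0.01

    def test_greyscale_conversion_identity_for_grey_input(self):
        img = _sinusoid()
        out = preprocess(img, denoise_strength=0.0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_rgb_collapses_to_luminance(self):
        grey = _sinusoid().pixels
        rgb = np.stack([grey] * 3, axis=-1)
        out = preprocess(DomainImage(rgb, 30.0), denoise_strength=0.0)
        assert out.channels == 1
        assert np.allclose(out.pixels, grey)

    def test_denoiser_reduces_variance(self, rng):
        clean = _sinusoid().pixels
        noisy = np.clip(clean + rng.normal(0, 0.08, clean.shape), 0, None)
        out = preprocess(DomainImage(noisy, 30.0), denoise_strength=0.08)
        assert out.pixels.var() < noisy.var()

    def test_non_finite_rejected(self):
        bad = _sinusoid().pixels.copy()
        with pytest.raises(ValueError):
            DomainImage(bad * np.inf, 30.0)


class TestRadialPSD:
    def test_sinusoid_peak_at_generating_frequency(self):
        psd = radial_psd(_sinusoid(period_px=16))
        f_peak = psd.frequencies[np.argmax(psd.power)]
        assert f_peak == pytest.approx(1 / 16, abs=1 / 256)

    def test_constant_image_has_no_power(self):
        psd = radial_psd(DomainImage(np.full((128, 128), 0.7), 30.0))
        assert psd.power.max() < 1e-20

    def test_generator_oracle_peak(self):
        # pure stripe scene: no domain-brightness mosaic competing at low f
        p = DomainImageParams(
            image_size=512,
            pixel_pitch=30.0,
            lattice_period=420.0,
            domain_contrast=0.0,
            seed=1,
        )
        psd = radial_psd(preprocess(simulate_domain_image(p), 0.0))
        f_peak = psd.frequencies[np.argmax(psd.power)]
        # the domain form factor broadens the lattice ring by a few bins
        assert f_peak == pytest.approx(30.0 / 420.0, abs=3 / 512)

    def test_rotation_invariance_90deg(self):
        img = simulate_domain_image(DomainImageParams(image_size=256, seed=3))
        a = radial_psd(DomainImage(img.pixels, 30.0))
        b = radial_psd(DomainImage(np.rot90(img.pixels).copy(), 30.0))
        assert np.allclose(a.power, b.power, rtol=1e-10)

    def test_parseval_total_power(self):
        img = _sinusoid()
        psd = radial_psd(img)
        total = float((psd.power * psd.n_pixels_per_bin).sum())
        from scipy.signal.windows import hann

        x = img.pixels - img.pixels.mean()
        w = np.outer(hann(256, sym=True), hann(256, sym=True))
        assert total == pytest.approx(float(((x * w) ** 2).mean()), rel=0.05)

    def test_requires_greyscale(self):
        rgb = np.stack([_sinusoid().pixels] * 3, axis=-1)
        with pytest.raises(ValueError):
            radial_psd(DomainImage(rgb, 30.0))


class TestCharacteristicScales:
    def test_single_domain_sinusoid(self):
        psd = radial_psd(_sinusoid(period_px=16, pitch=30.0))
        lattice, domain = characteristic_scales(psd)
        assert lattice == pytest.approx(16 * 30.0, rel=0.02)
        assert math.isnan(domain)  # no domain envelope in a pure carrier

    def test_domain_scale_monotone_in_domain_size(self):
        scales = {}
        for mds in (1500.0, 6000.0):
            vals = []
            for seed in range(5):
                p = DomainImageParams(
                    image_size=512,
                    pixel_pitch=50.0,
                    mean_domain_size=mds,
                    lattice_period=420.0,
                    orientation_jitter=20.0,
                    seed=seed,
                )
                psd = radial_psd(preprocess(simulate_domain_image(p), 0.0))
                vals.append(characteristic_scales(psd)[1])
            scales[mds] = np.mean(vals)
        assert scales[6000.0] > scales[1500.0]

    def test_unit_consistency_under_pixel_pitch_change(self):
        # the same physical scene sampled at half the resolution reports
        # the same physical scales
        results = []
        for pitch, size in ((25.0, 512), (50.0, 256)):
            p = DomainImageParams(
                image_size=size,
                pixel_pitch=pitch,
                mean_domain_size=3000.0,
                lattice_period=420.0,
                seed=7,
            )
            psd = radial_psd(preprocess(simulate_domain_image(p), 0.0))
            results.append(characteristic_scales(psd))
        (lat_a, dom_a), (lat_b, dom_b) = results
        assert lat_a == pytest.approx(lat_b, rel=0.05)
        assert dom_a == pytest.approx(dom_b, rel=0.35)

    def test_flat_psd_warns_and_returns_missing(self):
        psd = radial_psd(DomainImage(np.full((128, 128), 0.5), 30.0))
        with pytest.warns(UserWarning, match="no prominent peak"):
            lattice, domain = characteristic_scales(psd)
        assert math.isnan(lattice) and math.isnan(domain)


class TestBatchProtocol:
    def test_mean_psd_matches_peaks_of_identical_scenes(self):
        """Averaging PSDs of replicate images before peak-finding agrees
        with peak-finding on any one of them for identical scenes."""
        p = DomainImageParams(image_size=256, seed=4, noise_sd=0.0)
        img = simulate_domain_image(p)
        psds = [radial_psd(preprocess(img, 0.0)) for _ in range(3)]
        merged = mean_radial_psd(psds)
        lat_each = characteristic_scales(psds[0])[0]
        lat_mean = characteristic_scales(merged)[0]
        assert lat_mean == pytest.approx(lat_each, rel=1e-9)

    def test_batch_of_fifteen_replicates(self):
        """The measurement protocol averages 15 images per condition."""
        psds = []
        for seed in range(15):
            p = DomainImageParams(image_size=128, seed=seed)
            psds.append(radial_psd(preprocess(simulate_domain_image(p), 0.0)))
        merged = mean_radial_psd(psds)
        lattice, _ = characteristic_scales(merged)
        assert lattice == pytest.approx(420.0, rel=0.1)

    def test_mismatched_grids_rejected(self):
        a = radial_psd(_sinusoid(size=256))
        b = radial_psd(_sinusoid(size=128))
        with pytest.raises(ValueError):
            mean_radial_psd([a, b])
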