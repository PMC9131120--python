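"""Domain-structure image analysis by 2-D power spectral density.

Pipeline: non-local-means denoising, greyscale conversion, mean
subtraction, Hann windowing, 2-D FFT, squared modulus, azimuthal
average over unit-width annuli.  The radially averaged spectrum shows
the inter-cell lattice period as its highest-frequency prominent peak
and the crystalline-domain envelope as a low-frequency knee.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hann
from skimage.restoration import denoise_nl_means

from .datatypes import DomainImage

__all__ = ["RadialPSD", "preprocess", "radial_psd", "characteristic_scales", "mean_radial_psd"]

#: Rec. 709 luminance weights for RGB -> greyscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class RadialPSD:
    """Azimuthally averaged power spectral density.

    ``frequencies`` are annulus-centre spatial frequencies in cycles/px
    on ``(0, 0.5]``; ``power`` is the mean spectral power per annulus,
    normalized so that the total annulus-weighted power matches the
    variance of the windowed image (Parseval).
    """

    frequencies: np.ndarray
    power: np.ndarray
    n_pixels_per_bin: np.ndarray
    pixel_pitch_nm: float | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.n_pixels_per_bin = np.asarray(self.n_pixels_per_bin, dtype=int)
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if np.any(self.frequencies <= 0) or np.any(self.frequencies > 0.5 + 1e-12):
            raise ValueError("frequencies must lie in (0, 0.5] cycles/px")

    @property
    def frequencies_per_nm(self) -> np.ndarray:
        """Spatial frequencies in cycles/nm (requires a pixel pitch)."""
        if self.pixel_pitch_nm is None:
            raise ValueError("pixel pitch unknown")
        return self.frequencies / self.pixel_pitch_nm


def preprocess(image: DomainImage, denoise_strength: float = 0.05) -> DomainImage:
    """Denoise and convert to greyscale.

    Non-local-means denoising (patch size 7, search radius 10 px,
    filtering strength ``denoise_strength`` times the dynamic range)
    runs first, on all channels; RGB input is then collapsed to
    luminance with Rec. 709 weights.  Greyscale input passes through
    the conversion unchanged.  ``denoise_strength = 0`` skips the
    denoiser.
    """
    px = image.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite pixels")
    if denoise_strength > 0:
        span = float(px.max() - px.min()) or 1.0
        kwargs = dict(patch_size=7, patch_distance=10, h=denoise_strength * span, fast_mode=True)
        if px.ndim == 3:
            px = denoise_nl_means(px, channel_axis=-1, **kwargs)
        else:
            px = denoise_nl_means(px, **kwargs)
    if px.ndim == 3:
        px = px @ _LUMA
    return DomainImage(
        pixels=np.clip(px, 0.0, None),
        pixel_pitch_nm=image.pixel_pitch_nm,
        meta=dict(image.meta),
    )


def radial_psd(image: DomainImage) -> RadialPSD:
    """Azimuthally averaged 2-D power spectral density of a greyscale image.

    The image is mean-subtracted and tapered with a separable Hann
    window before the FFT; power is ``|F|^2 / N^2`` so that, by
    Parseval, the summed annulus totals equal the mean square of the
    windowed image.  Annuli are one frequency bin wide (bin width
    ``1/min(ny, nx)``) and the DC bin is excluded.
    """
    if image.channels != 1:
        raise ValueError("radial_psd expects a preprocessed greyscale image")
    px = image.pixels
    ny, nx = px.shape
    x = px - px.mean()
    # symmetric window: invariant under array flips, so quarter-turn
    # rotations of the image leave the radial PSD exactly unchanged
    w = np.outer(hann(ny, sym=True), hann(nx, sym=True))
    f = np.fft.fft2(x * w)
    power = np.abs(f) ** 2 / (nx * ny) ** 2

    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)

    bin_width = 1.0 / min(ny, nx)
    bins = np.rint(r / bin_width).astype(int)
    n_bins = int(math.floor(0.5 / bin_width + 1e-9))
    flat_bins = bins.ravel()
    flat_power = power.ravel()
    keep = (flat_bins >= 1) & (flat_bins <= n_bins)
    counts = np.bincount(flat_bins[keep], minlength=n_bins + 1)[1:]
    sums = np.bincount(flat_bins[keep], weights=flat_power[keep], minlength=n_bins + 1)[1:]
    nonempty = counts > 0
    freqs = (np.arange(1, n_bins + 1) * bin_width)[nonempty]
    mean_power = sums[nonempty] / counts[nonempty]
    return RadialPSD(
        frequencies=np.minimum(freqs, 0.5),
        power=mean_power,
        n_pixels_per_bin=counts[nonempty],
        pixel_pitch_nm=image.pixel_pitch_nm,
    )


def characteristic_scales(
    psd: RadialPSD,
    pixel_pitch_nm: float | None = None,
    rel_prominence: float = 0.02,
    knee_cutoff: float = 0.5,
    knee_floor: float = 1e-4,
) -> tuple[float, float]:
    """Lattice and domain length scales from a radial PSD.

    The lattice scale is the reciprocal of the highest-frequency peak
    whose prominence exceeds ``rel_prominence`` times the spectral
    maximum.  The domain scale is the reciprocal of the low-frequency
    knee — the maximum of ``f^2 * power`` at frequencies below
    ``knee_cutoff`` times the lattice frequency — and is reported as
    NaN when that weighted power never rises above ``knee_floor`` times
    its value at the lattice peak (no resolvable domain envelope, e.g.
    a single-domain scene).

    Returns ``(lattice_scale_nm, domain_scale_nm)``; scales are in
    pixels if no pixel pitch is known.
    """
    pitch = pixel_pitch_nm if pixel_pitch_nm is not None else psd.pixel_pitch_nm
    if pitch is None:
        pitch = 1.0  # report in pixels
    f, p = psd.frequencies, psd.power
    peaks, _ = find_peaks(p, prominence=rel_prominence * p.max())
    if peaks.size == 0:
        warnings.warn("no prominent peak in the radial PSD", stacklevel=2)
        return math.nan, math.nan
    i_lat = int(peaks.max())
    # refine the lattice frequency with a log-parabola through neighbours
    f_lat = f[i_lat]
    if 0 < i_lat < f.size - 1 and np.all(p[i_lat - 1 : i_lat + 2] > 0):
        lm, l0, lp = np.log(p[i_lat - 1 : i_lat + 2])
        denom = lm - 2 * l0 + lp
        if denom < 0:
            f_lat = f[i_lat] + np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5) * (
                f[1] - f[0]
            )
    lattice_scale = pitch / f_lat

    low = f < knee_cutoff * f_lat
    if not np.any(low):
        return float(lattice_scale), math.nan
    weighted = f[low] ** 2 * p[low]
    if weighted.max() < knee_floor * f_lat**2 * p[i_lat]:
        return float(lattice_scale), math.nan
    f_knee = f[low][int(np.argmax(weighted))]
    return float(lattice_scale), float(pitch / f_knee)


def mean_radial_psd(psds) -> RadialPSD:
    """Average radial PSDs over a batch of images of one condition
    (the published protocol averages 15 images per nutrient condition);
    all PSDs must share one frequency grid."""
    psds = list(psds)
    if not psds:
        raise ValueError("need at least one PSD")
    f0 = psds[0].frequencies
    for q in psds[1:]:
        if not np.array_equal(q.frequencies, f0):
            raise ValueError("PSDs must share a common frequency grid")
    power = np.mean([q.power for q in psds], axis=0)
    return RadialPSD(
        frequencies=f0,
        power=power,
        n_pixels_per_bin=psds[0].n_pixels_per_bin,
        pixel_pitch_nm=psds[0].pixel_pitch_nm,
    )
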