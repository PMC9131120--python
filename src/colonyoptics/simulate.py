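"""Synthetic goniometer maps, cell-diameter profiles and domain mosaics.

Every inverse analysis in this package is exercised against data from
these generators, which emulate the three measurement types of the
study — angular-resolved scattering maps, cryo-TEM width profiles and
optical-microscopy domain mosaics — with fully known ground truth.

The spectral forward model composes the two relations in
:mod:`colonyoptics.optics`.  The colony is a mixture of crystalline
domains: a fraction ``aligned_fraction`` lies parallel to the agar
surface (tilt 0) and the remainder is tilted, with tilt angles drawn
from a truncated Gaussian.  Each (order, tilt) component contributes a
Gaussian spectral ridge along its diffraction trajectory; the specular
reflection adds a strong band at ``-theta_illum`` centred on the
Snell-shifted peak wavelength.  Reflectance is strictly positive, so
measurement noise is modelled as multiplicative log-normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CellProfile, DomainImage, SpectralMap
from .optics import specular_shift

__all__ = [
    "ColonyOpticalParams",
    "MorphometryParams",
    "DomainImageParams",
    "simulate_spectral_map",
    "simulate_cell_profiles",
    "simulate_domain_image",
    "default_wavelengths",
    "default_angles",
]

#: Tilt-population discretization step (deg).
TILT_STEP = 1.0
#: Domains with |tilt| below this bound count as aligned (deg).
ALIGNED_TILT_BOUND = 2.0
#: Hard truncation of the tilted population (deg).
TILT_TRUNCATION = 60.0


def default_wavelengths() -> np.ndarray:
    """Visible-range wavelength grid, 360-800 nm at 1 nm."""
    return np.arange(360.0, 801.0, 1.0)


def default_angles() -> np.ndarray:
    """Detection-angle grid, -85 to +85 deg at 1 deg."""
    return np.arange(-85.0, 86.0, 1.0)


@dataclass(frozen=True)
class ColonyOpticalParams:
    """Ground truth for one simulated colony measurement.

    Parameters
    ----------
    d : float
        Lattice constant of the hexagonal packing (nm).
    n_avg : float
        Effective refractive index of the colony.
    lambda_p : float
        Normal-incidence specular peak wavelength (nm).
    theta_illum : float
        Illumination angle (deg, negative).
    aligned_fraction : float
        Fraction of domain volume aligned with the agar surface.
    tilt_sigma : float
        Standard deviation of the tilted sub-population (deg).
    orders : tuple of int
        Diffraction orders rendered; the second order matters in the
        UV/blue and is on by default.
    peak_width_lambda : float
        Spectral 1-sigma width of diffraction and specular features (nm).
    specular_gain : float
        Strength of the specular band relative to a unit-weight
        diffraction ridge (the display convention divides this window
        by 300 for the same reason).
    specular_width_deg : float
        Angular 1-sigma width of the specular band (deg).
    noise_sd : float
        Sigma of the multiplicative log-normal noise.
    seed : int
        RNG seed; equal seeds give bitwise-identical maps.
    """

    d: float = 425.0
    n_avg: float = 1.4
    lambda_p: float = 578.0
    theta_illum: float = -60.0
    aligned_fraction: float = 0.9
    tilt_sigma: float = 15.0
    orders: tuple[int, ...] = (1, 2)
    peak_width_lambda: float = 20.0
    specular_gain: float = 300.0
    specular_width_deg: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.lambda_p <= 0:
            raise ValueError("d and lambda_p must be positive")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must lie in [0, 1]")
        if self.tilt_sigma < 0 or self.noise_sd < 0:
            raise ValueError("tilt_sigma and noise_sd must be non-negative")
        if not -90.0 < self.theta_illum < 90.0:
            raise ValueError("theta_illum must lie in (-90, 90) deg")
        if self.peak_width_lambda <= 0:
            raise ValueError("peak_width_lambda must be positive")


def _tilt_population(aligned_fraction: float, tilt_sigma: float) -> list[tuple[float, float]]:
    """Discretized (tilt, weight) mixture of the domain orientation model.

    Aligned mass sits at tilt 0 with weight ``aligned_fraction``; the
    tilted pool is a Gaussian(0, tilt_sigma) on a 1-deg grid truncated
    to +/-60 deg, with near-aligned bins (|tilt| < 2 deg) excluded, and
    carries the remaining weight.
    """
    components = [(0.0, aligned_fraction)]
    tilted_weight = 1.0 - aligned_fraction
    if tilted_weight <= 0 or tilt_sigma <= 0:
        return components
    alphas = np.arange(-TILT_TRUNCATION, TILT_TRUNCATION + TILT_STEP / 2, TILT_STEP)
    alphas = alphas[np.abs(alphas) >= ALIGNED_TILT_BOUND]
    pdf = np.exp(-0.5 * (alphas / tilt_sigma) ** 2)
    if pdf.sum() == 0:
        return components
    weights = tilted_weight * pdf / pdf.sum()
    components.extend(zip(alphas.tolist(), weights.tolist()))
    return components


def simulate_spectral_map(
    params: ColonyOpticalParams,
    wavelengths: np.ndarray | None = None,
    angles: np.ndarray | None = None,
    dark_band_halfwidth: float = 3.0,
    specular_window_halfwidth: float = 8.0,
) -> SpectralMap:
    """Render a scattering-mode goniometer map with known ground truth.

    For every rendered order and tilt component the ridge is drawn so
    that, in each detection-angle column, the spectral Gaussian is
    centred on the wavelength that exactly satisfies the grating
    equation for that geometry — i.e. the noiseless ridge crest obeys
    the forward model to machine precision.

    Returns a :class:`SpectralMap` with the dark band masked and the
    specular window recorded (intensity kept physical, not rescaled).
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    ang = default_angles() if angles is None else np.asarray(angles, float)
    if wl.size == 0 or ang.size == 0:
        raise ValueError("wavelength and angle grids must be non-empty")

    p = params
    width = p.peak_width_lambda
    intensity = np.zeros((wl.size, ang.size))
    sin_ang = np.sin(np.radians(ang))
    rendered_any = False

    for m in p.orders:
        if m == 0:
            continue  # specular handled separately
        for alpha, weight in _tilt_population(p.aligned_fraction, p.tilt_sigma):
            if weight <= 0:
                continue
            # wavelength hitting each detection angle in this geometry
            lam_star = (
                p.d
                * (
                    np.sin(np.radians(alpha - p.theta_illum))
                    + np.sin(np.radians(alpha - ang))
                )
                / m
            )
            valid = (lam_star > wl[0] - 4 * width) & (lam_star < wl[-1] + 4 * width)
            valid &= lam_star > 0
            if not np.any(valid):
                continue
            rendered_any = True
            dl = wl[:, None] - lam_star[None, valid]
            intensity[:, valid] += weight * np.exp(-0.5 * (dl / width) ** 2)

    if not rendered_any and any(m != 0 for m in p.orders):
        warnings.warn(
            "no diffraction order propagates on the requested grids; "
            "map contains only the specular band",
            stacklevel=2,
        )

    # specular band at -theta_illum, Snell-shifted spectral profile
    lam_s = specular_shift(p.lambda_p, p.n_avg, abs(p.theta_illum))
    spec_angle = -p.theta_illum
    spectral = np.exp(-0.5 * ((wl - lam_s) / width) ** 2)
    angular = np.exp(-0.5 * ((ang - spec_angle) / p.specular_width_deg) ** 2)
    intensity += p.specular_gain * spectral[:, None] * angular[None, :]

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        intensity *= rng.lognormal(mean=0.0, sigma=p.noise_sd, size=intensity.shape)

    intensity[:, np.abs(ang - p.theta_illum) <= dark_band_halfwidth] = 0.0

    return SpectralMap(
        wavelengths=wl,
        angles=ang,
        intensity=intensity,
        theta_illum=p.theta_illum,
        dark_band_halfwidth=dark_band_halfwidth,
        specular_window=(
            spec_angle - specular_window_halfwidth,
            spec_angle + specular_window_halfwidth,
        ),
    )


@dataclass(frozen=True)
class MorphometryParams:
    """Ground truth for the synthetic cryo-TEM width-profile population.

    Diameters follow a two-level Gaussian model: each cell draws a
    baseline diameter (between-cell spread ``sd_diameter_between``) and
    each 300-nm width sample scatters around that baseline
    (``sd_diameter_within``).  Lengths are Gaussian, truncated so that
    every cell spans at least three sampling intervals.
    """

    n_cells: int = 40
    mean_diameter: float = 400.0
    sd_diameter_between: float = 20.0
    sd_diameter_within: float = 10.0
    mean_length: float = 3.4
    sd_length: float = 0.8
    sampling_interval: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("mean_diameter", "mean_length", "sampling_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sd_diameter_between", "sd_diameter_within", "sd_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Draw Normal(mean, sd) conditioned on being > lower, by resampling."""
    if sd == 0:
        if mean <= lower:
            raise ValueError("degenerate truncated normal below its bound")
        return np.full(size, mean) if size is not None else float(mean)
    n = int(np.prod(size)) if size is not None else 1
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[draw > lower]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out.reshape(size) if size is not None else float(out[0])


def simulate_cell_profiles(params: MorphometryParams) -> list[CellProfile]:
    """Generate diameter profiles for ``n_cells`` synthetic cells."""
    p = params
    rng = np.random.default_rng(p.seed)
    min_length_um = 3 * p.sampling_interval / 1000.0
    profiles: list[CellProfile] = []
    for i in range(p.n_cells):
        length_um = _truncated_normal(rng, p.mean_length, p.sd_length, min_length_um)
        n_samples = int(length_um * 1000.0 // p.sampling_interval) + 1
        baseline = _truncated_normal(rng, p.mean_diameter, p.sd_diameter_between, 0.0)
        diameters = _truncated_normal(
            rng, baseline, p.sd_diameter_within, 0.0, size=(n_samples,)
        )
        positions = np.arange(n_samples) * p.sampling_interval
        profiles.append(
            CellProfile(
                cell_id=f"cell_{i:03d}",
                positions_nm=positions,
                diameters_nm=diameters,
                length_um=length_um,
            )
        )
    return profiles


@dataclass(frozen=True)
class DomainImageParams:
    """Ground truth for the synthetic domain-mosaic image.

    The frame is partitioned into crystalline domains (Voronoi cells of
    Poisson-disk seed points with mean spacing ``mean_domain_size``);
    each domain carries a sinusoidal stripe pattern of period
    ``lattice_period`` at an orientation jittered domain-to-domain by
    ``orientation_jitter`` around a common direction.  Domains differ
    in mean brightness (``domain_contrast``), as differently oriented
    crystalline patches scatter differently under the microscope; this
    brightness mosaic is what carries the domain-size signal at low
    spatial frequency.
    """

    image_size: int = 512
    pixel_pitch: float = 30.0
    mean_domain_size: float = 3000.0
    lattice_period: float = 420.0
    orientation_jitter: float = 10.0
    domain_contrast: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 px")
        if self.pixel_pitch <= 0 or self.mean_domain_size <= 0:
            raise ValueError("pixel_pitch and mean_domain_size must be positive")
        if self.lattice_period <= 0:
            raise ValueError("lattice_period must be positive")
        if self.orientation_jitter < 0 or self.noise_sd < 0 or self.domain_contrast < 0:
            raise ValueError(
                "orientation_jitter, domain_contrast and noise_sd must be non-negative"
            )


def _poisson_disk_seeds(rng, size: int, spacing: float) -> np.ndarray:
    """Dart-throwing Poisson-disk sample with target mean spacing (px)."""
    min_dist = 0.65 * spacing
    target = max(1, int(round((size / spacing) ** 2)))
    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * target
    while len(points) < target and attempts < max_attempts:
        cand = rng.uniform(0, size, size=2)
        attempts += 1
        if all(np.hypot(*(cand - q)) >= min_dist for q in points):
            points.append(cand)
    if not points:  # pragma: no cover - cannot happen with max_attempts >= 1
        points.append(rng.uniform(0, size, size=2))
    return np.array(points)


def simulate_domain_image(params: DomainImageParams) -> DomainImage:
    """Render a domain-mosaic image with known lattice period and domain size."""
    p = params
    if p.lattice_period < 2 * p.pixel_pitch:
        raise ValueError(
            f"lattice_period {p.lattice_period} nm is below the Nyquist limit "
            f"2 * pixel_pitch = {2 * p.pixel_pitch} nm and would alias"
        )
    rng = np.random.default_rng(p.seed)
    spacing_px = p.mean_domain_size / p.pixel_pitch
    seeds = _poisson_disk_seeds(rng, p.image_size, spacing_px)

    base_orientation = rng.uniform(0.0, 180.0)
    orientations = np.radians(
        base_orientation + rng.normal(0.0, p.orientation_jitter, size=len(seeds))
    )
    phases = rng.uniform(0.0, 2 * np.pi, size=len(seeds))
    brightness = np.clip(
        0.5 + p.domain_contrast * rng.standard_normal(len(seeds)), 0.3, 0.7
    )

    yy, xx = np.mgrid[0 : p.image_size, 0 : p.image_size]
    coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    labels = cKDTree(seeds).query(coords, k=1)[1].reshape(yy.shape)

    period_px = p.lattice_period / p.pixel_pitch
    cos_t = np.cos(orientations)[labels]
    sin_t = np.sin(orientations)[labels]
    phase = phases[labels]
    stripe = np.sin(2 * np.pi * (xx * cos_t + yy * sin_t) / period_px + phase)
    img = brightness[labels] + 0.3 * stripe
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return DomainImage(
        pixels=img,
        pixel_pitch_nm=p.pixel_pitch,
        meta={"n_domains": len(seeds), "lattice_period_nm": p.lattice_period},
    )
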