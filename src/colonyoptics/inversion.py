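"""Inverse analyses of angular-resolved spectral maps.

Three quantities are recovered from a goniometer map of a structurally
coloured colony:

* the lattice constant ``d`` of the hexagonal cell packing, by tracking
  diffraction ridges and fitting them to the grating equation;
* the effective refractive index ``n_avg``, by fitting the Snell-shifted
  specular peak wavelength versus incidence angle;
* the aligned/tilted domain intensity ratio, the ordering proxy defined
  as the main diffraction-peak intensity in a -30 deg +/- 4 deg window
  divided by the intensity 55 deg away at the same wavelength.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import find_peaks

from .datatypes import SpectralMap

__all__ = [
    "DiffractionPeakTrack",
    "LatticeFit",
    "IndexFit",
    "AlignmentRatio",
    "FitError",
    "track_diffraction_peaks",
    "fit_lattice_constant",
    "fit_refractive_index",
    "alignment_ratio",
]

logger = logging.getLogger(__name__)

#: Intensity floor below which the tilted-domain signal counts as absent.
NOISE_FLOOR = 1e-6


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or fails to converge."""


@dataclass
class DiffractionPeakTrack:
    """One diffraction ridge extracted from a spectral map.

    ``points`` columns are wavelength (nm), detection angle (deg,
    sub-bin refined) and intensity; rows are sorted by wavelength.
    """

    points: np.ndarray
    order_hint: int | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (lambda, theta, I)")
        if np.any(np.diff(self.points[:, 0]) < 0):
            raise ValueError("points must be sorted by wavelength")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def angles(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class LatticeFit:
    """Grating-equation fit result."""

    d_hat: float
    orders_used: tuple[int, ...]
    rms_residual_deg: float
    n_points: int
    ci_halfwidth: float


@dataclass
class IndexFit:
    """Specular-shift fit result; ``at_upper_bound`` flags a flat curve."""

    n_hat: float
    lambda_p_hat: float
    rms_residual_nm: float
    at_upper_bound: bool = False


@dataclass
class AlignmentRatio:
    """Aligned/tilted domain intensity ratio (higher = more ordered)."""

    main_peak_angle: float
    main_peak_wavelength: float
    main_peak_intensity: float
    tilted_angle: float
    tilted_intensity: float
    ratio: float
    below_noise_floor: bool = False


def _parabolic_refine(values: np.ndarray, idx: int) -> float:
    """Sub-bin offset of a peak at ``idx`` from a log-parabola through
    its neighbours; Gaussian peaks are located exactly."""
    if idx == 0 or idx == values.size - 1:
        return 0.0
    triple = values[idx - 1 : idx + 2]
    if np.any(triple <= 0):
        return 0.0
    lm, l0, lp = np.log(triple)
    denom = lm - 2 * l0 + lp
    if denom >= 0:
        return 0.0
    delta = 0.5 * (lm - lp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def track_diffraction_peaks(
    smap: SpectralMap,
    exclude_specular: bool = True,
    rel_prominence: float = 0.05,
    max_jump_deg_per_nm: float = 3.0,
    min_length: int = 20,
    max_trend_rms: float = 0.8,
) -> list[DiffractionPeakTrack]:
    """Detect diffraction ridges in a spectral map.

    Per wavelength row, local intensity maxima above
    ``rel_prominence`` times the map maximum (dark band and, by
    default, the specular window excluded) are located and refined to
    sub-bin angular precision.  Maxima are linked across wavelengths by
    nearest-angle continuity with a maximum jump of
    ``max_jump_deg_per_nm`` degrees per nm of wavelength step; tracks
    shorter than ``min_length`` points are discarded.

    Genuine diffraction ridges follow a smooth angle-versus-wavelength
    trend, while chains of linked noise maxima execute a random walk;
    tracks whose rms deviation from a quadratic trend exceeds
    ``max_trend_rms`` (deg) are therefore rejected as noise.
    """
    smap.validate()
    excluded = smap.dark_band_mask()
    if exclude_specular:
        excluded = excluded | smap.specular_mask()
    # peaks touching an excluded column or the grid edge are shoulder
    # artefacts, not crests
    near_excluded = excluded.copy()
    near_excluded[:-1] |= excluded[1:]
    near_excluded[1:] |= excluded[:-1]
    near_excluded[:2] = True
    near_excluded[-2:] = True

    work = smap.intensity.copy()
    work[:, excluded] = 0.0
    if work.max() <= 0:
        warnings.warn("no usable intensity outside excluded regions", stacklevel=2)
        return []
    prominence = rel_prominence * work.max()

    wl = smap.wavelengths
    ang = smap.angles
    ang_step = float(np.median(np.diff(ang)))

    active: list[dict] = []
    finished: list[list[tuple[float, float, float]]] = []
    prev_wl = wl[0]
    for i, lam in enumerate(wl):
        row = work[i]
        idxs, _ = find_peaks(row, prominence=prominence)
        idxs = [j for j in idxs if not near_excluded[j]]
        peaks = []
        for j in idxs:
            theta = ang[j] + _parabolic_refine(row, j) * ang_step
            peaks.append((theta, row[j]))

        max_jump = max_jump_deg_per_nm * max(lam - prev_wl, 1.0)
        prev_wl = lam
        unmatched = set(range(len(peaks)))
        for track in active:
            best, best_dist = None, np.inf
            for k in unmatched:
                dist = abs(peaks[k][0] - track["theta"])
                if dist < best_dist:
                    best, best_dist = k, dist
            if best is not None and best_dist <= max_jump:
                theta, inten = peaks[best]
                track["points"].append((lam, theta, inten))
                track["theta"] = theta
                unmatched.discard(best)
            else:
                track["misses"] += 1

        survivors = []
        for track in active:
            if track["misses"] > 2:
                finished.append(track["points"])
            else:
                survivors.append(track)
        active = survivors
        for k in unmatched:
            theta, inten = peaks[k]
            active.append({"theta": theta, "misses": 0, "points": [(lam, theta, inten)]})
    finished.extend(track["points"] for track in active)

    def _smooth(pts: list) -> bool:
        lam = np.array([p[0] for p in pts])
        theta = np.array([p[1] for p in pts])
        coeffs = np.polyfit(lam - lam.mean(), theta, deg=2)
        resid = theta - np.polyval(coeffs, lam - lam.mean())
        return float(np.sqrt(np.mean(resid**2))) <= max_trend_rms

    tracks = [
        DiffractionPeakTrack(points=np.array(pts), window=(float(ang[0]), float(ang[-1])))
        for pts in finished
        if len(pts) >= min_length and _smooth(pts)
    ]
    if not tracks:
        warnings.warn("no diffraction ridge tracks found", stacklevel=2)
    return sorted(tracks, key=len, reverse=True)


def _predicted_angles(lam: np.ndarray, d: float, m: int, theta_illum: float) -> np.ndarray:
    """Lab detection angles of order ``m``; NaN where evanescent."""
    arg = m * lam / d + np.sin(np.radians(theta_illum))
    with np.errstate(invalid="ignore"):
        theta = -np.degrees(np.arcsin(arg))
    theta[np.abs(arg) > 1] = np.nan
    return theta


#: Per-point residual (deg) charged for a track excluded as an outlier.
_OUTLIER_PENALTY = 5.0


def _assignment_residuals(
    tracks: list[DiffractionPeakTrack],
    orders: tuple,
    d: float,
    theta_illum: float,
) -> np.ndarray:
    res = []
    for track, m in zip(tracks, orders):
        if m is None:  # track excluded from the fit at a fixed cost
            res.append(np.full(len(track), _OUTLIER_PENALTY))
            continue
        pred = _predicted_angles(track.wavelengths, d, m, theta_illum)
        r = track.angles - pred
        r[~np.isfinite(r)] = 90.0  # heavy penalty for evanescent predictions
        res.append(r)
    return np.concatenate(res)


def fit_lattice_constant(
    tracks: list[DiffractionPeakTrack],
    theta_illum: float,
    candidate_orders: tuple[int, ...] = (1, 2, 3),
    d_bounds: tuple[float, float] = (200.0, 800.0),
    d_starts: tuple[float, ...] = (250.0, 400.0, 550.0),
) -> LatticeFit:
    """Fit the lattice constant to tracked diffraction ridges.

    A single ``d`` is fitted jointly over all tracks by bounded
    nonlinear least squares on the angular residuals of the grating
    equation; the diffraction order of each track is chosen from
    ``candidate_orders`` by residual competition, and the optimiser is
    multi-started over ``d_starts`` to escape arcsin local minima.

    Two safeguards make the assignment robust: a track may be excluded
    as an outlier (at a fixed 5 deg-per-point cost) when no order fits
    it, and near-degenerate assignments — order ``k*m`` at lattice
    ``k*d`` predicts the same ridge as order ``m`` at ``d`` — are
    broken in favour of the lowest orders.

    Parameters
    ----------
    tracks : list of DiffractionPeakTrack
        At least one track.
    theta_illum : float
        Illumination angle of the measurement (deg, negative).
    """
    if not tracks:
        raise FitError("no diffraction tracks to fit")

    from itertools import product

    options = tuple(candidate_orders) + (None,)
    if len(tracks) <= 4:
        combos = [c for c in product(options, repeat=len(tracks)) if any(m is not None for m in c)]
    else:  # cap the enumeration: only the longest tracks may be outliers
        head = [c for c in product(options, repeat=4) if any(m is not None for m in c)]
        combos = [c + (candidate_orders[0],) * (len(tracks) - 4) for c in head]

    entries = []
    for orders in combos:
        for d0 in d_starts:
            try:
                sol = least_squares(
                    lambda x: _assignment_residuals(tracks, orders, x[0], theta_illum),
                    x0=[d0],
                    bounds=([d_bounds[0]], [d_bounds[1]]),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except ValueError:  # pragma: no cover - defensive
                continue
            entries.append((float(np.sum(sol.fun**2)), float(sol.x[0]), orders))
    if not entries:
        raise FitError("lattice-constant fit failed for every order assignment")

    # order k*m at lattice k*d predicts the same ridge as order m at d, so
    # costs tie to within numerical noise; among near-ties keep the lowest
    # orders (and smallest d)
    min_cost = min(e[0] for e in entries)
    tied = [e for e in entries if e[0] <= min_cost * 1.05 + 1e-9]
    cost, d_hat, orders = min(
        tied, key=lambda e: (sum(m for m in e[2] if m is not None), e[1])
    )
    used = [(t, m) for t, m in zip(tracks, orders) if m is not None]
    if not used:  # pragma: no cover - all-None combos are filtered out
        raise FitError("every track was rejected as an outlier")
    used_tracks = [t for t, _ in used]
    used_orders = tuple(m for _, m in used)
    residuals = _assignment_residuals(used_tracks, used_orders, d_hat, theta_illum)

    # a few points may sit past the propagation limit (noise at the ridge
    # end); drop them and refit, but refuse wholesale evanescence
    propagating = np.abs(residuals) < 89.0
    if not np.all(propagating):
        if np.mean(propagating) < 0.9:
            raise FitError("best assignment leaves evanescent predictions; fit rejected")
        trimmed = []
        start = 0
        for t, m in used:
            keep = propagating[start : start + len(t)]
            start += len(t)
            if keep.sum() >= 2:
                trimmed.append((DiffractionPeakTrack(points=t.points[keep], window=t.window), m))
        used_tracks = [t for t, _ in trimmed]
        used_orders = tuple(m for _, m in trimmed)
        sol = least_squares(
            lambda x: _assignment_residuals(used_tracks, used_orders, x[0], theta_illum),
            x0=[d_hat],
            bounds=([d_bounds[0]], [d_bounds[1]]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        d_hat = float(sol.x[0])
        residuals = sol.fun
        if not np.all(np.abs(residuals) < 89.0):
            raise FitError("evanescent predictions persist after trimming; fit rejected")

    tracks = used_tracks
    orders = used_orders
    n_points = residuals.size
    cost = float(np.sum(residuals**2))
    rms = float(np.sqrt(cost / n_points))

    # residual-based standard error via the scalar Jacobian d theta / d d
    eps = 1e-3
    jac = (
        _assignment_residuals(tracks, orders, d_hat + eps, theta_illum)
        - _assignment_residuals(tracks, orders, d_hat - eps, theta_illum)
    ) / (2 * eps)
    jtj = float(np.sum(jac**2))
    dof = max(n_points - 1, 1)
    se = np.sqrt(cost / dof / jtj) if jtj > 0 else np.inf
    return LatticeFit(
        d_hat=d_hat,
        orders_used=tuple(sorted(set(orders))),
        rms_residual_deg=rms,
        n_points=n_points,
        ci_halfwidth=float(1.96 * se),
    )


def fit_refractive_index(
    specular_peaks,
    n_bounds: tuple[float, float] = (1.0, 3.0),
) -> IndexFit:
    """Fit the effective refractive index to specular peak positions.

    Parameters
    ----------
    specular_peaks : sequence of (theta_in, lambda_s)
        Incidence angle (deg) and specular peak wavelength (nm) pairs;
        at least three angles spanning at least 30 deg.

    Returns
    -------
    IndexFit
        Fitted ``n_avg`` and normal-incidence peak wavelength.  A fit
        pinned at the upper index bound (spectrally flat data) is
        flagged via ``at_upper_bound``.
    """
    pts = np.asarray(list(specular_peaks), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError("need at least three (theta_in, lambda_s) pairs")
    theta, lam_s = pts[:, 0], pts[:, 1]
    if np.ptp(theta) < 30.0:
        raise FitError(
            "incidence angles must span at least 30 deg to constrain n_avg"
        )

    def model(th, lam_p, n):
        return lam_p * np.cos(np.arcsin(np.sin(np.radians(th)) / n))

    p0 = (float(lam_s.max()), 1.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            model,
            theta,
            lam_s,
            p0=p0,
            bounds=([1.0, n_bounds[0]], [np.inf, n_bounds[1]]),
            maxfev=10000,
        )
    lam_p_hat, n_hat = float(popt[0]), float(popt[1])
    resid = lam_s - model(theta, *popt)
    at_bound = n_hat >= n_bounds[1] - 1e-6
    if at_bound:
        logger.warning(
            "refractive-index fit pinned at upper bound %.3g (flat specular curve)",
            n_bounds[1],
        )
    return IndexFit(
        n_hat=n_hat,
        lambda_p_hat=lam_p_hat,
        rms_residual_nm=float(np.sqrt(np.mean(resid**2))),
        at_upper_bound=at_bound,
    )


def alignment_ratio(
    smap: SpectralMap,
    window_center: float = -30.0,
    window_halfwidth: float = 4.0,
    tilt_offset: float = 55.0,
    use_mean: bool = False,
) -> AlignmentRatio:
    """Aligned/tilted domain intensity ratio of a spectral map.

    The main diffraction peak is the global intensity maximum over
    detection angles in ``window_center +/- window_halfwidth`` across
    all wavelengths (``use_mean`` replaces the maximum by the window
    mean at the peak wavelength).  The tilted-domain intensity is read
    at the main-peak angle plus ``tilt_offset`` at the same wavelength;
    their ratio rises with colony ordering.  A tilted intensity at or
    below the noise floor caps the ratio and sets
    ``below_noise_floor``.
    """
    smap.validate()
    in_window = (smap.angles >= window_center - window_halfwidth) & (
        smap.angles <= window_center + window_halfwidth
    )
    if not np.any(in_window):
        raise ValueError("main-peak window lies outside the angle grid")
    sub = smap.intensity[:, in_window]
    i_wl, i_ang = np.unravel_index(np.argmax(sub), sub.shape)
    window_angles = smap.angles[in_window]
    main_angle = float(window_angles[i_ang])
    main_wl = float(smap.wavelengths[i_wl])
    if use_mean:
        main_intensity = float(sub[i_wl].mean())
    else:
        main_intensity = float(sub[i_wl, i_ang])

    tilted_angle = main_angle + tilt_offset
    if not smap.angles[0] <= tilted_angle <= smap.angles[-1]:
        raise ValueError(
            f"tilted angle {tilted_angle:.1f} deg lies outside the angle grid"
        )
    j = int(np.argmin(np.abs(smap.angles - tilted_angle)))
    tilted_intensity = float(smap.intensity[i_wl, j])

    below_floor = tilted_intensity <= NOISE_FLOOR
    denom = max(tilted_intensity, NOISE_FLOOR)
    if below_floor:
        logger.warning(
            "tilted-domain intensity %.3g at %.1f deg is below the noise floor; "
            "ratio capped",
            tilted_intensity,
            tilted_angle,
        )
    return AlignmentRatio(
        main_peak_angle=main_angle,
        main_peak_wavelength=main_wl,
        main_peak_intensity=main_intensity,
        tilted_angle=float(smap.angles[j]),
        tilted_intensity=tilted_intensity,
        ratio=main_intensity / denom,
        below_noise_floor=below_floor,
    )
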