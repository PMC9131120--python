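"""Parameter-recovery experiments on synthetic data.

Each experiment generates synthetic measurements at a nutrient-condition
preset (the published per-condition ground truth), runs the matching
inverse analysis and returns both the per-seed estimates and the ground
truth, so callers can report recovery accuracy and seed-to-seed spread.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .conditions import morphometry_preset, optics_preset
from .inversion import alignment_ratio, fit_lattice_constant, fit_refractive_index, track_diffraction_peaks
from .morphometry import summarize
from .optics import specular_shift
from .simulate import simulate_cell_profiles, simulate_spectral_map

__all__ = [
    "LatticeRecovery",
    "lattice_recovery",
    "index_recovery",
    "morphometry_recovery",
    "alignment_ratio_for",
]


@dataclass
class LatticeRecovery:
    condition: str
    d_true: float
    d_hats: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.d_hats.mean())

    @property
    def half_spread(self) -> float:
        """Half the range (max - min) / 2 of the fitted values."""
        return float((self.d_hats.max() - self.d_hats.min()) / 2)


def lattice_recovery(condition: str, seeds, noise_sd: float = 0.05) -> LatticeRecovery:
    """Simulate noisy spectral maps for a condition preset and fit d back."""
    d_hats = []
    d_true = optics_preset(condition).d
    for seed in seeds:
        params = optics_preset(condition, seed=int(seed), noise_sd=noise_sd)
        smap = simulate_spectral_map(params)
        tracks = track_diffraction_peaks(smap)
        fit = fit_lattice_constant(tracks, theta_illum=smap.theta_illum)
        d_hats.append(fit.d_hat)
    return LatticeRecovery(condition=condition, d_true=d_true, d_hats=np.array(d_hats))


def index_recovery(
    seeds,
    n_true: float = 1.4,
    lambda_p: float = 578.0,
    angles=(15.0, 30.0, 45.0, 60.0, 75.0),
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Generate Snell-shifted specular peaks with multiplicative noise and
    fit the refractive index back; returns the per-seed estimates."""
    n_hats = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        peaks = [
            (th, specular_shift(lambda_p, n_true, th) * rng.normal(1.0, noise_sd))
            for th in angles
        ]
        n_hats.append(fit_refractive_index(peaks).n_hat)
    return np.array(n_hats)


def morphometry_recovery(condition: str, seeds) -> dict:
    """Simulate 40-cell populations for a condition and summarize each;
    returns per-seed arrays of the summary statistics plus the truth."""
    params = morphometry_preset(condition)
    stats = {"mean_diameter": [], "mean_within_sd": [], "mean_length": [], "sd_between": []}
    for seed in seeds:
        summary = summarize(
            simulate_cell_profiles(morphometry_preset(condition, seed=int(seed)))
        )
        for key in stats:
            stats[key].append(getattr(summary, key))
    out = {key: np.array(val) for key, val in stats.items()}
    out["truth"] = {
        "mean_diameter": params.mean_diameter,
        "mean_within_sd": params.sd_diameter_within,
        "mean_length": params.mean_length,
        "sd_between": params.sd_diameter_between,
    }
    return out


def alignment_ratio_for(condition_or_params, seed: int = 0, noise_sd: float = 0.02) -> float:
    """Alignment ratio of one simulated map (condition preset name or params)."""
    if isinstance(condition_or_params, str):
        params = optics_preset(condition_or_params, seed=seed, noise_sd=noise_sd)
    else:
        params = dataclasses.replace(condition_or_params, seed=seed, noise_sd=noise_sd)
    return alignment_ratio(simulate_spectral_map(params)).ratio
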