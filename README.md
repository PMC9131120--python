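# colonyoptics

Optical and morphometric analysis of structurally coloured bacterial
colonies, for researchers studying photonic-crystal organization in
bacteria such as *Flavobacterium* IR1.

Colonies of these bacteria pack into two-dimensional hexagonal lattices
whose period sits at the scale of visible light, so the colony behaves
as a diffraction grating: its colour and angular response encode the
inter-cell spacing, the effective refractive index and the orientation
order of its crystalline domains.  This package provides a forward
model of the angular-resolved scattering measurement and the inverse
analyses that turn goniometer maps, cryo-TEM width profiles and
microscopy images of domain mosaics into quantitative structure:

* **Lattice constant** — diffraction ridges in a (wavelength, detection
  angle) map obey the grating equation
  `θ_m = arcsin(mλ/d − sin θ_i)`; tracking the ridges and fitting them
  jointly over orders `m` yields the packing period `d`.
* **Effective refractive index** — the specular peak shifts with
  incidence as `λ_s = λ_p cos(arcsin(sin θ_in / n_avg))` (Snell's law);
  fitting `λ_s(θ_in)` yields `n_avg` and the normal-incidence peak `λ_p`.
* **Domain alignment** — the ratio of the main diffraction-peak
  intensity (detection window −30° ± 4°) to the intensity 55° away is a
  proxy for the volume ratio of surface-aligned to tilted crystalline
  domains; ordered and disordered colonies differ by an order of
  magnitude.
* **Cell morphometry** — cell diameters sampled every 300 nm along each
  cell give per-cell means, within-cell variation and population
  summaries.
* **Domain imaging** — non-local-means denoising, 2-D FFT power
  spectral density and azimuthal averaging extract the lattice period
  and a characteristic domain scale from microscopy images.

Because the analyses are validated on synthetic data, the package also
ships first-class generators (`colonyoptics.simulate`) for all three
measurement types with fully controllable ground truth, plus presets
(`colonyoptics.conditions`) encoding the published per-nutrient
measurements (plain seawater agar ASWB, fucoidan-supplemented ASWBF,
carrageenan-supplemented ASWBC).

## Worked example

```python
from colonyoptics import (simulate_spectral_map, track_diffraction_peaks,
                          fit_lattice_constant, alignment_ratio)
from colonyoptics.conditions import optics_preset

params = optics_preset("ASWB_day1", seed=1, noise_sd=0.05)  # d = 425 nm
smap = simulate_spectral_map(params)
tracks = track_diffraction_peaks(smap)
fit = fit_lattice_constant(tracks, theta_illum=smap.theta_illum)
ratio = alignment_ratio(smap)
print(f"d = {fit.d_hat:.1f} nm (rms {fit.rms_residual_deg:.2f} deg, "
      f"orders {fit.orders_used}); alignment ratio {ratio.ratio:.0f}")
```

prints

```
d = 424.8 nm (rms 0.42 deg, orders (1,)); alignment ratio 5481
```

i.e. the day-1 lattice constant of 425 nm is recovered from the noisy
simulated map to well within the ±5 nm reproducibility of the
goniometer measurement, and the highly ordered colony (90% aligned
domains) shows a large aligned/tilted intensity ratio.

The numbered scripts under `analysis/` run the full study on synthetic
data: `01` writes example datasets, `02`–`06` perform lattice, index,
alignment, morphometry and image-PSD recovery, printing a short summary
and writing tables under `results/`.  A YAML-driven end-to-end run is
available as `colonyoptics run --config examples/demo_config.yaml`, and
each stage also has its own CLI subcommand (`fit-lattice`, `fit-index`,
`domain-ratio`, `morphometry`, `image-psd`, `simulate-*`).

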