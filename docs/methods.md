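# Methods

## Physical model

A structurally coloured colony is treated as a mosaic of crystalline
domains, each a 2-D hexagonal packing of cells with in-plane period
`d` (the lattice constant, nm).  Two scalar relations carry all the
optics:

* **Grating equation.** A domain illuminated at incidence `θ_i`
  diffracts wavelength `λ` into `θ_m = arcsin(mλ/d − sin θ_i)` for
  integer order `m`; orders with `|mλ/d − sin θ_i| > 1` are evanescent
  and are represented by a distinguished return value, not an error,
  so the simulator can silently skip them.
* **Specular shift.** The specular reflection peak of a slab with
  effective index `n_avg` and normal-incidence peak `λ_p` moves to
  `λ_s = λ_p cos θ_2` with `sin θ_2 = sin θ_in / n_avg` (Snell).

Angles are degrees everywhere in the API (radians internally).  Two
frames coexist: the textbook grating frame (incidence positive, mirror
at `−θ_i`) used by `diffraction_angle`, and the goniometer lab frame
(illumination negative, e.g. −60°, specular at `+60°`) used by
`detection_angle` and by all spectral maps; lab detection angles are
the negatives of grating-frame angles evaluated at `θ_i = −θ_illum`.
With illumination −60° and `d = 425` nm the 578-nm first order lands at
−29.6°, which is why the main-peak analysis window defaults to
−30° ± 4°.

**Domain tilt.** A domain tilted by `α` within the scattering plane
sees incidence `θ_illum − α`; its diffracted beam is computed in that
frame and rotated back.  For the zero order this is the mirror result
(a `2α` shift); for the first order the shift is larger — with the
defaults, the light reaching "main peak + 55°" comes from domains
tilted by roughly 50°, not 27.5°.  Out-of-plane tilt components are
ignored: the tilt construction and the ±55° bookkeeping are
one-dimensional in angle.

## Synthetic-data generators

The generators emulate the three measurement types the inverse code
consumes; their defaults encode the published study conditions
(`colonyoptics.conditions`): lattice constants 425/395/410 nm (ASWB
days 1–3), 450/460 nm (ASWBF days 1–2), index 1.4, illumination −60°,
diameters 400 nm (sd 20 between / 10 within) vs 480 nm (25/20),
lengths 3.4 vs 3.2 µm (sd 0.8), 300-nm sampling, 40 cells.

**Spectral maps.** Wavelength grid 360–800 nm at 1 nm, detection grid
−85°…85° at 1°, dark band ±3° around the illumination angle — the
detector cannot sit in the beam.  The tilt population is discretized
at 1° steps: aligned mass at `α = 0` with weight `aligned_fraction`, a
Gaussian(0, `tilt_sigma`) tilted pool truncated to ±60° with
`|α| < 2°` excluded.  Each (order, tilt) component contributes a
Gaussian spectral ridge (σ 20 nm) whose crest in every angle column
solves the grating equation exactly, so the generator doubles as the
oracle for the tracker and fitter.  The specular band (gain 300,
angular σ 2°) is centred on the Snell-shifted `λ_s`; the recorded
"specular window" spans ±8° (4 angular σ) so that its tails do not
contaminate ridge detection, and on disk that window is stored divided
by 300, following the display convention for such maps.  Noise is
multiplicative log-normal — reflectance is positive and normalized, so
additive Gaussian noise would be unphysical at the dark band.  The
true tilt distribution and the specular/diffuse radiometric ratio are
unpublished; `aligned_fraction`/`tilt_sigma` of 0.9/15° (ordered) and
0.4/25° (fucoidan-like) are free parameters chosen once to reproduce
the order-of-magnitude alignment-ratio gap.  The ASWBF `λ_p` presets
scale the 578-nm anchor with `d`, as no normal-incidence peak is
published for those plates.

**Cell profiles.** A two-level Gaussian model: per-cell baseline
diameter (between-cell sd) plus per-position scatter (within-cell sd)
at 300-nm intervals; lengths Gaussian truncated above three sampling
intervals; all diameters truncated positive by resampling.  Each
sample is one width measurement — whether the published per-cell lists
derive from one or both cell edges is not stated.

**Domain mosaics.** Voronoi cells of Poisson-disk (dart-throwing)
seeds with mean spacing `mean_domain_size`; each domain carries a
sinusoidal stripe (the cell rows) at a per-domain orientation jittered
about a common direction, a per-domain mean brightness
(`domain_contrast`, sd 0.1 — differently oriented domains scatter
differently under the microscope, and this brightness mosaic is what
carries the domain-size signal at low spatial frequency), and pixel
Gaussian noise.  Periods below twice the pixel pitch are rejected as
aliasing.  The generators are bitwise deterministic given their seed.

What the generators do **not** emulate: absolute radiometric
calibration, polarization, absorption by the nigrosin background,
out-of-plane domain tilts, curved/partial cells in TEM fields of view,
uneven microscope illumination.  Passing recovery tests therefore show
the inverse pipeline is correct and well-conditioned at realistic
noise, not that it is robust to every instrumental artefact of real
data.

## Inverse analyses and numerical choices

**Ridge tracking.** Per wavelength row, local maxima above 5% of the
usable map maximum (dark band, specular window and two edge columns
excluded) are refined to sub-bin angle by a log-parabola — exact for
Gaussian profiles — and linked across rows by nearest-angle continuity
(≤3°/nm, ≤2 missed rows).  Tracks need ≥20 points, and must follow a
smooth trend: chains of linked noise maxima execute a random walk, so
tracks whose rms deviation from a quadratic angle-versus-wavelength
trend exceeds 0.8° are rejected.

**Lattice fit.** One `d` is fitted jointly over all tracks by bounded
least squares (d ∈ [200, 800] nm, multi-start at 250/400/550 nm,
tolerances 1e-12) on the angular residuals; each track's order is
chosen from {1, 2, 3} by residual competition, with two safeguards:
a track may be excluded as an outlier at a fixed 5°-per-point cost,
and the exact degeneracy "order `km` at lattice `kd` predicts the same
ridge" is broken in favour of the lowest orders among fits within 5%
of the minimum cost.  A few points past the propagation limit (noise
at a ridge end) are trimmed and the fit repeated; wholesale
evanescence is a fit failure.  The confidence half-width is the
residual-based standard error via the scalar Jacobian.

**Index fit.** Bounded `curve_fit` of `λ_s(θ_in)` over `(λ_p, n_avg)`
with `n_avg ∈ [1, 3]`; at least three angles spanning ≥30° are
required, and a fit pinned at the upper bound (spectrally flat input)
is flagged rather than silently returned.

**Alignment ratio.** Main peak = global maximum over the −30° ± 4°
detection window across all wavelengths (window max, not mean — a mean
variant is available); tilted intensity is read at the main-peak angle
+55° *at the same wavelength*, the minimal reading of the published
recipe, which names no second wavelength.  The window is interpreted
in detection-angle coordinates and is configurable for other
illumination geometries.  Tilted intensities at or below 1e-6 cap the
ratio and set a flag.

**Morphometry.** Sample (n−1) standard deviations throughout (~11
samples per cell); cells shorter than two sampling intervals are
excluded with a logged count; the published "±" values are interpreted
as between-cell standard deviations.  Note the population statistic
"mean of per-cell sample sds" has the usual small-sample expectation
`c₄(n)·σ ≈ 0.98 σ`; recovery is therefore judged against the
generating value within three standard errors of a single 40-cell
experiment, under which this ~2% shrinkage is immaterial.

**Image PSD.** Mean subtraction, separable Hann window (symmetric
form, so quarter-turn rotations leave the radial PSD exactly
unchanged), 2-D FFT, power `|F|²/N²` (Parseval: annulus-weighted
totals equal the windowed image's mean square), azimuthal mean over
annuli one frequency bin wide, DC excluded.  The lattice scale is the
reciprocal of the highest-frequency peak with prominence ≥2% of the
spectral maximum (log-parabola refined); the domain scale is the
reciprocal of the maximum of `f²·power` below half the lattice
frequency, reported missing when that quantity never reaches 1e-4 of
its value at the lattice peak (no resolvable envelope, e.g. a
single-domain scene).  The domain scale is a characteristic scale —
monotone in the generating domain size but roughly twice the mean
Voronoi spacing — not a calibrated mean domain diameter.  Non-local
means uses patch size 7, search radius 10 px and strength
`h = 0.05 × dynamic range` by default.  Batch analysis averages the
radial PSDs of replicate images (15 per condition in the source
protocol) before peak-finding.

## Problem sizes

Recovery experiments use 10 noisy maps per lattice condition (441×171
grid, noise sd 0.05), 20 specular data sets at 1% noise, 50–200
replicate populations of 40 cells, and 512-px images at 30–50 nm/px —
sizes at which every experiment runs in seconds to a couple of minutes
on one CPU while leaving Monte-Carlo error well below the published
tolerances (±5 nm for `d`, ±0.05 for `n_avg`).

## Known limitations

* The forward model is kinematic (single-scattering ridge geometry);
  no rigorous electromagnetic solver stands behind the intensities, so
  absolute reflectance levels are arbitrary units.
* The tilted-domain intensity at +55° depends on the assumed tilt
  distribution; the alignment ratio is comparable across conditions
  within this model but is not a calibrated physical volume ratio.
* `fit_lattice_constant` assumes all tracks share one `d`; colonies
  with coexisting lattices would need per-track fits.
* The domain-scale estimator requires the brightness mosaic to be
  resolvable within the frame; domains comparable to the frame size
  return unstable knees.
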