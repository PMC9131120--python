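"""Nutrient-condition presets for the synthetic generators.

The study grows *Flavobacterium* IR1 on artificial-seawater black agar
without additives (ASWB), with 1% fucoidan (ASWBF) and with 0.5%
kappa-carrageenan (ASWBC).  The presets below encode the published
per-condition measurements as generator ground truth:

* lattice constants: ASWB 425 / 395 / 410 nm on days 1-3; ASWBF 450 /
  460 nm on days 1-2, 420 nm later; ASWBC close-packed at the ASWB
  day-2 value throughout;
* effective refractive index 1.4 for every condition and day;
* normal-incidence peak 578 nm (ASWB day 1) and 548 nm (day 2); for the
  other conditions the preset scales 578 nm with the lattice constant,
  since no normal-incidence peak is published for them;
* cell morphometry: diameter 400 nm (between-cell sd 20 nm, within-cell
  sd 10 nm), length 3.4 um for ASWB; diameter 480 nm (sds 25 / 20 nm),
  length 3.2 um for fucoidan-grown cells; length spread 0.8 um in both;
* domain ordering: fucoidan colonies are matte and disordered, encoded
  as a lower aligned fraction and wider tilt spread.  The true tilt
  distribution is unpublished; 0.9 / 15 deg (ordered) versus 0.4 /
  25 deg (fucoidan) reproduce the order-of-magnitude gap in the
  aligned/tilted intensity ratio.
"""

from __future__ import annotations

from dataclasses import replace

from .simulate import ColonyOpticalParams, MorphometryParams

__all__ = ["OPTICS_PRESETS", "MORPHOMETRY_PRESETS", "optics_preset", "morphometry_preset"]


def _scaled_lambda_p(d: float) -> float:
    # anchor: 578 nm peak at d = 425 nm (ASWB day 1)
    return round(578.0 * d / 425.0, 1)


OPTICS_PRESETS: dict[str, ColonyOpticalParams] = {
    "ASWB_day1": ColonyOpticalParams(
        d=425.0, lambda_p=578.0, aligned_fraction=0.9, tilt_sigma=15.0
    ),
    "ASWB_day2": ColonyOpticalParams(
        d=395.0, lambda_p=548.0, aligned_fraction=0.9, tilt_sigma=15.0
    ),
    "ASWB_day3": ColonyOpticalParams(
        d=410.0, lambda_p=_scaled_lambda_p(410.0), aligned_fraction=0.8, tilt_sigma=15.0
    ),
    "ASWBF_day1": ColonyOpticalParams(
        d=450.0, lambda_p=_scaled_lambda_p(450.0), aligned_fraction=0.4, tilt_sigma=25.0
    ),
    "ASWBF_day2": ColonyOpticalParams(
        d=460.0, lambda_p=_scaled_lambda_p(460.0), aligned_fraction=0.4, tilt_sigma=25.0
    ),
    "ASWBC_day1": ColonyOpticalParams(
        d=395.0, lambda_p=548.0, aligned_fraction=0.9, tilt_sigma=15.0
    ),
}

MORPHOMETRY_PRESETS: dict[str, MorphometryParams] = {
    "ASWB": MorphometryParams(
        n_cells=40,
        mean_diameter=400.0,
        sd_diameter_between=20.0,
        sd_diameter_within=10.0,
        mean_length=3.4,
        sd_length=0.8,
    ),
    "ASWBF": MorphometryParams(
        n_cells=40,
        mean_diameter=480.0,
        sd_diameter_between=25.0,
        sd_diameter_within=20.0,
        mean_length=3.2,
        sd_length=0.8,
    ),
}


def optics_preset(name: str, **overrides) -> ColonyOpticalParams:
    """Preset optical ground truth for ``name`` (e.g. ``"ASWB_day1"``),
    optionally overriding fields such as ``seed`` or ``noise_sd``."""
    return replace(OPTICS_PRESETS[name], **overrides)


def morphometry_preset(name: str, **overrides) -> MorphometryParams:
    """Preset morphometry ground truth for ``name`` (``"ASWB"`` or ``"ASWBF"``)."""
    return replace(MORPHOMETRY_PRESETS[name], **overrides)
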