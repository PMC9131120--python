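"""Cell-morphometry statistics from interval-sampled diameter profiles.

The cryo-TEM protocol reads the cell width every 300 nm along the cell
axis; a cell's diameter is the mean of those samples, its within-cell
variation their sample standard deviation, and the population summary
aggregates per-cell statistics over at least 40 cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .datatypes import CellProfile

__all__ = [
    "MorphometrySummary",
    "cell_mean_diameter",
    "cell_within_sd",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass
class MorphometrySummary:
    """Population summary of cell diameter and length.

    ``mean_diameter`` is the mean of per-cell mean diameters,
    ``sd_between`` their sample standard deviation (NaN for a single
    cell), and ``mean_within_sd`` the average of per-cell sample
    standard deviations — the published "+/-" values correspond to the
    between-cell spreads.
    """

    n_cells: int
    mean_diameter: float
    sd_between: float
    mean_within_sd: float
    mean_length: float
    sd_length: float
    n_excluded: int = 0


def cell_mean_diameter(profile: CellProfile) -> float:
    """Mean diameter of one cell (nm): the arithmetic mean of its
    interval samples."""
    profile.validate()
    return float(np.mean(profile.diameters_nm))


def cell_within_sd(profile: CellProfile) -> float:
    """Within-cell diameter variation (nm): the sample (n-1) standard
    deviation of the interval samples of one cell."""
    profile.validate()
    return float(np.std(profile.diameters_nm, ddof=1))


def summarize(profiles) -> MorphometrySummary:
    """Summarize a collection of cell profiles.

    Cells with fewer than two samples (shorter than two sampling
    intervals) cannot contribute a within-cell sd and are excluded with
    a logged count.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one cell profile")

    usable, excluded = [], 0
    for p in profiles:
        try:
            p.validate()
        except ValueError:
            excluded += 1
            continue
        usable.append(p)
    if excluded:
        logger.info("excluded %d cell(s) with fewer than two samples", excluded)
    if not usable:
        raise ValueError("no usable cell profiles (all too short)")

    means = np.array([cell_mean_diameter(p) for p in usable])
    within = np.array([cell_within_sd(p) for p in usable])
    lengths = np.array([p.length_um for p in usable])

    n = len(usable)
    sd_between = float(np.std(means, ddof=1)) if n > 1 else math.nan
    sd_length = float(np.std(lengths, ddof=1)) if n > 1 else math.nan
    return MorphometrySummary(
        n_cells=n,
        mean_diameter=float(means.mean()),
        sd_between=sd_between,
        mean_within_sd=float(within.mean()),
        mean_length=float(lengths.mean()),
        sd_length=sd_length,
        n_excluded=excluded,
    )
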