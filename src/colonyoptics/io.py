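"""File formats: delimited-text spectral maps with JSON sidecars,
cell-profile CSVs and domain images.

A spectral map on disk is a delimited-text matrix whose first row holds
detection angles (deg) and whose first column holds wavelengths (nm),
plus a JSON sidecar (``<file>.json``) carrying the measurement metadata
(illumination angle, dark band, specular window).  Following the
display convention for goniometer maps, the specular window may be
stored divided by 300; the sidecar records the factor and loading
undoes it, so in-memory intensities are always physical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellProfile, DomainImage, SpectralMap

__all__ = [
    "ParseError",
    "sidecar_path",
    "write_spectral_map",
    "read_spectral_map",
    "write_cell_profiles",
    "read_cell_profiles",
    "write_domain_image",
    "read_domain_image",
]

SPECULAR_SCALE = 300.0


class ParseError(ValueError):
    """Malformed input file."""


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_spectral_map(smap: SpectralMap, path, scale_specular: bool = True) -> Path:
    """Write a spectral map and its JSON sidecar; returns the data path."""
    smap.validate()
    path = Path(path)
    intensity = smap.intensity.copy()
    scaled = bool(scale_specular and smap.specular_window is not None)
    if scaled:
        intensity[:, smap.specular_mask()] /= SPECULAR_SCALE
    df = pd.DataFrame(intensity, index=smap.wavelengths, columns=smap.angles)
    df.index.name = "wavelength_nm"
    df.to_csv(path, float_format="%.17g")
    meta = {
        "theta_illum": smap.theta_illum,
        "dark_band_halfwidth": smap.dark_band_halfwidth,
        "specular_window": list(smap.specular_window) if smap.specular_window else None,
        "specular_scale": SPECULAR_SCALE if scaled else None,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_spectral_map(path) -> SpectralMap:
    """Read a spectral map written by :func:`write_spectral_map`.

    Raises :class:`ParseError` naming the offending row or column on
    non-monotone grids, negative intensities or missing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise ParseError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"unreadable sidecar {meta_path}: {exc}") from exc
    for key in ("theta_illum", "dark_band_halfwidth"):
        if key not in meta:
            raise ParseError(f"sidecar {meta_path} lacks required key '{key}'")

    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        wavelengths = df.index.to_numpy(dtype=float)
        angles = np.array([float(c) for c in df.columns])
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a numeric matrix with numeric headers: {exc}") from exc

    bad = np.flatnonzero(np.diff(wavelengths) <= 0)
    if bad.size:
        raise ParseError(f"{path}: wavelength column not increasing at row {bad[0] + 2}")
    bad = np.flatnonzero(np.diff(angles) <= 0)
    if bad.size:
        raise ParseError(f"{path}: angle header not increasing at column {bad[0] + 2}")

    intensity = df.to_numpy(dtype=float)
    if np.any(intensity < 0):
        i, j = np.argwhere(intensity < 0)[0]
        raise ParseError(
            f"{path}: negative intensity at wavelength {wavelengths[i]:g} nm, "
            f"angle {angles[j]:g} deg"
        )

    window = meta.get("specular_window")
    scale = meta.get("specular_scale")
    smap = SpectralMap(
        wavelengths=wavelengths,
        angles=angles,
        intensity=intensity,
        theta_illum=float(meta["theta_illum"]),
        dark_band_halfwidth=float(meta["dark_band_halfwidth"]),
        specular_window=tuple(window) if window else None,
    )
    if scale and window:
        smap.intensity[:, smap.specular_mask()] *= float(scale)
    return smap


def write_cell_profiles(profiles, path) -> Path:
    """Write cell profiles as CSV (cell_id, position_nm, diameter_nm, length_um)."""
    rows = []
    for p in profiles:
        p.validate()
        for pos, diam in zip(p.positions_nm, p.diameters_nm):
            rows.append((p.cell_id, pos, diam, p.length_um))
    pd.DataFrame(
        rows, columns=["cell_id", "position_nm", "diameter_nm", "length_um"]
    ).to_csv(path, index=False)
    return Path(path)


def read_cell_profiles(path) -> list[CellProfile]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"cell_id", "position_nm", "diameter_nm"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    profiles = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("position_nm")
        if "length_um" in grp.columns:
            length = float(grp["length_um"].iloc[0])
        else:  # reconstruct from the sampled extent
            length = float(grp["position_nm"].max()) / 1000.0
        try:
            profiles.append(
                CellProfile(
                    cell_id=str(cell_id),
                    positions_nm=grp["position_nm"].to_numpy(float),
                    diameters_nm=grp["diameter_nm"].to_numpy(float),
                    length_um=length,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: cell '{cell_id}': {exc}") from exc
    if not profiles:
        raise ParseError(f"{path}: no cells found")
    return profiles


def write_domain_image(image: DomainImage, path) -> Path:
    """Write a domain image (16-bit TIFF or PNG) plus pixel-pitch sidecar."""
    image.validate()
    path = Path(path)
    px = image.pixels
    span = float(px.max()) or 1.0
    scaled = np.round(px / span * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, scaled)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, scaled)
    sidecar_path(path).write_text(
        json.dumps({"pixel_pitch_nm": image.pixel_pitch_nm, "intensity_span": span})
    )
    return path


def read_domain_image(path, pixel_pitch_nm: float | None = None) -> DomainImage:
    """Read a domain image; the pixel pitch comes from the sidecar unless given."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta = {}
    if sidecar_path(path).exists():
        meta = json.loads(sidecar_path(path).read_text())
    if pixel_pitch_nm is None:
        pixel_pitch_nm = meta.get("pixel_pitch_nm")
    if pixel_pitch_nm is None:
        raise ParseError(f"{path}: pixel pitch unknown (no sidecar; pass pixel_pitch_nm)")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    px = raw.astype(float)
    if raw.dtype == np.uint16:
        px /= 65535.0
        px *= float(meta.get("intensity_span", 1.0))
    elif raw.dtype == np.uint8:
        px /= 255.0
    return DomainImage(pixels=px, pixel_pitch_nm=float(pixel_pitch_nm))
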