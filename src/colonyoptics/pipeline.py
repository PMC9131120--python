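"""End-to-end pipeline driven by a declarative run configuration.

A :class:`RunConfig` names the stages to run (spectral inversion,
refractive-index fit, morphometry, domain-image PSD) and, per stage,
either a path to measured input or the ground-truth parameters for the
synthetic generator.  ``run_pipeline`` executes the requested stages,
writes a resolved copy of the configuration next to the outputs and
emits a single JSON report with every fitted quantity plus provenance
(input hashes, seed, package version).  Runs are deterministic given
the seed: each stage draws its RNG seed from one seed sequence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conditions import MORPHOMETRY_PRESETS, OPTICS_PRESETS
from .inversion import (
    FitError,
    alignment_ratio,
    fit_lattice_constant,
    fit_refractive_index,
    track_diffraction_peaks,
)
from .io import ParseError, read_cell_profiles, read_domain_image, read_spectral_map
from .morphometry import summarize
from .optics import specular_shift
from .psd import characteristic_scales, preprocess, radial_psd
from .simulate import (
    ColonyOpticalParams,
    DomainImageParams,
    MorphometryParams,
    simulate_cell_profiles,
    simulate_domain_image,
    simulate_spectral_map,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _strict(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ParseError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Each stage dict accepts either ``path`` (measured input) or
    ``params`` (generator ground truth, as keyword arguments of the
    corresponding parameter dataclass or a preset name under
    ``preset``); unknown keys are rejected.
    """

    seed: int = 0
    output_dir: Path = Path("colonyoptics_out")
    log_level: str = "INFO"
    spectral: dict | None = None
    index: dict | None = None
    morphometry: dict | None = None
    domains: dict | None = None

    _STAGE_KEYS = {
        "spectral": {"path", "params", "preset", "window_center", "window_halfwidth", "tilt_offset"},
        "index": {"path", "params", "angles", "noise_sd", "n_points"},
        "morphometry": {"path", "params", "preset"},
        "domains": {"path", "params", "pixel_pitch_nm", "denoise_strength"},
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        _strict(raw, allowed, "run config")
        cfg = cls(**raw)
        cfg.output_dir = Path(cfg.output_dir)
        for stage, keys in cls._STAGE_KEYS.items():
            block = getattr(cfg, stage)
            if block is not None:
                if not isinstance(block, dict):
                    raise ParseError(f"stage '{stage}' must be a mapping")
                _strict(block, keys, f"stage '{stage}'")
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ParseError(f"no such config file: {path}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["output_dir"] = str(self.output_dir)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base_seed: int, index: int) -> int:
    state = np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
    return int(state % (2**31))


def _run_spectral(block: dict, seed: int, provenance: dict) -> dict:
    if "path" in block:
        smap = read_spectral_map(block["path"])
        provenance["inputs"][str(block["path"])] = _sha256(Path(block["path"]))
    else:
        params = OPTICS_PRESETS[block["preset"]] if "preset" in block else ColonyOpticalParams()
        params = dataclasses.replace(params, **block.get("params", {}))
        if "seed" not in block.get("params", {}):
            params = dataclasses.replace(params, seed=seed)
        smap = simulate_spectral_map(params)
        provenance["generated"]["spectral"] = dataclasses.asdict(params)
    tracks = track_diffraction_peaks(smap)
    fit = fit_lattice_constant(tracks, theta_illum=smap.theta_illum)
    ratio = alignment_ratio(
        smap,
        window_center=block.get("window_center", -30.0),
        window_halfwidth=block.get("window_halfwidth", 4.0),
        tilt_offset=block.get("tilt_offset", 55.0),
    )
    return {
        "d_hat_nm": fit.d_hat,
        "ci_halfwidth_nm": fit.ci_halfwidth,
        "rms_residual_deg": fit.rms_residual_deg,
        "orders_used": list(fit.orders_used),
        "n_points": fit.n_points,
        "n_tracks": len(tracks),
        "alignment_ratio": ratio.ratio,
        "main_peak_angle_deg": ratio.main_peak_angle,
        "ratio_below_noise_floor": ratio.below_noise_floor,
    }


def _run_index(block: dict, seed: int, provenance: dict) -> dict:
    if "path" in block:
        import pandas as pd

        df = pd.read_csv(block["path"])
        if not {"theta_in", "lambda_s"}.issubset(df.columns):
            raise ParseError(f"{block['path']}: need columns theta_in, lambda_s")
        peaks = df[["theta_in", "lambda_s"]].to_numpy(float)
        provenance["inputs"][str(block["path"])] = _sha256(Path(block["path"]))
    else:
        params = dict(block.get("params", {}))
        n_avg = params.get("n_avg", 1.4)
        lambda_p = params.get("lambda_p", 578.0)
        angles = block.get("angles", [15.0, 30.0, 45.0, 60.0, 75.0])
        noise_sd = block.get("noise_sd", 0.01)
        rng = np.random.default_rng(seed)
        peaks = [
            (
                th,
                specular_shift(lambda_p, n_avg, th) * rng.normal(1.0, noise_sd),
            )
            for th in angles
        ]
        provenance["generated"]["index"] = {
            "n_avg": n_avg,
            "lambda_p": lambda_p,
            "angles": list(angles),
            "noise_sd": noise_sd,
        }
    fit = fit_refractive_index(peaks)
    return {
        "n_hat": fit.n_hat,
        "lambda_p_hat_nm": fit.lambda_p_hat,
        "rms_residual_nm": fit.rms_residual_nm,
        "at_upper_bound": fit.at_upper_bound,
    }


def _run_morphometry(block: dict, seed: int, provenance: dict) -> dict:
    if "path" in block:
        profiles = read_cell_profiles(block["path"])
        provenance["inputs"][str(block["path"])] = _sha256(Path(block["path"]))
    else:
        params = (
            MORPHOMETRY_PRESETS[block["preset"]] if "preset" in block else MorphometryParams()
        )
        params = dataclasses.replace(params, **block.get("params", {}))
        if "seed" not in block.get("params", {}):
            params = dataclasses.replace(params, seed=seed)
        profiles = simulate_cell_profiles(params)
        provenance["generated"]["morphometry"] = dataclasses.asdict(params)
    summary = summarize(profiles)
    return dataclasses.asdict(summary)


def _run_domains(block: dict, seed: int, provenance: dict) -> dict:
    if "path" in block:
        image = read_domain_image(block["path"], block.get("pixel_pitch_nm"))
        provenance["inputs"][str(block["path"])] = _sha256(Path(block["path"]))
    else:
        params = DomainImageParams(**block.get("params", {}))
        if "seed" not in block.get("params", {}):
            params = dataclasses.replace(params, seed=seed)
        image = simulate_domain_image(params)
        provenance["generated"]["domains"] = dataclasses.asdict(params)
    grey = preprocess(image, denoise_strength=block.get("denoise_strength", 0.05))
    psd = radial_psd(grey)
    lattice_scale, domain_scale = characteristic_scales(psd)
    return {
        "lattice_scale_nm": lattice_scale,
        "domain_scale_nm": domain_scale,
        "n_frequency_bins": int(psd.frequencies.size),
    }


_STAGES = {
    "spectral": _run_spectral,
    "index": _run_index,
    "morphometry": _run_morphometry,
    "domains": _run_domains,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the JSON-able report.

    Writes ``resolved_config.json`` and ``report.json`` under
    ``config.output_dir``.  Any stage failure raises :class:`StageError`
    naming the stage; outputs of completed stages are retained.
    """
    logging.basicConfig(level=config.log_level)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(json.dumps(config.to_dict(), indent=1))

    provenance: dict = {"seed": config.seed, "version": __version__, "inputs": {}, "generated": {}}
    report: dict = {"provenance": provenance}
    for i, (stage, runner) in enumerate(_STAGES.items()):
        block = getattr(config, stage)
        if block is None:
            continue
        logger.info("running stage '%s'", stage)
        try:
            report[stage] = runner(block, _stage_seed(config.seed, i), provenance)
        except (ParseError, FitError, ValueError, KeyError) as exc:
            (outdir / "report.json").write_text(json.dumps(report, indent=1))
            raise StageError(stage, exc) from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
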