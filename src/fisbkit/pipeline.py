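"""Configurable end-to-end pipeline: simulate fixtures, run analyses.

A run is described by a small YAML/JSON config (seed, output directory,
stage list, per-stage parameter blocks).  Stages execute in dependency
order -- simulation first, then the analyses that consume its outputs --
and every run writes a ``manifest.json`` recording inputs, outputs, the
seed, the package version and a hash of the resolved configuration, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import fit_kd, read_titration_csv
from .exceptions import ConfigurationError
from .neck_model import (
    ModelParams,
    reference_params,
    solve_equilibrium,
    sweep_interaction_strength,
)
from .nucleation import (
    NucleationParams,
    infer_critical_n,
    mean_neck_count,
    nucleation_time,
)
from .quantify import (
    estimate_labeling_efficiency,
    fit_calibration,
    intensity_to_copies,
    read_bleach_csv,
    read_calibration_csv,
    read_spots_csv,
)
from .synth import (
    SimulationSpec,
    gen_bleach_traces,
    gen_brownian_tracks,
    gen_calibration_and_spots,
    gen_titration,
)
from .tracking import compute_msd, fit_diffusion, read_tracks_csv, write_tracks_csv
from .units import convert_units

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("fisbkit.pipeline")

_KNOWN_STAGES = ("simulate", "tracks", "binding", "quantify", "model", "nucleation")
_STAGE_ORDER = {name: i for i, name in enumerate(_KNOWN_STAGES)}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: Path
    stages: list
    options: dict

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        known_top = {"seed", "out_dir", "stages", "log_level", *_KNOWN_STAGES}
        unknown = set(raw) - known_top
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        stages = list(raw.get("stages", []))
        bad = [s for s in stages if s not in _KNOWN_STAGES]
        if bad:
            raise ConfigurationError(
                f"unknown stages {bad}; known: {list(_KNOWN_STAGES)}"
            )
        out_dir = Path(raw.get("out_dir", "results/run"))
        if base_dir is not None and not out_dir.is_absolute():
            out_dir = base_dir / out_dir
        level = raw.get("log_level", "INFO")
        logging.basicConfig()
        logger.setLevel(level)
        options = {s: dict(raw.get(s, {})) for s in _KNOWN_STAGES}
        # analyses need inputs: either the simulate stage runs first, or
        # explicit input paths must exist now
        for stage, key in (
            ("tracks", "in"),
            ("binding", "in"),
        ):
            path = options[stage].get(key)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(
                    f"{stage}.{key} references missing file {path}"
                )
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=out_dir,
            stages=stages,
            options=options,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw, base_dir=Path(path).resolve().parent)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "seed": config.seed,
            "stages": config.stages,
            "options": config.options,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "config_hash": _config_hash(config),
        "inputs": {},
        "outputs": [],
    }

    ordered = sorted(config.stages, key=_STAGE_ORDER.__getitem__)
    for stage in ordered:
        opts = config.options[stage]
        logger.info("running stage %s", stage)
        runner = _RUNNERS[stage]
        outputs = runner(config, opts, out)
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(p) for p in outputs)

    _write_json(out / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stage runners; each returns the list of files it wrote
# ---------------------------------------------------------------------------


def _run_simulate(config, opts, out: Path):
    spec = SimulationSpec(seed=config.seed, **opts)
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    write_tracks_csv(gen_brownian_tracks(spec), data_dir / "tracks.csv")
    tit = gen_titration(spec)
    import pandas as pd

    pd.DataFrame(
        {"lipid_conc_M": tit.lipid_conc, "fraction_bound": tit.fraction_bound}
    ).to_csv(data_dir / "titration.csv", index=False)
    calib, spots = gen_calibration_and_spots(spec)
    calib.to_csv(data_dir / "calibration.csv", index=False)
    spots.to_csv(data_dir / "spots.csv", index=False)
    bleach = gen_bleach_traces(spec)
    pd.DataFrame(
        {
            "trace_id": np.arange(len(bleach.step_counts)),
            "steps": bleach.step_counts,
        }
    ).to_csv(data_dir / "bleach.csv", index=False)
    return [
        data_dir / name
        for name in (
            "tracks.csv",
            "titration.csv",
            "calibration.csv",
            "spots.csv",
            "bleach.csv",
        )
    ]


def _run_tracks(config, opts, out: Path):
    path = opts.get("in", out / "data" / "tracks.csv")
    tracks = read_tracks_csv(path)
    curve = compute_msd(tracks)
    fit = fit_diffusion(curve, window_s=float(opts.get("window_s", 25.0)))
    curve.to_frame().to_csv(out / "msd.csv", index=False)
    _write_json(out / "diffusion.json", dataclasses.asdict(fit))
    return [out / "msd.csv", out / "diffusion.json"]


def _run_binding(config, opts, out: Path):
    path = opts.get("in", out / "data" / "titration.csv")
    data = read_titration_csv(path)
    fit = fit_kd(
        data,
        n_bootstrap=int(opts.get("n_bootstrap", 1000)),
        seed=config.seed,
    )
    _write_json(out / "binding.json", dataclasses.asdict(fit))
    return [out / "binding.json"]


def _run_quantify(config, opts, out: Path):
    data_dir = out / "data"
    copies, intens = read_calibration_csv(
        opts.get("calibration", data_dir / "calibration.csv")
    )
    curve = fit_calibration(copies, intens)
    spots = read_spots_csv(opts.get("spots", data_dir / "spots.csv"))
    corrected = spots["spot_sum_au"] - spots["background_sum_au"]
    est_copies = [intensity_to_copies(c, curve) for c in corrected]
    bleach = read_bleach_csv(
        opts.get("bleach", data_dir / "bleach.csv"),
        n_sites=int(opts.get("n_sites", 5)),
    )
    eff = estimate_labeling_efficiency(bleach)
    _write_json(
        out / "quantify.json",
        {
            "calibration": dataclasses.asdict(curve),
            "mean_copies_per_spot": float(np.mean(est_copies)),
            "labeling_efficiency": dataclasses.asdict(eff),
        },
    )
    return [out / "quantify.json"]


def _model_params(opts) -> ModelParams:
    if "params" in opts:
        return ModelParams.from_dict(opts["params"])
    return reference_params()


def _run_model(config, opts, out: Path):
    params = _model_params(opts)
    variant = opts.get("variant", "printed")
    state = solve_equilibrium(params, variant)
    _write_json(
        out / "equilibrium.json",
        {
            "R_nm": state.R,
            "phi_per_um2": convert_units(state.phi, "nm^-2", "um^-2")
            if not state.neck_open
            else None,
            "n_in_neck": state.n_in_neck,
            "neck_open": state.neck_open,
            "free_energy_kBT": state.free_energy,
            "variant": variant,
        },
    )
    written = [out / "equilibrium.json"]
    sweep_opts = opts.get("sweep")
    if sweep_opts:
        a_values = np.geomspace(
            float(sweep_opts.get("a_min", 1e2)),
            float(sweep_opts.get("a_max", 1e5)),
            int(sweep_opts.get("n_points", 25)),
        )
        sweep = sweep_interaction_strength(a_values, params, variant)
        sweep.to_frame(L=params.L).to_csv(out / "sweep.csv", index=False)
        written.append(out / "sweep.csv")
    return written


def _run_nucleation(config, opts, out: Path):
    R = float(opts.get("R", 6.0))
    L = float(opts.get("L", 40.0))
    phi0 = convert_units(float(opts.get("phi0_per_um2", 20.0)), "um^-2", "nm^-2")
    D = float(opts["D"]) if "D" in opts else 2800.0
    n = int(opts.get("n", 3))
    params = NucleationParams(R=R, L=L, phi0=phi0, D=D, n=n)
    result = {
        "mean_neck_count": mean_neck_count(R, L, phi0),
        "nucleation_time_s": nucleation_time(params),
        "n": n,
    }
    if "delay_s" in opts:
        inferred, flag = infer_critical_n(
            float(opts["delay_s"]), R=R, L=L, phi0=phi0, D=D
        )
        result["inferred_n"] = inferred
        result["delay_shorter_than_correlation_time"] = flag
    _write_json(out / "nucleation.json", result)
    return [out / "nucleation.json"]


_RUNNERS = {
    "simulate": _run_simulate,
    "tracks": _run_tracks,
    "binding": _run_binding,
    "quantify": _run_quantify,
    "model": _run_model,
    "nucleation": _run_nucleation,
}
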