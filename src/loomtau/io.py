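"""CSV dialects, YAML configuration, and reproducible run plumbing.

Dialects (UTF-8, header mandatory, decimal point):

* optical trace:      ``time_s, theta_rad, theta_dot_rad_s[, theta_ddot_rad_s2]``
  (degree variants ``theta_deg, theta_dot_deg_s`` are converted on read);
* firing rate:        ``t_rel_s, rate`` plus stimulus metadata
  (``half_size_m``, ``speed_m_s``) given as extra constant columns or a
  YAML sidecar;
* psychometric table: ``ttc_s, tp_s, size_label, prop_later, n_trials[, est_sd_s]``;
* score table:        one row per parameter set with all searched values
  plus ``rmse, robe, rank_rmse, rank_robe, size_label``.

Configuration is flat YAML with blocks owned by the respective modules
(``stimulus``, ``xi_params``, ``eta_params``, ``noise``, ``design``,
``trial``).  Every run artifact written by :func:`run_experiment` embeds
the resolved configuration hash and seed in a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FiringRateTrace
from .functions import EtaParams, XiParams
from .kinematics import ApproachStimulus, OpticalTrace
from .noise import NoiseSpec
from .psychophysics import ExperimentDesign, PsychometricPoint, TrialConfig

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_firing_csv",
    "write_firing_csv",
    "read_psychometric_csv",
    "write_psychometric_csv",
    "write_score_csv",
    "stimulus_from_config",
    "xi_params_from_config",
    "eta_params_from_config",
    "noise_from_config",
    "design_from_config",
    "trial_from_config",
    "load_config",
    "run_experiment",
]

DEG = np.pi / 180.0


def write_trace_csv(trace: OpticalTrace, path) -> None:
    cols = {"time_s": trace.times, "theta_rad": trace.theta, "theta_dot_rad_s": trace.theta_dot}
    if trace.theta_ddot is not None:
        cols["theta_ddot_rad_s2"] = trace.theta_ddot
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path) -> OpticalTrace:
    """Read an optical-trace CSV; degree-labelled columns are converted."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("trace CSV must have a 'time_s' column")
    if "theta_rad" in df.columns:
        theta = df["theta_rad"].to_numpy()
        theta_dot = df["theta_dot_rad_s"].to_numpy()
        ddot = df["theta_ddot_rad_s2"].to_numpy() if "theta_ddot_rad_s2" in df.columns else None
    elif "theta_deg" in df.columns:
        theta = df["theta_deg"].to_numpy() * DEG
        theta_dot = df["theta_dot_deg_s"].to_numpy() * DEG
        ddot = df["theta_ddot_deg_s2"].to_numpy() * DEG if "theta_ddot_deg_s2" in df.columns else None
    else:
        raise ValueError("trace CSV missing theta_rad/theta_deg columns")
    if df.isna().any().any():
        raise ValueError("trace CSV contains NaN values")
    times = df["time_s"].to_numpy()
    if np.any(np.diff(times) <= 0):
        raise ValueError("time_s must be strictly increasing")
    return OpticalTrace(times=times, theta=theta, theta_dot=theta_dot, theta_ddot=ddot)


def write_firing_csv(trace: FiringRateTrace, path) -> None:
    pd.DataFrame(
        {
            "t_rel_s": trace.times,
            "rate": trace.rate,
            "half_size_m": trace.stim_half_size,
            "speed_m_s": trace.stim_speed,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_firing_csv(path, half_size_m: float | None = None, speed_m_s: float | None = None) -> FiringRateTrace:
    """Read a firing-rate CSV; stimulus metadata from columns or arguments."""
    df = pd.read_csv(path)
    for col in ("t_rel_s", "rate"):
        if col not in df.columns:
            raise ValueError(f"firing-rate CSV missing column {col!r}")
    if df[["t_rel_s", "rate"]].isna().any().any():
        raise ValueError("firing-rate CSV contains NaN values")
    if half_size_m is None:
        if "half_size_m" not in df.columns:
            raise ValueError("stimulus half_size_m missing (column or argument)")
        half_size_m = float(df["half_size_m"].iloc[0])
    if speed_m_s is None:
        if "speed_m_s" not in df.columns:
            raise ValueError("stimulus speed_m_s missing (column or argument)")
        speed_m_s = float(df["speed_m_s"].iloc[0])
    return FiringRateTrace(
        times=df["t_rel_s"].to_numpy(),
        rate=df["rate"].to_numpy(),
        stim_half_size=half_size_m,
        stim_speed=speed_m_s,
    )


def write_psychometric_csv(points, path) -> None:
    pd.DataFrame(
        {
            "ttc_s": [p.ttc for p in points],
            "tp_s": [p.presentation_time for p in points],
            "size_label": [p.size_label for p in points],
            "prop_later": [p.proportion_later for p in points],
            "n_trials": [p.n_trials for p in points],
            "est_sd_s": [p.est_sd for p in points],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_psychometric_csv(path) -> list[PsychometricPoint]:
    df = pd.read_csv(path)
    needed = {"ttc_s", "tp_s", "size_label", "prop_later", "n_trials"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"psychometric CSV missing columns {sorted(missing)}")
    return [
        PsychometricPoint(
            ttc=float(r.ttc_s),
            presentation_time=float(r.tp_s),
            size_label=str(r.size_label),
            proportion_later=float(r.prop_later),
            n_trials=int(r.n_trials),
            est_sd=float(r.est_sd_s) if "est_sd_s" in df.columns and pd.notna(getattr(r, "est_sd_s", np.nan)) else None,
        )
        for r in df.itertuples()
    ]


def write_score_csv(entries, path) -> None:
    rows = []
    for e in entries:
        row = dict(e.params)
        row.update(
            rmse=e.rmse, robe=e.robe, rank_rmse=e.rank_rmse, rank_robe=e.rank_robe,
            size_label=e.size_label,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# --- configuration -------------------------------------------------------

def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _require(block: dict, key: str, block_name: str):
    if key not in block:
        raise ValueError(f"config block {block_name!r} missing key {key!r}")
    return block[key]


def stimulus_from_config(block: dict) -> ApproachStimulus:
    """Keys: half_size_m | diameter_m, speed_m_s, ttc_s, dt_s (optional)."""
    if "half_size_m" in block:
        half = float(block["half_size_m"])
    elif "diameter_m" in block:
        half = float(block["diameter_m"]) / 2.0
    else:
        raise ValueError("config block 'stimulus' missing key 'half_size_m' (or 'diameter_m')")
    return ApproachStimulus(
        half_size_R=half,
        speed_v=float(_require(block, "speed_m_s", "stimulus")),
        collision_time_tc=float(_require(block, "ttc_s", "stimulus")),
        dt=float(block.get("dt_s", 1e-3)),
    )


def xi_params_from_config(block: dict) -> XiParams:
    known = {"mu", "w", "xi_theta", "xi_theta_dot", "kappa", "eps"}
    extra = set(block) - known
    if extra:
        raise ValueError(f"unknown xi_params keys {sorted(extra)}")
    return XiParams(**{k: float(v) for k, v in block.items()})


def eta_params_from_config(block: dict) -> EtaParams:
    mapping = {"alpha": "alpha", "amplitude": "amplitude_C", "delay": "delay_delta", "baseline": "baseline"}
    extra = set(block) - set(mapping)
    if extra:
        raise ValueError(f"unknown eta_params keys {sorted(extra)}")
    return EtaParams(**{mapping[k]: float(v) for k, v in block.items()})


def noise_from_config(block: dict) -> NoiseSpec:
    return NoiseSpec(
        p_theta=float(block.get("p_theta", 0.0)),
        p_theta_dot=float(block.get("p_theta_dot", 0.0)),
        mode=str(block.get("noise_mode", "relative")),
        seed=int(block.get("seed", 0)),
        floor_at_zero=bool(block.get("floor_at_zero", False)),
    )


def design_from_config(block: dict) -> ExperimentDesign:
    kwargs = {}
    if "ttc_levels_s" in block:
        kwargs["ttc_levels"] = tuple(float(v) for v in block["ttc_levels_s"])
    if "diameters_m" in block:
        kwargs["size_levels"] = tuple(float(v) / 2.0 for v in block["diameters_m"])
    elif "half_sizes_m" in block:
        kwargs["size_levels"] = tuple(float(v) for v in block["half_sizes_m"])
    if "presentation_times_s" in block:
        kwargs["presentation_levels"] = tuple(float(v) for v in block["presentation_times_s"])
    if "t_ref_s" in block:
        kwargs["t_ref"] = float(block["t_ref_s"])
    if "d0_interval_m" in block:
        kwargs["d0_interval"] = tuple(float(v) for v in block["d0_interval_m"])
    if "d0_seed" in block:
        kwargs["d0_seed"] = int(block["d0_seed"])
    return ExperimentDesign(**kwargs)


def trial_from_config(block: dict, t_ref: float) -> TrialConfig:
    return TrialConfig(
        presentation_time_tp=float(_require(block, "tp_s", "trial")),
        reference_time_tref=t_ref,
        n_avg=int(block.get("n_avg", 50)),
        n_trials=int(block.get("n_trials", 200)),
        dt=float(block.get("dt_s", 1e-3)),
    )


# --- run plumbing --------------------------------------------------------

def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_experiment(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the pipeline named in ``config['pipeline']``.

    Supported pipelines: ``simulate`` (psychometric curves from a design
    and observer parameters) and ``kinematics`` (clean optical trace).
    Writes outputs plus ``manifest.json`` carrying the config hash, seed
    and package version; identical (config, seed) pairs give identical
    outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pipeline = config.get("pipeline")
    manifest = {
        "pipeline": pipeline,
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "version": __version__,
        "outputs": [],
        "complete": False,
    }
    if pipeline == "kinematics":
        from .kinematics import generate_trace

        stim = stimulus_from_config(config.get("stimulus", {}) or {})
        trace = generate_trace(stim, include_ddot=True)
        out = out_dir / "trace.csv"
        write_trace_csv(trace, out)
        manifest["outputs"].append(out.name)
    elif pipeline == "simulate":
        design = design_from_config(config.get("design", {}) or {})
        params = xi_params_from_config(config.get("xi_params", {}) or {})
        noise = noise_from_config(config.get("noise", {}) or {}).with_seed(seed)
        trial_block = dict(config.get("trial", {}) or {})
        trial_block.setdefault("tp_s", design.presentation_levels[0])
        cfg = trial_from_config(trial_block, design.t_ref)
        from .psychophysics import proportion_later

        points = proportion_later(design, params, noise, cfg, dt=cfg.dt)
        out = out_dir / "points.csv"
        write_psychometric_csv(points, out)
        manifest["outputs"].append(out.name)
    else:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    manifest["complete"] = True
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
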