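"""Config and dataset I/O: YAML/JSON configs, delimited-text trial and frame tables.

Every table written carries a commented header echoing the configuration
bit-exactly (JSON on ``# config:`` lines) for provenance.  Trials are long-one-
row-per-trial CSV; frames are long format (trial_id, frame_index, evidence)
with the frame duration carried by the config, not per row.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelParams, StimulusSpec, ThresholdSpec

__all__ = [
    "config_to_dict", "config_from_dict", "load_config", "save_config",
    "save_dataset", "load_dataset", "save_predictions",
]

TRIALS_REQUIRED = ("trial_id", "condition", "R", "C")
FRAMES_REQUIRED = ("trial_id", "frame_index", "evidence")


def config_to_dict(stim: StimulusSpec, params: ModelParams) -> dict:
    return {
        "stimulus": {"delta_mu": stim.delta_mu, "sigma_E": stim.sigma_E, "t_f": stim.t_f},
        "model": {
            "sigma_acc": params.sigma_acc, "sigma_phi": params.sigma_phi,
            "sigma_m": params.sigma_m, "pipeline_I": params.pipeline_I,
            "boundaries": list(params.boundaries),
            "threshold": {"family": params.threshold.family,
                          "params": list(params.threshold.params)},
        },
    }


def config_from_dict(cfg: dict):
    s = cfg["stimulus"]
    m = cfg["model"]
    th = m.get("threshold", {"family": "constant", "params": [1.0]})
    stim = StimulusSpec(delta_mu=float(s["delta_mu"]), sigma_E=float(s["sigma_E"]),
                        t_f=float(s["t_f"]))
    params = ModelParams(
        sigma_acc=float(m["sigma_acc"]), sigma_phi=float(m["sigma_phi"]),
        sigma_m=float(m["sigma_m"]), pipeline_I=float(m["pipeline_I"]),
        boundaries=tuple(float(b) for b in m["boundaries"]),
        threshold=ThresholdSpec(th["family"], tuple(th["params"])),
    )
    return stim, params


def load_config(path):
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    return config_from_dict(cfg)


def save_config(stim: StimulusSpec, params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(stim, params), sort_keys=False))


def _write_table(df: pd.DataFrame, path, config: dict | None) -> None:
    buf = _io.StringIO()
    if config is not None:
        buf.write("# config: " + json.dumps(config, sort_keys=True) + "\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def _read_table(path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    config = None
    if not path.exists():
        raise FileNotFoundError(str(path))
    lines = path.read_text().splitlines()
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            if ln.startswith("# config: "):
                config = json.loads(ln[len("# config: "):])
            body_start += 1
        else:
            break
    body = "\n".join(lines[body_start:])
    if not body.strip():
        return pd.DataFrame(), config
    return pd.read_csv(_io.StringIO(body), float_precision="round_trip"), config


def save_dataset(trials: pd.DataFrame, frames: pd.DataFrame | None, trials_path,
                 frames_path=None, config: dict | None = None) -> None:
    _write_table(trials, trials_path, config)
    if frames is not None:
        if frames_path is None:
            raise ValueError("frames_path required when frames are given")
        _write_table(frames, frames_path, config)


def load_dataset(trials_path, frames_path=None):
    """Load (trials, frames) tables with schema validation.

    Empty files yield empty DataFrames.  Raises ValueError naming the missing
    columns, the offending trial ids (frames/trials mismatch), or the rows
    with non-monotone frame indices.
    """
    trials, _ = _read_table(trials_path)
    if len(trials):
        missing = [c for c in TRIALS_REQUIRED if c not in trials.columns]
        if missing:
            raise ValueError(f"trials file {trials_path} missing columns {missing}")
    frames = None
    if frames_path is not None:
        frames, _ = _read_table(frames_path)
        if len(frames):
            missing = [c for c in FRAMES_REQUIRED if c not in frames.columns]
            if missing:
                raise ValueError(f"frames file {frames_path} missing columns {missing}")
            if len(trials):
                t_ids = set(trials["trial_id"])
                f_ids = set(frames["trial_id"])
                orphan = sorted(t_ids - f_ids)
                if orphan:
                    raise ValueError(
                        f"frames file missing trial id(s) present in trials: {orphan[:10]}"
                    )
            bad = []
            for tid, grp in frames.groupby("trial_id"):
                fi = grp["frame_index"].to_numpy()
                if np.any(np.diff(fi) <= 0):
                    bad.append(tid)
            if bad:
                raise ValueError(f"non-monotone frame indices for trial id(s): {bad[:10]}")
    return trials, frames


def save_predictions(predictions: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_table(predictions, path, config)
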