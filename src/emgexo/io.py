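"""Plain-text serialisation: trial CSVs, session manifests, model JSON,
feature/tick/report writers."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import ControlTick
from .errors import InvalidInputError
from .evaluation import EvaluationReport
from .network import BpnModel, model_from_dict, model_to_dict
from .processing import FeatureFrame
from .synth import ActivationParams, EmgRecording, TrialConfig, trial_seed

TRIAL_COLUMNS = (
    "time_s",
    "emg_biceps_uV",
    "emg_brachiorad_uV",
    "emg_triceps_uV",
    "emg_anconeus_uV",
    "angle_deg",
)


def write_trial_csv(recording: EmgRecording, path: str | Path) -> None:
    t = np.arange(recording.n_samples) / recording.fs_hz
    df = pd.DataFrame(
        dict(zip(TRIAL_COLUMNS, [t, *recording.emg_uV, recording.angle_deg]))
    )
    df.to_csv(path, index=False)


def read_trial_csv(path: str | Path, fs_hz: float | None = None) -> EmgRecording:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"trial file {path} lacks columns {sorted(missing)}")
    if fs_hz is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or np.any(dt <= 0):
            raise InvalidInputError("cannot infer sampling rate from time_s")
        fs_hz = float(round(1.0 / np.median(dt)))
    emg = df[list(TRIAL_COLUMNS[1:5])].to_numpy().T
    return EmgRecording(emg_uV=emg, angle_deg=df["angle_deg"].to_numpy(), fs_hz=fs_hz)


def write_session(
    recordings: list[EmgRecording],
    out_dir: str | Path,
    config: TrialConfig,
    params: ActivationParams,
) -> None:
    """One CSV per trial plus a JSON manifest of config, params and seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, rec in enumerate(recordings):
        name = f"trial_{i:03d}.csv"
        write_trial_csv(rec, out / name)
        names.append(name)
    manifest = {
        "config": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
        "trial_files": names,
        "trial_seeds": [trial_seed(config.seed, i) for i in range(len(recordings))],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_session(session_dir: str | Path) -> tuple[list[EmgRecording], dict]:
    out = Path(session_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    fs = manifest["config"]["fs_hz"]
    recs = [read_trial_csv(out / name, fs_hz=fs) for name in manifest["trial_files"]]
    return recs, manifest


def save_model(model: BpnModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model(path: str | Path) -> BpnModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def write_features_csv(frame: FeatureFrame, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_end_s": frame.t_end_s,
            "rms_biceps_uV": frame.rms_uV[:, 0],
            "rms_brachiorad_uV": frame.rms_uV[:, 1],
            "rms_triceps_uV": frame.rms_uV[:, 2],
            "rms_anconeus_uV": frame.rms_uV[:, 3],
        }
    )
    df.to_csv(path, index=False)


def write_ticks_csv(ticks: list[ControlTick], path: str | Path) -> None:
    rows = []
    for tick in ticks:
        cmd = tick.command
        rows.append(
            {
                "t_s": tick.t_s,
                "gated": int(tick.gated),
                "theta2_pred_deg": np.nan if tick.theta2_pred_deg is None else tick.theta2_pred_deg,
                "dP_Pa": np.nan if cmd is None else cmd.dP_Pa,
                "Pa_Pa": np.nan if cmd is None else cmd.Pa_Pa,
                "Pb_Pa": np.nan if cmd is None else cmd.Pb_Pa,
                "voltage_V": tick.voltage_V,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report_json(report: EvaluationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
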