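"""Streaming proportional myoelectric control loop.

Windowed EMG comes in; a gated valve voltage goes out. Each tick:
per-window RMS -> threshold gate -> angle prediction -> clamp to the
joint range -> differential-pressure command. Sub-threshold windows
emit a voltage of exactly 0 V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuator import ActuatorCommand, JointGeometry, MuscleParams, angle_to_command
from .errors import InvalidConfigurationError, InvalidInputError
from .network import BpnModel, forward
from .processing import WindowSpec, preprocess, rms_windows
from .synth import CHANNELS, EmgRecording


@dataclass(frozen=True)
class ControlConfig:
    """Everything one control tick needs.

    The documented latency contract: window length plus worst-case
    processing time stays under ``latency_budget_ms``.
    """

    model: BpnModel
    window: WindowSpec
    threshold_uV: float = 0.0
    geom: JointGeometry = field(default_factory=JointGeometry)
    params: MuscleParams = field(default_factory=MuscleParams)
    closure: str = "balance"
    latency_budget_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.threshold_uV < 0:
            raise InvalidConfigurationError("threshold_uV must be >= 0")
        if self.window.length_ms > self.latency_budget_ms:
            raise InvalidConfigurationError(
                f"window length {self.window.length_ms} ms exceeds the "
                f"{self.latency_budget_ms} ms latency budget"
            )


@dataclass(frozen=True)
class ControlTick:
    """One gate/predict/command step of the loop."""

    t_s: float
    rms_uV: np.ndarray  # (4,)
    gated: bool  # True when blocked below threshold
    theta2_pred_deg: float | None
    command: ActuatorCommand | None

    @property
    def voltage_V(self) -> float:
        return 0.0 if self.command is None else self.command.voltage_V


def gate(rms: np.ndarray, threshold_uV: float) -> bool:
    """True (pass) when any channel's RMS reaches the threshold.

    Ties pass: an RMS exactly at threshold counts as movement onset.
    """
    rms = np.asarray(rms, dtype=float)
    if np.any(rms < 0):
        raise InvalidInputError("RMS values must be non-negative")
    return bool(np.max(rms) >= threshold_uV)


def _tick_from_rms(rms: np.ndarray, t_s: float, config: ControlConfig) -> ControlTick:
    if not gate(rms, config.threshold_uV):
        return ControlTick(t_s=t_s, rms_uV=rms, gated=True, theta2_pred_deg=None, command=None)
    theta = forward(config.model, rms)
    lo, hi = config.geom.theta2_range_deg
    theta = float(np.clip(theta, lo, hi))
    cmd = angle_to_command(
        theta, config.geom, config.params, closure=config.closure, clamp=True
    )
    return ControlTick(t_s=t_s, rms_uV=rms, gated=False, theta2_pred_deg=theta, command=cmd)


def step(buffer: np.ndarray, config: ControlConfig, t_s: float = 0.0) -> ControlTick:
    """Process exactly one window of conditioned 4-channel EMG.

    ``buffer`` is (4, length_samples) of already-conditioned signal; the
    tick uses only those samples (causal by construction).
    """
    buffer = np.asarray(buffer, dtype=float)
    L = config.window.length_samples
    if buffer.shape != (len(CHANNELS), L):
        raise InvalidInputError(
            f"buffer must be ({len(CHANNELS)}, {L}), got {buffer.shape}"
        )
    rms = np.sqrt(np.mean(buffer**2, axis=1))
    return _tick_from_rms(rms, t_s, config)


def run_offline(recording: EmgRecording, config: ControlConfig) -> list[ControlTick]:
    """Batch replay of the streaming loop over a whole recording.

    Conditions the recording with the causal chain, then emits one tick
    per window step; the tick count equals the window-count formula.
    """
    if config.window.n_windows(recording.n_samples) == 0:
        raise InvalidInputError("recording shorter than one window")
    env = preprocess(recording)
    frame = rms_windows(env, config.window)
    return [
        _tick_from_rms(frame.rms_uV[i], float(frame.t_end_s[i]), config)
        for i in range(frame.n_windows)
    ]


def calibrate_threshold(
    rest_recording: EmgRecording, window: WindowSpec, factor: float = 3.0
) -> float:
    """Threshold = ``factor`` times the peak resting RMS across channels."""
    env = preprocess(rest_recording)
    frame = rms_windows(env, window)
    return factor * float(np.max(frame.rms_uV))
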