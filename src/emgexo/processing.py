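"""EMG conditioning chain and overlapped-window RMS feature extraction.

The conditioning chain is, per channel: causal 4th-order Butterworth
high-pass at 50 Hz, full-wave rectification, causal 4th-order
Butterworth low-pass at 10 Hz. Features are per-window RMS values
computed over 200 ms windows advanced in 50 ms steps by default.

All filtering is forward-only (causal) with zero initial conditions so
the identical chain can run inside the streaming controller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .errors import EmptyFeatureError, InvalidConfigurationError, InvalidInputError
from .synth import EmgRecording


@dataclass(frozen=True)
class FilterSpec:
    """One causal Butterworth stage."""

    kind: Literal["high_pass", "low_pass"]
    cutoff_hz: float
    fs_hz: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("high_pass", "low_pass"):
            raise InvalidConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidConfigurationError(f"order must be >= 1, got {self.order}")
        if not (0 < self.cutoff_hz < self.fs_hz / 2):
            raise InvalidConfigurationError(
                f"cutoff_hz must lie in (0, fs/2) = (0, {self.fs_hz / 2}), "
                f"got {self.cutoff_hz}"
            )

    def sos(self) -> np.ndarray:
        btype = "highpass" if self.kind == "high_pass" else "lowpass"
        return _signal.butter(self.order, self.cutoff_hz, btype=btype, fs=self.fs_hz, output="sos")


def default_highpass(fs_hz: float) -> FilterSpec:
    return FilterSpec(kind="high_pass", cutoff_hz=50.0, fs_hz=fs_hz)


def default_lowpass(fs_hz: float) -> FilterSpec:
    return FilterSpec(kind="low_pass", cutoff_hz=10.0, fs_hz=fs_hz)


@dataclass(frozen=True)
class WindowSpec:
    """Overlapped analysis window geometry.

    The default 200 ms window with a 50 ms step gives 75% overlap and a
    fresh feature every 50 ms, keeping window + processing inside a
    300 ms latency budget.
    """

    fs_hz: float
    length_ms: float = 200.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.step_ms <= self.length_ms):
            raise InvalidConfigurationError(
                f"need 0 < step_ms <= length_ms, got step={self.step_ms}, "
                f"length={self.length_ms}"
            )
        if self.fs_hz <= 0:
            raise InvalidConfigurationError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.length_samples < 1:
            raise InvalidConfigurationError("window shorter than one sample")

    @property
    def length_samples(self) -> int:
        # truncate: a partial trailing sample is never fabricated
        return int(self.length_ms * self.fs_hz / 1000.0)

    @property
    def step_samples(self) -> int:
        return max(1, int(self.step_ms * self.fs_hz / 1000.0))

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.length_samples:
            return 0
        return (n_samples - self.length_samples) // self.step_samples + 1


@dataclass(frozen=True)
class FeatureFrame:
    """Per-window RMS features aligned to window-end timestamps."""

    rms_uV: np.ndarray  # (n_windows, n_channels)
    t_end_s: np.ndarray  # (n_windows,)
    window: WindowSpec

    def __post_init__(self) -> None:
        rms = np.asarray(self.rms_uV, dtype=float)
        t = np.asarray(self.t_end_s, dtype=float)
        if rms.ndim != 2 or rms.shape[0] != t.shape[0]:
            raise InvalidInputError("rms_uV must be (n_windows, n_channels) matching t_end_s")
        if np.any(rms < 0):
            raise InvalidInputError("RMS values must be non-negative")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidInputError("t_end_s must be strictly increasing")
        object.__setattr__(self, "rms_uV", rms)
        object.__setattr__(self, "t_end_s", t)

    @property
    def n_windows(self) -> int:
        return self.rms_uV.shape[0]


def butterworth_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Causal (forward-only) Butterworth filtering with zero initial state.

    Accepts a 1-D trace or a (channels, samples) matrix; output length
    equals input length. No future samples are used, which makes the
    identical code path valid for the streaming controller.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise InvalidInputError(
            f"signal length {x.shape[-1]} too short for order-{spec.order} filter"
        )
    return _signal.sosfilt(spec.sos(), x, axis=-1)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def preprocess(recording: EmgRecording) -> np.ndarray:
    """Condition a recording: high-pass 50 Hz -> rectify -> low-pass 10 Hz.

    Returns the (4, n_samples) envelope matrix; the order of the three
    stages is part of the contract.
    """
    hp = default_highpass(recording.fs_hz)
    lp = default_lowpass(recording.fs_hz)
    return butterworth_filter(rectify(butterworth_filter(recording.emg_uV, hp)), lp)


def rms_windows(x: np.ndarray, window: WindowSpec) -> FeatureFrame:
    """Overlapped-window RMS: sqrt(mean(v_i^2)) per window and channel.

    Windows advance by ``step_samples``; a trailing partial window is
    dropped. Timestamps mark the window-end sample.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    L, S = window.length_samples, window.step_samples
    n_win = window.n_windows(n)
    if n_win == 0:
        raise EmptyFeatureError(
            f"trace of {n} samples shorter than one {L}-sample window"
        )
    sq = x**2
    # windowed means via cumulative sums: mean over [s, s+L)
    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(sq, axis=-1)], axis=-1)
    starts = np.arange(n_win) * S
    means = (csum[:, starts + L] - csum[:, starts]) / L
    rms = np.sqrt(means).T  # (n_windows, n_channels)
    t_end = (starts + L) / window.fs_hz
    return FeatureFrame(rms_uV=rms, t_end_s=t_end, window=window)


def window_end_indices(n_samples: int, window: WindowSpec) -> np.ndarray:
    """Index of the last sample inside each window (for label alignment)."""
    n_win = window.n_windows(n_samples)
    starts = np.arange(n_win) * window.step_samples
    return starts + window.length_samples - 1
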