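"""Seeded synthetic elbow flexion-extension trials.

Generates 4-channel surface-EMG traces (biceps brachii, brachioradialis,
triceps brachii, anconeus) synchronized with an elbow-angle trace, for
0-90 degree flexion-extension cycles at a configurable motion period.

The generative model is phenomenological: a smooth raised-cosine joint
trajectory drives per-muscle activation envelopes (velocity-split
agonist/antagonist terms, a gravitational load term on the flexors, a
co-contraction floor, and two switchable period-dependent degradations),
and each envelope amplitude-modulates an independent band-limited
(20-500 Hz) Gaussian carrier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import InvalidConfigurationError, InvalidInputError

#: Channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = (
    "biceps",
    "brachioradialis",
    "triceps",
    "anconeus",
)

#: Flexion peaks at this angle; trajectory spans [0, PEAK_ANGLE_DEG].
PEAK_ANGLE_DEG = 90.0

#: Shoulder angle is fixed for the single-DOF protocol.
SHOULDER_ANGLE_DEG = 90.0

#: Sensor band of the emulated acquisition chain, Hz.
CARRIER_BAND_HZ = (20.0, 500.0)

#: Hardware-style amplitude ceiling, microvolts.
MAX_AMPLITUDE_UV = 1600.0

#: Reference period used to normalise the acceleration-distortion term, so
#: the distortion amplitude scales like 1/T^2 relative to this period.
ACCEL_REF_PERIOD_S = 4.0


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one synthetic flexion-extension trial.

    Parameters
    ----------
    period_s : float
        Motion period T of one flexion-extension cycle, seconds.
    fs_hz : float
        Sampling rate; must exceed twice the carrier band upper edge.
    n_cycles : int
        Number of consecutive cycles in the trial.
    load_kg : float
        Held mass entering the flexor load term.
    seed : int
        RNG seed; identical configs produce bit-identical trials.
    amplitude_scale_uV : float
        Peak per-muscle EMG amplitude scale in microvolts, at most 1600.
    """

    period_s: float = 4.0
    fs_hz: float = 1024.0
    n_cycles: int = 1
    load_kg: float = 1.0
    seed: int = 0
    amplitude_scale_uV: float = 800.0
    shoulder_angle_deg: float = SHOULDER_ANGLE_DEG

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise InvalidConfigurationError(f"period_s must be > 0, got {self.period_s}")
        if not self.fs_hz > 2 * CARRIER_BAND_HZ[1]:
            raise InvalidConfigurationError(
                f"fs_hz must exceed {2 * CARRIER_BAND_HZ[1]} Hz to represent the "
                f"{CARRIER_BAND_HZ} Hz carrier band, got {self.fs_hz}"
            )
        if self.n_cycles < 1:
            raise InvalidConfigurationError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if not (0 <= self.amplitude_scale_uV <= MAX_AMPLITUDE_UV):
            raise InvalidConfigurationError(
                f"amplitude_scale_uV must lie in [0, {MAX_AMPLITUDE_UV}], "
                f"got {self.amplitude_scale_uV}"
            )
        if self.load_kg < 0:
            raise InvalidConfigurationError(f"load_kg must be >= 0, got {self.load_kg}")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.period_s * self.fs_hz))


@dataclass(frozen=True)
class ActivationParams:
    """Gains of the activation-envelope model.

    ``k_vel`` maps signed angular velocity to agonist activation,
    ``k_load`` maps gravitational load torque to flexor activation,
    ``k_cocontraction`` is a baseline shared by all muscles,
    ``k_accel_distort`` adds an |acceleration|-proportional corruption
    (largest at short periods), ``k_drift`` drives a per-channel random
    walk (largest accumulated effect at long periods), and
    ``synergist_ratio`` scales the synergist channel relative to its
    agonist.
    """

    k_vel: float = 0.2
    k_load: float = 0.6
    k_cocontraction: float = 0.02
    k_accel_distort: float = 0.06
    k_drift: float = 0.04
    synergist_ratio: float = 0.7

    def __post_init__(self) -> None:
        for name in ("k_vel", "k_load", "k_cocontraction", "k_accel_distort", "k_drift"):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")
        if not (0 < self.synergist_ratio <= 1):
            raise InvalidConfigurationError(
                f"synergist_ratio must lie in (0, 1], got {self.synergist_ratio}"
            )


@dataclass(frozen=True)
class EmgRecording:
    """A 4-channel EMG trace with its synchronized elbow-angle trace."""

    emg_uV: np.ndarray
    angle_deg: np.ndarray
    fs_hz: float
    labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        emg = np.asarray(self.emg_uV, dtype=float)
        ang = np.asarray(self.angle_deg, dtype=float)
        if emg.ndim != 2 or emg.shape[0] != len(self.labels):
            raise InvalidInputError(
                f"emg_uV must be ({len(self.labels)}, n_samples), got {emg.shape}"
            )
        if ang.shape != (emg.shape[1],):
            raise InvalidInputError("angle_deg length must match emg_uV columns")
        if not np.all(np.isfinite(emg)) or not np.all(np.isfinite(ang)):
            raise InvalidInputError("recording contains non-finite values")
        if np.any(ang < 0.0) or np.any(ang > 145.0):
            raise InvalidInputError("angle_deg must lie within [0, 145] degrees")
        if np.max(np.abs(emg)) > MAX_AMPLITUDE_UV + 1e-9:
            raise InvalidInputError(f"|emg_uV| must not exceed {MAX_AMPLITUDE_UV}")
        object.__setattr__(self, "emg_uV", emg)
        object.__setattr__(self, "angle_deg", ang)

    @property
    def n_samples(self) -> int:
        return self.emg_uV.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def angle_trajectory(config: TrialConfig) -> np.ndarray:
    """Raised-cosine 0-90 degree elbow trajectory.

    theta2(t) = 45 * (1 - cos(2*pi*t / T)); starts at 0 deg, peaks at
    90 deg at T/2 and returns to 0 deg at T, repeating for ``n_cycles``.
    """
    t = np.arange(config.n_samples) / config.fs_hz
    return (PEAK_ANGLE_DEG / 2.0) * (1.0 - np.cos(2.0 * np.pi * t / config.period_s))


def _velocity_accel(angle_deg: np.ndarray, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / fs_hz
    vel = np.gradient(angle_deg, dt)
    acc = np.gradient(vel, dt)
    return vel, acc


def activation_envelopes(
    angle_deg: np.ndarray,
    config: TrialConfig,
    params: ActivationParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-muscle activation envelopes in [0, 1], shape (4, n_samples).

    Flexors (biceps, brachioradialis) carry the positive-velocity term
    plus the gravitational load term; extensors (triceps, anconeus)
    carry the negative-velocity term. Synergists (brachioradialis,
    anconeus) are scaled by ``synergist_ratio``. The acceleration
    distortion is normalised against the peak acceleration of the
    reference 4-s trajectory, so it grows as 1/T^2; the drift term is a
    per-channel Gaussian random walk whose spread grows with trial
    duration.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(angle_deg)):
        raise InvalidInputError("angle trace must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    vel, acc = _velocity_accel(angle_deg, config.fs_hz)
    v_max = np.max(np.abs(vel))
    vel_pos = np.maximum(vel, 0.0) / v_max if v_max > 0 else np.zeros_like(vel)
    vel_neg = np.maximum(-vel, 0.0) / v_max if v_max > 0 else np.zeros_like(vel)

    load_term = params.k_load * config.load_kg * np.sin(np.deg2rad(angle_deg))

    flex = params.k_vel * vel_pos + load_term + params.k_cocontraction
    ext = params.k_vel * vel_neg + params.k_cocontraction

    base = np.vstack([flex, params.synergist_ratio * flex, ext, params.synergist_ratio * ext])

    if params.k_accel_distort > 0:
        # acceleration-proportional amplitude instability: smooth zero-mean
        # noise scaled by |theta''| relative to the 4-s reference peak, so
        # its spread grows as 1/T^2 and corrupts short-period trials most
        a_ref = (PEAK_ANGLE_DEG / 2.0) * (2.0 * np.pi / ACCEL_REF_PERIOD_S) ** 2
        wobble = _smooth_noise(rng, (len(CHANNELS), angle_deg.size), config.fs_hz)
        base = base + params.k_accel_distort * (np.abs(acc) / a_ref) * wobble

    if params.k_drift > 0:
        # slow speed/effort drift: integrated random walk whose spread grows
        # as t^1.5, normalised so the end-of-trace std equals k_drift at the
        # reference 4-s period; long-period trials accumulate the most
        steps = rng.standard_normal((len(CHANNELS), angle_deg.size))
        walk = np.cumsum(steps, axis=1) / np.sqrt(config.fs_hz)
        drift = np.cumsum(walk, axis=1) / config.fs_hz
        scale = params.k_drift * np.sqrt(3.0) / ACCEL_REF_PERIOD_S**1.5
        base = base + scale * drift

    return np.clip(base, 0.0, 1.0)


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs_hz: float, bw_hz: float = 2.0
) -> np.ndarray:
    """Unit-variance low-pass (slowly varying) Gaussian noise rows."""
    sos = _signal.butter(2, bw_hz, btype="lowpass", fs=fs_hz, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _bandlimited_carrier(rng: np.random.Generator, n: int, fs_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the sensor band."""
    lo, hi = CARRIER_BAND_HZ
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_trial(config: TrialConfig, params: ActivationParams | None = None) -> EmgRecording:
    """Generate one seeded trial: envelope-modulated band-limited noise."""
    if params is None:
        params = ActivationParams()
    rng = np.random.default_rng(config.seed)
    angle = angle_trajectory(config)
    env = activation_envelopes(angle, config, params, rng=rng)
    emg = np.empty_like(env)
    for ch in range(len(CHANNELS)):
        carrier = _bandlimited_carrier(rng, config.n_samples, config.fs_hz)
        emg[ch] = config.amplitude_scale_uV * env[ch] * carrier
    np.clip(emg, -MAX_AMPLITUDE_UV, MAX_AMPLITUDE_UV, out=emg)
    return EmgRecording(emg_uV=emg, angle_deg=angle, fs_hz=config.fs_hz)


def trial_seed(master_seed: int, trial_index: int) -> int:
    """Counter-based per-trial seed derivation from a session master seed."""
    ss = np.random.SeedSequence((master_seed, trial_index))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def generate_session(
    config: TrialConfig,
    params: ActivationParams | None = None,
    n_trials: int = 60,
) -> list[EmgRecording]:
    """Generate ``n_trials`` independent trials from one master seed.

    ``config.seed`` acts as the master seed; each trial uses a derived
    seed so sessions are reproducible while trials stay independent.
    """
    if n_trials < 1:
        raise InvalidConfigurationError(f"n_trials must be >= 1, got {n_trials}")
    out = []
    for i in range(n_trials):
        cfg_i = dataclasses.replace(config, seed=trial_seed(config.seed, i))
        out.append(generate_trial(cfg_i, params))
    return out
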