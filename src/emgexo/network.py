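"""From-scratch three-layer backpropagation network (4-3-1, sigmoid).

Maps the 4-muscle RMS feature vector to elbow angle. The hidden and
output nodes both use the logistic sigmoid; the network output in (0, 1)
is mapped to degrees through an explicit affine angle scaler. Training
is plain full-batch gradient descent on the mean squared error of the
scaled output.

Biases are included in both layers: a bias-free sigmoid output cannot
represent angle 0 at zero input. The angle scaler maps [0, 90] degrees
onto [0.05, 0.95] so targets never sit on the sigmoid's asymptotes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CannotSplitError,
    InvalidConfigurationError,
    InvalidInputError,
    TrainingFailureError,
)
from .processing import WindowSpec, preprocess, rms_windows, window_end_indices
from .synth import EmgRecording

N_INPUT = 4
N_HIDDEN = 3
SIGMOID_MARGIN = 0.05  # targets mapped into [margin, 1 - margin]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class LabeledDataset:
    """RMS feature rows paired with window-end elbow angles."""

    features: np.ndarray  # (n, 4)
    targets_deg: np.ndarray  # (n,)
    trial_ids: np.ndarray  # (n,) int provenance

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.targets_deg, dtype=float)
        ids = np.asarray(self.trial_ids, dtype=int)
        if X.ndim != 2 or X.shape[1] != N_INPUT:
            raise InvalidInputError(f"features must be (n, {N_INPUT}), got {X.shape}")
        if y.shape != (X.shape[0],) or ids.shape != (X.shape[0],):
            raise InvalidInputError("features, targets and trial_ids must share row count")
        if np.any(y < 0.0) or np.any(y > 145.0):
            raise InvalidInputError("targets_deg must lie within [0, 145]")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "targets_deg", y)
        object.__setattr__(self, "trial_ids", ids)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def trials(self) -> np.ndarray:
        """Unique trial ids in order of first appearance."""
        _, idx = np.unique(self.trial_ids, return_index=True)
        return self.trial_ids[np.sort(idx)]

    def subset(self, trial_ids: np.ndarray) -> "LabeledDataset":
        mask = np.isin(self.trial_ids, trial_ids)
        return LabeledDataset(
            features=self.features[mask],
            targets_deg=self.targets_deg[mask],
            trial_ids=self.trial_ids[mask],
        )


@dataclass(frozen=True)
class TrainSpec:
    """Hyperparameters of the gradient-descent training loop."""

    learning_rate: float = 5.0
    max_epochs: int = 4000
    tol: float = 1e-10
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise InvalidConfigurationError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise InvalidConfigurationError("max_epochs must be >= 1")
        if self.tol < 0:
            raise InvalidConfigurationError("tol must be >= 0")
        if not (0 <= self.momentum < 1):
            raise InvalidConfigurationError("momentum must lie in [0, 1)")


@dataclass
class BpnModel:
    """4-3-1 sigmoid network with input/angle scaling.

    ``input_offset``/``input_scale`` hold the per-feature min-max
    normalisation fitted on training data; ``angle_range_deg`` is mapped
    affinely onto ``(SIGMOID_MARGIN, 1 - SIGMOID_MARGIN)``.
    """

    w_hidden: np.ndarray  # (3, 4)
    b_hidden: np.ndarray  # (3,)
    w_out: np.ndarray  # (3,)
    b_out: float
    input_offset: np.ndarray = field(default_factory=lambda: np.zeros(N_INPUT))
    input_scale: np.ndarray = field(default_factory=lambda: np.ones(N_INPUT))
    angle_range_deg: tuple[float, float] = (0.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.w_hidden = np.asarray(self.w_hidden, dtype=float).reshape(N_HIDDEN, N_INPUT)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float).reshape(N_HIDDEN)
        self.w_out = np.asarray(self.w_out, dtype=float).reshape(N_HIDDEN)
        self.b_out = float(self.b_out)
        self.input_offset = np.asarray(self.input_offset, dtype=float).reshape(N_INPUT)
        self.input_scale = np.asarray(self.input_scale, dtype=float).reshape(N_INPUT)
        if np.any(self.input_scale == 0):
            raise InvalidConfigurationError("input_scale must be nonzero (invertible)")
        lo, hi = self.angle_range_deg
        if not hi > lo:
            raise InvalidConfigurationError("angle_range_deg must be increasing")

    # --- scaling -------------------------------------------------------
    def scale_features(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_offset) / self.input_scale

    def scale_angle(self, deg: np.ndarray) -> np.ndarray:
        lo, hi = self.angle_range_deg
        frac = (np.asarray(deg, dtype=float) - lo) / (hi - lo)
        return SIGMOID_MARGIN + frac * (1.0 - 2.0 * SIGMOID_MARGIN)

    def unscale_angle(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.angle_range_deg
        frac = (np.asarray(y, dtype=float) - SIGMOID_MARGIN) / (1.0 - 2.0 * SIGMOID_MARGIN)
        return lo + frac * (hi - lo)

    # --- network core --------------------------------------------------
    def forward_scaled(self, X_scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hidden activations, network output in (0, 1))."""
        h = sigmoid(X_scaled @ self.w_hidden.T + self.b_hidden)
        y = sigmoid(h @ self.w_out + self.b_out)
        return h, y

    def fit_input_scaler(self, X: np.ndarray) -> None:
        """Per-feature min-max normalisation fitted in place."""
        X = np.asarray(X, dtype=float)
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0] = 1.0
        self.input_offset = lo
        self.input_scale = span


def init_model(seed: int = 0, weight_scale: float = 0.5) -> BpnModel:
    """Seeded uniform(-weight_scale, weight_scale) initialisation."""
    rng = np.random.default_rng(seed)
    return BpnModel(
        w_hidden=rng.uniform(-weight_scale, weight_scale, (N_HIDDEN, N_INPUT)),
        b_hidden=rng.uniform(-weight_scale, weight_scale, N_HIDDEN),
        w_out=rng.uniform(-weight_scale, weight_scale, N_HIDDEN),
        b_out=float(rng.uniform(-weight_scale, weight_scale)),
        seed=seed,
    )


def forward(model: BpnModel, features: np.ndarray) -> np.ndarray | float:
    """Predict elbow angle(s) in degrees from raw RMS features.

    Accepts one 4-vector or an (n, 4) matrix; returns a float or an
    (n,) array accordingly.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != N_INPUT:
        raise InvalidInputError(f"expected {N_INPUT} features, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("features must be finite")
    _, y = model.forward_scaled(model.scale_features(X))
    deg = model.unscale_angle(y)
    return float(deg[0]) if single else deg


def loss_and_gradients(
    model: BpnModel, X_scaled: np.ndarray, t_scaled: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE of the scaled output and its analytic backprop gradients."""
    n = X_scaled.shape[0]
    h, y = model.forward_scaled(X_scaled)
    err = y - t_scaled
    loss = float(np.mean(err**2))
    dz2 = (2.0 / n) * err * y * (1.0 - y)  # (n,)
    g_w_out = h.T @ dz2
    g_b_out = float(np.sum(dz2))
    dh = np.outer(dz2, model.w_out)
    dz1 = dh * h * (1.0 - h)
    g_w_hidden = dz1.T @ X_scaled
    g_b_hidden = dz1.sum(axis=0)
    return loss, {
        "w_hidden": g_w_hidden,
        "b_hidden": g_b_hidden,
        "w_out": g_w_out,
        "b_out": np.asarray(g_b_out),
    }


def train(
    dataset: LabeledDataset, spec: TrainSpec | None = None
) -> tuple[BpnModel, np.ndarray]:
    """Full-batch gradient descent; returns the model and per-epoch loss.

    The input scaler is fitted on ``dataset`` (the caller passes the
    training split only). Deterministic given ``spec.seed``.
    """
    if spec is None:
        spec = TrainSpec()
    if dataset.n_rows == 0:
        raise InvalidInputError("cannot train on an empty dataset")

    model = init_model(spec.seed)
    model.fit_input_scaler(dataset.features)
    X = model.scale_features(dataset.features)
    t = model.scale_angle(dataset.targets_deg)

    vel = {k: 0.0 for k in ("w_hidden", "b_hidden", "w_out", "b_out")}
    losses = np.empty(spec.max_epochs)
    prev = np.inf
    n_epochs = 0
    for epoch in range(spec.max_epochs):
        loss, grads = loss_and_gradients(model, X, t)
        if not np.isfinite(loss):
            raise TrainingFailureError(f"loss diverged at epoch {epoch}", epoch=epoch)
        losses[epoch] = loss
        n_epochs = epoch + 1
        # stop only on a *non-negative* improvement smaller than tol, so
        # transient momentum-driven loss bumps don't end training early
        if spec.tol > 0 and epoch > 0 and 0.0 <= prev - loss < spec.tol:
            break
        prev = loss
        for key in vel:
            vel[key] = spec.momentum * vel[key] - spec.learning_rate * grads[key]
        model.w_hidden = model.w_hidden + vel["w_hidden"]
        model.b_hidden = model.b_hidden + vel["b_hidden"]
        model.w_out = model.w_out + vel["w_out"]
        model.b_out = model.b_out + float(vel["b_out"])
    return model, losses[:n_epochs]


# --- dataset assembly ---------------------------------------------------


def make_dataset(
    recordings: list[EmgRecording], window: WindowSpec
) -> LabeledDataset:
    """Condition each trial, window it, and label each window causally.

    The target of each row is the elbow angle at the window-end sample,
    so labels never use information past the window. Trials shorter than
    one window are skipped with a warning.
    """
    if not recordings:
        raise InvalidInputError("recordings must be nonempty")
    feats, targs, ids = [], [], []
    n_skipped = 0
    for i, rec in enumerate(recordings):
        if window.n_windows(rec.n_samples) == 0:
            n_skipped += 1
            continue
        env = preprocess(rec)
        frame = rms_windows(env, window)
        end_idx = window_end_indices(rec.n_samples, window)
        feats.append(frame.rms_uV)
        targs.append(rec.angle_deg[end_idx])
        ids.append(np.full(frame.n_windows, i))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} trial(s) shorter than one window", stacklevel=2)
    if not feats:
        raise InvalidInputError("no trial was long enough for a single window")
    return LabeledDataset(
        features=np.vstack(feats),
        targets_deg=np.concatenate(targs),
        trial_ids=np.concatenate(ids),
    )


def split_data(
    dataset: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded whole-trial split: every window of a trial lands on one side.

    Trial counts follow round(n_trials * train_fraction), clamped so
    both sides stay nonempty; 60 trials at 0.8 give 48 train / 12 test.
    """
    if not (0 < train_fraction < 1):
        raise InvalidConfigurationError("train_fraction must lie in (0, 1)")
    trials = dataset.trials
    if trials.size < 2:
        raise CannotSplitError(f"need at least 2 trials to split, got {trials.size}")
    n_train = int(round(trials.size * train_fraction))
    n_train = min(max(n_train, 1), trials.size - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(trials)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


# --- persistence --------------------------------------------------------


def model_to_dict(model: BpnModel) -> dict:
    return {
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out,
        "input_offset": model.input_offset.tolist(),
        "input_scale": model.input_scale.tolist(),
        "angle_range_deg": list(model.angle_range_deg),
        "seed": model.seed,
    }


def model_from_dict(d: dict) -> BpnModel:
    return BpnModel(
        w_hidden=np.asarray(d["w_hidden"]),
        b_hidden=np.asarray(d["b_hidden"]),
        w_out=np.asarray(d["w_out"]),
        b_out=d["b_out"],
        input_offset=np.asarray(d["input_offset"]),
        input_scale=np.asarray(d["input_scale"]),
        angle_range_deg=tuple(d["angle_range_deg"]),
        seed=int(d.get("seed", 0)),
    )
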