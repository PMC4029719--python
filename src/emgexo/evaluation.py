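"""Prediction-quality statistics and power-assist comparison summaries.

RMSE is sqrt(mean((predicted - actual)^2)); R^2 is the coefficient of
determination 1 - SS_res/SS_tot with residuals about the predictions
and total variation about the actual-series mean; the regression line
is the ordinary least squares fit of predicted on actual (actual on the
x-axis), whose ideal slope/intercept are 1 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidInputError, UndefinedStatisticError
from .network import BpnModel, LabeledDataset, forward
from .processing import WindowSpec, preprocess, rms_windows
from .synth import CHANNELS, EmgRecording


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE, R^2 and regression slope/intercept for one model/test pair."""

    rmse_deg: float
    r2: float
    k: float
    j_deg: float
    n: int
    period_s: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AssistComparison:
    """Per-muscle mean RMS by experimental condition, plus assist ratios."""

    conditions: tuple[str, ...]
    mean_rms_uV: dict[str, np.ndarray]  # condition -> (4,) per-muscle means
    reduction_ratios: np.ndarray | None  # powered / unpowered, (4,)
    labels: tuple[str, ...] = CHANNELS


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape or p.size == 0:
        raise InvalidInputError(
            f"predicted and actual must be equal-length and nonempty, "
            f"got {p.shape} vs {a.shape}"
        )
    return p, a


def rmse(predicted, actual) -> float:
    """Root-mean-square prediction error in degrees."""
    p, a = _paired(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def r_squared(predicted, actual) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    p, a = _paired(predicted, actual)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("actual series has zero variance")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def regression_line(actual, predicted) -> tuple[float, float]:
    """OLS fit of predicted on actual; returns (slope k, intercept j)."""
    p, a = _paired(predicted, actual)
    if a.size < 2:
        raise InvalidInputError("need at least 2 points for a regression line")
    var = float(np.sum((a - a.mean()) ** 2))
    if var == 0:
        raise UndefinedStatisticError("regressor (actual series) is degenerate")
    k = float(np.sum((a - a.mean()) * (p - p.mean())) / var)
    j = float(p.mean() - k * a.mean())
    return k, j


def evaluate_model(
    model: BpnModel,
    test_set: LabeledDataset,
    period_s: float | None = None,
) -> EvaluationReport:
    """Predict every test row and summarise with RMSE, R^2, k and j."""
    if test_set.n_rows == 0:
        raise InvalidInputError("test set is empty")
    pred = forward(model, test_set.features)
    actual = test_set.targets_deg
    k, j = regression_line(actual, pred)
    return EvaluationReport(
        rmse_deg=rmse(pred, actual),
        r2=r_squared(pred, actual),
        k=k,
        j_deg=j,
        n=test_set.n_rows,
        period_s=period_s,
    )


def assist_comparison(
    sessions: dict[str, list[EmgRecording]],
    window: WindowSpec,
    powered: str = "exo_powered",
    unpowered: str = "exo_unpowered",
) -> AssistComparison:
    """Mean per-muscle RMS under each condition and powered/unpowered ratios."""
    if not sessions:
        raise InvalidInputError("no conditions given")
    means: dict[str, np.ndarray] = {}
    for label, recs in sessions.items():
        if not recs:
            raise InvalidInputError(f"condition {label!r} has no recordings")
        frames = [rms_windows(preprocess(rec), window).rms_uV for rec in recs]
        means[label] = np.vstack(frames).mean(axis=0)
    ratios = None
    if powered in means and unpowered in means:
        ratios = means[powered] / means[unpowered]
    return AssistComparison(
        conditions=tuple(sessions),
        mean_rms_uV=means,
        reduction_ratios=ratios,
    )
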