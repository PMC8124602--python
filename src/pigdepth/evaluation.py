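"""Test-set metrics: per-target RMSE / MAE / MRE / R^2, aggregate MSE and
mean estimation time."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from pigdepth.labels import LABEL_NAMES

__all__ = [
    "rmse",
    "mae",
    "mre",
    "r_squared",
    "TargetMetrics",
    "MetricsReport",
    "evaluate",
]


def _as_pair(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(estimated, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def rmse(measured, estimated) -> float:
    """Root mean square error."""
    y, yhat = _as_pair(measured, estimated)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(measured, estimated) -> float:
    """Mean absolute error."""
    y, yhat = _as_pair(measured, estimated)
    return float(np.mean(np.abs(y - yhat)))


def mre(measured, estimated) -> float:
    """Mean relative error, in percent, with the measured value as
    denominator."""
    y, yhat = _as_pair(measured, estimated)
    if np.any(y == 0):
        raise ValueError("mre undefined: measured contains zero values")
    return float(np.mean(np.abs(y - yhat) / np.abs(y)) * 100.0)


def r_squared(measured, estimated) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot, SS_tot about the
    mean of the measured values."""
    y, yhat = _as_pair(measured, estimated)
    if y.size < 2:
        raise ValueError("r_squared needs at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined: measured values are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class TargetMetrics:
    rmse: float
    mae: float
    mre: float
    r_squared: float


@dataclass
class MetricsReport:
    """Per-target metrics plus the aggregates printed alongside them.

    ``total_mse`` is the sum over the six targets of the per-target mean
    squared errors (mixed kg^2/cm^2 units, reported as-is);
    ``mean_estimation_time_ms`` is wall-clock per image and is report-only.
    """

    per_target: dict[str, TargetMetrics] = field(default_factory=dict)
    total_mse: float = float("nan")
    mean_estimation_time_ms: float = float("nan")

    def to_dict(self) -> dict:
        out: dict = {}
        for name, m in self.per_target.items():
            out[name] = {
                "rmse": m.rmse,
                "mae": m.mae,
                "mre_percent": m.mre,
                "r_squared": m.r_squared,
            }
        out["total_mse"] = self.total_mse
        out["mean_estimation_time_ms"] = self.mean_estimation_time_ms
        return out


def evaluate(model, images: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Run ``model.predict`` over preprocessed gray images and compute the
    full report against measured labels (rows ordered as LABEL_NAMES)."""
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != len(LABEL_NAMES):
        raise ValueError(f"labels must be (n, {len(LABEL_NAMES)}), got {labels.shape}")
    n = labels.shape[0]
    t0 = time.perf_counter()
    preds = model.predict(images)
    elapsed = time.perf_counter() - t0
    preds = np.asarray(preds, dtype=float)
    if preds.shape != labels.shape:
        raise ValueError(f"prediction shape {preds.shape} != labels {labels.shape}")

    report = MetricsReport()
    total = 0.0
    for j, name in enumerate(LABEL_NAMES):
        y, yhat = labels[:, j], preds[:, j]
        report.per_target[name] = TargetMetrics(
            rmse=rmse(y, yhat),
            mae=mae(y, yhat),
            mre=mre(y, yhat),
            r_squared=r_squared(y, yhat),
        )
        total += float(np.mean((y - yhat) ** 2))
    report.total_mse = total
    report.mean_estimation_time_ms = elapsed / n * 1000.0
    return report
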