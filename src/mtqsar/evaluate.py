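"""Regression metrics (Pearson r, RMSE, MAE) and repeated-run
aggregation.

Metrics follow the standard definitions:

    r    = sum((yhat - mean(yhat)) (y - mean(y)))
           / sqrt(sum((yhat - mean(yhat))^2) sum((y - mean(y))^2))
    RMSE = sqrt(mean((yhat - y)^2))
    MAE  = mean(|yhat - y|)

For multitask models, metrics are computed per task over observed
(mask = 1) cells of the requested partition; run-level results are
aggregated as mean +/- sample standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import TaskMatrix, TrainedModel, predict
from .split import Split


def _pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted vectors must match in length")
    return y, yhat


def pearson_r(y, yhat) -> float:
    """Pearson correlation; NaN (with a warning) for constant vectors."""
    y, yhat = _pair(y, yhat)
    if len(y) < 2:
        raise ValueError("need n >= 2 for a correlation")
    dy = y - y.mean()
    dyh = yhat - yhat.mean()
    denom = np.sqrt((dyh * dyh).sum() * (dy * dy).sum())
    if denom == 0.0:
        warnings.warn("constant vector: Pearson r undefined", stacklevel=2)
        return float("nan")
    return float((dyh * dy).sum() / denom)


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def evaluate_model(
    model: TrainedModel,
    data: TaskMatrix,
    fingerprints: np.ndarray,
    split: Split,
    partition: str = "test",
    run: int | None = None,
) -> pd.DataFrame:
    """Per-task metric table over observed cells of one partition."""
    idx = getattr(split, partition)
    pred = predict(model, np.asarray(fingerprints)[idx])
    if pred.ndim == 1:
        pred = pred[:, None]
    rows = []
    for j, tid in enumerate(data.task_ids[: pred.shape[1]]):
        m = data.mask[idx, j].astype(bool)
        if m.sum() < 2:
            continue
        y = data.values[idx, j][m]
        yh = pred[m, j]
        rows.append(dict(task_id=tid, partition=partition,
                         run=split.run_index if run is None else run,
                         n=int(m.sum()), r=pearson_r(y, yh),
                         rmse=rmse(y, yh), mae=mae(y, yh)))
    return pd.DataFrame(rows)


def aggregate(per_run: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD of each metric per task (plus a __global__ row)
    over splitting runs.

    Single-run input yields SD 0 with ``single_run=True`` flagged; the
    task sets of all runs must agree.
    """
    if len(per_run) == 0:
        raise ValueError("no metric rows to aggregate")
    runs = sorted(per_run["run"].unique())
    task_sets = {
        r: frozenset(per_run.loc[per_run["run"] == r, "task_id"]) for r in runs
    }
    if len(set(task_sets.values())) > 1:
        raise ValueError(f"task sets differ across runs: {task_sets}")
    single = len(runs) == 1

    def _summarize(grp, label):
        row = dict(task_id=label, n_runs=len(runs), single_run=single)
        for metric in ("r", "rmse", "mae"):
            per_run_vals = grp.groupby("run")[metric].mean()
            row[f"{metric}_mean"] = float(per_run_vals.mean())
            row[f"{metric}_sd"] = (
                0.0 if single else float(per_run_vals.std(ddof=1))
            )
        return row

    rows = [
        _summarize(grp, tid) for tid, grp in per_run.groupby("task_id", sort=True)
    ]
    rows.append(_summarize(per_run, "__global__"))
    return pd.DataFrame(rows)
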