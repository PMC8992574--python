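"""Model accuracy metrics, the GPI composite ranking, and confusion summaries.

Metric conventions follow the reporting conventions of the greenhouse-grape
ripeness literature rather than the textbook forms, and are kept exactly as
reported there:

* ``R^2`` is the squared Pearson correlation between measured and estimated
  series (the per-element squared-cross-term variant breaks the
  Cauchy-Schwarz bound and cannot produce the published in-[0,1] values).
* ``RMSE`` uses an ``n - 1`` denominator.
* ``d`` (consistency index) is ``1 - sum (X_i - Y_i)^2 /
  sum (|Y_i - Ybar| + |X_i - Xbar|)^2`` with each deviation taken about its
  *own* series mean, which differs from the canonical Willmott index of
  agreement (deviations about the observed mean); documented, not "fixed".
* ``GPI`` for model m is ``sum_j alpha_j (Obar_j - O_{j,m})`` where ``O_j``
  is the min-max normalization of metric j across models, ``Obar_j`` its
  median, ``alpha = +1`` for MAE and RMSE and ``-1`` for R^2 and d.  Higher
  GPI means a better overall model; ranks are 1-based by descending GPI with
  ties kept in input order.

Maturity-level judging rounds a continuous Mc prediction to the nearest 0.1
(half-up), clips it to the ripening band [0.7, 1.0], and counts correct /
overestimated / underestimated outcomes; rates are percentages rounded to
one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricSet",
    "GPIResult",
    "ConfusionSummary",
    "RIPENING_LEVELS",
    "compute_metrics",
    "compute_gpi",
    "judge_levels",
    "per_level_accuracy",
]

RIPENING_LEVELS = (0.7, 0.8, 0.9, 1.0)

_METRIC_ALPHA = {"r2": -1.0, "mae": 1.0, "rmse": 1.0, "d": -1.0}


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    mae: float
    d: float
    n: int


@dataclass
class GPIResult:
    models: list[str]
    gpi: dict[str, float]
    rank: dict[str, int]                      # 1 = best (highest GPI)
    normalization: dict[str, dict[str, float]]   # per metric: min, max, median
    alpha: dict[str, float]


@dataclass
class ConfusionSummary:
    total: int
    correct: int
    overestimated: int
    underestimated: int
    accuracy: float          # percent, 1 decimal
    over_rate: float
    under_rate: float
    per_level: dict[float, dict[str, float | int | None]]

    @classmethod
    def from_counts(cls, correct: int, overestimated: int, underestimated: int,
                    per_level: dict | None = None,
                    total: int | None = None) -> "ConfusionSummary":
        """Summary from outcome counts.  ``total`` defaults to the count sum;
        pass it explicitly when the sample size is known independently (some
        published tables have counts that undershoot the stated total)."""
        if total is None:
            total = correct + overestimated + underestimated
        elif total < correct + overestimated + underestimated:
            raise ValueError("total smaller than the sum of outcome counts")
        return cls(total=total, correct=correct, overestimated=overestimated,
                   underestimated=underestimated,
                   accuracy=_pct(correct, total), over_rate=_pct(overestimated, total),
                   under_rate=_pct(underestimated, total), per_level=per_level or {})


def _pct(count: int, total: int) -> float:
    return _round_half_up(100.0 * count / total, 1)


def _round_half_up(x: float, nd: int) -> float:
    scale = 10.0**nd
    return math.floor(x * scale + 0.5) / scale


def compute_metrics(measured, estimated) -> MetricSet:
    """R^2, RMSE (n-1 denominator), MAE, and the consistency index d."""
    X = np.asarray(measured, dtype=float)
    Y = np.asarray(estimated, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("measured and estimated must be 1-D of equal length")
    n = X.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(X) == 0:
        raise ValueError("measured series is constant; R^2 undefined")
    if np.ptp(Y) == 0:
        r2 = 0.0   # no linear association with a constant estimate
    else:
        r2 = float(np.corrcoef(X, Y)[0, 1] ** 2)
    resid = Y - X
    rmse = float(np.sqrt(np.sum(resid**2) / (n - 1)))
    mae = float(np.mean(np.abs(resid)))
    denom = float(np.sum((np.abs(Y - Y.mean()) + np.abs(X - X.mean())) ** 2))
    d = 1.0 - float(np.sum(resid**2)) / denom if denom > 0 else 0.0
    return MetricSet(r2=r2, rmse=rmse, mae=mae, d=d, n=n)


def _minmax(values: np.ndarray) -> np.ndarray:
    span = values.max() - values.min()
    if span == 0:
        return np.zeros_like(values)   # constant metric carries no information
    return (values - values.min()) / span


def compute_gpi(metric_sets: dict[str, MetricSet]) -> GPIResult:
    """GPI and 1-based descending ranks across >= 2 competing models."""
    if len(metric_sets) < 2:
        raise ValueError("GPI needs at least 2 models to compare")
    models = list(metric_sets)
    gpi = np.zeros(len(models))
    normalization: dict[str, dict[str, float]] = {}
    for metric, alpha in _METRIC_ALPHA.items():
        raw = np.array([getattr(metric_sets[m], metric) for m in models], dtype=float)
        O = _minmax(raw)
        Obar = float(np.median(O))
        gpi += alpha * (Obar - O)
        normalization[metric] = {"min": float(raw.min()), "max": float(raw.max()),
                                 "median_normalized": Obar}
    order = np.argsort(-gpi, kind="stable")
    ranks = np.empty(len(models), dtype=int)
    ranks[order] = np.arange(1, len(models) + 1)
    return GPIResult(
        models=models,
        gpi={m: float(g) for m, g in zip(models, gpi)},
        rank={m: int(r) for m, r in zip(models, ranks)},
        normalization=normalization,
        alpha=dict(_METRIC_ALPHA),
    )


def _to_level(mc: np.ndarray) -> np.ndarray:
    """Round to the nearest 0.1 (half-up) and clip to the ripening band."""
    rounded = np.floor(np.asarray(mc, float) * 10.0 + 0.5) / 10.0
    return np.clip(rounded, RIPENING_LEVELS[0], RIPENING_LEVELS[-1])


def judge_levels(predicted_mc, true_level) -> ConfusionSummary:
    """Judge ripening-period predictions against true 0.1-grid levels."""
    pred = np.asarray(predicted_mc, dtype=float)
    true = np.asarray(true_level, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predicted and true series must be 1-D of equal length")
    on_grid = np.isclose(true * 10.0, np.rint(true * 10.0), atol=1e-6)
    if not np.all(on_grid):
        raise ValueError("true levels must lie on the 0.1 grid")
    if np.any(true < RIPENING_LEVELS[0] - 1e-9) or np.any(true > RIPENING_LEVELS[-1] + 1e-9):
        raise ValueError(f"true levels must lie in {RIPENING_LEVELS}")
    true = np.rint(true * 10.0) / 10.0
    pred_level = _to_level(pred)
    diff = np.rint((pred_level - true) * 10.0).astype(int)
    correct = int(np.sum(diff == 0))
    over = int(np.sum(diff > 0))
    under = int(np.sum(diff < 0))
    per_level = _per_level_counts(diff, true)
    return ConfusionSummary.from_counts(correct, over, under, per_level)


def _per_level_counts(diff: np.ndarray, true: np.ndarray) -> dict:
    table: dict[float, dict[str, float | int | None]] = {}
    for level in RIPENING_LEVELS:
        sel = np.isclose(true, level)
        n = int(sel.sum())
        row: dict[str, float | int | None] = {
            "n": n,
            "correct": int(np.sum(diff[sel] == 0)),
            "overestimated": int(np.sum(diff[sel] > 0)),
            "underestimated": int(np.sum(diff[sel] < 0)),
        }
        row["accuracy"] = _pct(row["correct"], n) if n else None   # undefined bucket
        table[level] = row
    return table


def per_level_accuracy(predicted_mc, true_level) -> pd.DataFrame:
    """Per-level n / correct / over / under / accuracy% table."""
    summary = judge_levels(predicted_mc, true_level)
    rows = [{"level": lv, **counts} for lv, counts in summary.per_level.items()]
    return pd.DataFrame(rows)
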