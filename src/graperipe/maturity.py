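"""Maturity-coefficient (Mc) construction from indicator change rates.

The ripening season is divided into an immature stage and a mature
(color-changing) stage by watching how fast the min-max-normalized
indicators change per week.  The stage boundary (Mc = 0.7) is the first week
from which the *chemical* indicators (SSC, titratable acid, SSC/acid) change
by less than the settling threshold per week through harvest; full maturity
(Mc = 1.0) is the first week from which *all* indicators do.  Between the
anchors (0.1 at the first monitored week, 0.7 at the boundary, 1.0 at full
maturity) Mc is interpolated linearly and quantized to the 0.1 grid.

"Rate of change" is the absolute first difference of the normalized value
divided by the week spacing; the suffix ("stays below through harvest")
condition makes detection robust to a single early dip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import IndicatorSeries

__all__ = [
    "NormalizedSeries",
    "ChangeRateSeries",
    "McTimeline",
    "CHEMICAL_INDICATORS",
    "ConstantIndicatorError",
    "NoSettlingError",
    "normalize_indicators",
    "change_rates",
    "find_boundaries",
    "assign_mc",
    "construct_mc_timeline",
    "write_mc_csv",
    "read_mc_csv",
]

CHEMICAL_INDICATORS = ("ssc", "titratable_acid", "ssc_acid_ratio")

DEFAULT_SETTLE_THRESHOLD = 0.2   # normalized change per week


class ConstantIndicatorError(ValueError):
    """An indicator is constant over the window and cannot be normalized."""


class NoSettlingError(ValueError):
    """No week from which the watched rates stay below the threshold."""


@dataclass
class NormalizedSeries:
    weeks: np.ndarray
    values: dict[str, np.ndarray]    # each min-max scaled to [0, 1]


@dataclass
class ChangeRateSeries:
    """Per-interval absolute normalized change rates (per week)."""

    interval_start: np.ndarray   # week at which each interval begins
    interval_end: np.ndarray
    rates: dict[str, np.ndarray]

    @property
    def weeks(self) -> np.ndarray:
        return np.append(self.interval_start, self.interval_end[-1])


@dataclass
class McTimeline:
    weeks: np.ndarray
    mc: np.ndarray               # values on the 0.1 grid, non-decreasing
    stage: list[str]             # "immature" | "mature"  (mature iff mc >= 0.7)
    boundary_week: float
    full_maturity_week: float
    mc_raw: np.ndarray | None = None   # continuous ramp before 0.1 quantization

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"week": self.weeks, "mc": self.mc, "stage": self.stage})
        if self.mc_raw is not None:
            df["mc_raw"] = self.mc_raw
        return df


def normalize_indicators(series: IndicatorSeries) -> NormalizedSeries:
    """Min-max scale every indicator to [0, 1] over the monitored window."""
    values = {}
    for name in IndicatorSeries.INDICATORS:
        x = np.asarray(getattr(series, name), dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ConstantIndicatorError(f"indicator {name!r} is constant over the window")
        values[name] = (x - lo) / (hi - lo)
    return NormalizedSeries(weeks=np.asarray(series.week, float), values=values)


def change_rates(norm: NormalizedSeries) -> ChangeRateSeries:
    """Absolute normalized change per week for each sampling interval."""
    weeks = np.asarray(norm.weeks, dtype=float)
    if weeks.size < 2:
        raise ValueError("need at least 2 weeks to compute change rates")
    dw = np.diff(weeks)
    if np.any(dw == 0):
        raise ValueError("duplicate weeks in the series")
    rates = {name: np.abs(np.diff(v)) / dw for name, v in norm.values.items()}
    return ChangeRateSeries(interval_start=weeks[:-1], interval_end=weeks[1:], rates=rates)


def _first_settled_week(rates: ChangeRateSeries, names, threshold: float) -> float:
    stacked = np.vstack([rates.rates[n] for n in names])   # (indicators, intervals)
    quiet = np.all(stacked < threshold, axis=0)
    # suffix condition: all intervals from the candidate week onward are quiet
    settled_from = np.flip(np.cumprod(np.flip(quiet))).astype(bool)
    hits = np.flatnonzero(settled_from)
    if hits.size == 0:
        raise NoSettlingError(
            "rates never stay below the threshold through harvest; "
            "monitor a longer window or raise the threshold"
        )
    return float(rates.interval_start[hits[0]])


def find_boundaries(rates: ChangeRateSeries,
                    settle_threshold: float = DEFAULT_SETTLE_THRESHOLD
                    ) -> tuple[float, float]:
    """Stage boundary (chemical indicators settled) and full-maturity week
    (all indicators settled), each as the first week from which the relevant
    rates stay below ``settle_threshold`` through harvest."""
    if not settle_threshold > 0:
        raise ValueError("settle_threshold must be positive")
    boundary = _first_settled_week(rates, CHEMICAL_INDICATORS, settle_threshold)
    full = _first_settled_week(rates, list(rates.rates), settle_threshold)
    return boundary, full


def _round_to_grid(x: np.ndarray) -> np.ndarray:
    # half-up to the nearest 0.1 (platform-independent, no banker's rounding)
    return np.floor(x * 10.0 + 0.5) / 10.0


def assign_mc(weeks, boundary_week: float, full_maturity_week: float) -> McTimeline:
    """Piecewise-linear Mc: 0.1 at the first monitored week, 0.7 at the
    stage boundary, 1.0 at full maturity, constant 1.0 afterwards; quantized
    to the 0.1 grid (half-up), never exceeding 1.0."""
    weeks = np.asarray(weeks, dtype=float)
    if not weeks[0] < boundary_week < full_maturity_week:
        raise ValueError(
            "need first week < boundary_week < full_maturity_week "
            f"(got {weeks[0]}, {boundary_week}, {full_maturity_week})"
        )
    raw = np.where(
        weeks <= boundary_week,
        0.1 + 0.6 * (weeks - weeks[0]) / (boundary_week - weeks[0]),
        0.7 + 0.3 * (weeks - boundary_week) / (full_maturity_week - boundary_week),
    )
    raw = np.minimum(raw, 1.0)
    mc = np.minimum(_round_to_grid(raw), 1.0)
    stage = ["mature" if v >= 0.7 else "immature" for v in mc]
    return McTimeline(weeks=weeks, mc=mc, stage=stage,
                      boundary_week=float(boundary_week),
                      full_maturity_week=float(full_maturity_week),
                      mc_raw=raw)


def construct_mc_timeline(series: IndicatorSeries,
                          settle_threshold: float = DEFAULT_SETTLE_THRESHOLD) -> McTimeline:
    """End-to-end Mc construction from an indicator table."""
    rates = change_rates(normalize_indicators(series))
    boundary, full = find_boundaries(rates, settle_threshold)
    return assign_mc(series.week, boundary, full)


def write_mc_csv(timeline: McTimeline, path) -> None:
    timeline.to_frame().to_csv(path, index=False)


def read_mc_csv(path) -> McTimeline:
    df = pd.read_csv(path)
    mc = df["mc"].to_numpy(float)
    weeks = df["week"].to_numpy(float)
    raw = df["mc_raw"].to_numpy(float) if "mc_raw" in df.columns else None
    # anchors are exact on the raw ramp; the quantized labels only bound them
    ramp = raw if raw is not None else mc
    boundary = float(weeks[np.flatnonzero(ramp >= 0.7 - 1e-12)[0]])
    full = float(weeks[np.flatnonzero(ramp >= 1.0 - 1e-12)[0]])
    return McTimeline(weeks=weeks, mc=mc, stage=list(df["stage"]),
                      boundary_week=boundary, full_maturity_week=full, mc_raw=raw)
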