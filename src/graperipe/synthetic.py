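"""Synthetic greenhouse-grape phenology, skin-color trajectories, and berry images.

This module emulates the measurement campaign that the rest of the package
analyses: weekly physical/chemical indicator tables for three table-grape
variety archetypes, per-week mean skin RGB trajectories, and rendered
berry-cluster images on a near-white reference board with exact ground-truth
masks.  Every generator is a pure function of its inputs and a seed, so all
downstream stages (segmentation, maturity-coefficient construction, network
training) are testable without field data.

Growth model
------------
Weight, the two berry diameters, and soluble solid content (SSC) follow
logistic ("slow-fast-slow") curves, affinely rescaled so they hit their
configured start value at week 4 post-flowering and their final value exactly
at harvest.  Chemistry (SSC) is centred midway between week 4 and the stage
boundary, i.e. sugar accumulation is essentially complete at veraison, while
berry sizing is centred 2.5 weeks before harvest and is still finishing when
the fruit is picked.  Titratable acid rises to a mid-season peak and then
declines to its final value at the stage boundary.  Cluster compactness
(bounding-box area over fruit area) decays exponentially to a plateau.
The SSC/acid ratio is always the exact ratio of the (noisy) SSC and acid
columns, never an independent draw.

Noise model
-----------
Each weekly value is the mean over ``n_clusters`` monitored clusters; each
cluster observation carries multiplicative Gaussian noise with relative
standard deviation ``noise_sd``, truncated at +-3 sd so values stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "ChannelTrajectory",
    "VarietyArchetype",
    "TrajectoryConfig",
    "IndicatorSeries",
    "ColorSeries",
    "SyntheticImage",
    "DEFAULT_ARCHETYPES",
    "default_weeks",
    "generate_indicator_series",
    "generate_color_series",
    "render_cluster_image",
    "write_indicator_csv",
    "read_indicator_csv",
    "write_color_csv",
    "read_color_csv",
    "save_image_png",
    "load_image_png",
    "archetype_to_yaml",
    "archetype_from_yaml",
]

FIRST_WEEK = 4.0  # monitoring starts four weeks post-flowering

# Fraction of the final value at which each sigmoid indicator starts.
_START_FRACTION = {"weight": 0.05, "long_diam": 0.25, "horiz_diam": 0.25}
_SSC_START = 4.0            # % soluble solids of green berries
_COMPACTNESS_START_EXTRA = 1.0   # initial compactness = final + this
_TA_DECLINE_SHAPE = 0.8     # concave post-peak acid decline exponent
_PHYSICAL_MIDPOINT_OFFSET = 2.5  # sizing logistic midpoint: harvest - 2.5 wk
_PHYSICAL_RATE = 1.2             # sizing logistic steepness, 1/week

CHANNELS = ("r", "g", "b")
_MODES = ("monotone_increasing", "monotone_decreasing", "unimodal")


class ArchetypeValidationError(ValueError):
    """An archetype field violates its invariants."""


@dataclass(frozen=True)
class ChannelTrajectory:
    """Noise-free trajectory of one skin-color channel over the season.

    ``monotone_*`` modes ease from ``start`` to ``end`` over
    [week 4, harvest]; ``unimodal`` rises to ``peak_value`` at ``peak_week``
    and falls back to ``end``.  Values outside [0, 255] are clamped on
    emission.
    """

    mode: str
    start: float
    end: float
    peak_week: float | None = None
    peak_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ArchetypeValidationError(
                f"unknown color mode {self.mode!r}; expected one of {_MODES}"
            )
        if self.mode == "unimodal" and (self.peak_week is None or self.peak_value is None):
            raise ArchetypeValidationError("unimodal channel needs peak_week and peak_value")
        if self.mode == "monotone_increasing" and self.end < self.start:
            raise ArchetypeValidationError("monotone_increasing channel with end < start")
        if self.mode == "monotone_decreasing" and self.end > self.start:
            raise ArchetypeValidationError("monotone_decreasing channel with end > start")


@dataclass(frozen=True)
class VarietyArchetype:
    """Final values and timing knobs defining one variety's season.

    Units: weight g, diameters mm, SSC and titratable acid %, weeks are
    post-flowering weeks.  ``stage_boundary_week`` is where the maturity
    coefficient reaches 0.7 (veraison); ``harvest_week`` ends monitoring.
    """

    name: str
    final_weight: float
    final_long_diam: float
    final_horiz_diam: float
    final_compactness: float
    final_ssc: float
    final_ta: float
    ta_peak_week: float
    ta_peak_value: float
    stage_boundary_week: float
    harvest_week: float
    color: dict[str, ChannelTrajectory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fname in ("final_weight", "final_long_diam", "final_horiz_diam",
                      "final_compactness", "final_ssc", "final_ta", "ta_peak_value"):
            if not getattr(self, fname) > 0:
                raise ArchetypeValidationError(f"{self.name}: {fname} must be positive")
        if not FIRST_WEEK < self.stage_boundary_week < self.harvest_week:
            raise ArchetypeValidationError(
                f"{self.name}: need {FIRST_WEEK} < stage_boundary_week < harvest_week"
            )
        if self.final_compactness < 1.0:
            raise ArchetypeValidationError(
                f"{self.name}: compactness < 1 (bounding box smaller than fruit)"
            )
        if not FIRST_WEEK < self.ta_peak_week < self.harvest_week:
            raise ArchetypeValidationError(
                f"{self.name}: ta_peak_week must lie inside ({FIRST_WEEK}, harvest_week)"
            )
        if self.ta_peak_value <= self.final_ta:
            raise ArchetypeValidationError(f"{self.name}: acid peak must exceed final acid")
        if set(self.color) != set(CHANNELS):
            raise ArchetypeValidationError(f"{self.name}: color must define channels {CHANNELS}")


@dataclass(frozen=True)
class TrajectoryConfig:
    """Sampling weeks, noise level, and seed for one simulated campaign."""

    weeks: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0
    n_clusters: int = 10

    def __post_init__(self) -> None:
        weeks = np.asarray(self.weeks, dtype=float)
        if weeks.size < 2 or np.any(np.diff(weeks) <= 0):
            raise ValueError("weeks must be strictly increasing with at least 2 entries")
        if not 0 <= self.noise_sd <= 0.3:
            raise ValueError("noise_sd must be in [0, 0.3] (positivity of indicators)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class IndicatorSeries:
    """Weekly indicator table for one variety (arrays aligned on ``week``)."""

    week: np.ndarray
    weight: np.ndarray
    long_diam: np.ndarray
    horiz_diam: np.ndarray
    compactness: np.ndarray
    ssc: np.ndarray
    titratable_acid: np.ndarray
    ssc_acid_ratio: np.ndarray
    variety: str = ""

    INDICATORS = ("weight", "long_diam", "horiz_diam", "compactness",
                  "ssc", "titratable_acid", "ssc_acid_ratio")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"week": self.week, **{k: getattr(self, k) for k in self.INDICATORS}})


@dataclass
class ColorSeries:
    """True mean skin RGB per sampling week, with maturity-coefficient labels."""

    week: np.ndarray
    rgb: np.ndarray          # (n_weeks, 3) in [0, 255]
    mc: np.ndarray           # grid label (0.1 steps) per week
    variety: str = ""
    mc_raw: np.ndarray | None = None   # continuous Mc ramp (regression target)

    def as_pairs(self) -> list[tuple[float, tuple[float, float, float]]]:
        return [(float(w), tuple(row)) for w, row in zip(self.week, self.rgb)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"week": self.week, "r": self.rgb[:, 0],
                           "g": self.rgb[:, 1], "b": self.rgb[:, 2], "mc": self.mc})
        if self.mc_raw is not None:
            df["mc_raw"] = self.mc_raw
        return df


@dataclass
class SyntheticImage:
    """Rendered berry cluster plus exact ground truth."""

    pixels: np.ndarray       # (H, W, 3) uint8
    berry_mask: np.ndarray   # (H, W) bool
    berry_geometry: list[tuple[tuple[float, float], tuple[float, float]]]


# --------------------------------------------------------------------------
# default archetypes
# --------------------------------------------------------------------------

DEFAULT_ARCHETYPES: dict[str, VarietyArchetype] = {
    # Yellow-green variety turning golden: R and G climb steadily, B humps.
    "drunk_incense": VarietyArchetype(
        name="drunk_incense",
        final_weight=14.0, final_long_diam=31.03, final_horiz_diam=28.0,
        final_compactness=1.45, final_ssc=22.45, final_ta=0.368,
        ta_peak_week=9.0, ta_peak_value=1.05,
        stage_boundary_week=12.0, harvest_week=15.0,
        color={
            "r": ChannelTrajectory("monotone_increasing", 60.0, 185.0),
            "g": ChannelTrajectory("monotone_increasing", 105.0, 195.0),
            "b": ChannelTrajectory("unimodal", 60.0, 70.0, peak_week=10.0, peak_value=110.0),
        },
    ),
    # Dark purple variety: all channels rise then fall as pigment accumulates.
    "muscat_hamburg": VarietyArchetype(
        name="muscat_hamburg",
        final_weight=8.54, final_long_diam=24.59, final_horiz_diam=22.0,
        final_compactness=1.45, final_ssc=21.25, final_ta=0.47,
        ta_peak_week=11.0, ta_peak_value=1.2,
        stage_boundary_week=14.0, harvest_week=17.0,
        color={
            "r": ChannelTrajectory("unimodal", 70.0, 55.0, peak_week=11.0, peak_value=200.0),
            "g": ChannelTrajectory("unimodal", 110.0, 50.0, peak_week=10.0, peak_value=150.0),
            "b": ChannelTrajectory("unimodal", 55.0, 40.0, peak_week=9.0, peak_value=90.0),
        },
    ),
    # Red/pink variety, latest to ripen.
    "xiang_yue": VarietyArchetype(
        name="xiang_yue",
        final_weight=11.02, final_long_diam=26.39, final_horiz_diam=24.0,
        final_compactness=1.55, final_ssc=18.4, final_ta=0.69,
        ta_peak_week=12.0, ta_peak_value=1.93,
        stage_boundary_week=17.0, harvest_week=20.0,
        color={
            "r": ChannelTrajectory("unimodal", 70.0, 145.0, peak_week=14.0, peak_value=190.0),
            "g": ChannelTrajectory("unimodal", 115.0, 70.0, peak_week=10.0, peak_value=150.0),
            "b": ChannelTrajectory("unimodal", 60.0, 45.0, peak_week=10.0, peak_value=95.0),
        },
    ),
}


def default_weeks(archetype: VarietyArchetype, step: float = 0.5) -> tuple[float, ...]:
    """Sampling grid from week 4 to harvest (default twice a week)."""
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    n = int(round((archetype.harvest_week - FIRST_WEEK) / step))
    weeks = FIRST_WEEK + step * np.arange(n + 1)
    return tuple(float(w) for w in weeks)


# --------------------------------------------------------------------------
# noise-free curves
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logistic_curve(t: np.ndarray, start: float, final: float,
                    midpoint: float, rate: float, t0: float, t1: float) -> np.ndarray:
    """Logistic from ``start`` at t0 to exactly ``final`` at t1 (affine rescale)."""
    s = _sigmoid(rate * (np.asarray(t, float) - midpoint))
    s0 = _sigmoid(rate * (t0 - midpoint))
    s1 = _sigmoid(rate * (t1 - midpoint))
    return start + (final - start) * (s - s0) / (s1 - s0)


def _physical_curve(t: np.ndarray, final: float, start_frac: float,
                    arch: VarietyArchetype) -> np.ndarray:
    # Berry sizing finishes just before harvest (still growing when picked).
    mid = arch.harvest_week - _PHYSICAL_MIDPOINT_OFFSET
    return _logistic_curve(t, start_frac * final, final, mid, _PHYSICAL_RATE,
                           FIRST_WEEK, arch.harvest_week)


def _ssc_curve(t: np.ndarray, arch: VarietyArchetype) -> np.ndarray:
    # Sugar accumulation completes at the stage boundary: midpoint halfway
    # between week 4 and the boundary, rate ln(99)/(mid-4) so the curve covers
    # 1% of its range at week 4 and 99% at the boundary.
    mid = (FIRST_WEEK + arch.stage_boundary_week) / 2.0
    rate = math.log(99.0) / (mid - FIRST_WEEK)
    return _logistic_curve(t, _SSC_START, arch.final_ssc, mid, rate,
                           FIRST_WEEK, arch.harvest_week)


def _ta_curve(t: np.ndarray, arch: VarietyArchetype) -> np.ndarray:
    """Unimodal titratable acid: ease up to the peak, concave decline to the
    final value at the stage boundary, flat plateau afterwards."""
    t = np.asarray(t, dtype=float)
    lo, peak = arch.final_ta, arch.ta_peak_value
    pw, bw = arch.ta_peak_week, arch.stage_boundary_week
    out = np.full_like(t, lo)
    rising = t <= pw
    u = (t[rising] - FIRST_WEEK) / (pw - FIRST_WEEK)
    out[rising] = lo + (peak - lo) * 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0, 1)))
    falling = (t > pw) & (t < bw)
    s = (t[falling] - pw) / (bw - pw)
    out[falling] = lo + (peak - lo) * (1.0 - s) ** _TA_DECLINE_SHAPE
    return out


def _compactness_curve(t: np.ndarray, arch: VarietyArchetype) -> np.ndarray:
    rate = math.log(100.0) / (arch.stage_boundary_week - FIRST_WEEK)
    extra = _COMPACTNESS_START_EXTRA
    return arch.final_compactness + extra * np.exp(-rate * (np.asarray(t, float) - FIRST_WEEK))


def noise_free_indicators(archetype: VarietyArchetype, weeks: Sequence[float]) -> dict[str, np.ndarray]:
    """Noise-free indicator curves evaluated at ``weeks`` (exposed for tests)."""
    t = np.asarray(weeks, dtype=float)
    ssc = _ssc_curve(t, archetype)
    ta = _ta_curve(t, archetype)
    return {
        "weight": _physical_curve(t, archetype.final_weight, _START_FRACTION["weight"], archetype),
        "long_diam": _physical_curve(t, archetype.final_long_diam, _START_FRACTION["long_diam"], archetype),
        "horiz_diam": _physical_curve(t, archetype.final_horiz_diam, _START_FRACTION["horiz_diam"], archetype),
        "compactness": _compactness_curve(t, archetype),
        "ssc": ssc,
        "titratable_acid": ta,
    }


# --------------------------------------------------------------------------
# noisy generation
# --------------------------------------------------------------------------

def _cluster_mean_noise(values: np.ndarray, rel_sd: float, n_clusters: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Mean over n_clusters observations with truncated multiplicative noise."""
    if rel_sd == 0:
        return values.copy()
    eps = rng.normal(0.0, rel_sd, size=(n_clusters, values.size))
    eps = np.clip(eps, -3.0 * rel_sd, 3.0 * rel_sd)
    return (values[None, :] * (1.0 + eps)).mean(axis=0)


def generate_indicator_series(archetype: VarietyArchetype,
                              config: TrajectoryConfig) -> IndicatorSeries:
    """Simulate the weekly physical/chemical indicator table for one variety.

    The SSC/acid column is computed from the noisy SSC and acid columns so the
    ratio identity holds exactly in the emitted table.
    """
    weeks = np.asarray(config.weeks, dtype=float)
    if weeks[0] < FIRST_WEEK or weeks[-1] > archetype.harvest_week:
        raise ValueError(
            f"sampling weeks must lie within [{FIRST_WEEK}, {archetype.harvest_week}]"
        )
    clean = noise_free_indicators(archetype, weeks)
    rng = np.random.default_rng(config.seed)
    noisy = {k: _cluster_mean_noise(v, config.noise_sd, config.n_clusters, rng)
             for k, v in clean.items()}
    return IndicatorSeries(
        week=weeks,
        weight=noisy["weight"],
        long_diam=noisy["long_diam"],
        horiz_diam=noisy["horiz_diam"],
        compactness=noisy["compactness"],
        ssc=noisy["ssc"],
        titratable_acid=noisy["titratable_acid"],
        ssc_acid_ratio=noisy["ssc"] / noisy["titratable_acid"],
        variety=archetype.name,
    )


def _maturity_progress(mc_timeline, t: np.ndarray) -> np.ndarray:
    """Normalized ripening progress u in [0, 1]: linear in the continuous Mc
    ramp (0.1 -> u=0, 1.0 -> u=1), interpolated to arbitrary weeks."""
    tl_weeks = np.asarray(mc_timeline.weeks, dtype=float)
    raw = getattr(mc_timeline, "mc_raw", None)
    ramp = np.asarray(raw if raw is not None else mc_timeline.mc, dtype=float)
    return np.clip((np.interp(t, tl_weeks, ramp) - 0.1) / 0.9, 0.0, 1.0)


def _channel_curve(traj: ChannelTrajectory, u: np.ndarray,
                   u_peak: float | None = None) -> np.ndarray:
    """Channel value as a function of ripening progress ``u``.

    Skin color tracks ripening stage, not the calendar: monotone channels are
    linear in u, unimodal channels are two linear segments meeting at the
    progress ``u_peak`` of the configured peak week.
    """
    u = np.asarray(u, dtype=float)
    if traj.mode in ("monotone_increasing", "monotone_decreasing"):
        return traj.start + (traj.end - traj.start) * u
    pv = float(traj.peak_value)
    up = min(max(float(u_peak), 1e-6), 1.0 - 1e-6)
    out = np.empty_like(u)
    rising = u <= up
    out[rising] = traj.start + (pv - traj.start) * (u[rising] / up)
    out[~rising] = pv + (traj.end - pv) * ((u[~rising] - up) / (1.0 - up))
    return out


def generate_color_series(archetype: VarietyArchetype, mc_timeline,
                          config: TrajectoryConfig) -> ColorSeries:
    """True mean skin RGB per sampling week, labelled with the maturity
    coefficient from ``mc_timeline`` (a :class:`graperipe.maturity.McTimeline`).

    Skin color is driven by ripening progress (the continuous Mc ramp in the
    timeline), so color change concentrates in the color-changing mature
    stage exactly as the maturity coefficient does.  Channel trajectories
    follow the archetype's per-channel modes; noise is truncated
    multiplicative Gaussian per ``config.noise_sd``; emitted values are
    clamped to [0, 255].
    """
    weeks = np.asarray(config.weeks, dtype=float)
    tl_weeks = np.asarray(mc_timeline.weeks, dtype=float)
    idx = np.searchsorted(tl_weeks, weeks)
    if np.any(idx >= tl_weeks.size) or not np.allclose(tl_weeks[np.clip(idx, 0, tl_weeks.size - 1)], weeks):
        raise ValueError("mc_timeline does not cover the configured sampling weeks")
    rng = np.random.default_rng(config.seed)
    u = _maturity_progress(mc_timeline, weeks)
    cols = []
    for ch in CHANNELS:
        traj = archetype.color[ch]
        u_peak = None
        if traj.mode == "unimodal":
            u_peak = float(_maturity_progress(mc_timeline, np.asarray([traj.peak_week]))[0])
        clean = _channel_curve(traj, u, u_peak)
        noisy = _cluster_mean_noise(clean, config.noise_sd, config.n_clusters, rng)
        cols.append(np.clip(noisy, 0.0, 255.0))
    raw = getattr(mc_timeline, "mc_raw", None)
    return ColorSeries(week=weeks, rgb=np.column_stack(cols),
                       mc=np.asarray(mc_timeline.mc, float)[idx], variety=archetype.name,
                       mc_raw=None if raw is None else np.asarray(raw, float)[idx])


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

_BERRY_JITTER_SD = 8.0       # per-berry channel offset sd
_BACKGROUND_RANGE = (235, 251)   # near-white reference board


def render_cluster_image(mean_rgb: Sequence[float], n_berries: int,
                         image_size: int = 128, seed: int = 0,
                         jitter_sd: float = _BERRY_JITTER_SD) -> SyntheticImage:
    """Render ``n_berries`` elliptical berries on a near-white board.

    Berries sit on a jittered grid (never overlapping); each berry's color is
    ``mean_rgb`` plus a per-berry offset.  Offsets are recentred by berry area
    so the area-weighted mean over the ground-truth mask reproduces
    ``mean_rgb`` up to rounding and [0, 255] clamping.
    """
    mean_rgb = np.asarray(mean_rgb, dtype=float)
    if mean_rgb.shape != (3,) or np.any(mean_rgb < 0) or np.any(mean_rgb > 255):
        raise ValueError("mean_rgb must be three channels in [0, 255]")
    if n_berries < 1:
        raise ValueError("n_berries must be >= 1")
    rng = np.random.default_rng(seed)
    H = W = int(image_size)
    cols = math.ceil(math.sqrt(n_berries))
    rows = math.ceil(n_berries / cols)
    cell_h, cell_w = H // rows, W // cols
    radius = int(0.35 * min(cell_h, cell_w))
    if radius < 3:
        raise ValueError(
            f"image of size {image_size} too small to place {n_berries} berries"
        )

    pixels = rng.integers(_BACKGROUND_RANGE[0], _BACKGROUND_RANGE[1],
                          size=(H, W, 3)).astype(float)
    mask = np.zeros((H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]

    geometry: list[tuple[tuple[float, float], tuple[float, float]]] = []
    berry_masks = []
    for k in range(n_berries):
        r_idx, c_idx = divmod(k, cols)
        cy = (r_idx + 0.5) * cell_h + rng.uniform(-0.05, 0.05) * cell_h
        cx = (c_idx + 0.5) * cell_w + rng.uniform(-0.05, 0.05) * cell_w
        a = radius * rng.uniform(0.85, 1.0)   # semi-axis, rows
        b = radius * rng.uniform(0.85, 1.0)   # semi-axis, cols
        m = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        geometry.append(((cy, cx), (a, b)))
        berry_masks.append(m)
        mask |= m

    areas = np.array([m.sum() for m in berry_masks], dtype=float)
    offsets = rng.normal(0.0, jitter_sd, size=(n_berries, 3))
    offsets -= np.average(offsets, axis=0, weights=areas)   # recentre by area
    for m, off in zip(berry_masks, offsets):
        pixels[m] = np.clip(mean_rgb + off, 0.0, 255.0)

    return SyntheticImage(pixels=np.clip(np.rint(pixels), 0, 255).astype(np.uint8),
                          berry_mask=mask, berry_geometry=geometry)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_indicator_csv(series: IndicatorSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_indicator_csv(path, variety: str = "") -> IndicatorSeries:
    df = pd.read_csv(path)
    return IndicatorSeries(
        week=df["week"].to_numpy(float),
        **{k: df[k].to_numpy(float) for k in IndicatorSeries.INDICATORS},
        variety=variety,
    )


def write_color_csv(series: ColorSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_color_csv(path, variety: str = "") -> ColorSeries:
    df = pd.read_csv(path)
    raw = df["mc_raw"].to_numpy(float) if "mc_raw" in df.columns else None
    return ColorSeries(week=df["week"].to_numpy(float),
                       rgb=df[["r", "g", "b"]].to_numpy(float),
                       mc=df["mc"].to_numpy(float), variety=variety, mc_raw=raw)


def save_image_png(image: SyntheticImage, path, mask_path=None) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)
    if mask_path is not None:
        Image.fromarray((image.berry_mask * 255).astype(np.uint8), mode="L").save(mask_path)


def load_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def archetype_to_yaml(archetype: VarietyArchetype, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(archetype), fh, sort_keys=False)


def archetype_from_yaml(path) -> VarietyArchetype:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["color"] = {ch: ChannelTrajectory(**spec) for ch, spec in raw["color"].items()}
    return VarietyArchetype(**raw)
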