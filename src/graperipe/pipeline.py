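"""End-to-end orchestration: simulate -> extract -> Mc -> train -> evaluate.

The pipeline mirrors the full study design on synthetic data: simulate a
variety's indicator table, construct the maturity-coefficient timeline,
produce labelled skin-color observations (either directly from the color
trajectories or by rendering cluster images and segmenting them), train the
six single-feature networks, rank them with GPI, build the seven
single/two/three-factor models from the top three singles, and report
metrics, GPI ranks, and ripening-period confusion summaries.

A single ``RunConfig.seed`` drives every stochastic stage through spawned
child seeds, so identical configurations yield byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, maturity, neuralnet, synthetic
from .evaluation import (ConfusionSummary, MetricSet, compute_gpi, compute_metrics,
                         judge_levels)
from .neuralnet import (ColorSample, FeatureSet, NetworkConfig, enumerate_feature_sets,
                        feature_matrix, predict_mc, train)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_ripening_samples",
           "RIPENING_SAMPLE_COUNTS"]

logger = logging.getLogger("graperipe")

#: evaluation-set design for the ripening band: clusters sampled per Mc level
RIPENING_SAMPLE_COUNTS = {0.7: 25, 0.8: 25, 0.9: 15, 1.0: 10}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    variety: str = "drunk_incense"
    seed: int = 0
    noise_sd: float = 0.05          # indicator / color trajectory noise
    week_step: float = 0.5
    settle_threshold: float = maturity.DEFAULT_SETTLE_THRESHOLD
    samples_per_week: int = 3       # replicate color observations per week
    color_noise_sd: float = 0.02    # per-observation RGB noise for replicates
    render_images: bool = False     # go through render + segmentation
    image_size: int = 96
    n_berries: int = 6
    n_hidden: int = 10
    learning_rate: float = 0.05
    max_epochs: int = 5000
    validation_fraction: float = 0.3
    out_dir: str | None = None

    def archetype(self) -> synthetic.VarietyArchetype:
        try:
            return synthetic.DEFAULT_ARCHETYPES[self.variety]
        except KeyError:
            raise PipelineError(
                f"stage config: unknown variety {self.variety!r}; "
                f"choose from {sorted(synthetic.DEFAULT_ARCHETYPES)}"
            ) from None


def _child_seeds(seed: int, n: int) -> list[int]:
    # spawn stage seeds below 2**31 so they stay portable ints
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _samples_via_rendering(series: synthetic.ColorSeries, cfg: RunConfig,
                           seed: int) -> list[ColorSample]:
    """Render one cluster image per (week, replicate) and measure it back."""
    rng = np.random.default_rng(seed)
    out: list[ColorSample] = []
    for (r, g, b), mc in zip(series.rgb, series.mc):
        for _ in range(cfg.samples_per_week):
            img = synthetic.render_cluster_image(
                (r, g, b), n_berries=cfg.n_berries, image_size=cfg.image_size,
                seed=int(rng.integers(0, 2**31)))
            seg = imaging.segment_berries(img.pixels)
            rr, gg, bb = imaging.extract_mean_rgb(img.pixels, seg.mask)
            out.append(ColorSample.from_rgb(rr, gg, bb, float(mc)))
    return out


def make_ripening_samples(archetype: synthetic.VarietyArchetype,
                          timeline: maturity.McTimeline,
                          counts: dict[float, int] = RIPENING_SAMPLE_COUNTS,
                          noise_sd: float = 0.02, seed: int = 0) -> list[ColorSample]:
    """Color observations for the ripening band with the designed per-level
    sampling (25/25/15/10 clusters at Mc 0.7/0.8/0.9/1.0 by default)."""
    cfg = synthetic.TrajectoryConfig(weeks=tuple(float(w) for w in timeline.weeks),
                                     noise_sd=0.0, seed=0)
    series = synthetic.generate_color_series(archetype, timeline, cfg)
    rng = np.random.default_rng(seed)
    samples: list[ColorSample] = []
    for level, n in counts.items():
        weeks_at_level = np.flatnonzero(np.isclose(series.mc, level))
        if weeks_at_level.size == 0:
            raise PipelineError(f"stage ripening-sampling: no week labelled Mc={level}")
        for k in range(n):
            idx = int(weeks_at_level[k % weeks_at_level.size])
            rgb = series.rgb[idx]
            if noise_sd > 0:
                eps = np.clip(rng.normal(0, noise_sd, 3), -3 * noise_sd, 3 * noise_sd)
                rgb = np.clip(rgb * (1 + eps), 0, 255)
            samples.append(ColorSample.from_rgb(*rgb, float(level)))
    return samples


def _split(samples: list[ColorSample], fraction: float, seed: int):
    n = len(samples)
    n_val = max(1, int(round(n * fraction)))
    order = np.random.default_rng(seed).permutation(n)
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]
    return tr, val


def _evaluate_model(net, val: list[ColorSample]) -> MetricSet:
    y = np.array([s.mc for s in val])
    pred = predict_mc(net, feature_matrix(val, net.feature_set))
    return compute_metrics(y, pred)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns (and optionally writes) the report."""
    t_start = time.perf_counter()
    arch = config.archetype()
    s_ind, s_col, s_obs, s_split, s_net, s_band = _child_seeds(config.seed, 6)
    logger.info("run: variety=%s seed=%d stage seeds=%s", config.variety, config.seed,
                [s_ind, s_col, s_obs, s_split, s_net, s_band])

    # --- simulate indicators and construct the Mc timeline -----------------
    weeks = synthetic.default_weeks(arch, step=config.week_step)
    traj = synthetic.TrajectoryConfig(weeks=weeks, noise_sd=config.noise_sd, seed=s_ind)
    try:
        series = synthetic.generate_indicator_series(arch, traj)
        timeline = maturity.construct_mc_timeline(series, config.settle_threshold)
    except Exception as exc:
        raise PipelineError(f"stage maturity: {exc}") from exc
    logger.info("maturity: boundary=%.1f full=%.1f over %d weeks",
                timeline.boundary_week, timeline.full_maturity_week, len(weeks))

    # --- color observations -------------------------------------------------
    color_cfg = synthetic.TrajectoryConfig(weeks=weeks, noise_sd=config.noise_sd, seed=s_col)
    color = synthetic.generate_color_series(arch, timeline, color_cfg)
    if config.render_images:
        samples = _samples_via_rendering(color, config, s_obs)
    else:
        samples = neuralnet.samples_from_color_series(
            color, n_replicates=config.samples_per_week,
            noise_sd=config.color_noise_sd, seed=s_obs)
    train_set, val_set = _split(samples, config.validation_fraction, s_split)
    logger.info("samples: %d total (%d train / %d validation)",
                len(samples), len(train_set), len(val_set))

    # --- single-feature models and GPI ranking ------------------------------
    net_cfg = NetworkConfig(n_hidden=config.n_hidden, learning_rate=config.learning_rate,
                            max_epochs=config.max_epochs, seed=s_net)
    nets: dict[str, neuralnet.TrainedNetwork] = {}
    single_metrics: dict[str, MetricSet] = {}
    for name in neuralnet.FEATURE_NAMES:
        fs = FeatureSet((name,))
        nets[fs.label] = train(train_set, fs, net_cfg)
        single_metrics[fs.label] = _evaluate_model(nets[fs.label], val_set)
    single_gpi = compute_gpi(single_metrics)
    top3 = sorted(single_gpi.rank, key=single_gpi.rank.get)[:3]
    logger.info("single-feature GPI ranking: %s (top3=%s)", single_gpi.rank, top3)

    # --- seven-model search --------------------------------------------------
    seven = enumerate_feature_sets(top3)
    model_metrics: dict[str, MetricSet] = {}
    for fs in seven:
        if fs.label not in nets:
            nets[fs.label] = train(train_set, fs, net_cfg)
        model_metrics[fs.label] = _evaluate_model(nets[fs.label], val_set)
    seven_gpi = compute_gpi(model_metrics)

    two_factor = [fs.label for fs in seven if fs.arity == 2]
    best_two = min(two_factor, key=lambda m: seven_gpi.rank[m])

    # --- ripening-band confusion: best two-factor vs best single ------------
    band = make_ripening_samples(arch, timeline, noise_sd=config.color_noise_sd,
                                 seed=s_band)
    band_true = np.array([s.mc for s in band])
    best_single = top3[0]

    def _band_confusion(label: str) -> ConfusionSummary:
        net = nets[label]
        pred = predict_mc(net, feature_matrix(band, net.feature_set))
        return judge_levels(pred, band_true)

    confusion = _band_confusion(best_two)
    confusion_single = _band_confusion(best_single)
    logger.info("confusion (%s): accuracy=%.1f%% over=%.1f%% under=%.1f%% "
                "(best single %s: %.1f%%)",
                best_two, confusion.accuracy, confusion.over_rate,
                confusion.under_rate, best_single, confusion_single.accuracy)

    report = {
        "config": asdict(config),
        "variety": config.variety,
        "boundary_week": timeline.boundary_week,
        "full_maturity_week": timeline.full_maturity_week,
        "n_samples": len(samples),
        "single_models": _model_block(single_metrics, single_gpi),
        "top3_singles": top3,
        "seven_models": _model_block(model_metrics, seven_gpi),
        "best_two_factor": best_two,
        "best_single_factor": best_single,
        "confusion": _confusion_block(confusion),
        "confusion_best_single": _confusion_block(confusion_single),
    }
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t_start)

    if config.out_dir is not None:
        _write_artifacts(Path(config.out_dir), config, series, timeline, color,
                         model_metrics, seven_gpi, confusion, nets, report)
    return report


def _model_block(metrics: dict[str, MetricSet], gpi) -> dict:
    return {
        m: {"r2": ms.r2, "rmse": ms.rmse, "mae": ms.mae, "d": ms.d, "n": ms.n,
            "gpi": gpi.gpi[m], "rank": gpi.rank[m]}
        for m, ms in metrics.items()
    }


def _confusion_block(c: ConfusionSummary) -> dict:
    return {
        "total": c.total, "correct": c.correct,
        "overestimated": c.overestimated, "underestimated": c.underestimated,
        "accuracy": c.accuracy, "over_rate": c.over_rate, "under_rate": c.under_rate,
        "per_level": {str(k): v for k, v in c.per_level.items()},
    }


def metric_table(metrics: dict[str, MetricSet], gpi) -> pd.DataFrame:
    """Wide table: metric rows (plus GPI and rank) by model columns."""
    rows = ["r2", "mae", "rmse", "d", "gpi", "rank"]
    data = {}
    for m, ms in metrics.items():
        data[m] = [ms.r2, ms.mae, ms.rmse, ms.d, gpi.gpi[m], gpi.rank[m]]
    return pd.DataFrame(data, index=rows)


def _write_artifacts(out: Path, config, series, timeline, color, model_metrics,
                     seven_gpi, confusion, nets, report) -> None:
    out.mkdir(parents=True, exist_ok=True)
    synthetic.write_indicator_csv(series, out / "indicators.csv")
    maturity.write_mc_csv(timeline, out / "mc_timeline.csv")
    synthetic.write_color_csv(color, out / "color_series.csv")
    metric_table(model_metrics, seven_gpi).to_csv(out / "model_metrics.csv")
    conf_rows = [{"level": lv, **cnt} for lv, cnt in confusion.per_level.items()]
    pd.DataFrame(conf_rows).to_csv(out / "confusion_per_level.csv", index=False)
    for label, net in nets.items():
        neuralnet.save_network_json(net, out / f"model_{label}.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("artifacts written to %s", out)
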