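"""One-hidden-layer back-propagation network mapping skin color to Mc.

The regressor maps 1-3 color features (chosen from R, G, B, H, S, I) to a
continuous maturity coefficient.  Training is deterministic full-batch
gradient descent on mean squared error: inputs are min-max scaled to [-1, 1]
(scaling fitted on the training data only), weights start uniform in
[-0.5, 0.5] from the run seed, the hidden layer uses tanh by default (the
logistic unit f(x) = 1/(1+exp(-x)) is available by config), and the output
is linear.  Predictions are clipped to the Mc range [0.1, 1.0]; the 0.1-grid
discretization is deferred to the evaluation module.

Everything here is hand-rolled on numpy on purpose: the network, its
gradients, and the feature-set enumeration are the method under study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .imaging import rgb_to_hsi

__all__ = [
    "FEATURE_NAMES",
    "FeatureSet",
    "NetworkConfig",
    "TrainedNetwork",
    "ColorSample",
    "logistic",
    "train",
    "predict_mc",
    "select_hidden_size",
    "enumerate_feature_sets",
    "feature_matrix",
    "samples_from_color_series",
    "save_network_json",
    "load_network_json",
]

FEATURE_NAMES = ("R", "G", "B", "H", "S", "I")

MC_MIN, MC_MAX = 0.1, 1.0


@dataclass(frozen=True)
class ColorSample:
    """One observation: mean skin RGB, derived HSI, and the true Mc label."""

    r: float
    g: float
    b: float
    h: float
    s: float
    i: float
    mc: float

    @classmethod
    def from_rgb(cls, r: float, g: float, b: float, mc: float) -> "ColorSample":
        h, s, i = rgb_to_hsi((r, g, b))
        return cls(r=r, g=g, b=b, h=h, s=s, i=i, mc=mc)

    def feature(self, name: str) -> float:
        return getattr(self, name.lower())


@dataclass(frozen=True)
class FeatureSet:
    """Ordered subset of the six color features, arity 1-3."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.names) <= 3:
            raise ValueError("feature set arity must be 1, 2 or 3")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        for n in self.names:
            if n not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {n!r}; expected one of {FEATURE_NAMES}")

    @property
    def arity(self) -> int:
        return len(self.names)

    @property
    def label(self) -> str:
        return "".join(self.names)


@dataclass(frozen=True)
class NetworkConfig:
    n_hidden: int = 10
    hidden_activation: str = "tanh"     # "tanh" | "logistic"
    learning_rate: float = 0.05
    max_epochs: int = 5000
    seed: int = 0
    early_stop_window: int = 50
    early_stop_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_activation not in ("tanh", "logistic"):
            raise ValueError("hidden_activation must be 'tanh' or 'logistic'")


@dataclass
class TrainedNetwork:
    w1: np.ndarray              # (n_features, n_hidden)
    b1: np.ndarray              # (n_hidden,)
    w2: np.ndarray              # (n_hidden,)
    b2: float
    feature_set: FeatureSet
    x_min: np.ndarray           # per-feature training minima (for scaling)
    x_max: np.ndarray
    config: NetworkConfig
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def logistic(x):
    """Numerically stable logistic 1/(1+exp(-x)) for scalars or arrays."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else logistic(z)


def _activate_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # expressed through the activation value itself
    return 1.0 - a**2 if kind == "tanh" else a * (1.0 - a)


def feature_matrix(samples: Sequence[ColorSample], feature_set: FeatureSet) -> np.ndarray:
    return np.array([[s.feature(n) for n in feature_set.names] for s in samples], dtype=float)


def _scale(X: np.ndarray, x_min: np.ndarray, x_max: np.ndarray) -> np.ndarray:
    span = x_max - x_min
    safe = np.where(span == 0, 1.0, span)
    scaled = 2.0 * (X - x_min) / safe - 1.0
    return np.where(span == 0, 0.0, scaled)


def _forward(X: np.ndarray, w1, b1, w2, b2, kind: str):
    A = _activate(X @ w1 + b1, kind)
    return A, A @ w2 + b2


def loss_and_gradients(X: np.ndarray, y: np.ndarray, w1, b1, w2, b2, kind: str):
    """MSE loss and its analytic gradients (exposed for the gradient check)."""
    n = X.shape[0]
    A, yhat = _forward(X, w1, b1, w2, b2, kind)
    err = yhat - y
    loss = float(np.mean(err**2))
    d_out = 2.0 * err / n                      # dL/dyhat
    g_w2 = A.T @ d_out
    g_b2 = float(d_out.sum())
    d_hidden = np.outer(d_out, w2) * _activate_deriv(A, kind)
    g_w1 = X.T @ d_hidden
    g_b1 = d_hidden.sum(axis=0)
    return loss, (g_w1, g_b1, g_w2, g_b2)


def train(samples: Sequence[ColorSample], feature_set: FeatureSet,
          config: NetworkConfig) -> TrainedNetwork:
    """Full-batch gradient descent on MSE; deterministic given the seed."""
    if len(samples) < 10:
        raise ValueError("need at least 10 training samples")
    X_raw = feature_matrix(samples, feature_set)
    y = np.array([s.mc for s in samples], dtype=float)
    if not np.all(np.isfinite(X_raw)):
        raise ValueError("non-finite feature values in the training set")
    if np.any(y < MC_MIN - 1e-9) or np.any(y > MC_MAX + 1e-9):
        raise ValueError(f"targets must lie in [{MC_MIN}, {MC_MAX}]")
    if np.ptp(y) == 0:
        raise ValueError("all targets identical; nothing to fit")

    x_min, x_max = X_raw.min(axis=0), X_raw.max(axis=0)
    X = _scale(X_raw, x_min, x_max)

    rng = np.random.default_rng(config.seed)
    k, h = feature_set.arity, config.n_hidden
    w1 = rng.uniform(-0.5, 0.5, size=(k, h))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=h)
    b2 = float(rng.uniform(-0.5, 0.5))

    lr = config.learning_rate
    history = []
    for epoch in range(config.max_epochs):
        loss, (g_w1, g_b1, g_w2, g_b2) = loss_and_gradients(X, y, w1, b1, w2, b2,
                                                            config.hidden_activation)
        history.append(loss)
        w1 -= lr * g_w1
        b1 -= lr * g_b1
        w2 -= lr * g_w2
        b2 -= lr * g_b2
        win = config.early_stop_window
        if epoch >= win and history[-win - 1] - loss < config.early_stop_tol:
            break

    return TrainedNetwork(w1=w1, b1=b1, w2=w2, b2=b2, feature_set=feature_set,
                          x_min=x_min, x_max=x_max, config=config,
                          loss_history=np.asarray(history))


def predict_mc(net: TrainedNetwork, features) -> np.ndarray | float:
    """Predict Mc for features of shape (k,) or (n, k); clipped to [0.1, 1]."""
    F = np.asarray(features, dtype=float)
    single = F.ndim == 1
    F = np.atleast_2d(F)
    if F.shape[1] != net.feature_set.arity:
        raise ValueError(
            f"expected {net.feature_set.arity} features ({net.feature_set.label}), "
            f"got {F.shape[1]}"
        )
    X = _scale(F, net.x_min, net.x_max)
    _, yhat = _forward(X, net.w1, net.b1, net.w2, net.b2, net.config.hidden_activation)
    yhat = np.clip(yhat, MC_MIN, MC_MAX)
    return float(yhat[0]) if single else yhat


def predict_samples(net: TrainedNetwork, samples: Sequence[ColorSample]) -> np.ndarray:
    return predict_mc(net, feature_matrix(samples, net.feature_set))


def _level_accuracy(predicted: np.ndarray, true_mc: np.ndarray) -> float:
    # fraction of predictions landing on the correct 0.1 level
    pred_level = np.floor(np.asarray(predicted) * 10.0 + 0.5) / 10.0
    true_level = np.floor(np.asarray(true_mc) * 10.0 + 0.5) / 10.0
    return float(np.mean(np.isclose(pred_level, true_level)))


def select_hidden_size(samples: Sequence[ColorSample], feature_set: FeatureSet,
                       candidates: Iterable[int] = range(2, 21),
                       validation_fraction: float = 0.25,
                       base_config: NetworkConfig | None = None) -> int:
    """Pick the hidden-layer size with the best validation level accuracy on a
    seeded split; ties go to the smallest candidate."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    base = base_config or NetworkConfig()
    n = len(samples)
    n_val = int(round(n * validation_fraction))
    if n_val == 0 or n - n_val < 10:
        raise ValueError("validation split empty or training split too small")
    rng = np.random.default_rng(base.seed)
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_set = [samples[i] for i in train_idx]
    val_set = [samples[i] for i in val_idx]
    y_val = np.array([s.mc for s in val_set])

    best_size, best_acc = None, -1.0
    for size in sorted(candidates):
        cfg = NetworkConfig(n_hidden=size, hidden_activation=base.hidden_activation,
                            learning_rate=base.learning_rate, max_epochs=base.max_epochs,
                            seed=base.seed, early_stop_window=base.early_stop_window,
                            early_stop_tol=base.early_stop_tol)
        net = train(train_set, feature_set, cfg)
        acc = _level_accuracy(predict_samples(net, val_set), y_val)
        if acc > best_acc:
            best_size, best_acc = size, acc
    return best_size


def enumerate_feature_sets(top3_singles: Sequence[str]) -> list[FeatureSet]:
    """The 3 singles, 3 pairs, and 1 triple built from the top three
    single-feature models, in that order (7 sets)."""
    names = tuple(top3_singles)
    if len(names) != 3 or len(set(names)) != 3:
        raise ValueError("need exactly 3 distinct feature labels")
    a, b, c = names
    combos = [(a,), (b,), (c,), (a, b), (a, c), (b, c), (a, b, c)]
    return [FeatureSet(t) for t in combos]


def samples_from_color_series(series, n_replicates: int = 1, noise_sd: float = 0.0,
                              seed: int = 0, mature_only: bool = False) -> list[ColorSample]:
    """Expand a :class:`graperipe.synthetic.ColorSeries` into ColorSamples,
    optionally replicated with per-observation multiplicative RGB noise.

    The sample target is the continuous Mc ramp (``mc_raw``) when the series
    carries one, falling back to the grid label; level discretization stays in
    the evaluation stage."""
    rng = np.random.default_rng(seed)
    out: list[ColorSample] = []
    raw = series.mc_raw if getattr(series, "mc_raw", None) is not None else series.mc
    for (r, g, b), level, mc in zip(series.rgb, series.mc, raw):
        if mature_only and level < 0.7 - 1e-9:
            continue
        for _ in range(n_replicates):
            if noise_sd > 0:
                eps = np.clip(rng.normal(0, noise_sd, 3), -3 * noise_sd, 3 * noise_sd)
                rr, gg, bb = np.clip(np.array([r, g, b]) * (1 + eps), 0, 255)
            else:
                rr, gg, bb = r, g, b
            out.append(ColorSample.from_rgb(rr, gg, bb, float(mc)))
    return out


# --------------------------------------------------------------------------
# JSON persistence
# --------------------------------------------------------------------------

def save_network_json(net: TrainedNetwork, path) -> None:
    payload = {
        "w1": net.w1.tolist(), "b1": net.b1.tolist(),
        "w2": net.w2.tolist(), "b2": net.b2,
        "feature_set": list(net.feature_set.names),
        "x_min": net.x_min.tolist(), "x_max": net.x_max.tolist(),
        "config": asdict(net.config),
        "loss_history": np.asarray(net.loss_history).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network_json(path) -> TrainedNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    return TrainedNetwork(
        w1=np.asarray(payload["w1"], float), b1=np.asarray(payload["b1"], float),
        w2=np.asarray(payload["w2"], float), b2=float(payload["b2"]),
        feature_set=FeatureSet(tuple(payload["feature_set"])),
        x_min=np.asarray(payload["x_min"], float),
        x_max=np.asarray(payload["x_max"], float),
        config=NetworkConfig(**payload["config"]),
        loss_history=np.asarray(payload["loss_history"], float),
    )
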