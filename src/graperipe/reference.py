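"""Bundled reference values for the six single-feature ripeness models.

Two small CSVs ship with the package so that evaluation can be exercised
offline against published benchmark numbers for the three greenhouse grape
varieties: per-model accuracy metrics (R^2, MAE, RMSE, d) for the six
single-color-feature models, and ripening-period confusion counts for the
best two-factor model of each variety.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import MetricSet

__all__ = ["load_reference_metrics", "load_reference_confusion_counts", "VARIETIES"]

VARIETIES = ("drunk_incense", "muscat_hamburg", "xiang_yue")

# n is not part of the published metric tables; MetricSet carries it for
# bookkeeping only, so the loader records the evaluation-set size used there.
_REFERENCE_N = 75


def _read(name: str) -> pd.DataFrame:
    with resources.files("graperipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_metrics(variety: str) -> dict[str, MetricSet]:
    """Per-model MetricSet for the six single-feature models of ``variety``."""
    if variety not in VARIETIES:
        raise ValueError(f"unknown variety {variety!r}; expected one of {VARIETIES}")
    df = _read("single_factor_metrics.csv")
    df = df[df["variety"] == variety].set_index("metric")
    models = [c for c in df.columns if c != "variety"]
    return {
        m: MetricSet(r2=float(df.at["r2", m]), mae=float(df.at["mae", m]),
                     rmse=float(df.at["rmse", m]), d=float(df.at["d", m]),
                     n=_REFERENCE_N)
        for m in models
    }


def load_reference_confusion_counts() -> pd.DataFrame:
    """Published ripening-period confusion counts per variety (75 clusters)."""
    return _read("ripening_confusion_counts.csv")
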