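# graperipe

Predicting greenhouse table-grape ripeness from berry skin color.

`graperipe` implements a complete desk-scale version of a grape-maturity
pipeline: it simulates weekly physical/chemical indicator campaigns and
berry-cluster imagery for three variety archetypes, constructs a **maturity
coefficient** (Mc, 0.1–1.0; 0.7 = veraison, 1.0 = full maturity) from
normalized indicator change rates, segments berries and extracts mean skin
color (RGB and derived HSI), trains one-hidden-layer back-propagation
networks mapping 1–3 color features to Mc, and ranks competing feature-set
models with R²/MAE/RMSE/d and the GPI composite index. Published reference
tables (single-feature model metrics and ripening-period confusion counts
for the three varieties) ship with the package so evaluation runs offline.

See [docs/methods.md](docs/methods.md) for the model, the synthetic study
design, and every parameter choice.

## Worked example

Run the whole study for one variety — simulate a season, build the Mc
timeline, train the six single-feature networks, rank them by GPI, search
the seven one/two/three-factor models, and judge the ripening band with the
best two-factor model:

```sh
$ graperipe run --variety drunk_incense --seed 7 --out work/
{
  "variety": "drunk_incense",
  "boundary_week": 12.0,
  "full_maturity_week": 14.0,
  "top3_singles": [
    "R",
    "I",
    "G"
  ],
  "best_two_factor": "RI"
}
accuracy 94.7% (over 1.3%, under 4.0%)
```

`work/` now contains the indicator table, Mc timeline, color series, one
JSON model per feature set, a Table-1-style metric/GPI CSV, the per-level
confusion table, and `report.json` (byte-identical across reruns with the
same seed).

The stages are also composable:

```sh
graperipe simulate --variety drunk_incense --seed 1 --out work/
graperipe extract  --images work/images --out work/features.csv
graperipe maturity --indicators work/indicators.csv --out work/mc.csv
graperipe train    --features work/features.csv --mc work/mc.csv \
                   --feature-set RG --out work/model_RG.json
graperipe report   --run work/ --out work/plots
```

Rank the bundled published single-feature metrics (the R model ranks first
and the S model carries the lowest GPI, −3.03):

```sh
$ graperipe evaluate --bundled-metrics drunk_incense
         R     G      B      H      S     I
r2   0.650 0.630  0.410  0.560  0.370 0.610
mae  0.090 0.100  0.110  0.120  0.180 0.120
rmse 0.120 0.130  0.240  0.140  0.260 0.130
d    0.760 0.700  0.670  0.720  0.620 0.730
gpi  0.974 0.292 -1.605 -0.109 -3.026 0.212
rank 1.000 2.000  5.000  4.000  6.000 3.000
```

From Python:

```python
import numpy as np
from graperipe import (DEFAULT_ARCHETYPES, TrajectoryConfig, default_weeks,
                       construct_mc_timeline, generate_color_series,
                       generate_indicator_series)
from graperipe.neuralnet import (FeatureSet, NetworkConfig, predict_samples,
                                 samples_from_color_series, train)

arch = DEFAULT_ARCHETYPES["drunk_incense"]
cfg = TrajectoryConfig(weeks=default_weeks(arch), noise_sd=0.0, seed=0)
series = generate_indicator_series(arch, cfg)
timeline = construct_mc_timeline(series)          # boundary 12.0, full 13.5
color = generate_color_series(arch, timeline, cfg)
samples = samples_from_color_series(color, n_replicates=3)
net = train(samples, FeatureSet(("R", "G")), NetworkConfig(seed=0))
rmse = float(np.sqrt(np.mean((predict_samples(net, samples)
                              - [s.mc for s in samples]) ** 2)))
print(f"training RMSE {rmse:.4f}")                # ~0.003
```

## Layout

- `src/graperipe/synthetic.py` — archetypes, indicator/color generators, renderer
- `src/graperipe/imaging.py` — Otsu, segmentation, mean RGB, HSI, compactness
- `src/graperipe/maturity.py` — change-rate analysis and the Mc timeline
- `src/graperipe/neuralnet.py` — the BPNN, feature sets, model search helpers
- `src/graperipe/evaluation.py` — metrics, GPI ranking, level judging
- `src/graperipe/pipeline.py`, `cli.py` — orchestration and the `graperipe` CLI
- `src/graperipe/data/` — bundled published reference tables (CSV)
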