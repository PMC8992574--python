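# Methods

This note documents the model, the synthetic study design, the parameter
choices, and the numerical conventions implemented by `graperipe`.

## Scientific problem

Table grapes grown in solar greenhouses are harvested by appearance and
experience; an objective, non-destructive ripeness indicator is valuable for
timing the harvest. The approach implemented here monitors berry clusters
weekly from four weeks post-flowering, constructs a **maturity coefficient
(Mc)** from the physical and chemical development of the fruit, and then
predicts Mc directly from skin color measured in RGB images — so that, once
trained, ripeness can be judged from a photograph alone.

## Maturity coefficient

Mc runs on a 0.1 grid from 0.1 (start of monitoring) to 1.0 (full maturity);
0.7 marks the boundary between the immature stage and the mature
(color-changing) stage, i.e. veraison.

Seven indicators are monitored per week: berry weight, longitudinal and
horizontal diameters, cluster compactness (bounding-box area over fruit
area), soluble solid content (SSC, %), titratable acid (%), and the SSC/acid
ratio. Construction:

1. Min–max normalize each indicator over the monitoring window.
2. Compute per-interval change rates: |Δ normalized value| / Δ week.
3. The **stage boundary** (Mc = 0.7) is the first week from which the three
   *chemical* indicators (SSC, titratable acid, SSC/acid) all stay below the
   settling threshold (default 0.2 per week) through harvest. The suffix
   condition ("from which … through harvest") makes detection robust to a
   single early quiet interval.
4. **Full maturity** (Mc = 1.0) is the first week from which *all seven*
   indicators stay below the threshold.
5. Between the anchors (0.1 at the first week, 0.7 at the boundary, 1.0 at
   full maturity, constant afterwards) Mc is piecewise linear; the grid label
   is the ramp rounded half-up to the nearest 0.1.

Both the continuous ramp (`mc_raw`) and the grid label (`mc`) are kept: the
network regresses the ramp; level judgments quantize at evaluation time.

## Imaging

Clusters are photographed against a near-white reference board. The
segmentation pipeline: grayscale by unweighted channel mean (equal to HSI
intensity), Otsu's between-class-variance threshold (classes `level < t` and
`level ≥ t`, lowest maximizer on ties), darker class as foreground, largest
8-connected component with holes filled as the region of interest. Mean skin
RGB is the arithmetic per-channel mean over the segmented pixels.

HSI derives from RGB with I = (R+G+B)/3, S = 1 − 3·min/(R+G+B), and the
max-channel piecewise hue (60(G−B)/(max−min) when R is the maximum; +120 / 
+240 offsets when G / B are), wrapped to [0, 360). Achromatic pixels take
H = 0 and pure black takes S = 0, keeping the conversion total.

## Network

A one-hidden-layer back-propagation network maps 1–3 color features (from R,
G, B, H, S, I) to Mc. Conventions: inputs min–max scaled to [−1, 1] with
scaling fitted on training data only; hidden activation tanh (logistic unit
available); linear output; full-batch gradient descent on MSE; weights
initialized uniform in [−0.5, 0.5] from the run seed; predictions clipped to
[0.1, 1.0]. Defaults: 10 hidden units, learning rate 0.05, up to 5000
epochs, early stop when the loss improves by less than 1e−8 over 50 epochs.
Training is deterministic given the seed.

Model search follows the study design: train the six single-feature models,
rank them with GPI, then build the seven models from the top three singles
(3 singles, 3 pairs, 1 triple) and pick the best two-factor model.

## Evaluation

Metric conventions are kept exactly as reported in the source literature,
not "fixed" to textbook forms:

- **R²** — squared Pearson correlation.
- **RMSE** — `n − 1` denominator.
- **MAE** — mean absolute error.
- **d** (consistency index) — `1 − Σ(X−Y)² / Σ(|Y−Ȳ| + |X−X̄|)²` with each
  deviation about its *own* series mean (differs from the canonical Willmott
  index, which centers both on the observed mean).
- **GPI** — per metric, min–max normalize across models; with `Ō` the median
  normalized value, GPI(m) = Σⱼ αⱼ(Ōⱼ − Oⱼₘ), α = +1 for MAE/RMSE and −1 for
  R²/d. Higher is better; ranks are 1-based by descending GPI, ties stable
  in input order.

Ripening-period judgment rounds a predicted Mc half-up to the nearest 0.1
and clips to the band [0.7, 1.0]; outcomes are counted as correct /
overestimated / underestimated overall and per level, with the designed
evaluation sample of 75 clusters split 25/25/15/10 across Mc 0.7/0.8/0.9/1.0.

Published reference tables (single-feature metrics for the three varieties,
and ripening-period confusion counts) ship as package data; one published
counts row sums to 74 while its stated total is 75, so rate computation
accepts an explicit total.

## Synthetic study design

No field data are available, so the package generates the campaign it
analyses. Three variety archetypes mirror the studied cultivars:

| archetype | boundary wk | harvest wk | final weight (g) | color habit |
|---|---|---|---|---|
| drunk_incense | 12 | 15 | 14.00 | R, G rise monotonically; B unimodal |
| muscat_hamburg | 14 | 17 | 8.54 | all channels unimodal (pigmenting dark) |
| xiang_yue | 17 | 20 | 11.02 | unimodal, reddening late |

Sampling runs from week 4 to harvest, default step 0.5 weeks.

**Indicator curves.** Weight, diameters: logistic ("slow–fast–slow") curves
with midpoint 2.5 weeks before harvest and rate 1.2/week, affinely rescaled
to hit the configured start at week 4 and the final value exactly at
harvest — sizing is still finishing at picking, which puts full maturity
strictly after the stage boundary. SSC: logistic centred midway between
week 4 and the boundary with rate ln(99)/(mid−4), so sugar accumulation is
99% complete at veraison. Titratable acid: cosine ease up to a mid-season
peak, concave decline reaching the final value exactly at the boundary, flat
afterwards. Compactness: exponential decay to its final value. The SSC/acid
column is always the exact ratio of the (noisy) SSC and acid columns.

These shapes are chosen so the noise-free change-rate analysis recovers the
configured boundary weeks exactly (12 / 14 / 17) — the generator defaults
*are* the study conditions the recovery tests probe.

**Color trajectories.** Skin color is driven by ripening progress, not the
calendar: veraison is by definition the color-changing stage. Channel curves
are functions of u = (mc_raw − 0.1)/0.9 interpolated from the Mc timeline —
monotone channels linear in u, unimodal channels two linear segments meeting
at the progress of the configured peak week — then clamped to [0, 255].
Color is therefore constant once full maturity is reached.

**Noise.** Each weekly value is the mean over 10 monitored clusters, each
carrying multiplicative Gaussian noise (relative SD `noise_sd`, default
0.05, truncated at ±3 SD to preserve positivity). Averaging over clusters is
what keeps boundary recovery within ±1 week in ≥90% of replicates at the
default noise.

**Rendering.** Cluster images place elliptical berries on a jittered grid
over a near-white board (background gray 235–250); per-berry color offsets
are recentred by berry area so the ground-truth-mask mean reproduces the
configured mean RGB up to rounding. Exact masks accompany every image.

## Numerical conventions

- Grid rounding is half-up via `floor(10x + 0.5)/10` — platform-independent,
  no banker's rounding.
- Rate percentages are half-up to one decimal.
- All stochastic stages draw from `numpy` Generators seeded from the run
  seed (the pipeline spawns per-stage child seeds with `SeedSequence`), so a
  run is byte-identical given its configuration.

## Known limitations and resolved questions

- **Boundary weeks 12/14/17 vs a published 14/15/17 summary.** The source
  narrative is internally inconsistent about the boundary weeks; the
  archetypes follow the per-variety development narratives (the recovery
  target for the first variety is week 12).
- **Published GPI values.** The documented normalization reproduces the
  published S-model GPI (−3.03) and the full published rank row for the
  first variety; some other printed GPI values are not reproducible from the
  printed metrics under any normalization variant tried, and are treated as
  erratum rather than targets.
- **Zero-margin weeks.** With a 0.5-week step and boundary 12, the raw Mc
  ramp passes exactly through 0.25 and 0.55, which sit on rounding edges;
  the grid label there is a tie-break with zero margin, so all-weeks level
  accuracy cannot be exactly 100% for any regressor with nonzero error.
  Level accuracy is therefore judged on the ripening band, whose true levels
  lie exactly on the grid.
- The generator models means and plausible shapes, not within-cluster
  variance structure, weather shocks, or year effects; two-season replication
  in the source data is out of scope.
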