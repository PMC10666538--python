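# Methods

## Labels: areal productivity

A growth interval is delimited by two consecutive density measurements
tagged `harvest_cycle`; pairs touching `grow_out` or `final_harvest` rows
are discarded.  Its label is

    P = (AFDW_end − AFDW_start) · V_ORP / (t · A_ORP)   [g/m²/d]

with V_ORP = 1025 L and A_ORP = 4.2 m² by default (configurable).  Negative
productivities (net biomass loss) are kept in the data model; training
utilities can exclude them.  Sensor windows attached to an interval are
half-open `[start, end)` so a boundary record belongs to exactly one
interval.  The interval start uses the post-dilution density value, the end
the pre-harvest value.

## Pretreatment

Outliers are removed per pond/parameter stream with Tukey box-plot fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, quartiles by linear interpolation (type 7).
This is a *single* pass: iterated trimming is not a fixpoint on skewed
diurnal data (zero-inflated PAR, half-sine DO/pH) and is deliberately not
performed.  Outlier removal runs on the full seasonal streams before
interval assembly.  Cadence coarsening is stride decimation (keep every
n-th record), emulating an instrument that logs less often; no averaging.
Intervals missing more than 10% of expected records (configurable) are
excluded.

## Profile-image encoding

Each interval becomes a square RGB raster (224, 336 or 448 px; 50,176 /
112,896 / 200,704 pixels).  Five horizontal panels are stacked in the fixed
order pH, T, DO, TDS, PAR; each band is `floor(size/5)` rows with the
remainder given to the last band.  A panel is a bare 1-px polyline of value
vs time: no axes, ticks or margins; the y-axis autoscales to the data range
padded 5% on each side; a constant trace draws at band mid-height; gaps
longer than 1.5 cadence steps break the line; the time axis spans the
interval exactly.

Rasterization is an integer Bresenham renderer without anti-aliasing, so
encoding is bit-deterministic.  Normalized y-values are quantized to 1e-9
before pixel mapping so traces that are mathematically affine-equivalent
(e.g. offset by a constant) map to identical pixels despite last-ulp float
drift.  The affine autoscaling means a panel encodes only the *shape* of a
trace, not its level or amplitude — the property the sensitivity analysis
exploits.

### Perturbation operators

For a series X with window mean X̄ and factor F:

* offset:  `A = X ± F·X̄`
* expand:  `B = X̄ + (1+F)(X − X̄)`
* shrink:  `C = X̄ + (X − X̄)/(1+F)`

Expand and shrink preserve the mean exactly.  When a perturbed panel is
rendered for sensitivity analysis, *magnitude* perturbations (expand,
shrink) take the unperturbed series' padded extent as an axis floor: the
axis grows to fit larger data but never contracts.  Hence an expansion is
invisible (axis and data scale together) while a shrink visibly compresses
the line inside the original axis.  Offset panels render under plain
autoscale, which already makes them invisible; applying the axis-floor rule
to offsets would instead shift the line and break that invariance, so the
floor applies to magnitude operators only.  The exact algebra of the
operator family is configurable in principle; the defaults above satisfy
every stated behavioral property (offset and expand invisible, only shrink
informative).

## Synthetic campaign generator

The generator emulates the structure of an outdoor multi-pond monitoring
campaign; it is a testbed, not a mechanistic growth model (no nutrients, no
species competition, no hydraulics).

Per 15-min step (cadence configurable, must divide 1440):

* **PAR** = `peak · s(t) · cloud_d · flicker`, where `s(h) = max(0,
  sin(π(h−6)/12))` (zero at night), `peak` is scaled so the stream mean hits
  the configured target (default 377.7 μE/m²/s), `cloud_d` is a per-day
  log-normal factor (log-sd 0.35, unit mean) and `flicker` a within-day
  log-normal (log-sd 0.08).
* **T** = baseline + a·s(t − 2 h) + daily shift (sd 0.8 °C) + noise (sd
  0.4 °C), passed through a soft cap `softmin(·, T_cap = 33 °C, w = 1.5)`
  emulating evaporative cooling.  The per-pond diurnal amplitude `a` is
  drawn uniformly (default 8 ± 4 °C) and the baseline is chosen so the
  stream mean sits at the envelope mean (default 26 °C) regardless of `a`.
* **DO** and **pH** ride the cloud-modulated light signal in deviation form
  around their means (6.8 mg/L, 8.0) with Gaussian noise.
* **TDS** is a bounded Gaussian random walk around 27 g/L (±3 g/L).

Ground truth: daily growth `g_d = μ_max · M_d/(M_d + K_L) · exp(−λ·f_d)`
with `M_d` the day's mean PAR, `K_L = 60` (a saturating light term so light
explains only a minor share of variance), `μ_max = 0.04 g/L/d`, `λ = 3`,
and `f_d` the fraction of the day with T above `T_crit = 29.5 °C`.  AFDW
accumulates `g_d` without dilution events, and density rows are written at
every harvest boundary, so the Eq-1 label of each assembled interval equals
the integrated rule exactly.  Seeding is counter-based
(`SeedSequence((seed, pond, stream))`): adding ponds or streams never
perturbs existing ones, and identical configs are bit-reproducible.

**Why the temperature cap matters.**  Because panels are affine-normalized,
a noiseless sinusoid looks identical at any amplitude — excursion time
above `T_crit` would be invisible.  The cap produces flat-topped traces
exactly when stress occurs, making `f_d` visible in the image while the
interval *mean* temperature (all the tabular model sees) remains nearly
uninformative.  This realizes the designed confound: pond pairs with equal
mean temperature but different excursion time carry identical tabular
features and different images/labels.  `generate_matched_pair` constructs
such pairs exactly, root-finding the baseline so the capped means agree to
1e-9.

What the generator does *not* emulate: sensor drift/faults, weather
autocorrelation beyond one day, nutrient or CO₂ limitation, culture crashes,
inter-pond coupling.  Passing tests therefore demonstrate that the pipeline
recovers dynamics-encoded structure that averaging discards — not that the
specific field-data accuracies transfer.

## Models

* **AVM** — LightGBM gradient boosting on the five interval means.
  Hyperparameters (learning rate, leaves, trees, L2, min leaf samples) are
  tuned by an in-package Bayesian optimizer (Matern-5/2 GP with expected
  improvement over the unit cube, seeded) minimizing mean 5-fold CV RMSE on
  the training rows; the booster is refit on the full training set with the
  best parameters.  Default 25–50 trials.
* **IBM** — ensemble of five from-scratch CNNs (`pondcast.cnn.TinyCNN`):
  four conv(3×3)/ReLU/maxpool(2) blocks with 8/16/32/64 channels, global
  average pooling, linear head; trained with Adam (lr 3e-3, batch 16) on
  standardized inputs/labels, inputs being the 4×4 mean-pooled ink mask of
  the profile image (224 → 56 px working resolution).  The training set is
  split five times into random 80/20 subtrain/validation partitions (not
  disjoint folds); each member early-stops when validation MSE has not
  improved for 8 epochs (80 max) and restores its best-epoch weights.
  Ensemble prediction is the arithmetic member mean.  A pretrained
  large-corpus backbone is the production-scale option; this package does
  not ship pretrained weights, and `backbone` accepts only `"tiny-cnn"`.
* **Split protocol** — one random 80/20 train/test split per run seed,
  drawn within pond groups so every pond appears on both sides; the AVM and
  IBM consume the identical id lists.
* **Grad-CAM** — gradients of the scalar output w.r.t. the last conv
  block's activations are spatially averaged into channel weights; the
  rectified weighted activation sum is upsampled (nearest-neighbour) to the
  image and max-normalized to [0, 1].

## Sensitivity procedures

* **Monitoring resolution** — retrain the IBM at stride-decimated cadences
  with the shared split; fit test R² on ln(minutes) by OLS.  The
  establishment fit uses the 15/60/240-min models, with 120/180 as held-out
  verification, mirroring the published protocol; any point set is
  accepted.
* **Image resolution** — retrain at 224/336/448.
* **Per-parameter perturbations** — on the best-predicted interval per
  retention time (2, 3, 7 d), re-encode with shrink factors 0.05…1.0 per
  parameter, re-predict, and accumulate |Δprediction| (absolute and as
  percent of the unperturbed prediction, which is the chosen denominator).
  The sensitivity index divides each parameter's cumulative error by the
  maximum; exactly one parameter scores 1.0, ties all report 1.0 with a
  warning, and an all-zero run (e.g. offset perturbations) yields no index.

**Percent-change convention.**  All improvements/penalties use the
*reference* value as denominator, with metric orientation passed
explicitly; a penalty is the sign-flipped improvement.  Under this single
convention the published improvement triple (97.5/36.3/39.0%), the
monitoring-cadence penalties (36.1/38.6%) and the 2.25× image-density
penalties (2.9/3.0/6.5%) all reproduce exactly, while the two published MAE
penalties for the cadence (36.3%) and 4× density (10.9%) rows do not
reproduce under any single denominator (the latter only with the *new*
value as denominator); those two are therefore documented as inconsistent
and excluded from reproduction checks.

## Desk-scale study sizes

The bundled comparison study (`pondcast.study`) uses 12 ponds × 58 days
with harvest intervals cycling 2/3/4/7 d (198 labeled intervals), three
seeds, 25 HPO trials, and the 56-px CNN working resolution — sizes chosen
so a full three-seed comparison runs in minutes on one CPU while leaving
the qualitative orderings (IBM > AVM; 240 min ≤ 15 min) stable across
seeds.

## Known limitations

* The image encoder discards level and amplitude by design; models cannot
  distinguish, e.g., a pond at pH 7 from pH 9 with the same trace shape.
  The field workflow accepts this; it is the mechanism behind offset
  invariance.
* The tiny CNN is a desk-scale stand-in for a pretrained deep backbone;
  absolute accuracies on real campaign data are out of scope here.
* The Bayesian optimizer is a compact GP/EI implementation intended for
  ≤6-dimensional spaces and ≤100 trials.
* Timestamps are naive local time; no timezone or daylight-saving
  arithmetic.
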