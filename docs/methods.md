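# Methods

This note documents the models, the simulator, the numerical choices and
the limitations of the package, in the order data flows through it.

## The monitored system and the fresh-weight calculation

A monitored system is one substrate slab (stone wool, volume V litres, dry
mass M grams) hosting `plants_per_slab` plants on a weighing frame. The
load cell reports the total system weight W (crop + substrate + water);
a dielectric sensor reports the slab's volumetric water content θ
(dimensionless fraction). With water density fixed at 1 g mL⁻¹, the water
mass in kilograms equals θ·V with V in litres. The daily estimate is

    FW(d) = mean_24h W(d) − M/1000 − θ̄_night(d) · V     [kg per system]

**Night window.** Irrigation is radiation-triggered and transpiration is
radiation-driven, so at night the slab's water store is quiet and θ then
measures stored water without crop-weight contamination; by day the
10-minute weight change tracks the VWC-derived water change roughly 1:1
(irrigation doses and transpiration move both), which is exactly why a
daytime θ cannot be used to subtract water. The default night window is
22:00–04:00, closed at the start, open at the end (36 samples on a
10-minute grid); samples after midnight are attributed to the day that
just ended, since that night belongs to the preceding growth day. Both the
window and the attribution are configurable.

**Aggregation minima.** A day needs 120 of 144 weight samples and 75% of
its night window to produce an aggregate; thinner days are dropped with a
warning. These tolerances absorb small residual gaps after interpolation.

**Gap handling.** Invalid records (wireless-upload losses) are linearly
interpolated per channel between the nearest valid neighbours. The stream
must start and end valid; an all-invalid channel is an unrecoverable-gap
error. No learned imputation is attempted.

**Root imputation.** Destructive references add an imputed root fresh
weight to the sampled shoot fresh weight: root dry = shoot dry × RS,
root fresh = root dry / DF. RS (root/shoot dry) and DF (root dry/root
fresh) are required configuration with no package default — they are
season- and culture-specific measurements; the simulator supplies its own
true values in tests. Negative computed fresh weights are reported and
flagged, never clipped: they signal calibration faults a monitoring system
must surface.

**Units.** Internal canonical units are grams and cm³; the public API
speaks kg and L. The substrate weight subtracted is the *dry* mass — the
water it holds is what the θ·V term accounts for.

## The greenhouse simulator

The simulator produces everything the pipeline consumes with known truth:

* **Growth.** Fresh weight per system and leaf area per plant both follow
  logistic curves in days after transplanting; harvests/hard prunings are
  step decreases; topping (removing the shoot apical meristems) freezes
  leaf-area growth and lets it decay by 0.2%/day. Shoot and root dry
  masses derive from a fixed dry-matter fraction (default 0.10) split so
  that root dry = shoot dry × RS exactly. Defaults put the season in a
  0–3.2 kg/system and 0–5100 cm²/plant range over ~100 days.
* **Radiation.** A half-sinusoid between 06:00 and 18:00 whose daily
  integral is lognormal around 10 MJ m⁻² day⁻¹ (CV 0.25) — the simplest
  driver with a day/night structure.
* **Irrigation.** A radiation-integral controller: the accumulator starts
  at zero each midnight, and each time it reaches the threshold
  (0.5 MJ m⁻²) an event delivers `dose_per_dripper` (66 mL) × drippers
  and the threshold is subtracted (carry-over semantics). The number of
  events on a day therefore equals ⌊daily radiation / threshold⌋, which is
  the oracle the tests check. A dose that could never fit the slab's
  holding capacity is a configuration error.
* **Water balance.** Transpiration is bilinear in radiation and leaf area
  (coefficient 200 g of water per MJ m⁻² per m² of leaf, throttled when
  the store falls below 25% of capacity); excess water above
  capacity = `water_capacity` × V drains instantly. θ = store/V exactly;
  sensor noise (gaussian, defaults 50 g on weight, 0.01 on θ) applies to
  the *reported* values only, never to the hidden balance.
* **Within-day weight interpolation** is centred: the 144-step profile of
  a day averages exactly to that day's ground-truth fresh weight, so daily
  averaging introduces no growth-trend bias.
* **Camera.** Frames are a grey-brown textured background plus green
  ellipses ("leaves", mean 110 cm², hue-jittered) drawn sequentially from
  a seeded generator; the leaf count scales with leaf area, so the green
  projected area is a monotone, saturating function of leaf area, and for
  a fixed seed a larger canopy draws a superset of a smaller one's leaves
  (pixel-level monotonicity by construction). An illumination factor
  scales brightness per frame (lognormal CV 0.15 through the day). Default
  sensor 1280×720; 18 px per cm² of leaf puts a closed 4-plant canopy near
  40% frame coverage. No photorealism is attempted — the estimator is
  meant to rely on projected canopy area.
* **Data loss.** Non-overlapping invalid runs (≤ `max_gap_len`) are
  injected until exactly round(rate·n) records are invalid; the first and
  last records are never invalidated so interpolation is always bounded.

**What the simulator does not emulate.** Real canopies occlude
themselves in depth, cameras see neighbouring rows, substrates age,
sensors drift, and radiation has cloud-scale flicker. Passing tests
demonstrate that the algorithms are correct and well-conditioned under the
stated mechanisms, not that the accuracy numbers transfer to a particular
greenhouse.

### A structural note on daily conservation

The estimate subtracts the *night* water store from the *24-h mean*
weight. Whenever the store draws down intra-day (transpiration between
irrigation events), the daily mean store is strictly below its night
value, so the estimate carries a structural error equal to that gap — with
the default transpiration coefficient it is of order 0.03 kg RMSE over a
season, and no estimator using this window pairing can avoid it. The
conservation check therefore runs the *equilibrium-irrigation*
configuration (transpiration coefficient 0; the controller plus instant
drainage pin the store at capacity), where the identity is exact to float
precision (< 10⁻⁹ g observed, asserted < 1 g/day). The irrigation-
invariance check runs with transpiration *on* and shows the structural
error is insensitive to irrigation frequency (doubling the event rate at
unchanged daily water moves the seasonal RMSE by ≲ 0.015 kg, bounded in
the tests by 5% of the asymptotic crop weight).

## Leaf-area labeling

`SigmoidGrowthModel` fits LA(DAT) = L/(1+exp(−k(DAT−x₀))) + b by
nonlinear least squares (scipy `curve_fit`, bounds L,k > 0) with
multi-start initialisation: L from the data range, x₀ from the median and
mid-range DAT, k from a coarse grid of 1–16 transitions per span. One
outlier pass removes samples with |standardised residual| > 2.5 (skipped
when the residual SD is float dust, < 10⁻⁸ of the data scale) and refits
with multi-start again — refitting only from the contaminated optimum can
land in a bad basin. A monotone-decaying variant L·exp(−k(DAT+x₀)−b) is
available as `form="decay"` for comparison; it cannot describe sigmoidal
growth and is not used for labels. Labels are per plant; a camera view of
n plants sees n× the area, which the image regressor absorbs as a constant
factor as long as the plant count in view is stable.

## The image track

Frames with clock time in the closed window 08:00–16:00 are kept; margins
of (80, 300) px are cropped symmetrically (1280×720 → 1120×120), the crop
is bilinearly resized to 128×128 and scaled to [0, 1]. The regressor is a
4-stage strided conv stack (16→32→64→64 filters, 3×3, stride 2, batch
norm, ReLU) with global average pooling and a 64-unit dense head — the
smallest capacity that passes the overfit smoke test; it is fully
configurable via `RegressorSpec`. Training minimises MAE with Adam on
z-scored labels (inverted at prediction), with a 70/30 train/validation
split stratified by DAT so both splits span the season. Flip/shift/rotate
augmentation (±10% translation, ±15°, reflection fill) is implemented and
tested but off by default: the package applies it as a one-shot transform
of the training copies rather than per-epoch resampling, and at the
default 80 epochs that acts as label-preserving input noise and measurably
lowered cross-season accuracy in development. Training runs in float32
(halves CPU matmul time at no measurable accuracy cost), decays the
learning rate by 0.3× after 2/3 of the epochs, and restores the weights of
the best-validation epoch at the end (early-stopping checkpoint) — the
standard variance damper for small stochastic trainings. Desk-scale
protocol: 5 frames/day over 80 simulated training days (400 frames) and
8 frames/day over 60 test days (more test frames stabilise the daily
means being scored), 80 epochs, batch 16, lr 2·10⁻³ — about 3 minutes on
one CPU with the numpy engine.

The cross-season check trains on season A and scores daily-mean
predictions on season B (different growth curve, 15% dimmer illumination,
topping) against B's label curve; the negative control permutes A's daily
labels across dates before training, which must destroy generalisation.
A signal-dependence check requires per-frame predictions to rank-correlate
(Spearman ρ ≥ 0.8) with the green-pixel fraction of the test frames.

## The daily-weight comparison

One sample per complete day: the raw 144-step weight sequence (kg) as
input, the calculated daily crop weight as target. Features and targets
are standardised with *training-season statistics only* — deliberately, as
this is the mechanism that cannot transfer a between-season offset. The
linear baseline is the minimum-norm least-squares map (numpy `lstsq`;
optional ridge for ill-conditioned inputs). The sequence network embeds
the day with a strided 1-D conv (d=16), adds sinusoidal positions, applies
one single-head self-attention block with a residual connection and layer
norm, pools, and regresses through a 32-unit head; a plain 1-D conv stack
is available behind the same interface. MAE, Adam, 200 epochs.

The bias experiment gives the test season a slab 0.3 kg heavier than the
training season's and runs both seasons in the equilibrium-irrigation
configuration so the offset mechanism is isolated from the intra-day
drawdown error: the learned models inherit ≈ 0.3 kg of mean bias, the
subtraction formula stays within ±0.002 kg, because it is told each
season's own substrate mass — re-measuring the substrate is the entire
calibration burden of the closed-form method.

Within a season, this task is *exactly linear* (target = mean weight −
night water − constant), so the OLS baseline sits at the irreducible
sensor-noise floor (~0.03 kg) and the sequence network cannot beat it;
measured ratios were 2.9–4.7× at 40–66 training days. The comparability test
asserts the qualitative finding — both families accurate (R² ≥ 0.9), no
deep-learning advantage, same order of error — rather than a fixed ratio
band, which a floor-sitting baseline makes unattainable.

## Orchestration and reproducibility

`run_pipeline` executes simulate → preprocess → calc_fw → labels →
train_la → train_fw → report on a file-based artifact store; every stage
re-loads its inputs, so stage subsets compose to the same result as a full
run. Every stochastic stage derives its seed from the global seed by
hashing (seed, stage, season), so one integer reproduces the entire report
bundle, including figures and a config-hash provenance block. The CLI
(`phenoscale simulate|calc-fw|fit-labels|train-la|train-fw|evaluate|run-all`)
is a thin wrapper over the same stages.

## Known limitations

* The camera model carries no 3-D structure; occlusion is only mimicked by
  ellipse overlap, so the saturation of green area with leaf area is
  milder than in a real dense canopy.
* The transpiration model is bilinear and instantaneous; real crops buffer
  water, which decouples daytime weight and VWC changes more strongly than
  the simulator does.
* The structural error of the mean-day/night-window pairing (above) is
  inherent to the method, not to the implementation.
* Label quality bounds the image model: it is trained and scored against
  the fitted growth curve, not against per-day measured leaf area.
* The numpy network engine is single-threaded and meant for desk-scale
  protocols (hundreds of frames, ≤ 10⁵ parameters), not for production
  training.
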