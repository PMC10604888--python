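# Methods

## Problem and model

`weanwave` predicts the outcome of ventilator weaning — reintubation for
respiratory failure within 48 h of extubation ("failure") versus stable
extubation ("success") — from nothing but what the ventilator itself
records during a 30-minute spontaneous breathing trial (SBT): a
3-channel waveform (airway pressure Paw in cmH2O, flow in L/min, volume
in mL, one sample every 15 ms) and 25 numeric monitoring channels logged
at a sub-breath cadence.

The classifier is a two-branch convolutional network.  Each branch is a
MobileNetV3-Large feature extractor at 0.75 width: a stride-2 stem
convolution, 15 inverted-residual bottlenecks (pointwise expansion,
depthwise 3×3 or 5×5 convolution, squeeze-excitation on the standard
subset of blocks, pointwise projection, residual skip where shapes
match), and a 1×1 head convolution to 720 channels.  The waveform branch
has a 3-channel stem, the numeric branch a 25-channel stem; everything
downstream of the stems is identical.  Each 1-D multichannel series is
first folded row-major into a 2-D image (width 130 for the waveform,
70 for the numeric table), which lets ordinary 2-D convolutions see both
within-breath morphology (along a row) and breath-to-breath structure
(down a column).

The two pre-pool 720-channel maps are fused by adaptively
average-pooling each to 10 spatial slots and concatenating them into a
720×20 map.  An MLP encodes this fused map to a 720-vector: 1×1
convolution 720→36 with batch norm and hard-swish, flatten (36×20=720),
then two skip-connected subblocks (linear 720→3724, batch norm, SiLU,
linear 3724→720, skip add, SiLU).  The MLP output is concatenated with
the two branches' globally averaged 720-vectors and classified by two
biased 1×1 convolutions (2160→1280, hard-swish, 1280→1).  The single
output is the logit for weaning failure (the minority class is the
positive class); a sigmoid is applied only at predict time.

Because all spatial aggregation is by global or adaptive average
pooling, the forward pass accepts any input length; full uncropped
recordings are used at inference.

### Parameter census

The default model has exactly **17,124,721** trainable parameters.  The
backbone rows fix both extractors (1,789,648 + 1,792,816 parameters) and
the classifier head, but two MLP integers are not architecturally
determined: the 1×1-conv output width *m* and the subblock hidden width
*h*.  `scripts/backsolve_census.py` enumerates every admissible reading
with a closed-form census model; the shipped defaults (*m*=36, *h*=3724,
subblocks on the flattened 720-vector, batch norm after the 1×1 conv)
are the solution in which the classifier consumes three equal
720-vectors — the most symmetric of the three exact solutions the search
finds.  The census is recomputed from realized tensors at assembly and
embedded in every checkpoint as an integrity check.

## Preprocessing

1. **Min-max normalization** per channel over the full recording:
   `(x − min)/(max − min)`; a constant channel maps to zeros (it carries
   no information, and this avoids 0/0).  Normalizing before cropping
   means every crop sees the recording's global scale.
2. **Random crop** (training only): a contiguous window of 13,000
   waveform steps and 3,500 numeric steps, start uniform over valid
   positions, all channels sharing the start.
3. **Row-major fold** to 2-D with widths 130 and 70.  The training
   lengths factor exactly (13,000 = 100×130, 3,500 = 50×70), so training
   images carry no padding.  At inference the tail is truncated to a
   whole number of fold rows (at most 129 waveform / 69 numeric steps,
   ≤0.6% of a recording) rather than padded: on short recordings a
   padded partial row is a substantial out-of-distribution region of the
   small folded image and measurably distorts eval-mode activations.

## Training recipe

Binary cross entropy on the failure logit; AdamW with learning rate
1e-4, weight decay 5e-2, batch size 4.  The cohort is split 8:2
(stratified by label) into training and test sets; a `val_fraction`
slice of the training set (default 10%) drives early stopping
(default patience 10, max 50 epochs).

Three recipe details matter for short CPU-scale runs and are the
package's own design choices:

* **Identity-at-init residuals.**  The projection batch norm of every
  residual bottleneck starts with zero scale, so each residual block is
  initially the identity.  Without this, a randomly initialized
  15-block stack contracts inter-sample differences until the output is
  effectively constant, and brief training runs cannot recover.
* **Crop augmentation factor.**  `crops_per_epoch` (default 4)
  independent random crops of each recording are drawn per epoch.  An
  "epoch" over a few dozen recordings at batch size 4 is otherwise only
  a handful of optimizer updates; random cropping is the natural
  augmentation on offer.
* **Batch-norm recalibration.**  After the last epoch the running
  statistics of every batch norm are recomputed as the equal-weight
  average of batch statistics under the final weights.  Exponential
  running averages remember early, stale activations after short runs,
  which otherwise opens a gap between train-mode and eval-mode forward
  passes.

Optimizer moment state is kept in float32 (parameters stay float64).
Training is a pure function of `(cohort, TrainingConfig.seed)`.

## Evaluation

Nine metrics on the held-out test set, all computed from full-length
inputs: AUROC, AUPRC, sensitivity, specificity, PPV, NPV, accuracy, F1
and the parameter count.  Records are *ranked by logit* — the sigmoid is
monotone, so AUCs are unchanged, but probabilities underflow to exactly
0 or 1 beyond |logit| ≈ 37 and would collapse distinct records into
artificial ties.  Threshold metrics are evaluated at the Youden-index
cutoff (J = sensitivity + specificity − 1, maximized over observed
scores, ties broken toward the smallest threshold; reported on the
probability scale).  Any 0/0 ratio is reported as an explicit undefined
marker (`None`), never silently 0.  Confidence intervals are 95%
percentile bootstrap over case resampling (default 2,000 replicates,
single-class resamples redrawn, seed-controlled).

The comparison baseline is the rapid shallow breathing index,
RSBI = f/VT (breaths/min/L), computed from each record's realized mean
rate and tidal volume, with the classical cutoff of 105; the boundary
value counts as a failure call.  For ROC purposes the continuous RSBI
value is the score.

A small `grid_search` utility trains one model per declared
hyperparameter combination and selects by internal-validation loss; it
is a convenience for exploring MLP/recipe dimensions, not a re-run of
any full-scale search.

## Grad-CAM explanation

For a chosen branch, with A the branch extractor's final 720-channel
convolutional map on the full-length input: α_k is the spatial mean of
∂(failure logit)/∂A_k, and the class-discriminative map is
L = ReLU(Σ_k α_k A_k).  L is bilinearly upsampled to the folded image
grid, unfolded row-major, truncated to the recording length and
max-normalized to [0, 1], giving one brightness weight per time step.
`render_overlay` draws these weights behind the three waveform channels
and emits a machine-readable sidecar (`*.bands.json`) listing contiguous
intervals whose weight exceeds a threshold (default 0.5), so downstream
checks never parse pixels.  The "success" explanation is the negated
gradient of the same single logit.  Faithfulness is tested two ways:
algebraic properties on the real model (non-negativity; a branch the
classifier ignores yields an identically zero map) and rank agreement
with an occlusion oracle on toy conv→ReLU→pool→linear models, where the
logit is linear in the feature map and Grad-CAM is provably faithful.
On the full 15-block model the first-order Grad-CAM approximation is an
interpretation aid, not a guarantee.

## Synthetic SBT simulator

No public SBT waveform corpus with outcome labels exists, so the
simulator generates the study conditions the package is exercised
under: 30-minute (configurable) pressure-support trials at PEEP
5 cmH2O + 6 cmH2O support, waveform sampled every 15 ms, numeric
channels logged every 0.5 s.  A per-breath logging cadence cannot
produce the 3,500-step training length within a 30-minute trial at
physiological rates (≈600–1,000 breaths), so a sub-breath cadence is
used and each numeric channel is held piecewise-constant across a
breath — 3,600 steps per 30-minute trial.

The breath template is closed-form-checkable rather than a
lung-mechanics ODE: half-sine inspiratory flow raised to the power
1 + dyssynchrony (rounding the profile), discretely rescaled so peak
volume equals the breath's tidal volume; passive exponential expiration
with time constant Te/3, rescaled so volume returns to baseline; Paw
rising to PEEP + PS with a dyssynchrony-scaled mid-inspiratory dip
(depth 1.5·dys·PS, dipping below PEEP at high effort) and exponential
relaxation in expiration.  Breath-to-breath periods and volumes jitter
with per-phenotype coefficients of variation; small Gaussian measurement
noise is added per channel.  Cough artifacts are ~0.6-s biphasic
transients (a 200 L/min-scale expiratory blast with a Paw surge, then a
brief rebound) injected at Poisson-distributed times (default
0.1/min), local by construction: samples more than 2 s away are
bitwise unchanged.

**Outcome phenotypes.**  Success: regular breathing, rate 14–24/min,
tidal volume 0.35–0.55 L, dyssynchrony ≤ 0.15.  Failure is a mixture:
60% rapid-shallow (28–38/min, 0.15–0.30 L — RSBI well above 105) and
40% dyssynchrony-dominant (18–28/min, 0.30–0.45 L — near-normal RSBI,
but deep Paw dips, rounded flow and 2–3× larger breath-to-breath
variability).  This mixture keeps the expected failure RSBI above
105 and the expected success RSBI below it, while making a thresholded
RSBI an informative but beatable baseline — clinically, RSBI's known
weakness is exactly the patient who fails for reasons other than rapid
shallow breathing.  Labels are assigned by stratified rounding
(`round(n × prevalence)` failures exactly), and the whole cohort is a
pure function of the seed.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: real lung mechanics (no equation of
motion, no compliance/resistance dynamics shaping the waveforms), mode
changes, suctioning and position-change artifacts, sensor drift,
demographic covariates, and any clinically realistic overlap structure
between outcome groups beyond the RSBI overlap designed in.  Results on
simulated cohorts demonstrate that the pipeline is implemented
correctly and can learn morphology-level signal, not that the
architecture attains any particular clinical performance.

## Scaled-down study sizes

The acceptance experiment runs the full pipeline at desk scale: 40
patients, 5-minute recordings, stratified 8:2 split, 10 epochs with
`crops_per_epoch=8` (640 optimizer updates), all seeds 0.  At 5 minutes
a recording has 600 numeric steps, so that experiment uses a 560-step
numeric crop (8 fold rows) in place of the 30-minute default of 3,500;
the waveform keeps its full 13,000-step crop.  On one CPU the experiment
takes roughly 8–10 minutes.

## Numerical choices and degenerate inputs

* All computation in float64 (optimizer moments float32); batch-norm
  eps 1e-5, momentum 0.1; Adam betas (0.9, 0.999), eps 1e-8.
* He/fan-in initialization for convolutions, uniform ±1/√fan_in for
  linears; initialization is deterministic under the assembly seed.
* BCE computed in the underflow-safe softplus form.
* Constant channels normalize to zeros; empty series, NaN values,
  mismatched lengths, unknown channel names and duplicate patient ids
  all raise typed errors at validation time rather than propagating.
* Youden ties break toward the smallest threshold; RSBI exactly 105 is
  called failure; bootstrap resamples with a single class are redrawn.
* CSV round-trips are preserved to ≤1e-4 absolute by writing 8
  significant digits.

## Known limitations

* The 25 numeric channel names are a documented stand-in inventory (the
  clinical system's own list is not public); the set is
  config-overridable but the canonical order is fixed package-wide.
* Grad-CAM on the deep model is first-order and coarse (the map grid is
  the final conv layer's); short recordings have little or no vertical
  CAM resolution.
* Training at clinical scale (hundreds of 30-minute recordings, many
  epochs) is possible but slow on pure-CPU numpy; the package is built
  for method-level correctness and desk-scale experiments.
* The RSBI baseline uses recording-level mean f/VT, not the classical
  1-minute bedside measurement window.
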