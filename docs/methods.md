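# Methods

This note documents the models and procedures implemented in `icuacuity`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate.

## Problem and phenotype

ICU acuity is treated as a per-window, four-level state. Each stay is tiled
into consecutive prediction windows (default 4 h, half-open `[start, end)`,
0-based indices, times in fractional hours since admission). A window is

* **unstable** if any life-sustaining therapy overlaps it — invasive
  mechanical ventilation (MV), intravenous vasopressors (VP, including
  one-time pushes, represented as zero-length intervals that mark their
  enclosing window), continuous renal replacement therapy (CRRT) — or if the
  massive-blood-transfusion criterion (≥ 10 units in the trailing 24 h,
  threshold configurable) holds anywhere in the window;
* **deceased** or **discharge** on the stay's final window according to the
  disposition; the terminal state overrides an active therapy;
* **stable** otherwise.

The final partial window (stays whose length is not a multiple of the window
length) is kept so terminal outcomes are never dropped. Cohort filters keep
stays with length of stay in `[8 h, 30 d]`, at least one recording of each of
the six routine vitals (HR, RR, SBP, DBP, Temp, SPO2), and complete static
fields; every exclusion carries a machine-readable reason code.

Nine binary outcomes are labeled per prediction window: the four primary
states (one-hot), the two transitions (stable→unstable, unstable→stable;
masked — not negative — on the first prediction window, which has no
predecessor state), and three therapy onsets (MV, VP, CRRT). An onset
requires a therapy interval starting inside the window with the therapy
absent throughout the preceding 4 h; the preceding interval always exists
(the first prediction window is preceded by the first observation window),
so onset labels are never masked. BT has no onset label: its definition
looks back 24 h, so the therapy is already underway at prediction time.

The rolling transfusion flag is evaluated exactly: the trailing-24 h unit
sum is piecewise constant and can only reach its maximum over a window at
the window start or at an event time inside it, so only those points are
checked.

## Encoding

Observation windows are encoded as padded triplet sequences — (time since
admission, scaled value, integer variable code) — with a binary mask and no
imputation of any kind. The vocabulary is fitted on the development cohort:
variables in fewer than 5 % of stays are dropped (the boundary is inclusive:
exactly 5 % is retained), codes are dense and assigned by order of first
appearance with 0 reserved for padding, outliers outside the 1st–99th
percentile band (inclusive) or configurable hard physiologic bounds are
removed, and min–max scaling ranges are frozen from the development data
(validation values clip to `[0, 1]`; constant variables scale to 0.5).
Times are scaled by a fixed 720-h horizon (the 30-day maximum stay), which
keeps the encoding invertible. Simultaneous events are ordered by ascending
code, making the encoding a pure function; when a window holds more than
`L` events the most recent `L` are kept, on the view that recency carries
the most predictive information.

## Sequence model

The network follows the architecture: 1-D convolutions embed the time and
value channels (causally — an event's embedding never sees later events or
tail padding), a lookup table embeds the code channel (the padding row is
fixed at zero), the three are summed with a parameter-free sinusoidal
positional encoding, and two gated selective state-space blocks add
temporal context. Each block applies an input projection, a causal
depthwise convolution and SiLU, then a diagonal input-conditioned linear
recurrence

    h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t x_t,    y_t = C_t h_t + D x_t

with Δ_t = softplus of a low-rank projection of the input, B_t and C_t
linear in the input, A initialized as −(1 … S) per channel, followed by
multiplicative SiLU gating and a residual output projection. The per-step
log-decay Δ_t·|A| is capped at 30 (a decay of e⁻³⁰ per event is already
total forgetting), which also keeps the vectorized scan's running products
inside double precision. Top-k pooling summarizes the sequence: the k
unmasked positions with the largest L2 norm are averaged ("most important
states" is not further specified in the source description; a norm
criterion is the parameter-free reading). The pooled vector passes through
an MLP to the model width and is added to a two-layer embedding of the
static features; nine independent sigmoid heads read out the outcome
probabilities (no cross-head normalization). The static pathway is
initialized at a tenth of the usual weight scale: at initialization a wide
untrained static branch would inject large random per-stay offsets into
every head (and corresponding spurious attribution mass), so the temporal
pathway dominates until training finds genuinely predictive statics.

Defaults: model width D = 64, two blocks, inner width 64 (expand 1), state
size 16, Δ-rank 32, k = 8, maximum sequence length L = 256, trunk MLP
hidden width 4096 and static hidden width 1024. The wide per-window MLPs
put the parameter count at ≈ 0.64 M — the ~1 M-parameter regime the method
targets — while keeping the per-token sequence-layer cost small enough for
single-CPU training. None of the widths are prescribed by the source
description; they are this package's choices and are all configurable.

Three scan implementations exist and are held to mutual agreement by
contract tests: a step-by-step sequential reference, a chunked vectorized
numpy scan (running products with per-chunk renormalization; valid for
strictly positive decays), and a fused numba kernel (the default) that
evaluates the recurrence and its adjoint in single passes over memory,
recomputing decays on the fly. Further contracts: causality (perturbing a
position never changes earlier outputs — exact, not approximate), and an
LTI limit: with input-independent Δ/B/C and gating, convolution and
activation disabled, the block must match a direct convolution with the
impulse response implied by its parameters to 1e−5.

Training minimizes the sum over heads of class-weighted binary cross
entropy (positive weight = N_neg/N_pos on the training split, capped at
100; heads without positive training labels are frozen with a warning;
masked labels contribute nothing). The development split is by patient,
never by window. Optimization uses Adam (lr 1e−3, batch 32, 3–5 epochs at
the scales exercised here), with windows of similar event count bucketed
into common batches and batch order reshuffled per epoch; the
best-validation-loss checkpoint is kept. Training is bit-reproducible
under a fixed seed. Decision thresholds per head maximize the Youden index
J = sensitivity + specificity − 1 over observed probability values, ties
broken toward the lower threshold.

A fixed priority logic maps thresholded heads to one acuity state:
deceased first; else unstable if any of {unstable, stable→unstable, MV,
VP, CRRT} fires; else discharge if the discharge head fires; else stable.
The unstable→stable head is evaluated but does not enter the logic.

## Evaluation, calibration, baselines

Step-level metrics: AUROC (midrank ties), AUPRC (precision–recall step
integration), and sensitivity/specificity/PPV/NPV at a threshold. Episode
level scores each admission once by the maximum predicted probability over
eligible windows — strictly pre-onset when the outcome occurs, all windows
otherwise; admissions whose outcome begins in the first eligible window are
excluded with a logged reason. Alert thresholds can target an episode-level
precision (default 33 %); lead time is the gap in hours between the first
super-threshold window and onset, and alerts are counted up to and
including the onset window (an onset-window alert is a correct zero-lead
prediction). Uncertainty comes from a stay-level bootstrap (100 iterations,
2.5/50/97.5 percentiles; failed resamples are redrawn up to 10 times);
models are compared with a two-sided Wilcoxon rank-sum test, exact for
tie-free samples up to n = 25 and normal-approximated with tie correction
otherwise.

Isotonic regression (pool-adjacent-violators, via scikit-learn) recalibrates
head probabilities on a seeded 10 % stay-level sample; the fitted step
function clamps outside its domain, serializes to JSON exactly, and is
evaluated by the Brier score and an equal-width reliability curve (10 bins
by default, empty bins omitted). A single-class fit sample yields the
constant map rather than an error. Note that the monotone map can merge
misranked pairs into ties, so AUROC after calibration may move slightly in
either direction; what is guaranteed — and tested — is that no pair is ever
inverted.

The SOFA baselines consume a precomputed integer 0–24 score series per
window: the raw score scaled by 1/24 as a risk score, and the binary
criterion of a ≥ 2-point rise over the admission (baseline) score.
Computing SOFA from organ components is out of scope.

## Attribution

Integrated gradients are computed at the embedding layer, from an
all-padding baseline (and zero static vector) to the window's embedding,
with midpoint interpolation. Because top-k pooling selects positions
discontinuously, the selection is frozen at the actual input's choice along
the path, which makes the integrand smooth and restores the completeness
axiom (checked to < 1 % relative gap at 256 steps, and exactly on a linear
surrogate). Per-event attributions sum the embedding channels and are
exactly zero at padded positions. Feature importance averages signed
attributions (absolute behind a flag) over events, windows, and the six
increased-acuity heads (unstable, stable→unstable, MV, VP, CRRT onset,
deceased), reporting a ranked top-15 table. The importance table is
computed over elevated-acuity windows: signed attributions averaged over a
mostly-stable cohort measure the net direction of a feature's influence
rather than its importance (an elevated vital on a stable window
legitimately attributes *against* instability), whereas on unstable
windows the features that drive increased-acuity predictions surface with
positive mass.

## Synthetic cohort generator

The generator is the test bed for everything above. Each stay draws a
length of stay from a log-normal (mean 48 h, matching the roughly two-day
median of real ICU cohorts; truncation to `[8 h, 30 d]` can be disabled to
exercise the cohort filters), and a latent risk trajectory: a bounded
random walk on `[0, 1]` on an hourly knot grid, linearly interpolated, with
a positive drift for a deteriorating subpopulation (35 % of stays).
Observed events are per-variable homogeneous Poisson processes (default
0.5 events/h per variable, 12 temporal variables, 10 % missingness
thinning). Risk-coupled vitals carry the planted signal: an event's mean is
shifted by `signal_strength × coupling × risk(t)` standard deviations
(couplings: HR +1.0, RR +0.7, SBP −0.8, DBP −0.4, SPO2 −0.6; extra "lab"
variables are uncoupled noise so attribution has non-predictive
competitors).

Therapies start via per-window Bernoulli draws with a steep logistic link
on risk (thresholds 0.70/0.65/0.85 for MV/VP/CRRT) and stop shortly after
the risk recedes below threshold − 0.15 — clinically, support is weaned as
the patient improves. The steep link and risk-linked stopping keep
instability aligned with the instantaneous latent risk, which is what makes
the planted signal recoverable at the window level: with signal strength 3
the latent risk itself separates unstable from stable windows at AUROC
≈ 0.93, and a plain logistic fit on window vital means reaches ≥ 0.9 (the
generator's required sanity floor). Death follows a discrete-time hazard
increasing in risk (≈ 5–7 % cohort mortality); transfusion bursts of single
units occur around the stay's risk peak so the rolling 24-h rule fires
during genuine crises; a synthetic SOFA series is a noisy monotone
transform of risk — note this makes SOFA an unrealistically strong
baseline on synthetic data (it nearly reads the latent risk directly),
unlike real SOFA against real deterioration. Zero hazard scales reproduce the degenerate cohorts
exactly (no therapies, everyone discharged). Ground truth (the latent
trajectory) lives in a sidecar structure and is never consumed by the
pipeline.

What passing tests on this generator do **not** show: realistic physiology
or pharmacology, inter-variable clinical correlation beyond the shared
latent risk, realistic inter-event time structure (sampling is homogeneous
Poisson, not clinically triggered), site effects, or the label noise of
real therapy records. Results on the synthetic bed validate the machinery,
not clinical performance.

## The null experiment

The no-signal control trains the same model with permuted labels and must
score at chance. The permutation is **global** across windows: it destroys
every feature–label association while preserving marginal label rates. A
within-stay permutation is provided as an option but is *not* a chance
control: it preserves each stay's outcome base rate, which remains
genuinely predictable from static covariates and the risk-coupled vitals —
on this generator a stay-propensity oracle scores AUROC ≈ 0.95 against
within-stay-permuted labels, and a trained model drifts above 0.55 as soon
as it learns any propensity. The global permutation tests what a null
should test: that the training pipeline cannot conjure discrimination out
of nothing.

## Problem sizes and numerical choices

The acceptance-scale experiments use 2,000 stays (~22,000 windows, ~450
held-out stays), three training epochs for both the signal and null runs,
and 32-step integrated gradients over 128 held-out windows; oracle
equivalence checks run on 1,000 stays and 10,000 random transfusion
configurations. Scan agreement is asserted at 1e−5, gradient rules are
finite-difference-checked at 1e−5, encode/decode round-trips at 1e−9, and
transition-matrix row sums at 1e−12. Degenerate inputs are handled
explicitly: empty grids for stays shorter than two windows, zero-vector
pooling for fully masked sequences, constant variables scaling to
mid-range, frozen heads without positive labels, and redrawn bootstrap
resamples when a metric is undefined.

## Known limitations

* The selective-scan kernel is single-threaded CPU code; the architecture
  is faithful but not a performance claim about accelerated
  implementations.
* SOFA is consumed, never computed; real deployments need an upstream
  score pipeline.
* Calibration and thresholds are fitted on the same validation split at
  desk scale; with more data a dedicated calibration split is preferable.
* The generator's missingness is independent thinning; informative
  missingness (sicker patients measured more often) is real and absent
  here.
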