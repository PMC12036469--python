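# Methods

This note documents the models, conventions and design choices behind
`sleepstrat`, in the order the pipeline runs.

## Synthetic data: what it emulates and what it does not

The package is exercised entirely on synthetic data with planted ground
truth, because the clinical registries this kind of analysis targets are
access-restricted.

**Nights** (`synthetic.generate_recording`). The hypnogram is a
discrete-time Markov chain over {W, N1, N2, N3, REM} at one step per 30-s
epoch. The per-epoch switch probability is `stage_transition_rate / 120`
(rate in switches per hour; 120 epochs per hour), capped at 0.95; on a
switch the next stage is drawn from a fixed stage-preference matrix with
self-transitions excluded. Optional `stage_weights` multiply the
preference columns, shifting the stationary stage mix (used to give
planted regimes distinct sleep architecture). Respiratory and
desaturation events are a homogeneous Poisson process restricted to sleep
epochs, with durations uniform on [10, 60] s, clipped to the recording
span — the simplest process consistent with AHI semantics (events per
hour of sleep). Signals are stage-dependent sinusoid-plus-noise
caricatures: EEG carries stage-specific carrier frequency and amplitude
(large 1.2 Hz amplitude in N3, alpha-band in wake), EMG amplitude falls
from wake to REM, the respiratory family is a 0.25 Hz breathing carrier
whose amplitude collapses tenfold during respiratory events, and SpO2 sits
at a configurable baseline with smooth 4–10 % dips co-located with
desaturation annotations. These caricatures preserve exactly the
structure the encoder's three tasks need (stage-dependent spectra,
event-dependent amplitude, saturation dips) and nothing else: passing
tests demonstrate that the pipeline machinery recovers planted structure,
not that it would score clinical PSG at any particular accuracy.

**Cohorts** (`synthetic.generate_cohort`). Survival times are exponential
with hazard `h0 · exp(β_g + Σ β_c (x_c − x̄_c))`; proportional hazards
holds by construction, so Cox fits have a well-defined estimand.
Censoring is independent exponential dropout plus administrative
censoring at the follow-up horizon (default 20 y, matching the scale of a
long observational registry). Covariates (age ~ N(52, 13²), sex, BMI ~
N(31, 6²), six comorbidity flags at realistic prevalences) are
group-independent by default so that adjusted and unadjusted fits
estimate the same group effect; `covariate_log_hazards` can plant
covariate effects when the distinction matters. AHI is drawn with a mild
upward shift per group so AHI-adjusted models have something to adjust
for. The event indicator is 1 when death precedes both censoring times.

## Preprocessing

Filters are elliptic IIR designs specified as *single-pass* targets:
total order 16, ≤ 1 dB passband ripple, ≥ 40 dB stopband attenuation.
A band-pass of total order 16 is designed as an order-8 low-pass prototype
(the band transform doubles the order). Filtering is applied forward and
backward (`sosfiltfilt`), which cancels phase and doubles attenuation in
dB; the printed specs are met by the single pass alone, verified
numerically in `measure_design` with a 0.35-octave transition margin
(an elliptic design reaches its stopband floor only past a finite
transition band). Resampling to 128 Hz uses polyphase rational resampling
with linear edge padding — zero padding would ring hard on channels with a
non-zero baseline such as SpO2 — and runs before filtering. Snore and
EtCO2 have no printed filter class and are assigned the airflow band-pass
as an explicit assumption. Normalization maps the empirical 5th/95th
percentiles to −1/+1; it is an affine map, hence idempotent on its own
output. A degenerate channel (5th = 95th percentile) normalizes to zeros
with a logged warning rather than raising mid-pipeline.

## Epoch encoder

The encoder is implemented in NumPy with hand-written backpropagation
(`nn.py`): dense layers, layer normalization, exact-erf GELU, unmasked
multi-head self-attention in pre-norm residual blocks, and Adam.
Gradient correctness is enforced by finite-difference tests rather than
inherited from an autodiff framework; float64 is used throughout.

Tokenization: ten 384-sample patches per channel per epoch, one shared
linear projection across channels (learned absolute position embeddings
supply channel identity; per-channel projections are available by
config), a learned SEP after every channel block — including the last,
so the sequence is `11·C + 1` tokens with CLS at the end; the fence-post
variant is a config switch. The stage head has 5 classes including wake
(wake epochs exist in any hypnogram and downstream metrics need them); a
`mask_wake` switch restricts the stage loss to the four sleep stages.
The total loss is the arithmetic mean of stage cross-entropy and the two
binary cross-entropies, verified to 1e-9 in tests.

Two configurations matter: `ModelConfig.full_scale()` (768-dim, 12
layers, 12 heads, learning rate 1e-5, batch 500, 50 training epochs) is
constructible but never trained in tests; the desk-scale default (64-dim,
2 layers, 4 heads, learning rate 1e-3, batch 250, 5 training epochs) is
what the end-to-end runs train. The higher desk-scale learning rate is
the standard compensation for training a small model from scratch rather
than fine-tuning a large pretrained one. Training is seeded and
single-device deterministic.

Event labeling uses the 5-second rule: an epoch is flagged when
annotations of a type overlap it by at least 5 s in total; overlap is
evaluated per epoch on raw intervals (long events flag several epochs),
and the result is independent of annotation order.

## Distributional clustering

Embedding matrices have shape d × T with T varying per night, so they are
compared distributionally: per embedding dimension, the values over
epochs form an empirical sample, two nights are compared per dimension
with the energy distance (or 1-D EMD), and distances are averaged over
dimensions. The per-time-step reading of "corresponding rows" is
impossible for unequal night lengths and is rejected. Both kernels are
computed by O(n log n) sorted prefix-sum identities and are tested to
1e-12 against the literal double-sum and quantile-L1 oracles; all rows of
a matrix are processed in one flat `searchsorted` by offsetting rows
beyond the global value range.

The N×N projection retains the zero self-distance column (dropping it
would make feature vectors unequal across samples; a constant column is
inert for k-means). k-means uses 10 seeded restarts and 300 iterations;
silhouette is computed on the same feature vectors, with 0 returned by
convention for a degenerate single-cluster outcome. Consensus matrices
subsample 80 % of samples and 80 % of feature columns for 100 iterations
and normalize co-assignment counts by co-sampling counts — not by the
iteration count — so rarely co-sampled pairs are not deflated;
never-co-sampled pairs are 0 and flagged undefined (probability
negligible at these sizes). The display ordering is the leaf order of
Ward clustering on 1 − consensus. Risk labels RG1..RGk sort clusters by
crude mortality (deaths per person-year) ascending, ties broken by
cluster id.

## Hypnogram metrics

Sleep fragmentation encodes the hypnogram numerically (default depth
scale W=0, N1=1, N2=2, N3=3, REM=1.5; the statistic is invariant to
affine recodings but not arbitrary ones, so the encoding is explicit
config), removes the mean, takes a rectangular-window periodogram (nights
are short; segment averaging is available by config), and reports the
fraction of total power at frequencies strictly above 1/600 Hz
(switching faster than 10 minutes). A constant hypnogram returns 0. A
binary transition-indicator variant is implemented as an alternative
definition; the encoded-hypnogram variant is the default and the one
asserted in tests. TST counts non-wake epochs at 0.5 min; stage
percentages are relative to TST; AHI and the arousal index divide
annotation counts by TST hours, with severity bands normal < 5 ≤ mild
< 15 ≤ moderate < 30 ≤ severe; zero-TST nights report these indices as
undefined flags, never infinity.

## Cluster predictability

XGBoost with fixed, recorded hyperparameters (300 trees, depth 4,
learning rate 0.1, single thread) on an 80/20 stratified split; features
are ranked by total gain, and the model is refit on the top-1 and top-5
features. Accuracy is plain top-1 classification accuracy. Reports are
bit-for-bit reproducible under a fixed seed.

## Outcome analysis

Eligibility keeps subjects with ≥ 5 years of pre-study history and no
prevalent occurrence of the outcome. The six Cox variants share the
exposure coding (indicators against RG1, or against normal AHI for the
severity sensitivity analysis): 1 unadjusted; 2 + age/sex/BMI; 3
+ comorbidities; 4 + AHI; 5 and 6 use the model-3 covariates on the
PAP-free and age ≥ 55 subsets. Ties use the Efron approximation (lower
bias than Breslow; the choice is otherwise open). Weighted fits use
robust sandwich variance. A Schoenfeld-residual trend test is available
as an advisory proportional-hazards check (α = 0.05), not a gate. A
group with zero events is flagged and its CI reported unbounded.

Propensity weights come from multinomial logistic regression of group on
age, sex, BMI, comorbidities and history length (standardized inputs,
mild ridge to guard against separation); the stabilized weight is the
marginal group frequency over the fitted conditional probability.
"Trimmed at the 5th and 95th percentiles" is implemented as *clipping* to
the percentile values — preserving sample size, which matches how cohort
sizes are reported — with an exclusion variant by config. Kaplan-Meier
estimates use lifelines (weighted variant included); pairwise log-rank
tests against the reference are computed by an in-package routine that
supports subject weights and reproduces lifelines exactly at unit
weights.

## Problem sizes and numerical conventions

The end-to-end study trains the desk-scale encoder on 200 nights × 240
epochs (4-channel montage), subsampling 30 labeled epochs per night for
training (6,000 epochs, 5 passes) and embedding all 48,000 epochs; nights
stream one at a time through generation → preprocessing → embedding, so
memory stays near a single night's signals. The two planted regimes for
that study differ the way clinical risk extremes do — transition rate 8/h
vs 30/h, event rates 3/h vs 30/h, saturation baseline 96.5 % vs 92 %, and
opposite stage-architecture weights — because a marginal-distribution
distance cannot see temporal order: regimes separable only by switching
*dynamics* at identical stage mix would be invisible to it by design.
The metrics-classifier study instead plants regimes differing *only* in
transition rate (4/h vs 30/h, event rates equal), isolating fragmentation
as the discriminating feature. Cox recovery simulations use n = 6,000–
7,000 with baseline hazard 0.01/person-year, ~20 % exponential-dropout
censoring and a 20-year horizon; equal group proportions are used in the
five-group recovery design to balance per-arm event counts. Monte-Carlo
checks (null calibration, coverage) use 100–200 seeds at small n.

## Known limitations

- Signal synthesis is deliberately schematic; no claim is made about
  clinical stage-scoring accuracy, and the full-scale encoder
  configuration is never trained here.
- The energy/EMD projection ignores within-night temporal ordering by
  construction; fragmentation-style dynamics enter only through the
  summary-metric pathway.
- The consensus "proportion of iterations" convention (co-sampled
  denominator) and the SEP fence-post layout are documented choices among
  defensible alternatives, switchable by config.
- Weighted log-rank uses the classical hypergeometric variance on
  weighted counts, an approximation that is standard but not exact for
  extreme weights.
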