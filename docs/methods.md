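# Methods

This note documents the models, algorithms and design choices behind
`cardiopatch`, the conventions its numbers follow, and what its synthetic
evaluation does and does not demonstrate.

## Synthetic single-lead ECG generator

**Waveform model.** Each beat is a sum of five Gaussian components on a beat
phase φ ∈ (−π, π]:

    s(φ) = Σ_w a_w · exp(−(φ − θ_w)² / (2 b_w²)),   w ∈ {P, Q, R, S, T}

with the R peak anchored at φ = 0. Defaults (θ in radians, a in mV, b in
radians): P (−π/3, 0.15, 0.20), Q (−π/12, −0.10, 0.05), R (0, 1.00, 0.05),
S (π/12, −0.15, 0.05), T (π/2, 0.30, 0.30) — a textbook normal morphology.
Because every wave is an analytic Gaussian, onset/offset fiducials are exact:
each wave spans θ_w ± 2.5 b_w, the QRS span runs from Q onset to S offset,
and the ST segment is the half-open interval [QRS offset, T onset). Sample
indices use 0-based, floor(x + 0.5) rounding; fiducial spans are half-open
`[onset, offset)`.

**Rhythm model.** Instantaneous heart rate is drawn per beat from
N(mean_hr, hr_sd) (clipped to [20, 240] bpm), modulated by a respiratory
sinusoid (default 0.25 Hz, depth 0.05); RR = 60/HR. Defaults 70 ± 3 bpm.
Phase is piecewise linear between beat midpoints, so the R peak of beat *k*
falls exactly at its centre time.

**Pathology.** Each class alters exactly the waveform feature a clinician
reads:

| class | mechanism | default magnitude |
|---|---|---|
| MI  | additive ST-segment offset (flat within the span, 16 ms cosine ramps outside it) | +0.2 mV |
| AR  | HR standard deviation multiplied; premature beats (RR × 0.6 with compensatory pause) inserted per-beat | ×4, p = 0.1 |
| AH  | P amplitude and width scaled | ×2.0, ×1.5 |
| NR  | identity | — |

Magnitudes were fixed when the generator was written, at values giving clear
but non-trivial class structure: each class's summary statistic (mean ST
level, RR SD, P/R ratio) sits ≥ 5 pooled standard deviations from normal at
30 s duration (verified by a test). AR and AH re-synthesize the waveform from
modified parameters, so fiducials stay exact.

**Wear orientation.** The triangular patch admits three stable placements.
O0 is identity; O120 and O240 apply
`y = polarity · scale · [(1−mix)·x + mix·smooth(x)] + offset` with
smooth = Gaussian spectral low-pass (σ = 12 ms): a baseline shift, an
amplitude/polarity change, and a morphology blunting — the three distortion
modes a rotated single-lead placement produces. Defaults: O120 (0.6, −1,
+0.1 mV, 0.3), O240 (0.7, +1, −0.1 mV, 0.5); these are synthetic stand-ins,
not measurements. The combined gain is strictly positive in frequency
domain, so every transform is exactly invertible (`invert_position`), and
orientation labels compose as the cyclic group O0 → O120 → O240 → O0.

**Noise.** Additive baseline wander (0.3 Hz, 0.1 mV), mains hum (50 Hz,
0.02 mV), broadband Gaussian (0.02 mV SD), and Poisson-timed motion bursts
(2/min, 0.3 mV, 75 ms Gaussian envelope). `broadband_sd_for_snr` solves the
noise SD for an exact target power-ratio SNR, which the SNR-estimator checks
use as ground truth.

**Datasets.** `make_dataset` apportions classes and orientations by
largest-remainder rounding, derives per-record seeds from one master seed,
and returns a class-stratified 80/20 split. Identical seeds reproduce the
dataset bitwise. The default orientation mix is all-O0: the diagnosis task
presumes a corrected placement, and misplacement datasets request an
explicit mix.

## Preprocessing

Fixed order: 50 Hz IIR notch (Q = 30) → order-4 Butterworth band-pass
0.5–40 Hz → baseline correction → segmentation → normalization. All filters
are applied forward–backward (zero phase), so R-peak positions move ≤ 1
sample. Baseline correction subtracts a two-stage median-filter estimate
(200 ms then 600 ms): the first stage removes QRS complexes, the second P/T
waves, leaving only the sub-0.5 Hz baseline. A median baseline (rather than
a high-pass filter alone) is used because it preserves ST-segment levels,
on which the MI class depends. Trailing partial windows are dropped, not
padded, so all model inputs have equal length.

## Pan-Tompkins vitals

The 1985 adaptive-threshold formulation: 5–15 Hz band-pass, five-point
derivative, squaring, 150 ms moving-window integration, dual signal/noise
peak estimates with threshold = NPK + 0.25 (SPK − NPK) and update
coefficients 0.125/0.25, a 200 ms refractory period, and search-back at
1.66× the running 8-beat mean RR accepting candidates above half threshold.
Accepted peaks are refined to the raw-signal maximum within ±50 ms; the
refractory invariant is enforced after refinement.

Heart rate per update window (default 6 s) is 60 / mean(RR) over the RR
intervals whose midpoint falls in the window — steadier for short windows
than peak counting — with windows holding fewer than two peaks flagged
missing. HRV metrics use all detected RR intervals without ectopic
rejection: SDNN is the population SD of RR (ms), RMSSD the RMS of
successive differences (ms), pNN50 the percentage of successive differences
exceeding 50 ms.

The streaming path finalizes a window only when the buffer extends one full
window past its end, so a late R peak whose RR midpoint belongs to the
window is always available; emitted values are exactly the batch values.

## Signal quality

* **Template SNR.** Beats aligned on R peaks over a median-RR window
  (40%/60% split around the peak); the ensemble average is the signal
  estimate and per-beat departures are noise:
  SNR = 10 log₁₀(n·Σtemplate² / Σresidual²). This makes records comparable
  across runs of this package without a noise-free reference; on records
  with natural RR jitter the residual includes beat-length variation, so
  clean-but-jittered records read ~15–20 dB, and rigid-rhythm records
  > 40 dB. On constructed mixtures of known power ratio the estimate is
  within 1 dB.
* **Drift amplitude.** Peak-to-peak excursion of the sub-0.5 Hz baseline
  (order-4 zero-phase low-pass, discarding two cutoff periods of warm-up at
  each end) divided by the peak-to-peak of the remaining cardiac signal.
  The ratio form makes the metric scale-invariant by construction; it is a
  convention of this package, not of any particular device.
* **Instantaneous frequency.** Short-time spectrum (1 s window, 75%
  overlap) with a first-moment ridge IF(t) = Σ f·|S|² / Σ|S|². The spectral
  moment is used rather than an analytic-signal phase derivative because the
  ECG is multi-component; the moment stays stable where a phase derivative
  oscillates.
* **Cross-correlation.** Pearson correlation scanned over lags |L| ≤ 0.5 s;
  the reported value is the signed correlation at the lag maximizing |ρ|,
  so an inverted copy reports −1 rather than being hidden.

## Interpretable attention transformer (IAT)

The 10 s diagnostic window (2500 samples at 250 Hz) is cut into 50
non-overlapping 0.2 s slices. Each slice passes through a 1-D convolution
(8 channels, kernel 7) with ReLU and a linear projection into a 64-d
embedding; a learned CLS token is prepended and learned positional encodings
added. Two pre-norm encoder blocks (4 heads, MLP width 128, dropout 0.1)
yield the encoded tokens and the per-layer attention tensors. Classification
reads a *class-query attention readout*: one learned query per class scores
the final token representations, and each class logit is a linear read of
its class's attention-pooled context. The architecture is deliberately small
enough to train on one CPU in about a minute.

**Why a class-query readout and strictly local token attention.** The
attention map is only evidence if the model *must* look at the pathology to
score its class. Two standard transformer conveniences break that link:
(a) token-token self-attention copies class information into every token,
after which a global readout can attend anywhere; and (b) a single
class-agnostic aggregation query cannot adapt its target per class, so its
row parks on whatever content is easiest. Both were observed directly on
synthetic data (region-density diagnostics: near-uniform rows, or sharp
rows on uninformative tokens). The design therefore (a) restricts slice
tokens to self-attention only (`local_attn_window = 0`; the CLS row remains
global, and tokens never attend the CLS, so global information cannot be
re-broadcast into them), keeping every token's representation strictly
local to its 0.2 s of signal; and (b) gives each class its own readout row,
so raising the MI logit on an infarction record requires attending tokens
whose *content* separates MI from the other classes — the elevated ST
slices. A small banded window (±1–2 tokens) was probed and rejected: even
±2 tokens × 2 layers spans a whole beat and re-delocalizes the evidence.

**Input normalization (why not a plain z-score).** Levels are referenced to
the TP-segment isoelectric line (located from the detected R peaks) and
amplitudes to the median detected R-peak height, after mains-notch and
40 Hz low-pass filtering only. Every global alternative probed leaks a
localized pathology into window-wide statistics, letting the model detect a
class without looking at it: mean-centring moves the resting baseline
whenever a short ST segment is elevated; SD-scaling shrinks the R-peak
height whenever the P wave is enlarged; even a high-quantile scale shifts
by a few percent between classes. Filters leak too: an IIR high-pass droops
around a shifted ST segment, and a median-filter baseline absorbs part of
an enlarged wave and leaves class-dependent dips beside it — so neither is
applied to the model input (residual wander stays, as class-independent
noise). TP line and R amplitude are the references an electrocardiographer
uses, and they confine each pathology's signature to its own region — the
precondition for the attention map to mean anything.

**Training objective.** Cross-entropy plus an entropy penalty on every
class-readout row (λ = 0.1): each class's evidence should be a few tokens,
not a uniform mix. Adam at 1e-3, 30 epochs, batch 32, seeded init, batch
order and dropout; two runs with one seed agree to the last bit.

**Saliency.** Default (`"readout"`): the predicted class's readout row,
spread uniformly over each token's sample span and normalized to sum to 1.
The encoder-attention readings — final-layer CLS row, head-averaged, CLS
self-score removed (`"cls"`), and attention rollout across layers
(`"rollout"`) — are retained as options; with the strictly local encoder
they are nearly uniform and are kept for comparison, not for use.

**Leakage control.** The shuffled-label control re-trains the identical
configuration on permuted training labels and must score at chance on the
held-out set. Because a trained model predicts each true class as a block,
single-permutation accuracy has ~0.04 SD around 0.25; the control is
therefore reported as the mean over three independent permutations.

## Wear-position network

Input is the raw-mV 10 s window — deliberately *not* normalized, since
baseline offset, amplitude and polarity are exactly the cues misplacement
leaves. Ten 1 s chunks are each projected by a shared fully connected layer
into 32-d (tanh), a 1-D convolution (kernel 3) extracts relations between
neighbouring chunks, and a GRU (hidden 32) summarizes the sequence; its
final hidden state feeds (a) a 3-way softmax over {O0, O120, O240} and (b) a
discriminator — an MLP on [summary ‖ reference] with sigmoid output — where
the reference is the mean summary of correctly-placed training records
under the final weights.

Training is adversarial in the verification sense: the discriminator's BCE
(real = standard placement, fake = misplaced) is added to the
classification cross-entropy and *both* shape the feature extractor — there
is no gradient reversal, because the discriminator is a verifier and the
features should expose misplacement, not hide it. The tolerance threshold
defaults to 0.5. The adjustment suggestion is the group-inverse rotation
(0/−120/+120°) of the predicted orientation; applying the corresponding
inverse transform to the record and re-scoring is the end-to-end usefulness
check.

## Reference study conditions and problem sizes

* Diagnosis: 1000 records (balanced classes, default noise, seed 7),
  stratified 80/20, default IAT; held-out accuracy and row-normalized
  confusion diagonal are the headline numbers.
* Placement: 600 records (balanced orientations, seed 11), identical split
  logic, default position net.
* Detection/vitals/quality checks run on 30–60 s single records.

These sizes were chosen so the complete evaluation trains both networks
from scratch on one CPU core in a few minutes.

## What the synthetic evaluation shows — and does not

The generator produces idealized Gaussian-sum morphology, stationary noise
statistics, and pathology expressed through single isolated mechanisms.
Passing the evaluation shows the *pipeline* is correct and self-consistent:
the detector finds the beats the generator placed, the models recover the
class structure the generator encoded, attention localizes the evidence the
generator localized, and every number is reproducible from seeds. It does
not show clinical-grade performance: real ECG exhibits inter-patient
morphology variation, non-stationary artifacts, co-occurring pathologies
and electrode-contact physics that the generator does not model. Accuracy
figures on this synthetic task are not comparable to accuracy on patient
data.

## Numerical conventions and degenerate inputs

Signal processing in float64; the neural-network engine computes in
float32 (the models are small and noise-robust, and memory bandwidth
dominates single-CPU runtime) with class probabilities finished in float64.
Single-threaded numpy, so results are bit-stable.
Constant windows normalize to zeros with a flag rather than dividing by
zero. Flat signals yield empty R-peak sets; HRV requires ≥ 3 peaks and
template SNR ≥ 5 beats (errors otherwise). Zero-phase filtering is used
everywhere a later stage consumes sample positions. JSON reports serialize
with sorted keys so determinism can be checked bytewise.
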