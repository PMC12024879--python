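# Methods

This note records the modelling and numerical choices behind each
stage, the defaults and their units, and what the synthetic study can
and cannot demonstrate.

## Synthetic PPG generator

**Waveform model.** Each beat is the sum of two Gaussians: a systolic
peak (amplitude 1.0 a.u., SD 0.10 s) and a dicrotic bump (amplitude
0.35, delay 0.25 s, width 1.6× systolic). The dicrotic delay is capped
at 40% of the beat period so high heart rates stay physical. Beats are
scheduled from half a period into the record with per-interval
Gaussian jitter (`hr_jitter_sd`, default 0 s in unit fixtures, 0.02 s
in the pipeline), so a jitter-free record holds exactly
⌊duration/period⌋ beats. This two-Gaussian shape is the simplest
waveform that exposes every extracted morphological feature; it is not
a validated pulse-wave model, and results on it do not establish
performance on clinical PPG.

**Corruption model.** Additive white Gaussian noise (SD 0.05 a.u.
default), sinusoidal baseline wander (amplitude 0.30 a.u. at 0.08 Hz,
random phase), and motion artifacts as Gaussian bumps of random sign,
0.15–0.5 s width and 0.8 a.u. amplitude arriving as a Poisson process
at 2 events/min. These reproduce the *kinds* of corruption seen in
wearable PPG, not their empirical distributions.

**Glucose link.** Reference BGLs are drawn uniformly on 50–300 mg/dL —
wide enough to populate all three clinical classes; no fidelity to any
patient population is claimed. The glucose→morphology effect is linear:
an affected morphology parameter p becomes p·(1 + s·(BGL − 125)) with
per-feature slope s (defaults: pulse width 1.2×10⁻³ and pulse
amplitude 1.6×10⁻³ per mg/dL, i.e. roughly ±20% variation across the
BGL range — a clearly recoverable desk-scale effect). Width and
amplitude modulation necessarily cascades into correlated features
(AUC, slopes, fractal dimension); timing-based features (IPI, HRV,
SD1/SD2, dominant frequency) stay untouched. Glucose classes use the
standard clinical cut-offs 70/180 mg/dL (closed band = normoglycemia),
configurable.

**Federation heterogeneity.** A heterogeneity h shifts each client's
BGL mean by h·25 mg/dL·u, u ~ U(−1,1), and scales its sensor-noise SD
by a factor in 1 ± h/2. At h = 0 all clients are exchangeable, and a
single-client federation is bit-identical to pooled generation at the
same seed (per-record seeds are spawned from one root sequence).

**Planted feature matrices.** For selector tests, a separate generator
emits standard-normal features where the BGL is an affine image of the
*sum* of the informative columns plus residual noise (SD 0.5 of the
standardized score by default). Each informative feature then carries
an independent share of the signal, so a correct selector must keep
all of them — informative features are complementary, not redundant
copies.

## Wavelet denoising

**Transforms.** The CWT is computed in the frequency domain from the
analytic spectra of the mother wavelets (Mexican hat
ψ̂(ω) = √(2π)·ω²·e^(−ω²/2); Morlet ψ̂(ω) = √π·e^(−(ω−ω₀)²/4)), which
makes the forward transform exact for band-limited periodic signals;
boundary handling is circular. The inverse uses the
resolution-of-identity formula with the admissibility constant
C_ψ = ∫|ψ̂(ω)|²/ω dω evaluated by adaptive quadrature per family, and
trapezoid weights in log-scale for the scale integral. Reconstruction
error therefore comes from grid truncation and discretization: on a
64-scale grid spanning 0.125–16 Hz a band-limited signal round-trips
with < 5% relative L2 error. For the complex Morlet wavelet (analytic,
no negative-frequency energy) the real signal is recovered as twice
the real part.

**Scale grid.** Default 32 log-spaced scales covering pseudo-frequencies
0.5–8 Hz — below the cardiac fundamental at rest down to drift, up
through the harmonics that carry beat morphology. Pseudo-frequency
uses the spectral peak of ψ̂ (√2/2π ≈ 0.225 Hz·s for the Mexican hat;
f₀ for Morlet). Note the *response* peak for a pure tone includes the
√a amplitude factor of the L2-normalized wavelet and sits at
√2.5/ω for the Mexican hat; the tests use that analytic maximizer as
the oracle.

**Thresholding.** One global universal threshold T = σ̂√(2 ln N)
(natural log; N = signal length) applied by soft shrinkage to all
coefficients; for complex coefficients the modulus is shrunk and the
phase kept. σ̂ = median|finest-scale coefficients|/0.6745 — the MAD
estimator in coefficient units, which is exactly the unit T needs, so
no calibration back to the signal domain is required. The default
denoising family is the Mexican hat: its coefficients are real, so
shrinkage has its textbook semantics; Morlet is provided for analysis.

**Baseline elimination.** Coefficients at pseudo-frequencies below
0.5 Hz are zeroed before reconstruction. With the default grid this is
belt-and-braces: sub-0.5 Hz content is already outside the
reconstruction band, which is why denoised output is effectively
AC-coupled (zero-mean). Denoising gains are accordingly measured on
mean-removed signals.

## Cycle segmentation

Peak candidates are local maxima of the first derivative above an
adaptive threshold — half the rolling 2-s upper quartile of the
positive derivative, which is invariant to amplitude rescaling — then
snapped to the largest signal value within the following 0.2 s
(maximal upslope precedes the waveform peak). A refractory interval of
60/max_hr s suppresses double detections, with one sample of slack so
beats at exactly the max_hr period survive sample-grid rounding; when
two candidates collide the taller peak wins. Records shorter than one
min_hr period, or with no qualifying upstroke (e.g. constant signals),
return an empty peak list rather than an error.

Boundaries: interior cycle edges at ⌊(Rp_{k−1}+Rp_k)/2⌋ (floor
division — deterministic tie-break toward the earlier sample); the
first start and last end extend a fixed window Tf from the outer
peaks, clipped to the record. Default Tf is half the median inter-peak
interval (0.5 s fallback below two peaks). Each segment (boundary
samples inclusive) is linearly interpolated to Lg = 100 samples and
min–max scaled to [0, 1]; a degenerate flat segment yields zeros and a
logged warning. Linear resampling and min–max scaling commute, so the
order of those two steps is immaterial.

## Features

One scalar per record and feature; cycle-wise features are averaged
over cycles. Estimator choices where several definitions are current:
pulse width = time between half-amplitude crossings of the normalized
cycle (sub-sample interpolated); pulse amplitude = max−min of the
*raw* segment (the normalized cycle is 1 by construction); AUC =
trapezoidal area of the normalized cycle over its duration in seconds;
slopes = extreme forward differences of the normalized cycle times its
resampled rate; HRV = SDNN of inter-pulse intervals in ms; "PSD" is
scalarized as 10·log₁₀ of total Welch power in 0.5–8 Hz (Welch
segments of 8 s; a PSD is a curve, some scalar reduction is
unavoidable); dominant frequency = Welch argmax in 0.5–3 Hz; fractal
dimension by Higuchi's method with k_max = 8; entropy = Shannon
entropy (bits) of a 16-bin histogram of the min–max-normalized record;
SD1/SD2 = sample SDs of the successive-interval Poincaré scatter
projected onto the ±45° axes. The rotation definition is used rather
than the common variance shortcut SD2² = 2·var(IPI) − var(ΔIPI)/2
because the two differ on finite series (the shortcut assumes head and
tail subseries share the full-series variance); the rotation form is
the construction the scatter plot actually shows. Records shorter than
10 s get NaN spectral features; fewer than 2 peaks NaN IPI, fewer than
3 NaN HRV, fewer than 4 NaN SD1/SD2. Rows with any NaN are dropped
(with a logged count) before selection and training. The 13-feature
order is frozen: selection masks index into it.

## Feature selection (BPSO)

Classic binary PSO: 30 particles, inertia 0.729, cognitive = social =
1.49, 50 iterations, early stop after 10 non-improving iterations,
velocities clamped to ±6 so the sigmoid transfer never saturates
irrecoverably. Fitness Ft = α·score − β·|mask|/d with α = 1, β = 0.1:
one selected feature costs 0.1/d of fitness, so a feature must buy at
least that much cross-validated score. The empty mask scores −∞ and
can never become a personal or global best. Two evaluator modes: 5-fold
CV accuracy of a standardized logistic regression on the glucose class
(default, matching the accuracy-based fitness), or 1 − RMSE/SD(y) of a
ridge regression clipped to [0, 1] (an RMSE-minimizing variant; both
are provided because either reading is defensible). Evaluations are
cached per distinct mask; the swarm is fully reproducible from its
seed.

## Federated training

Local models are small numpy networks sharing a two-headed output
(linear BGL regression; 3-way softmax over hypo/normo/hyper). Default
architecture: MLP with 2×64 ReLU hidden layers and dropout 0.3 — small
enough to train on tens of records per client, large enough to exploit
the planted nonlinearity. A stacked 3×64 tanh recurrent network over
sequences of consecutive cycle-level feature vectors is provided as
the `recurrent` mode; its input pipeline (sequence length, what the
recurrence consumes) is a documented reconstruction, and gating was
deliberately left out — nothing in the desk-scale task exercises it.
Gradients are hand-derived backpropagation, verified against central
finite differences to ~1e−10 relative error in the test suite.

Training: λ₁ = λ₂ = 1 joint loss (MSE + categorical cross-entropy,
both batch means — the weighted sum is not re-normalized a second
time); Adam (lr 0.001, batch 32) by default, plain SGD available (and
used by the closed-form equivalence test); 20 global FedAvg rounds,
one local epoch per round. FedAvg shares parameters only: each local
call starts a fresh optimizer (no server-side optimizer state), and
the aggregation API accepts nothing but `ModelParams`/deltas — raw
data cannot cross the boundary by construction. Per-round per-client
seeds are spawned from the global seed, so the whole federation is
reproducible, and centralized training is *defined* as the one-client
federation (hence exactly equal to it). Feature and BGL-target
standardization statistics are computed once from the pooled training
set and shipped with the model as scalar metadata; predictions are
returned de-standardized in mg/dL. Both standardizations can be
switched off (the analytic-gradient test does so).

## Evaluation

MAE, MSE, RMSE, MARD = 100·mean(|e|/ref) in percent, R² = 1 − SSE/SST
(NaN when the reference is constant). Clarke zones use the canonical
piecewise inequalities listed in `ppglucose/metrics.py`, evaluated in
the conventional order A → E → C → D → else B. Under that ordering a
point exactly on the 20% line belongs to A (ties at the A/B edge go to
the less severe zone); at the three-way corner (70, 180) the ordering
assigns E, the standard behaviour of published implementations. Zone
percentages always partition to 100.

## Problem sizes

The synthetic federated study runs 5 clients × 100 records of 12 s at
100 Hz (uniform BGLs, heterogeneity 0.5, default noise), holds out the
last quarter of each client's records, and trains with the default
configuration above; one run takes ~20 s, and the robustness check in
the test suite repeats it over 10 seeds. Unit fixtures use 10–20 s
records and 40–300-record feature matrices.

## Known limitations

- The generator's two-Gaussian beats lack pulse-wave physiology
  (no respiratory modulation, no amplitude–period coupling, no
  sensor transfer function); passing tests demonstrate pipeline
  correctness and recoverability of a planted effect, not clinical
  accuracy.
- The CWT uses circular boundary handling; records with large
  start/end discontinuities will show edge artifacts.
- A single global threshold is used across all scales (matching the
  single-N universal threshold); per-scale thresholding is not
  implemented.
- The PSO evaluator sees the pooled training features, which is a
  desk-scale simplification — a strictly federated selector would
  need a distributed evaluator.
- `recurrent` mode is functional but lightly exercised; the MLP is
  the supported default.
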