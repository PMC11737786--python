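# Methods

This note records the modelling choices behind `emdpcnn`: what each stage
assumes, which parameters matter and why their defaults were chosen, what
the synthetic generator does and does not emulate, and the numerical
conventions adopted where the underlying method leaves room.

## Preprocessing

Raw recordings are band-pass filtered per channel with a 3rd-order
Butterworth between 4 and 38 Hz — the span of the mu (8–12 Hz) and beta
(12–30 Hz) rhythms whose event-related desynchronization (ERD) carries
the motor-imagery signature, with the roll-off also suppressing drift and
line noise. The filter is applied **causally** (forward only) by
default, matching online BCI operation where future samples are
unavailable; a zero-phase option (`zero_phase=True`) exists for offline
analyses. Each channel is then standardized with exponential moving
statistics,

    m_t = (1−d)·x_t + d·m_{t−1}
    v_t = (1−d)·(x_t − m_t)² + d·v_{t−1}
    x'_t = (x_t − m_t) / max(√v_t, ε)

with decay d = 0.999 (a ~1000-sample, i.e. 4 s, memory at 250 Hz) — the
convention of the deep-learning EEG literature, which removes slow
amplitude drifts while preserving within-trial dynamics. State is
initialised m₀ = x₀, v₀ = 1 so constants map to exactly zero and there
is no divide-by-zero burn-in; ε = 10⁻⁸ guards the degenerate
zero-variance limit.

Epochs are cut on the half-open window [0.5 s, 2.5 s) after each cue —
sample `floor(0.5·rate)` up to but excluding `floor(2.5·rate)` — which at
250 Hz yields exactly 500 samples; trials truncated by the end of a
recording are dropped with a logged warning rather than padded.

## Empirical mode decomposition

Envelopes are cubic splines through the extrema (the standard EMD
interpolant). Plateaus of equal samples contribute one extremum at the
integer midpoint of the run. Zero crossings are counted as sign changes
between consecutive nonzero samples (zeros are transparent); since the
IMF conditions only use the *difference* between extrema and crossing
counts, the endpoint convention is immaterial downstream. Boundary
effects are controlled by mirroring the two extrema nearest each end
about the endpoint before fitting (`boundary="mirror"`), which suppresses
the end swings free splines otherwise produce; a `clamp` mode that pins
the endpoints is available.

Sifting subtracts the envelope mean until the candidate satisfies both
IMF conditions — |#extrema − #zero crossings| ≤ 1 and envelope mean below
`mean_tol = 0.05` of the peak-to-peak range — checked **first** on every
pass. A Cauchy criterion `SD = Σ(c_prev − c)² / Σ c_prev² <
sd_threshold` acts as a stagnation guard with default 10⁻⁶. This
deliberately departs from the classic "SD < 0.2" rule of thumb: that
value belongs to the pointwise-normalised SD definition, and under the
energy-ratio form used here it stops after one or two passes, long
before the envelope-mean condition is met — leaving stored components
that are not IMFs. With the small default, essentially every returned
component passes the formal IMF test (verified across random and tonal
suites); `max_sift_iters = 100` caps pathological cases, with a
per-component validity flag (`IMFSet.imf_ok`) recorded either way.

Decomposition subtracts each IMF from the running residue (which makes
reconstruction algebraically exact) and stops when the residue has fewer
than two maxima or minima, or after `max_imfs = 10` components. A sifted
candidate that itself ends up with fewer than two maxima or minima has
no evaluable envelope — it is a trend, not an oscillatory mode — and is
left in the residue rather than stored.

## Features

Per (channel, IMF): energy, AR(7) coefficients, fuzzy approximate
entropy, peak-to-peak, skewness, excess kurtosis — a block of p + 5 = 12
scalars, concatenated channel-major/IMF-minor over the first K = 4 IMFs
(the rhythmic content of 250 Hz MI-EEG lives in the first few modes;
missing modes are zero-padded with a flag so vector length is fixed).

- **AR coefficients** are estimated by Burg's method (statsmodels),
  which is stable on short segments and needs no windowing; signs follow
  the prediction convention `ĝ(t) = Σ a_i g(t−i)`. Order 7 is the
  customary choice for motor-imagery EEG.
- **Fuzzy approximate entropy** uses embedding m = 2 and tolerance
  r = 0.2, the literature defaults. Templates are baseline-removed
  (each minus its own mean); similarity is `exp(−d²/r_eff)` with d the
  Chebyshev distance and `r_eff = r · var(f)`, the variance scaling
  matching the squared distance in the exponent. `Φ^m` averages
  `ln` of each template's mean similarity to all *other* templates
  (self-matches excluded, normalisation by the template count); the
  entropy is `Φ^m − Φ^{m+1}`. A zero-variance signal returns 0 by
  convention. The naive normalisation *without* the similarity sum
  would make the statistic identically zero, so the standard
  fuzzy-entropy form is used.
- **Kurtosis** is the excess kurtosis (fourth standardised moment − 3),
  and skewness the third standardised moment with population (biased)
  normalisation; both via scipy.stats.

Degenerate inputs (constant IMFs) yield NaN for the affected feature
with a recorded flag instead of aborting the whole epoch.

## Parallel CNN

The reference architecture is: shared stem conv1d(32 filters, kernel 20,
stride 1, same padding — symmetric zeros, extra sample on the right for
even kernels) → batch-norm → ReLU; two branches conv1d(32, kernel 10,
same) → ReLU → pool(size 4, stride 4), one max and one average, merged
by concatenation along the filter axis; head = dropout 0.5 → dense 64
(ReLU, L2-penalised) → dense K → softmax. Kernels span all input
channels and slide along time only (a 1-D CNN over multichannel
rasters). Max pooling keeps the sharpest response in each window,
average pooling the smoothest; giving the merge both views is the point
of the parallel topology. All sizes are configurable (`ArchConfig`), and
pooling is 1-D along time.

Every layer is implemented directly on NumPy arrays with hand-derived
backward passes; inference is a pure function of (weights, input) —
dropout disabled, batch-norm using stored running statistics (momentum
0.1). Weights are initialised from a variance-scaled uniform
distribution with limit √(6/fan_in), seeded from the architecture
config. Gradients are verified against central finite differences in the
test suite; the check jitters parameters off the zero-bias
initialisation first, because flat ReLU regions upstream otherwise place
conv pre-activations *exactly* on the ReLU kink, where a central
difference reports the mean of the two one-sided slopes while backprop
uses the standard subgradient 0 — a property of the kink, not an error.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on mean categorical
cross-entropy plus `l2·Σw²` over conv/dense weight matrices (biases and
batch-norm parameters unpenalised), learning rate 10⁻³, batch 32,
epochs visiting all examples once in seeded random order. Early
stopping watches validation loss with patience 20 (default) and restores
the best-validation weights. The L2 coefficient defaults to 10⁻⁴ and
the validation share to 20 % of the training split — both left
unspecified by the method description, chosen as conventional values.
Data splits are stratified 70/30 (scikit-learn shuffle splits),
deterministic under seed.

Transfer learning deep-copies the pretrained network, optionally
freezes the convolutional stem (Adam then skips those tensors), and
fine-tunes on the target subject's 70 % training split; with zero
epochs the copy is weight-identical. The pretraining corpus excludes
the target subject ("group" model); including it is a caller decision.

## Synthetic data

The generator emulates the one physiological contrast motor-imagery
classifiers exploit — class-dependent ERD — not realistic EEG. Each
epoch is, per channel,

    x(t) = 5 µV·g_mu·AM(t)·sin(2π·10t + φ) + 3 µV·g_beta·AM'(t)·sin(2π·22t + φ') + n(t)

where AM is a slow (0.5–2 Hz) random-phase amplitude modulation of
depth 0.3, g are per-class per-channel gains, and n(t) is Gaussian
noise spectrally shaped to 1/f power (slope −1), default SD 2 µV. The
default montage is the minimal lateralised set C3/Cz/C4 at 250 Hz with
2 s (500-sample) epochs. Class archetypes attenuate the contralateral
channel's gains by `erd_factor` (left hand → C4, right hand → C3, foot →
Cz; the four-class "tongue" archetype attenuates beta diffusely).
Per-subject multiplicative gain jitter (`subject_shift_sd`) supplies the
inter-subject distribution shift used in the transfer experiments.

What this does **not** model: volume conduction and channel
correlation, eye-blink/EMG artifacts, non-stationary drifts, realistic
ERD time courses or rebound (ERS). Passing tests therefore demonstrate
that the pipeline recovers the band-power contrast it is designed for —
they say nothing about robustness to real-world artifacts or montage
effects.

## Experiment scales

The packaged experiments (acceptance script, end-to-end tests) use the
3-channel synthetic montage with 500-sample epochs and reduced network
widths — 16 stem/branch filters, pool 8, dense 32 for the
classification runs; 8 filters, dense 16 for the transfer study — with
12 and 10 epoch budgets respectively. These sizes were chosen so a full
run completes in minutes on a single CPU while leaving the conclusions
unchanged: the two-class task (500 trials/class, strong ERD, attenuation
0.3) and the four-class task (250 trials/class) are both solved
essentially perfectly, and the transfer study (4 pretraining subjects ×
120 trials, one shifted target subject × 200 trials, 10 fine-tuning
seeds) shows fine-tuning meeting or beating the pretrained-only model in
every seed. The full-width 32-filter architecture is the default in
`ArchConfig` and is what `build_model` produces out of the box.

## Known limitations

- EMD mode mixing is not addressed (no ensemble/noise-assisted
  variants); closely spaced tones will share IMFs.
- The EDF+ writer covers the subset of the format needed for fixtures
  (1 s records, integer rates, numeric annotation codes).
- Bit-identical training reproducibility holds within one
  platform/BLAS; across platforms, floating-point reduction order may
  differ.
- GDF files are read through MNE; GDF writing is not supported, so
  file round-trip tests use EDF+.
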