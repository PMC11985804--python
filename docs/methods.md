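# Methods

This note documents the models, parameter choices and numerical conventions
behind `docfc`, in enough detail to judge what the passing tests do and do
not establish.

## Preprocessing chain

Recordings (19 channels of the 10-20 montage, 256 Hz) are processed as:
trim the first and last 120 s (setup/teardown artifacts) → common average
reference → zero-phase 1-48 Hz FIR band-pass → zero-phase FIR band-stop
49-51 Hz (mains) → per-band zero-phase FIR band-pass for δ 1-4, θ 4-8,
α 8-13, β 13-30, γ 30-48 Hz. Band edges are configurable; γ is capped at
48 Hz by the broadband front-end filter.

All filters are Hamming-window FIR designs by the windowed time-domain
(firwin) method. The transition bandwidth at a band edge f is
min(max(0.25·f, 2 Hz), f); the filter length is ceil(3.3/(Δf/fs)) rounded
up to odd (the Hamming design factor), which fixes the design's figures of
merit at roughly 53 dB stopband attenuation and a 0.0194 dB passband
ripple. Zero-phase behaviour is obtained by applying the symmetric kernel
once and compensating its integer group delay with edge padding
(non-causal), so an in-band sinusoid exits at lag zero.

**Measurement conventions.** `measure_fir_figures` evaluates the response
on a dense grid; stopband attenuation is −20·log₁₀ of the largest stopband
magnitude with stopbands starting one full transition width outside the
passband edges, and the ripple figure is 20·log₁₀(1 + δ_p) with δ_p the
maximum passband deviation over [lo, hi]. For the realized band-pass these
measure ≈52.6 dB and ≈0.029 dB on the α band: the attenuation sits
slightly below the rounded single-transition table value, and the ripple
roughly doubles it because a band-pass has two transitions whose passband
deviations superpose.

**Windowing.** A W-second window with 50% overlap yields
K = ⌊(T−W)/S⌋ + 1 windows, S = W/2. Because usable record lengths differ
across subjects, every band series is truncated to W + (K*−1)·S samples so
all subjects contribute the same count K*; the canonical counts per window
length are 16 s → 120, 17 s → 115, 18 s → 109, 19 s → 103, 20 s → 95
(shorter recordings fall back to the largest common K). With 15 subjects ×
4 groups these give 7,200 / 6,900 / 6,540 / 6,180 / 5,700 design rows.

## Connectivity estimators

The analytic signal is computed by Hilbert transform **once per recording**
(not per window) to avoid edge transients inside every window; a 1 s guard
is then dropped from both ends before segmentation. Per window and band:

* PLI = |mean_t sgn(sin(φ_x − φ_y))|;
* wPLI = |E[Im X]| / E[|Im X|] with X = z_x·z̄_y — the cross-spectrum
  estimator. The denominator is guarded by a relative floor
  (10⁻¹² of the mean envelope product), returning 0 when Im X is pure
  rounding noise (e.g. identical zero-lag channels). The debiased variant
  is out of scope.
* AEC = Pearson r of the envelopes; a near-constant envelope (SD below
  10⁻⁹ of its mean) makes the correlation undefined and returns 0.

Diagonals are fixed at 0 (PLI/wPLI) and 1 (AEC) for serialization
stability; features use only the strict upper triangle, vectorized in
row-major (i < j) order with channel order fixed to the 10-20 listing
(F3, F4, C3, C4, F7, F8, P3, P4, T7, T8, P7, P8, O1, O2, Fp1, Fp2, Fz, Pz,
Cz). The vectorized all-pairs path is asserted equal (1e-10) to the scalar
per-pair estimators in the tests.

## Sliding-window correlation

SWC correlates **consecutive** windows' vectorized connectivity:
r_k = corr(w_k, w_{k+1}), k = 1..K−1 (an all-pairs-at-lag-L variant is a
configurable alternative). The per-subject summary uses the mean and the
population SD of the r_k; at K ≈ 95 the population/sample distinction is
negligible but the convention is fixed. Zero-variance rows make r_k
undefined; such pairs are recorded as NaN and counted, not silently
dropped. Group tables average the per-subject summaries per
(group, band, metric).

## Synthetic cohort generator

Each band b has one latent oscillator at the band's geometric-mean centre
frequency. Channel i contributes A_ib(t)·cos(θ_b(t) + ψ_bi + ε_bi(t)):

* **Envelopes**: white Gaussian noise low-passed at 1 Hz (4th-order
  Butterworth, forward-backward), unit-standardized, mixed as
  e_i = a_i·s + √(1−a_i²)·u_i (shared factor s, private u_i), then offset
  by +3 SD and floored at 0.05 for positivity. Pairwise envelope
  correlation is a_i·a_j by construction, which the AEC estimator recovers
  to ±0.05 at the planted 0.6 over 120 windows (tested against the
  generator's own envelopes as oracle).
* **Phases**: per-sample von Mises(0, κ) draws smoothed with a moving
  average and rescaled to the raw draws' SD, so κ governs the realized
  phase consistency while the jitter stays slow enough for the Hilbert
  transform to track. The averaging time is band-adaptive,
  max(0.1 s, 2/margin) where margin is the carrier's distance to the
  nearer band edge: long enough that ≥90% of each latent component's power
  stays inside its band at the lowest preset concentration, short enough
  that wPLI remains strictly monotone in κ (both properties are asserted
  in the tests). Fixed offsets ψ plant consistent non-zero lags (0.12 rad
  per channel step in the presets, keeping all pairwise lags below π).
* **Nuisance**: 1/√f-shaped broadband noise (SD 2 µV) and a 50 Hz sinusoid
  (1 µV) with random phase; per-band carrier gain 2 µV.
* **State drift**: in consecutive 20 s blocks the loadings a_i and
  concentrations κ are perturbed (additive Gaussian clipped to [0,1];
  log-normal respectively) with a group-specific SD, planting slow
  connectivity variability. Drifted values are recorded in the ground
  truth.

**Group presets** (envelope-loading centre, κ, drift SD): coma (0.40, 1,
0.10), UWS (0.55, 2, 0.08), MCS (0.67, 4, 0.06), HC (0.81, 8, 0.03);
per-channel loading profiles are spread ±0.12 around the centre and
permuted with a fixed group-specific permutation so groups differ in
spatial pattern as well as level. These values encode only the qualitative
ordering coma < UWS < MCS < HC reported for clinical cohorts; no
quantitative clinical connectivity levels are claimed, and the presets are
configuration, not findings. All randomness descends from one master seed
via `numpy.random.SeedSequence` children, one per subject in group-major
order; identical (spec, seed) reproduce recordings bit-exactly.

**What the generator does not emulate**: volume conduction and a forward
head model, eye-blink/EMG artifacts, non-stationary band power typical of
arousal fluctuations, inter-subject montage variability, and realistic
cross-band coupling. Passing tests therefore demonstrate that the pipeline
recovers *planted* structure and that the protocol is sound — not that the
classifiers would reach comparable accuracy on clinical EEG.

## Classifiers and evaluation

The seven architectures follow their published layer plans: mlp1
(128→64→4, dropout 0.5/0.3, Adam 1e-3, 50 epochs), mlp2 (256→128→64→4,
batch-norm, dropout 0.4/0.4/0.3, L2 1e-3 on layers 2-3, Adam 1e-3, 100
epochs), mlp3 (256→128→4 with batch-norm, dropout 0.4, L2 1e-3, 60 epochs,
early stopping; the two-hidden-layer narrative description is followed
where the summary table differs), rnn/lstm/gru (128 return-sequences → 64
→ dense 32 → 4, dropout 0.4/0.3/0.2, batch-norm after each recurrent
layer, Adam 5e-4), and cnn_lstm (conv 64 → pool → conv 128 → pool →
LSTM 64 → LSTM 32 → dense 32 → 4, dropout 0.3/0.2/0.2, Adam 5e-4).
Convolutions use kernel 3 with 'same' padding so the 5-step sequence
survives two pooling stages. Sequence models consume the natural
band-major factorization of the 855-vector: 5 time steps (bands) × 171
pair features per metric, metrics stacked on the feature axis.

The layers run on a small NumPy engine with explicit backward passes,
verified against central finite differences (relative error < 1e-4 across
all layer types). Training uses mini-batch Adam (β₁ 0.9, β₂ 0.999, ε
1e-7), batch 32, a 10% validation split carved from a seeded shuffle,
categorical cross-entropy plus L2 penalties, and — where an architecture
specifies them — early stopping (patience 10 on validation loss, best
weights restored) and learning-rate reduction on plateau (factor 0.5,
patience 5, min-delta 1e-4, floor 1e-5). Seeded runs are reproducible to
<1e-6 in test metrics.

Inputs are standardized per feature with training-set statistics only
(constant features map to 0); labels are one-hot with fixed class order
(coma, UWS, MCS, HC). Two protocols: a stratified fixed 80/20 split
(windows of one subject may land on both sides — matching the reported
near-balanced metrics, but optimistic) and subject-grouped k-fold (k = 10
by default; all of a subject's windows stay on one side of every fold —
the leakage-safe protocol). Fold harnesses report the best fold alongside
the mean, since the best fold alone is optimistically biased. Metrics are
accuracy and support-weighted precision/recall/F1 with percentile-bootstrap
95% CIs (1,000 resamples, seeded): per-sample correctness for accuracy,
resampled (true, predicted) pairs for the weighted metrics.

## Problem sizes used in the test suite

The suite exercises the full pipeline at reduced scale, chosen so
statistical assertions retain power: the end-to-end run uses 3 subjects
per group × 260 s recordings (23 twenty-second windows each, 276 design
rows); estimator-recovery checks use 120 windows (AEC ± 0.05 band) and
3-point parameter grids with ~30 windows per point; the classification
benchmark uses 480/600 train/test rows in 855 dimensions. Full-scale runs
(15 subjects per group, 26-30 min recordings) use identical code paths via
`ExperimentConfig` defaults.

## Known limitations

* The synthetic cohort is a one-factor connectivity world; classifiers can
  separate groups from overall connectivity level alone, which inflates
  accuracy relative to clinical data.
* The 80/20 protocol leaks subject identity by design (it mirrors the
  published protocol); grouped k-fold is the defensible alternative and
  both are emitted.
* wPLI is the standard cross-spectrum estimator; the debiased square
  estimator and orthogonalized AEC are not implemented.
* The EDF writer targets the subset of EDF needed here (integer sampling
  rates, 1 s records, 16-bit amplitudes); reading back through MNE is the
  round-trip check.
* No artifact detection or channel interpolation: bad-segment handling is
  limited to an optional annotation mask (`clean_window_mask`) that drops
  windows overlapping annotated samples.
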