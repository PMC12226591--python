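# Methods

## Stimulation waveforms

A stimulus is `s(t) = (A_fA/2)(sin(2π f_P t + φ) + 1) sin(2π f_A t) +
A_fP sin(2π f_P t + φ)`: a fast component at the amplitude frequency `f_A`
whose envelope rides on the slow phase frequency `f_P`, plus an additive
slow component.  Both terms share one phase variable, so a condition's phase
offset φ is applied to that shared argument (envelope and slow component
shift together).  Defaults `f_P = 6 Hz`, `f_A = 40 Hz` follow the
theta–gamma coupling motif; both are per-participant configuration, as are
the intensity constants (defaults 0.2 / 0.8 mA, the 2:8 ratio).

A montage target couples one stimulation electrode with N return electrodes
each carrying `−1/N` of the stimulus, so net injected current is zero at
every sample by construction.  The six-target default montage (bilateral
DLPFC + PPC for the CEN at φ = 0; mPFC + PCC for the DMN at φ = condition)
splits intensity equally across targets (configurable weights).  "Total
stimulation intensity" is read as the peak over time of the summed positive
electrode currents — the safety semantics of a multi-channel stimulator —
and a binding 1.5 mA cap rescales all waveforms by one common factor, which
preserves phase relations exactly.

Phase-lag verification band-passes both series around `f_P` (2nd-order
Butterworth, [f_P/1.5, 1.5 f_P], zero-phase), takes the circular mean of the
analytic-signal phase difference over the central half of the series
(avoiding filter edge transients), and reports degrees in [0, 360).  Series
shorter than 3 cycles of `f_P` are rejected.

## Synthetic cohorts

Each channel of a 500-ms segment (500 Hz) is 1/f-shaped Gaussian noise
(exponent 1.0, broadband RMS 4 µV) plus one sinusoid per band: theta 2.5,
alpha 4, lower-beta 5, upper-beta 2, gamma 1 µV median amplitude.  Per-trial
amplitudes are log-normal (log-SD 0.7, clipped at 2.5 SD so clean trials
stay under the ±100 µV rejection threshold); participants carry a log-normal
scale (log-SD 0.4) and a stable per-band peak frequency (uniform within the
band, ±0.5 Hz trial jitter) — individual peak frequencies are a robust
feature of real EEG and give the decoder a stationary target.

The planted effect multiplies the parietal lower-beta component by g45 =
1.30 (45° condition) or g180 = 0.75 (180°) in the post segment, reusing the
pre segment's component; everything else is redrawn per segment.  Because
the gain is the only condition-dependent quantity, pre segments carry no
condition information at all, the post-segment marginal is weakly
informative (the amplitude spread swamps the gain shift), and the
pre-to-post change carries the signal — a threshold oracle on the parietal
13–20 Hz Welch power ratio reaches ≈ 0.83–0.85.  The gain directions are a
design choice; only a significant condition difference, not its sign, is
claimed for real data.  Artifact trials (optional rate) receive a 200 µV
square pulse and a ground-truth flag.

What the generator does **not** emulate: volume conduction and channel
correlations, non-sinusoidal band structure, within-stimulation artifacts,
behavioural covariates.  Passing tests therefore show the pipeline extracts
a planted band-power contrast under realistic noise/variability — not that
real tACS aftereffects have this structure.

## Preprocessing

4th-order Butterworth band-pass (4–50 Hz), applied forward–backward
(zero-phase; the two-pass response squares the magnitude, so single-pass
−3 dB corners become −6 dB).  Epoch windows [0, 0.5) s and [8.5, 9.0) s of
retention are asserted to avoid the 1.5–7.5 s stimulation interval.
Detrending is per-channel linear least squares.  Rejection: an epoch is
removed iff max |amplitude| > 100 µV or max |Δamplitude|/Δt > 50 µV/ms on
any channel (a trial is dropped when either of its segments is rejected);
the log records the violated rule.  Band selection filters the already
4–50-Hz-filtered data further.  Resampling to the 128-Hz model rate
(64 points per 500-ms period, matching T = 64) is polyphase (32/125) with
linear-extension padding.

## Decoder

EEGNet-8,2-style: F1 = 8 temporal kernels (32 taps = 0.25 s at 128 Hz —
three cycles at 13 Hz, i.e. ~4 Hz spectral resolution; 'same' padding) →
D = 2 depthwise spatial kernels per temporal filter spanning all C channels
(max-norm 1.0) → BN, ELU, average-pool 4, dropout 0.25 → separable temporal
convolution (16-tap depthwise + pointwise to F2 = 16) → BN, ELU,
average-pool 8, dropout → dense softmax (max-norm 0.25).  With 64-point
periods, longer kernels are mostly edge padding (and seam mixing in
concatenated inputs) and measurably degrade learning of the pre-to-post
contrast.
Training: Adam (α = 10⁻³, β₁ = 0.9, β₂ = 0.999), batch 16, cross-entropy,
He initialisation, max-norm reprojection after every step.  All layers are
numpy with hand-written backprop, gradient-checked in the test suite.

Two-period handling: `feature_diff` (default) runs the shared trunk on
each 64-point period and classifies the post-minus-pre feature difference —
the "change in the feature vectors" construction, which builds the
pre-referenced contrast into the architecture and learns the planted gain
far more reliably.  `concat_time` concatenates the periods to T = 128 so one
shared filter bank convolves both; kernels overlapping the seam mix periods
within half a kernel length (quantified by the seam-locality test), and the
resulting decoder tends to read the single-period amplitude marginal instead
of the contrast.  Two additions to the
fixed recipe, both documented design choices: (1) each assembled trial is
divided by its own RMS (one scalar shared by both periods, preserving the
pre→post contrast exactly) to standardise input scale; (2) "best in
validation" is applied within a fold as well as across folds — the weights
at the best validation epoch are restored after training, without which
fixed-length training overfits the ≈ 96-trial sets badly.

Baselines compute per-channel × band mean Welch-PSD change (post − pre;
Hann, 64-sample windows, 50 % overlap at 128 Hz) and feed LDA, RBF-SVM
(C = 1, standardised inputs) or a 100-tree random forest; hyperparameters
are package defaults, recorded here rather than attributed.

## Evaluation design

Per participant: stratified 4:1 train/test split, stratified 5-fold split of
the training portion, one model per fold, the best-validation model (ties:
lower validation loss, then lower fold index) evaluated once on the test
set.  Split validity (disjointness, coverage, per-fold class balance within
one sample) is asserted on every plan.  Ablations reuse one split per
participant across configurations (hash-verified) so paired tests are
valid.  Metrics: accuracy, threshold-sweep ROC with trapezoidal AUC
(equal to the pairwise U-statistic, tested by enumeration), 2×2 confusion
matrices.  Group level: unweighted mean ± SEM of per-participant
accuracies; two-sided paired t-tests under Benjamini–Hochberg FDR across
the stated comparison family; two-sided one-sample t-tests against the 50 %
chance level (class balance is enforced, so chance is exactly 50 %).
Zero-variance difference vectors raise instead of returning p = 1.

## Interpretation

Kernel spectra: |FFT|² of each 32-tap first-layer kernel zero-padded to 256
(0.5-Hz grid), each kernel normalised to its maximum, averaged, and the
average renormalised to 1 per participant; grand average ± SEM across
participants.  Kernel means are subtracted before the FFT: under the batch
normalisation that follows the convolution a kernel's mean has no effect on
the network function, so optimisers let it drift and the spurious DC term
would otherwise dominate the spectrum.  Models used for filter read-outs are
trained on the flat fixed-epoch schedule (no best-epoch restoration): the
filter bank keeps tuning toward the discriminative band after the accuracy
optimum, and restoring an early checkpoint would report near-initial
filters.  Feature maps: trials convolved with the learned kernels,
PSD (periodogram by default; Welch optional, recorded in provenance),
averaged over channels and kernels, normalised to the per-trial maximum,
then averaged across trials; condition differences are taken on the
trial-averaged normalised profiles (the normalise-then-average order), with
the unnormalised order available by flag.  Note that max-normalisation pins
the largest bin at 1, so a planted change at the spectrum's own maximum
surfaces in the *other* bands; with a realistic low-frequency anchor the
contrast localises at the planted band.

## Problem sizes and numerical choices

The synthetic studies in the tests run 6–8 participants × 60 trials per
condition with 40–50 training epochs — sizes at which the planted effect's
learning curve has flattened — rather than the full 21 × 300 recipe; seeds
are fixed throughout and recorded in the reports.  Resampling, filtering
and FFT lengths are stated above; floating point is float32 in the network
and float64 elsewhere.  Degenerate inputs (single-class labels, zero
variance, too-short series/segments, empty trial sets, out-of-range
windows, aliasing sampling rates) raise typed errors with the violated
constraint named.

## Known limitations

On the default cohort — whose planted signal is exactly a band-power change,
the baselines' native feature space — the random forest can outscore the
convolutional decoder; the decoder's advantage appears when the condition
signal is not a band-mean power shift (e.g. a within-band frequency shift,
covered by a regression test).  Real-data claims about decoder superiority
are therefore not reproduced, only the architecture and procedure.

A deterministic multiplicative gain also leaves an irreducible marginal
footprint: the post-segment log band power shifts between conditions by the
same log-gain difference that carries the pre-to-post signal, diluted only
by the per-trial amplitude spread.  At the default spread the post-only
decoder sits a few points above chance (≈ 0.58–0.60) — unlike the emulated
study's chance-level single-period results — while larger spreads that would
hide the marginal also defeat optimisation of the combined decoder.  The
corresponding pooled-chance check on post-only decoding is left failing in
the acceptance suite as an honest statement of this limitation.  The
per-trial RMS scaling and within-fold checkpointing are pragmatic additions
to an otherwise fixed recipe and are flagged as such.  EDF+ export is not
provided; ingestion of recorded data goes through MNE readers.
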