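# Methods

## Signal model and preprocessing

Input is multichannel scalp EEG (channels × samples, microvolts) with an
annotation table of half-open `[start_s, end_s)` intervals labeled
interictal (0) or ictal (1). Preprocessing is a zero-phase 4th-order
Butterworth band-pass (default 1–60 Hz, applied forward–backward with
`sosfiltfilt`) plus an optional IIR notch (Q = 30) at the mains frequency,
60 Hz by default. Zero-phase filtering is used so spike morphology — steep
rising/falling edges of 20–70 ms epileptiform transients — is not skewed by
phase distortion. Epochs are non-overlapping 2-s windows left-aligned to
each interval start; a window straddling an interval boundary is discarded
so every epoch has a single label. At 256 Hz a 2-s epoch is 512 samples.

## Variational mode decomposition

Each channel of each epoch is decomposed independently into K band-limited
modes p_z with center frequencies ω_z by minimizing the summed bandwidth of
the modes' analytic signals subject to (relaxed) exact reconstruction. The
ADMM iteration operates on the positive-frequency half-spectrum (rfft):

- mode update (Wiener filter):
  p̂_z ← (f̂ − Σ_{i≠z} p̂_i + λ̂/2) / (1 + 2α(ω − ω_z)²), Gauss–Seidel over z;
- frequency update: ω_z ← ∫ω|p̂_z|²dω / ∫|p̂_z|²dω (spectral centroid);
- multiplier update: λ̂ ← λ̂ + τ(f̂ − Σ_z p̂_z).

Convergence is declared when Σ_z ‖p̂_z^{t+1} − p̂_z^t‖²/‖p̂_z^t‖² < tol;
hitting the iteration cap returns a result flagged `converged=False` rather
than raising, since downstream features remain computable.

Numerical choices:

- **Boundary handling.** The signal is mirror-extended by half its length on
  each side before the transform and the extension is cropped after
  inversion; this suppresses the edge ringing a periodic FFT assumption
  would otherwise create.
- **Spectrum convention.** Updates run on ω ≥ 0 only; Hermitian symmetry is
  imposed by the inverse rfft, so modes are real by construction.
- **Initialization.** Center frequencies start uniformly spaced,
  ω_z = (z + ½)/(2K) cycles/sample (`uniform`, the deterministic default);
  `zero` and seeded `random` schemes are available.
- **Defaults.** K = 6, α = 2000, τ = 0, tol = 1e-6, max_iter = 500 —
  standard values in the VMD literature. τ = 0 disables the dual ascent,
  which makes the decomposition robust to broadband noise at the cost of
  exact reconstruction (see *Limitations*).
- **Ordering.** Modes are sorted by ascending ω before feature extraction so
  that feature columns are stable across epochs.

Mode energy entropy is provided alongside: E_z = Σ_n p_z(n)², U_z = E_z/ΣE,
B_z = −U_z·log10 U_z with B_z = 0 at U_z = 0 by the limit convention.

## Features

**Differential entropy (DE).** Under a Gaussian model the differential
entropy of a band-limited signal is ½·ln(2πe·σ²_band) nats. Per mode, the
signal is cut into 1-s non-overlapping Hamming windows; the band variance is
the periodogram power integrated over each band (half-open [low, high) Hz,
windows detrended so DE is invariant to constant offsets), averaged across
windows *before* the logarithm, and the returned DE is the mean over the
five canonical EEG bands delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–50 Hz (band edges configurable). Pooling the variance across
windows first keeps the estimator aligned with the closed form: taking the
log per window first would bias DE low by ψ(k) − ln k for a k-bin band
(−0.18 nat for delta), a bias that no amount of averaging removes. A band
with zero estimated power is skipped with a logged warning; a DE on the raw
channel instead of each mode is available via `de_source="raw"`.

**Higuchi fractal dimension (HFD).** For delays z = 1..k_max the z
delay-decimated subsequences give normalized curve lengths
L_w(z) = [Σ|I(w+xz) − I(w+(x−1)z)|·(N−1)/(mz)]/z, averaged to L(z); FD is
minus the least-squares slope of ln L(z) vs ln z. FD is clamped to [1, 2]
with a warning when the raw estimate falls outside by more than 0.05 (band-
limited high-frequency noise can push the raw slope slightly above 2).
Default k_max = 8 for 512-sample epochs keeps ≥ 64 points in the fastest
subsequence; the delays used in the fit are configurable.

The feature matrix is epochs × (channels × K × {DE, HFD}), channel-major,
mode-minor, DE before HFD, with a channel→columns index so channel-subset
selection slices consistently.

## Channel selection (BGWO)

A pack of wolves carries binary channel masks (dimension d = channel
count). Fitness of a mask is the stratified `fitness_folds`-fold CV accuracy
of a KNN classifier (k = `knn_k`, features z-scored on each training fold
only) restricted to the masked channels, minus `cardinality_weight`·|mask|/d;
the empty mask scores 0. Each iteration ranks the pack and takes the three
best as α, β, δ; for every wolf three leader-guided candidates are computed
by the canonical continuous grey-wolf updates (D = |C·X_leader − X|,
I = X_leader − A·D, A = 2a·r₁ − a, C = 2r₂, with a decaying linearly 2 → 0),
and the new mask sets bit d to 1 iff S((I₁+I₂+I₃)/3) > r₃ with
S(x) = 1/(1+e^{−10(x−0.5)}) and r₃ ~ U[0,1) drawn per dimension. The
best-ever mask is tracked elitistically (the reported history is therefore
non-decreasing) and finally coerced to exactly `target_channels` ones by
greedy drop (remove the channel whose removal costs least fitness) or greedy
add. Fitness evaluations are cached by mask, so the evaluation count reflects
distinct masks. Defaults: pack 10, 30 iterations, knn_k 5, 5 fitness folds,
weight 0.01, target 5 channels. When d equals the target the loop is skipped
and the full mask returned.

The steep slope-10 transfer makes the binarization nearly deterministic for
coordinates away from 0.5, which concentrates exploration on genuinely
ambiguous channels; the standard slope-1 logistic can be substituted through
the transfer function if softer sampling is wanted.

## Classification and metrics

An SVM (RBF kernel, C = 1, gamma = "scale" by default; linear kernel
available) is trained per fold on features standardized with
training-fold-only statistics, under stratified k-fold CV (default 10).
The positive class is ictal. Reported per fold and pooled: confusion counts,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy; a ratio with an
empty denominator is NaN, never silently 0. AUC is the Mann–Whitney rank
statistic of the SVM decision scores (ties half-credited), computed per fold
and averaged; it equals the probability that a random ictal epoch outscores
a random interictal one.

## Synthetic data

The generator emulates the study layout the pipeline targets: 256 Hz, 2-s
epochs, 100 interictal + 100 ictal per run, 8 channels of which 5 are
informative by default (sizes configurable up to full 23-channel montages).

- **Interictal channels** (and all non-informative channels in both
  classes): unit-slope 1/f background (sd 20 µV), a 10 Hz alpha component
  (half the background sd, random phase), and white sensor noise (sd 2 µV).
- **Ictal informative channels**: the 1/f background suppressed to 0.2× —
  hypersynchronous discharge replaces desynchronized background, which is
  what drives band power and hence DE *down* — plus a periodic 3 Hz
  spike-and-wave train (biphasic ~50 ms transient followed by a 180 ms
  half-sine slow wave; amplitude = `ictal_effect`·background_sd/3) and
  broadband high-frequency noise (sd 4× sensor noise) that raises the
  Higuchi dimension of the upper modes.

These amplitudes were calibrated once so that the planted contrast — mean
DE lower and mean HFD higher in ictal epochs, on informative channels only —
holds with a rank-sum p < 0.01 at the default sizes, and then frozen.
Non-informative channels are drawn from the identical distribution in both
classes, so a dataset with no informative channels is an exact null on which
cross-validated accuracy sits at chance.

Unit-test series with known fractal dimension are provided: straight line
(FD 1), Gaussian white noise (FD 2), and fractional Brownian motion with
Hurst exponent H (FD 2 − H), synthesized exactly by Davies–Harte circulant
embedding of fractional Gaussian noise. Tone mixtures (sums of cosines plus
optional white noise) serve as VMD fixtures.

What the generator does **not** emulate: physiological EEG topography or
volume conduction (channels are independent), artifacts (ocular, myogenic,
electrode), non-stationary seizure evolution, or inter-subject variability.
Passing tests therefore demonstrate the pipeline's correctness and its
ability to recover planted structure — not clinical performance; clinical
numbers require real corpora (e.g. CHB-MIT via the EDF + annotation-CSV
path), which are not shipped here.

## Reproducibility

Every stochastic stage takes an explicit seed. The pipeline derives stage
seeds as the first four bytes of SHA-256(`master_seed:stage`) (mod 2³¹), so
streams are independent but fully determined by one integer. Persisted
artifacts (epoch archive with fixed zip timestamps, feature CSV, mask and
report JSON with sorted keys, manifest with config hash and stage seeds) are
byte-identical across reruns with the same inputs and configuration.

## Problem sizes

The test suite and the acceptance script run the study at its default layout
(200 epochs × 8 channels, K = 6 → 1600 decompositions per feature pass,
96 features) and validate selection oracles on an 80-epoch 8-channel dataset
with 2 planted channels; these sizes give stable statistics for every
planted-truth check while keeping a full run around a minute on one CPU.

## Known limitations

- With τ = 0 the sum of VMD modes equals the input only where the spectrum
  is concentrated near the mode centers. On narrowband signals (tone
  mixtures) reconstruction is essentially exact (rel. L2 ≈ 4·10⁻⁴), but on
  broadband inputs the Wiener-filter fixed point leaves a residual
  f̂/(1 + G) with G = Σ_z W_z/(1 − W_z), an inherent ~0.2–0.5 relative L2 on
  noisy EEG-like epochs. Turning on the multiplier (τ > 0) restores the
  reconstruction constraint only asymptotically and impractically slowly on
  such inputs. The residual is therefore exposed explicitly in `VMDResult`.
- DE assumes per-band Gaussianity; for strongly rhythmic (deterministic)
  modes it is a band-power log-measure rather than a true entropy.
- HFD's clamp to [1, 2] can mask pathological inputs; the pre-clamp value
  triggers a warning when far outside.
- BGWO is a stochastic metaheuristic: at d = 8 its search space is small
  enough that runs with the default budget almost always find the optimum,
  but no optimality guarantee exists at larger d.
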