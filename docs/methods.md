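# Methods

`walkassr` analyses mobile-EEG recordings from a dichotic auditory
steady-state paradigm: continuous 1 kHz tones, amplitude-modulated at 39 Hz
in the left ear and 41 Hz in the right ear, played while a participant
stands, steps in place, or walks an 8-shaped path (~12 s per lap).  The scalp
response at each modulation rate (the ASSR) indexes auditory cortical
processing of the corresponding ear's input; occipital alpha power (8–14 Hz)
indexes cortical inhibition.  This note documents the models, parameters and
numerical choices, and what the synthetic-data tests do and do not establish.

## Synthetic session generator

Because no public dataset accompanies the paradigm, every stage is validated
by parameter recovery on forward-simulated sessions
(`walkassr.synth.simulate_eeg`).  The forward model is deliberately simple —
fixed Gaussian scalp topographies rather than a head-model leadfield — so the
ground truth is exact and reproducible.

Sources, mixed into 18 scalp channels (10 % montage) plus two earlobe
references and six noise-only EOG channels, all at 500 Hz:

* **ASSR sources** — sinusoids at 39 and 41 Hz with a frontocentral Gaussian
  topography (centre just anterior to Cz, σ = 0.65 on the unit scalp disc).
  Source amplitude depends on movement state; defaults 0.5 / 0.7 / 1.0 µV for
  stand / step / walk.  They are modelled directly as cortical oscillations
  at the modulation rates, not through an auditory-pathway model, because the
  analyses only consume the scalp-level response.
* **Turn-phase gain** — during walking, a gain g (default 1.5) multiplies the
  turn-side frequency's amplitude before the turn apex and divides it after,
  antisymmetrically for the two sources: the exponent profile is
  p(t) = −sin(π·(t − t_apex)/2) inside apex ± 2 s (so +1 one second before
  the apex, 0 at the apex, −1 one second after), and the 39 Hz amplitude is
  scaled by g^p with the 41 Hz amplitude scaled by g^−p for a left turn
  (signs flipped for a right turn).  This reproduces the qualitative pattern
  the turn-locked lateralization analysis targets, with a smooth,
  sign-symmetric time course.
* **Alpha source** — 8–14 Hz band-limited Gaussian noise with an occipital
  topography (centred between POz and the O-line, σ = 0.35), RMS 2.0 / 1.8 /
  1.0 µV for stand / step / walk.  The topography is deliberately sharp
  enough that POz carries the maximum weight with a clear margin over Pz, so
  the occipital-maximum selection criterion holds in the ground truth.  The
  simulated montage contains no Oz electrode: the selection rule compares
  O1/O2/POz against "all other" sensors, and an electrode sitting directly on
  the alpha focus but outside the criterion set would make the rule fail by
  construction rather than by measurement.
* **Aperiodic background** — per-channel Gaussian noise spectrally shaped to
  log₁₀ PSD = offset − exponent·log₁₀ f (defaults 0.5, 1.5; µV²/Hz), plus
  0.5 µV white sensor noise.
* **Burst events** — 100 ms white-noise bursts per ear (left / right /
  central), onsets with uniform 3–7 s gaps per kind.  Each burst multiplies
  the matching ASSR source amplitude by (1 − d) for 300 ms with exponential
  recovery (τ = 150 ms), default dip d = 0.5; the perturbation is modelled
  multiplicatively because the analysis measures a relative power drop.
  Bursts also add P1/P2 evoked templates (Gaussians at 165 ms, σ 15 ms,
  1.0 µV and 325 ms, σ 20 ms, 0.8 µV) on the frontocentral topography.
* **Gyroscope** — the waist sensor's yaw rate for walking is
  A·tanh(k·sin(2πt/T))/tanh(k) with A = 50 deg/s and T = 12 s, one positive
  (left) and one negative (right) excursion per lap, plus a 2 Hz gait ripple
  and white noise; stepping has ripple but no turns.  Left turn = positive
  yaw (right-hand rule), flippable.  The shaping factor k is solved from the
  configured turn duration but clamped at 1.5: beyond that the profile's 3rd
  harmonic exceeds ~1/9 of the fundamental after the 0.3 Hz low-pass and the
  filtered apex splits into twin ripples, which would corrupt the very
  ground truth the turn detector is tested against.  A 6 s straight-walking
  lead-in/out frames the laps so zero-phase filter transients never overlap
  a turn.

All randomness flows from one integer seed; identical configurations give
bit-identical sessions.  Ground truth (apex times, amplitudes, topographies)
is embedded in `Recording.meta["truth"]`.

What the generator does **not** emulate: eye or muscle artifacts, electrode
impedance drift, head-model field spread, heteroscedastic gait noise, or
inter-subject topography variability.  Passing recovery tests therefore
demonstrates that the analysis chain measures what it claims under its own
assumptions — not that it is robust to every artifact class of real mobile
EEG.

## Preprocessing

Earlobe-average rereference; zero-phase Butterworth filters (1 Hz high-pass
order 2, 100 Hz low-pass order 4, 49.5–50.5 Hz band-stop order 3, all
forward–backward so evoked latencies are unshifted); PCA to 16 dimensions
(SVD whitening) on the 18 EEG channels, EOG/reference channels excluded;
extended Infomax ICA (mne's `infomax`, seeded); Welch spectra of component
activations with a 1 s Hamming window and 50 % overlap (1 Hz grid, one-sided
density).  Back-projection of a component subset is
`mixing[:, keep] @ activations[keep]`, i.e. exact within the retained rank-16
subspace.

## Component selection

ASSR components: accepted when the parameterized spectrum has a peak centred
within ±0.5 Hz of 39 or 41 Hz with over-aperiodic height ≥ 0.10 log₁₀ units
— the height threshold makes "clear ASSR signal" operational and is recorded
in each report.  Alpha components: the four-criterion rule (local peak in
6–14 Hz; width between adjacent local minima ≥ 4 Hz, widest peak taken when
several exist; peak power ≥ 3× the 20–50 Hz mean; occipital topography
maximum over O1/O2/POz).  Local extrema use strict neighbour comparison;
plateaus are represented by their lowest-frequency bin; when a peak has no
interior minimum on one side, the spectrum edge brackets the width.  All
passing components are retained and back-projected jointly.

## Spectral parameterization

Power spectra on 1–48 Hz are decomposed into an aperiodic component
(log₁₀ P = offset − exponent·log₁₀ f, fixed mode — no knee term, defensible
below 50 Hz) plus Gaussian peaks in log-power over the aperiodic fit.
"Parameterized power" is the over-aperiodic peak height in log₁₀ units; for
alpha it is the summed heights of peaks with centres in 8–14 Hz.

The fit is iterative: a robust aperiodic line fit (three rounds, discarding
points more than one SD above the running fit — peaks only push residuals
upward); then repeated extraction of the largest residual Gaussian (max 6
peaks, min height 0.05 log₁₀ units, width 1–12 Hz) with a local refinement;
then a joint refit of all Gaussians; then a final aperiodic refit on the
peak-removed spectrum.

Two numerical choices matter for this paradigm and were tuned on constructed
spectra (noiseless two-peak cases), because 39 and 41 Hz lie only two bins
apart on the 1 Hz Welch grid:

* the half-height width walk also stops where the residual turns upward
  (a local minimum marks the border to a neighbouring peak), and
* each Gaussian's centre is pinned near its own grid maximum during both the
  local refinement (±0.75 bin) and the joint refit (± max(σ/2, 0.25 bin)).

Without these, the 39/41 Hz pair merges into a single 40 Hz Gaussian
whenever burst dips or turn-phase gain broaden the peak bases, and the
nearest-peak lookup (tolerance ±1 Hz; ties broken by centre distance)
returns zero at both target frequencies.

## Turn extraction and epoching

Yaw is low-pass filtered at 0.3 Hz (zero-phase Butterworth order 4) —
comfortably above the 1/12 Hz turn fundamental and far below the 2 Hz gait
ripple; the cutoff is configurable since hardware and gait cadence vary.
Apices are local extrema above a magnitude threshold (default: half the
median absolute peak magnitude from an unthresholded calibration pass);
peaks closer than 3 s merge keeping the larger; peaks within 1 s of the
trace edges are discarded (zero-phase filter warm-up).  Turn duration is the
span where |yaw| exceeds half the apex magnitude.  Epochs are apex ± 2 s
(2001 samples at 500 Hz, t = 0 at the lock sample); event times are mapped
from the 120 Hz motion clock to the EEG clock by rounding t·f_s, giving
sub-sample round-trip error; windows crossing recording bounds are dropped
and counted.

## Time-resolved power, lateralization, perturbation

Narrow-band power is the squared magnitude of the analytic signal of the
±0.5 Hz band-passed trace (zero-phase Hamming FIR, 1 Hz transition width,
~3.3 s impulse response; 0.5 s edge trim recorded), computed on continuous
blocks before any epoching.  The lateralization index is
(P39 − P41)/(P39 + P41), positive when the left-ear input is preferred;
zero-power samples become NaN and are flagged rather than silently zeroed.

Turn-locked contrasts epoch the index by apex per direction.  On the
8-shaped path left and right turns alternate within a lap, so trials pair
naturally lap-by-lap; the paired cluster test treats lap pairs as the
exchangeable unit when a single session is analysed.  Burst perturbation:
trials of narrow-band power locked to burst onset are averaged first, then
value(t) = 10·log₁₀(P(t)/mean P over [−400, 0) ms), summarised as the mean
over (0, 700] ms.  Note the ±0.5 Hz band's long impulse response smears a
300 ms dip over seconds and leaks part of it backwards into the baseline, so
measured responses are an order of magnitude shallower than the injected
amplitude drop; the recovery tests therefore assert sign and monotonicity in
dip depth, not absolute depth.

ERPs: ±2 s epochs on the frontocentral set (AFz, Fz, F3, F4, Cz), per-trial
absolute baseline over [−700, 0) ms, trial average, then window means —
P1 [140, 190] ms and P2 [300, 350] ms.  A [150, 200] ms P1 preset exists as
well, since both window conventions appear in the literature for this
paradigm; channel-mean and window-mean commute, the order (channels first)
is fixed for definiteness.

## Statistics

* **Cluster-based permutation test** (paired, two-sided): per-sample paired
  t; contiguous runs with |t| above the two-sided t critical value at
  α = 0.05 form clusters; mass = summed t; the null is the per-permutation
  maximum |mass| under per-subject condition sign-flips (1000 permutations,
  seeded); p = (1 + #{max ≥ |mass|})/(n_perm + 1).  A one-sided variant is
  available via `tails`.  Validity is established by simulation
  (family-wise false-positive rate within Monte-Carlo tolerance of 0.05) and
  the observed clustering cross-checked against mne's implementation.
* **FDR**: Benjamini–Hochberg step-up (statsmodels), checked against a
  brute-force enumeration.
* **Repeated-measures ANOVA** (1–3 within factors, balanced): orthonormal-
  contrast projection — for effect contrast matrix K, Z = YK,
  F = (n·‖z̄‖²/q)/(Σ(z − z̄)²/(q(n−1))); Greenhouse–Geisser
  ε = tr(S)²/(q·tr(S²)) from the contrast-score covariance, clipped to
  [1/q, 1], applied to effects with more than 1 df.  Verified against a
  textbook marginal-means decomposition to 1e-8 and against pingouin.
* **Robust Spearman**: bivariate outlier flags per method (boxplot whiskers
  at 1.5·IQR; median-absolute-deviation and Sn robust scale, both with the
  2.24 ≈ √χ²₀.₉₇₅ cutoff; a point is flagged by a method if it is an outlier
  on either variable); only points flagged by **all three** methods are
  removed; Spearman ρ with average ranks, one-sided in a declared direction
  when hypothesised.  The Sn estimator is the naive O(n²)
  median-of-medians — adequate at per-study sample sizes.

## Problem sizes in the test and acceptance runs

Simulation studies run at desk scale, chosen so each check retains a clear
margin: sessions of 8–30 laps (102–372 s) instead of the full 480 s walking
blocks; burst counts scaled with block duration at the paradigm's one-per-
15 s-per-kind rate; permutation-stage time axes decimated to 100 Hz (the
lateralization index carries no structure above a few Hz); 500/200 datasets
for the false-positive/power study; 20 seeds for end-to-end pattern
recovery; full ICA exercised per block in the pipeline tests and once per
state in the schema tests, while the 20-seed lateralization loop uses the
sensor-space route (the frontocentral average contains the same two
narrow-band sources it would after ASSR-component back-projection, and the
recovery margin does not depend on the ICA step).

## Known limitations

* The specparam peak model on a 1 Hz grid resolves the 39/41 Hz pair but
  splits heavily broadened peaks into 2–3 Gaussians; single-peak heights are
  then conservative (the nearest peak, not the sum).  Band-sum queries are
  available where totals are wanted.
* Perturbation responses are attenuated (not unbiased estimates of the
  injected dip) — inherent to ±0.5 Hz Hilbert power; comparisons across
  conditions remain valid because the attenuation is common.
* ICA on sessions dominated by two near-deterministic sinusoids often
  distributes ASSR variance over several components; selection accepts all
  of them and back-projects jointly, so downstream measures are unaffected,
  but per-component counts are not comparable to human data.
* The rm-ANOVA requires complete balanced tables; missing cells raise.
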