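# Methods

This note documents the models, parameter choices and numerical conventions
behind `psgpheno`, and what the synthetic-data validation does and does not
demonstrate.

## Synthetic polysomnography generator

**Hypnogram.** Wake/NREM/REM dynamics are a semi-Markov chain: bout
durations are gamma-distributed with shape 2 (which suppresses
unrealistically short bouts) and phase-dependent means, by default
wake 120 s / NREM 300 s / REM 90 s in the light phase and 400/180/70 s in
the dark, on a 14 h/10 h light–dark cycle with lights on at 06:00
(configurable — the cycle length is the modeled constraint, the clock phase
is not). The embedded transition chain forbids direct wake→REM entry
(REM is entered only from NREM). The labels are emitted at 4 s epoch
resolution. A protein-deficient animal's light-phase REM bout mean is
scaled by `1 − rem_reduction_light·(1 − protein_level)` (default reduction
0.4), which scales light-phase REM occupancy approximately proportionally
and produces the selective light-phase REM deficit, with the deficit
shrinking linearly as protein is restored.

**EEG synthesis.** Each state bout is generated by FFT-shaping white
Gaussian noise to a target spectrum, so the phase structure is that of a
random process rather than a sum of sinusoids. The target is a
`1/(f+1)^χ` background (χ = 2 by default) with state modifications: a
Gaussian δ bump near 2.5 Hz in NREM, a θ peak near 6.5 Hz (with reduced δ)
in REM, and a mild broadband high-frequency lift in wake. Bouts are scaled
to per-state standard deviations (45/80/40 µV for wake/NREM/REM). EMG is
white noise at 60/18/5 µV RMS, fixing the atonia ordering
wake > NREM > REM by construction. Line noise is a 60 Hz sinusoid
(5 µV default); artifacts are 0.5–3 s, ~800 µV slow excursions at
2 events/h on all EEG channels.

**Genotype effect.** The mutant spectrum multiplies 8–25 Hz power by
`1 + band_effect_low·(1 − protein_level)` and 50–100 Hz power by
`1 − band_effect_high·(1 − protein_level)` (defaults 0.3 and 0.4). The
resulting power imbalance is absorbed inside 25–50 Hz so that total
1–100 Hz power — and therefore the relative power of the unmanipulated
δ and θ bands — is unchanged by genotype. This realizes the emulation
target of a phenotype confined to the mid-frequency rise and γ fall, with
a genuinely null δ band for the association stage's negative control. No
published effect sizes exist in physical units for these shifts; the
defaults were chosen once so that all manipulated bands separate
comfortably at n = 8 animals per group with 2 h analysis windows, and are
flagged as arbitrary.

**Poly-spikes.** Episode onsets are Poisson; each episode is 3 + Poisson(1.5)
biphasic transients (Ricker wavelets, half-amplitude widths 25–60 ms,
inter-spike gaps 80–180 ms) added to the first EEG channel at 5.0 robust
z-units (jittered ±10 %). The amplitude deliberately sits *below* the 8-z
gross-artifact criterion: epileptiform transients are large relative to
background but are not movement-artifact large, and episodes overlapping
artifact-flagged windows are discarded downstream, so injected events must
be distinguishable from artifacts by amplitude.

**Covariates.** Antisense-transcript (ATS) level is generated as the
inverse of the one-phase decay `protein = e^(−1.2·ATS)` with 5 %
multiplicative noise (protein floored at 0.02 before inversion), so the
association module's decay fit has a recoverable generating law. Poly-spike
rates scale as `spike_rate·(1 − protein_level)` in cohort simulation.

**What the generator does not emulate:** real electrode impedance drift,
inter-animal spectral heterogeneity beyond the protein covariate,
state-transition microstructure (brief arousals), spindles/ripples, and
non-Gaussian artifact morphology. Passing the validation suite therefore
demonstrates correctness of the pipeline's computations and its ability to
recover effects of the modeled form — not performance on real recordings.

## Preprocessing

Order is fixed: artifact exclusion → mean detrend → zero-phase notch.
Artifact windows (1 s default) are flagged when any EEG channel's peak
|deviation| exceeds 8 robust z-units (median/MAD over the whole recording)
or saturates (±1990 µV against the ±2 mV EDF range); a flag on any channel
excludes the window on all channels. The published pipeline this
operationalizes identified artifacts visually, so the automated rule is a
documented stand-in with its parameters exposed. The notch is an order-8
Butterworth band-stop (58–62 Hz) in second-order sections applied with
`sosfiltfilt`; "bidirectional" is read as forward–backward filtering, so
the effective magnitude response is squared and the phase response is zero.
Excluded windows are dropped from Welch segment formation, never
zero-filled.

The six analysis hours start at 12 AM, 4 AM, 8 AM, 12 PM, 4 PM and 8 PM of
the second *calendar* day, resolved against the recording's start clock
time; a partial first day is fine as long as day 2 is fully covered.

## Spectral estimation

Welch segments (2 s Hann, 50 % overlap, per-segment mean removal,
density scaling) are drawn only from maximal artifact-free runs — segments
never straddle a masked window. Density scaling makes band power an
integral (area under the PSD), computed by the trapezoid rule with band
edges on the 0.5 Hz grid; since the seven bands share edges and tile
1–100 Hz, their absolute powers sum to the 1–100 Hz total exactly. The
58–62 Hz repair fits one least-squares line through the 10 grid points
below 58 and the 10 above 62 Hz; reading the published phrasing as a line
through the two flank means instead is available as
`method="flank_means"`, with no claim about which the original authors
used. Zero total power raises an error rather than producing NaN tables,
and a zero γ₂ band power makes the ratio an error, not infinity.

## Poly-spike detection

Detection operates on a 5 Hz high-passed copy of each EEG channel: on
steep 1/f backgrounds the raw robust z is dominated by slow waves, and the
high-pass makes the threshold refer to sharp-transient amplitude. Local
extrema of either polarity above 6 robust z-units whose half-amplitude
width (at half prominence) lies in 20–70 ms are spikes; same-channel events
within 30 ms merge, keeping the larger. Spikes are pooled across channels
and clustered by single linkage with a 200 ms gap; clusters of ≥ 3 spikes
are episodes. Thresholding in robust z-units makes the detector invariant
to global amplitude scaling, and pooling makes it invariant to channel
order. Absolute agreement with visual review on real data cannot be
established without raw recordings; only injection recovery on synthetic
data is claimed (≥ 90 % sensitivity, ≤ 10 % spurious at default SNR).

## Sleep staging

The stager is a deliberately transparent stand-in for CNN-based scorers,
retaining their hidden-Markov smoothing idea: a 3-component full-covariance
Gaussian mixture on (log EMG RMS, log θ/δ, log δ) — features averaged over
EEG channels — identified with wake/NREM/REM by signature (highest mean
log EMG is wake; components within 0.5 nats of it are also wake, which
handles recordings containing little sleep; of the sleeping components the
higher θ/δ is REM, and a lone sleeping component is REM only if θ exceeds
δ). Decoding is Viterbi under a fixed transition matrix
(self-transition 0.97, wake→REM probability 0) — so isolated single-epoch
flips are suppressed relative to raw argmax labels. Externally produced
hypnograms enter via the hypnogram CSV and feed identical budget and
agreement code.

Budgets are computed over the second calendar day when the hypnogram
covers it, or over an exactly-24 h hypnogram as given; per phase, state
seconds (including artifact epochs) sum to the phase duration. Agreement
metrics use one-vs-rest confusion counts with epochs labelled ARTIFACT by
either scorer excluded; zero-denominator metrics are reported as NaN with
an explanation, never silently 0.

## Association fits

Normalization divides by the wild-type-control group mean, making that
group's mean normalized value 1 by construction. The exponential decay
`Y = a·e^(−kX) + b` is fitted by bounded (k ≥ 0) nonlinear least squares
with initialization b₀ = min(y), a₀ = max(y) − b₀, k₀ from a
log-linearization, plus 5 jittered restarts keeping the lowest residual
sum of squares; an effectively flat fitted decay is flagged as
non-identifiable in the (a, b) split. The linear fit is ordinary least
squares with the conventional two-sided t-test on the slope; a permutation
null exists only in the test suite as an independent check. Group omnibus
tests (ANOVA/Kruskal–Wallis families) are deliberately delegated to stock
statistical routines and not re-derived here; multiple-testing correction
across phenotypes is flagged, not applied.

## Problem sizes and numerical choices

Validation studies run at 500 Hz sampling (Nyquist 250 Hz covers the
1–100 Hz analysis range; the acquisition-faithful 5000 Hz remains the
configuration default), with 20 × 1 h recordings for injection recovery,
4 × 3 h recordings for stager accuracy, and 16-animal cohorts (n = 8 per
genotype) using 2 h spectral windows plus 48 h hypnograms for REM budgets —
2 h windows are the package's chosen compromise between the 6 h published
sampling schedule and simulation cost, long enough that state-mix
variability no longer swamps the band-power effects. EDF output quantizes
to 16 bits over ±2 mV (a typical rodent EEG amplifier range; the modeled
studies do not state theirs). Sample intervals are half-open and 0-based
throughout; epoch k of a hypnogram covers samples [k·L·fs, (k+1)·L·fs).

## Known limitations

* The artifact rule and spike detector operationalize steps that were
  visual/manual in the published workflow; their absolute thresholds are
  design choices, exposed as parameters.
* The stager is not a CNN and makes no domain-invariance claim; it is
  validated only against the generator's ground truth.
* The generator's effect sizes are arbitrary by necessity (no published
  physical-unit effect sizes exist); recovery results validate the
  machinery, not any quantitative claim about real animals.
* EDF support is baseline EDF (16-bit, 1 s records, whole-second
  recordings); EDF+ annotations are out of scope, with events carried in
  sidecar CSVs instead.
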