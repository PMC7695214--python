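# Methods

This note documents the models, conventions and numerical choices behind
`tovaqeeg`, and what the synthetic validation does and does not establish.

## Study protocol emulated

A 19-channel EEG (International 10-20 montage, Fp1 … O2 ordered frontal to
occipital, 256 Hz) is recorded during (i) a 5 min eyes-open rest and (ii) a
Test of Variables of Attention (TOVA): 648 stimuli presented every 2 s
(100 ms display + 1.9 s response window), 324 targets and 324 nontargets
split over four quarters, 21.6 min total. Subjects press a button for
targets only; trials classify as correct target response, correct nontarget
response, omission (missed target) or commission (pressed on a nontarget).
Per-subject Beck Depression Inventory (BDI) scores accompany the EEG.

## Synthetic cohort generator

No public recordings exist for this protocol, so the package ships a seeded
generator whose outputs carry the statistical structure the analysis layer
is built to detect. Every operation is a pure function of (inputs, seed).

**Schedule.** Onsets at k·2 s. Quarter target counts follow configurable
ratios (default 0.225/0.225/0.775/0.775 of each quarter's trials — the
standard target-infrequent-then-frequent TOVA halves) scaled by largest
remainder so the total is exactly `n_targets`; order is shuffled within
quarter.

**Responses.** Each target is omitted with probability `omission_rate`,
otherwise answered at a latency drawn from a normal (`rt_mean`, `rt_sd`)
truncated to the 100–1900 ms response window; nontargets draw a commission
press with probability `commission_rate`. Defaults are typical group
summaries for healthy controls and depressed adults on this task
(control: 1.70% omissions, 2.06% commissions, 363 ± 47.8 ms; patient arm:
7.29%, 3.33%, 450 ± 92.5 ms; BDI 6.22 ± 6.76 vs 30.8 ± 11.7).

**EEG.** For each band (δ 1–4, θ 4–8, α 8–12, β 12–16 Hz) a 19-source
Gaussian field is synthesized in the frequency domain (power strictly
confined to the band), mixed through a spatial mixing matrix, and each
channel rescaled to the profile's per-channel band power target (µV²;
defaults δ 30, θ 15, α 20, β 8). Because the sources are exactly
band-limited, the generated per-channel band powers match their targets to
within sampling error (verified < 10% at 300 s). Artifacts added on top:

* blinks — 0.25 s squared-Hann transients (~120 µV at Fp1/Fp2) at
  `blink_rate`/min with a fixed frontal topography decaying with distance
  from the eyes (Fp1/Fp2 highest, then F7/F8);
* drift — Gaussian noise band-limited to 0.02–0.5 Hz at `drift_amplitude`
  µV RMS per channel;
* line — a 60 Hz sinusoid of `line_amplitude` µV, common phase.

**Covariance regularity.** The knob `covariance_regularity ∈ [0, 1]`
(separately for rest and task) sets the target channel covariance to a
convex blend of a smooth Toeplitz kernel in channel-order distance
(Gaussian, length scale 3 channels) and a seeded random Wishart matrix; the
mixing matrix is its Cholesky factor. The Toeplitz end makes the
covariance approximately constant along matrix diagonals — the repetitive
image structure that the two-scale entropy score reads as regular — while
the Wishart end produces an irregular pair pattern. The response of the
entropy score to this knob is graded and monotone (Spearman ≈ 0.97 between
irregularity and score in calibration runs). The random component's
maximum weight is 0.5.

**The "study" preset** (`study_profiles()`) encodes the
group-by-state crossover the analysis is designed to recover: control
regularity 0.5 at rest / 0.8 in task; patient 0.65 at rest / 0.25 in task.
Thus patients are *less* regular (higher entropy) than controls during the
task and *more* regular (lower entropy) at rest. The patient profile also
carries 1.6× θ power at F7, giving the left-frontal theta-cordance excess.
`artifacts=False` zeroes blink/drift/line for analysis-layer studies that
bypass preprocessing.

## Preprocessing

1. **Baseline wander** — per channel, the baseline estimate is a cascade of
   two running medians (0.04 s then 0.2 s windows, reflect padding)
   subtracted from the signal. Note the consequence of these window
   lengths: the cascade tracks (and therefore removes) oscillations below
   roughly 3 Hz — measured attenuation ≈ 32 dB at 1 Hz, 18 dB at 2 Hz,
   4 dB at 4 Hz, < 0.2 dB at 10 Hz. Delta-band absolute power downstream of
   this stage is consequently a high-passed quantity; the stage is also not
   idempotent in the delta band. Both window lengths are configurable.
2. **Line interference** — a linear-phase FIR band-reject (Hamming, 257
   taps, stop edges 60 ± 4 Hz) applied zero-phase through the frequency
   domain (spectrum × |H|²), avoiding boundary ringing. Contract: ≥ 40 dB
   at 60 Hz, < 1 dB ripple outside 60 ± 6 Hz.
3. **Ocular artifacts** — the four EOG-related channels (Fp1, Fp2, F7, F8)
   are decomposed by FastICA (seeded); components whose absolute
   correlation with the low-frequency (< 4 Hz) frontal envelope exceeds 0.7
   become EOG references; every channel then passes through a
   recursive-least-squares adaptive filter (3 taps per reference,
   forgetting 0.999) and the fitted ocular contribution is subtracted. All
   channels share the same regressor vector, so the RLS gain recursion is
   shared and only the weight vectors are per-channel. When no component
   clears the threshold — the expected outcome on blink-free, near-Gaussian
   data, where FastICA has nothing non-Gaussian to converge to — the
   recording passes through unchanged; `ica_strict=True` turns
   non-convergence into an error instead.

## Epoching and behavioral scores

Task epochs are `[onset, onset + 2 s)` (19 × 512 samples at 256 Hz; no
pre-stimulus offset), classes copied from the response log. The resting
recording is cut into consecutive non-overlapping 2 s windows for
comparability. Scores: omission % , commission %, mean and SD of
correct-target latencies, and d′ = z(hit) − z(false alarm) with rates
clipped to [1/(2N), 1 − 1/(2N)] before the normal quantile.

## Band power and cordance

Per epoch and channel: boxcar periodogram (no detrending), power summed
over each half-open band; Parseval holds exactly, so a pure on-bin tone of
amplitude A contributes A²/2 to its band. Epochs are averaged within a
condition (correct targets, correct nontargets, resting); relative power is
each band's share of the four-band total. Each channel is then averaged
with its grid neighbors (e.g. F3 ← (F3 + Fp1 + F7 + Fz + C3)/5; the full
symmetric adjacency ships in `montage.DEFAULT_ADJACENCY` and is
overridable), z-scored across the 19 channels (population SD, per band;
pooling available), and cordance(ch) = z_abs(ch) + z_rel(ch). Cordance is
invariant to any global gain on the raw signal.

## Covariance images

Per trial X (19 × 512): the trace-normalized scatter X Xᵀ / tr(X Xᵀ)
(non-centered, as the quantity is defined on raw signal vectors; a centered
variant is a flag). Trial matrices are averaged over a condition's correct
trials, min-max mapped to 0–255 (round half up; a constant matrix maps to
zeros and is flagged), then histogram-equalized with the discrete CDF
formula over 256 levels — a monotone relabeling of gray levels.

## Two-scale approximate entropy

The image is flattened row-major into Sn (length 361; consecutive diagonal
elements 20 apart). For pattern length m,
`ApEn(Sn, m, r) = mean_i #{j : ‖Sn[i:i+m] − Sn[j:j+m]‖∞ < r}/(n−m+1)`
with self-matches included; the score is
`(1/n) · ApEn(Sn, m1, r) / ApEn(Sn, m2, r)` with m1 = 20 (one diagonal
period) and m2 = 50. Since a long-window match implies a match of its
prefix, the ratio measures how quickly pattern matches die out as the
window grows — faster for irregular images, so higher scores mean less
regularity. The constant image is the floor: both components 1, score 1/n.

**Similarity threshold.** r defaults to 1.5 SD of the sequence. The
classical 0.2 SD convention was designed for short patterns (m = 2) on raw
time series; with 20–50-sample patterns under the max norm on an equalized
8-bit image it admits essentially no non-self matches for any input, and
the score collapses to the constant (n−m2+1)/(n−m1+1)/n. 1.5 SD keeps both
match fractions informative across the regular-to-irregular range; r is
configurable (SD-relative or absolute), and every reported score records
the r used. Euclidean distance and an inverted-ratio/no-prefactor reading
are available by flags; both components are always stored so any variant
can be reconstructed.

## Statistical layer

* Mann–Whitney U, two-sided; exact null distribution for arms ≤ 20 without
  ties, tie-corrected normal approximation otherwise.
* Two-way ANOVA (group × condition) by OLS with type-II sums of squares;
  per-condition group contrasts use pooled-MSE t statistics with
  Bonferroni-adjusted p values and simultaneous CIs. Both factors are
  between-observation; results carry a note that repeated measures per
  subject are not modeled.
* Channelwise unpaired t-tests (pooled variance) for cordance maps.
* Spearman rank correlation, two-tailed.
* ROC: empirical curve over midpoint thresholds; AUC = U/(n₁n₀);
  Hanley–McNeil SE with a normal 95% CI; cut-off by Youden's J, with exact
  (Clopper–Pearson) binomial CIs on its sensitivity and specificity — a
  transparent, reproducible cut-off rule chosen over discriminant-based
  alternatives.
* Combination score: entropy + w·omission% on raw scales, w swept over
  0.0–1.0 in 0.1 steps (a z-scored mode exists because raw-scale weights
  are unit-dependent).
* Bootstrap: B = 1000 resampled means per group × condition cell; Gaussian
  KDE (Silverman bandwidth) for density curves; one-way ANOVA across the
  six cells with all 15 pairwise Bonferroni CIs (pooled MSE); ROC with
  AUC/SE/CI on the bootstrapped means per condition. Seeded and
  bit-reproducible.

## Problem sizes used in validation

The recovery and calibration studies run at deliberately reduced sizes
chosen to keep the full validation suite fast while leaving the effects
they probe far above their detection thresholds: crossover cohorts use
6 + 6 subjects, 48 s rest (24 windows) and 120 trials instead of
18 + 18 / 300 s / 648; the acceptance script's full run uses 18 + 18
subjects with 60 s rest and 120 trials, artifacts on and preprocessing
enabled. Type-I calibration uses 18 per arm (10 000 simulations in the
test suite); bootstrap coverage uses n = 30 Gaussian cells over 500
replicates.

Within a group, BDI scores are drawn independently of the EEG parameters,
so the within-group correlation between BDI and the entropy score is null
by construction; only between-group contrasts carry designed signal.

## What passing tests do and do not show

The generator produces stationary Gaussian band-limited fields with exact
band powers, idealized artifact morphology, and a covariance-regularity
structure purpose-built to be visible to the two-scale entropy score. Real
EEG is nonstationary, has 1/f broadband structure, muscle and movement
artifacts, reference effects and inter-subject montage variation — none of
which are modeled. Passing the recovery tests therefore shows the
*pipeline* is correct and sensitive to the covariance structure it targets
(and the statistical layer is calibrated), not that the biomarker separates
clinical groups on real recordings.

## Known limitations

* The delta band is distorted by the 0.2 s/0.04 s median baseline cascade
  (see above); comparisons of absolute delta power across pipelines should
  use the raw recordings.
* The entropy score's dynamic range under the max norm is bounded by the
  diagonal-spike geometry of equalized covariance images (matches occur
  only at lags ≡ 0 mod 20), so synthetic scores occupy a narrower numeric
  range than clinically reported values; group ordering and discrimination,
  not absolute score values, are the validated quantities.
* EDF files are read (via mne) but not written; the canonical on-disk
  format is long CSV.
* The two-way ANOVA treats condition as between-observation, matching the
  analysis it reproduces; a mixed-model treatment would be more efficient
  for per-subject repeated measures.
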