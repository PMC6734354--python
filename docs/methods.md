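# Methods

`richrv` implements a heart-rate-variability (HRV) analysis of the remote
ischemic conditioning (RIC) protocol — four cycles of 5-min limb-cuff
occlusion followed by 5-min reperfusion, bracketed by a 10-min resting
baseline and a final 5-min rest — together with a synthetic cohort
generator, because no public recordings of this protocol exist.  This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic data can and cannot show.

## Synthetic RR model

The tachogram generator produces intervals from a sum of sinusoids on the
interval sequence itself:

    RR_k = m + g(t) * [a_VLF sin(2π f_VLF t_{k−1}) + a_LF sin(2π f_LF t_{k−1})]
             + a_HF sin(2π f_HF t_{k−1}) + ε_k ,     t_k = t_{k−1} + RR_k/1000

with `ε_k ~ N(0, σ²)` and a hard floor at 250 ms (no physiological interval
is shorter).  Default band frequencies are 0.02 / 0.10 / 0.25 Hz — the
centres of the conventional VLF (< 0.04 Hz), LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) bands of the RR spectrum.  `g(t)` is the post-RIC gain: 1
before the end of the last occlusion and `post_effect_multiplier`
afterwards, applied to the slow (VLF+LF) amplitudes only, emulating a rise
in long-term variability (SD2) with short-term (SD1, rMSSD) left alone.

This model was chosen over an integral-pulse-frequency-modulation (IPFM)
model because it is analytically checkable: a single sinusoid of amplitude
A contributes RR variance A²/2 exactly, so spectral recovery, Parseval
behaviour and SD1/SD2 monotonicity all have closed-form expectations.  The
cost is realism: real tachograms are modulated in continuous time and
sampled by the beats themselves (IPFM), carry respiration-coupled
nonstationarity, and have 1/f-like broadband VLF rather than a line.  Tests
passing on this model therefore demonstrate correctness of the *analysis
chain*, not validity of any physiological claim.

Cohort defaults (per 3300-s subject record):

| parameter | young | senior | rationale |
|---|---|---|---|
| mean RR (ms) | 800 | 900 | resting rates ~75 vs ~67 bpm |
| VLF / LF / HF amplitude (ms) | 35 / 30 / 25 | 18 / 14 / 10 | overall variability roughly halved in seniors, mirroring the reported much lower senior baseline SD2 |
| noise SD (ms) | 10 | 6 | beat-to-beat jitter |
| post-effect multiplier | 1.5 | 1.5 | the study never quantifies its per-subject SD2 change, so the default is a free choice: large enough to be a clear effect, small enough that segment-level variability still matters |
| ectopic rate | 0 (configurable < 0.1) | | isolated premature beats only |

Ages are drawn uniformly in [20, 60) for young and (60, 86) for senior
subjects, matching the strict "> 60 years" senior definition.  Per-subject
randomness derives from `SeedSequence((cohort_seed, subject_index))`, so
adding a subject never perturbs existing ones.

The ECG renderer centres a fixed template at every beat time: a biphasic
QRS wavelet (Gaussian R of σ = 10 ms with Q/S side lobes, ~100 ms support,
normalized so the R peak equals `qrs_amp_mv` exactly) plus low-amplitude P
and T deflections that exercise the detector's T-wave rejection; optional
Gaussian noise and a 0.22-Hz sinusoidal baseline wander are added.  A
fixed, not learned, morphology is sufficient because the pipeline exercises
*detection*, not morphology analysis.  Records carry 0.5 s of flat lead-in
and lead-out so edge beats render completely.

Ectopic injection displaces a chosen beat early by `displacement_frac` of
its interval, shortening RR_k and lengthening RR_{k+1} by the same amount —
the classic premature-beat-plus-compensatory-pause signature, with total
duration preserved exactly.  Injections are kept ≥ 3 intervals apart, so
every ectopic is isolated.

## R-peak detection

The Pan-Tompkins pipeline is implemented with its classical constants
(collected in one block in `qrs.py`): 5–15 Hz band-pass, five-point
derivative, squaring, 150-ms moving-window integration, dual adaptive
thresholds on the integrated and band-passed signals with 0.125/0.875
running-level updates, 200 ms refractory, slope-based T-wave rejection
within 360 ms, and search-back at half threshold when no beat arrives
within 1.66× the running RR average.

Differences from the 1985 real-time formulation, all consequences of
running offline:

* every stage is zero-phase (forward–backward Butterworth, centred
  derivative and integration kernels), so fiducials are not delayed and the
  final refinement — local maximum of the *raw* ECG within ±40 ms — finds
  the true R peak;
* initial signal/noise levels come from whole-record statistics rather
  than a 2-s learning phase (still scale-free, so detection is invariant to
  amplitude scaling, which is tested);
* candidates below 10⁻⁴ of the record's maximum integrated energy are
  discarded — this floor is relative, preserving amplitude invariance, and
  only removes numerical filter ringing on silent stretches.

The detector assumes upright R peaks (true of the synthetic lead);
polarity-agnostic detection is a known limitation.

## Segmentation

HRV features are meaningful on 5-min (or 24-h) windows, so the 10-min
baseline is analysed as two 5-min segments and the 10-min post-procedure
window as `non_occlusion_4` + `post_rest`.  An interval belongs to the
phase whose half-open window [start, end) contains its *terminating* beat —
deterministic, no interval counted twice, boundary beats go to the later
phase.  Segments with fewer than 100 intervals (≈ 33 bpm floor) are flagged
`low_beat_count`, never silently dropped; all exclusions happen explicitly
at the statistics stage and are logged.

The timeline totals 55 min.  Whether the protocol's post-procedure window
includes the last reperfusion phase or starts after it is ambiguous; the
default reading (include it) is configurable through the phase tuples in
`stats`.

## HRV features

**Time domain.**  Mean, median, SDRR, SDSD, rMSSD, NN50 (strict |ΔRR| > 50
ms) and pNN50.  All standard deviations use the population (divide-by-N)
convention so the Poincaré identity below is exact and constant series
score exactly 0; at N ≈ 300 the sample-variance alternative differs by
< 1%.  pNN50 divides by the number of RR *intervals*; the more common
divide-by-(N−1) convention is available as `denominator="diffs"`.

**Frequency domain.**  The segment's tachogram is first cleaned of ectopic
beats: an interval deviating > 30% from the median of its 11-interval
centred window is deviant; a lone deviant interval is replaced by the mean
of its neighbours, and a deviant short-interval/long-interval couplet (the
premature-beat signature) is linearly re-interpolated across both
intervals.  Same-sign adjacent deviations and longer runs are left
untouched with a QC note — they are not the signature of an isolated
ectopic, and guessing would destroy real variability.  A deviant fraction
above 5% flags `high_ectopic_load`.  The corrected knots (original beat
times, corrected values) are cubic-spline resampled at 10 Hz, mean-
subtracted, and passed to Welch's method: 256-sample Hann windows, 50%
overlap, per-window mean removal, one-sided density normalization (the PSD
integral approximates the signal variance).  Mean subtraction happens after
resampling; for stationary 5-min segments the difference from subtracting
before is negligible.

Band powers integrate the density over VLF [0, 0.04), LF [0.04, 0.15) and
HF [0.15, 0.4) Hz.  Because the Welch grid spacing is 10/256 ≈ 0.039 Hz,
only 2–3 grid points fall inside the LF band; the band integral therefore
treats the density as piecewise linear and integrates over the *exact*
band limits with interpolated edge values, so contiguous bands tile the
spectrum without losing edge half-bins.  Normalized powers divide by
(total − VLF) with total = VLF+LF+HF, hence nuLF + nuHF = 100 identically;
integrating "total" to the 5-Hz Nyquist instead would make the normalized
values hostage to spline high-frequency artefacts.  Degenerate spectra
(zero normalizable power, zero HF) yield NaN plus a QC flag rather than an
exception.

**Poincaré.**  SD1² = ½ Var(RRₙ − RRₙ₊₁) = ½ SDSD² and SD2² = 2 SDRR² −
½ SDSD², the ellipse-fit identities, with population variance.  SD1² +
SD2² = 2 SDRR² follows algebraically and is enforced to 1e-9 relative in
tests.  SD2² can go negative on short alternating series; it is clamped to
0 with the `sd2_clamped` flag and the SD1/SD2 ratio becomes NaN.

## Statistics

Comparisons are within-subject Wilcoxon signed-rank tests at α = 0.05, no
multiple-testing correction by default (a Holm option exists), on ten
features: mean RR, median RR, pNN50, rMSSD, nuLF, nuHF, LF/HF, SD1, SD2,
SD1/SD2.

* **pre vs post**: per subject, pre = mean of the two baseline segments,
  post = mean of `non_occlusion_4` and `post_rest`; subjects missing any of
  the four segments are excluded and logged.
* **occlusion vs non-occlusion**: per subject, mean over the four occlusion
  segments vs mean over the four reperfusion segments.  (Whether the
  original analysis pooled segments or averaged per subject is unstated;
  subject-wise averaging keeps one independent pair per subject.)
* **subsets**: the same tests on young (age ≤ 60) and senior (> 60) strata.

The signed-rank test drops zero differences, ranks |d| with average ranks
for ties, and uses W = min(W⁺, W⁻).  For n ≤ 25 nonzero pairs the two-sided
p is exact: the full null distribution of W⁺ over all 2ⁿ sign assignments
is built by convolution over the (doubled, hence integer) ranks, which is
valid in the presence of ties — the reason the test is written here rather
than delegated to `scipy.stats.wilcoxon`, whose exact mode cannot handle
ties.  Beyond n = 25 a normal approximation with tie and continuity
correction is used.  scipy is retained as a cross-check oracle for tie-free
inputs, and literal sign-pattern enumeration for tied ones.

Per-subject feature changes (post − pre) are correlated with Spearman's
rho.  The study this emulates attributes its correlation coefficients to a
"Wilcoxon test", which produces no correlation coefficient; Spearman is the
standard non-parametric correlation and the closest coherent reading, with
Pearson available as an option.

## Calibration and power of the study conditions

Under the defaults (n = 17: 9 young + 8 senior, the cohort size after the
protocol's one exclusion), the acceptance script measures, per run:

* type-I error of the pre/post SD2 test on null cohorts
  (multiplier = 1.0) over 400 replicates — expected within [0.02, 0.08]
  given the discreteness of the exact test at n = 17;
* power and direction of the SD2 test under a 1.5× post-RIC slow-band
  amplification over 200 replicates — essentially every replicate detects
  the increase, because a 50% amplitude step dwarfs segment-level sampling
  noise in this stationary model.  Real-data power would be far lower;
  the simulation validates the machinery, not the effect size.

These replicate counts keep the full run under about a minute on one core
while the binomial standard error on the type-I rate (≈ 0.01 at 400
replicates) stays well inside the acceptance band.

## Known limitations

* The RR model is a line spectrum plus white noise; no 1/f VLF background,
  no respiration coupling, no nonstationarity within phases.
* The ECG template has fixed morphology and upright polarity; no real
  inter-subject morphology variation, lead placement, or muscle artefact.
* Ectopic correction recognises only isolated singles and compensatory
  couplets; runs of arrhythmia are flagged, not repaired.
* The detector is tuned for single-lead adult ECG between roughly 40 and
  180 bpm; bradycardia below the search-back horizon or sustained
  tachyarrhythmia is out of scope.
* With only 2–3 Welch grid points in the LF band, LF power carries
  systematic leakage error of a few percent (visible as LF/HF ≈ 1.87 for a
  true ratio of 2.0); a longer window would shrink it but the 256-sample
  window is part of the specified analysis.
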