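"""Seeded synthetic RR series, ECG signals and RIC cohorts.

The study protocol this package targets — four cycles of 5-min limb-cuff
occlusion / 5-min reperfusion, bracketed by 10-min baseline and a 5-min
post-rest — has no public recordings, so the generators here provide ground
truth for every downstream stage.

The RR model is a sum of sinusoids on the interval sequence itself:

    RR_k = mean + sum_band amp_b * sin(2*pi*f_b*t_{k-1}) + eps_k

with ``eps_k ~ N(0, noise_sd^2)`` and a hard 250 ms floor; the beat clock is
``t_k = t_{k-1} + RR_k / 1000``.  The three bands emulate the canonical
tachogram spectrum: VLF (< 0.04 Hz), LF (0.04–0.15 Hz, baroreflex-mediated
Mayer waves) and HF (0.15–0.4 Hz, respiratory sinus arrhythmia).  This is
deliberately simpler than an integral-pulse-frequency-modulation model: it
is analytically checkable (a single sinusoid of amplitude A contributes RR
variance A^2/2) and sufficient for exercising detection, segmentation,
spectral estimation and the paired statistics.  See docs/methods.md for the
limitations this implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import ECGRecord, ProtocolTimeline, RRSeries, SubjectInfo

__all__ = [
    "RRGenParams",
    "CohortSpec",
    "SubjectRecord",
    "generate_rr_series",
    "generate_ecg",
    "inject_ectopic_beats",
    "generate_ric_cohort",
    "YOUNG_BASELINE",
    "SENIOR_BASELINE",
]

#: intervals shorter than this are physiologically impossible; noise is clipped
RR_FLOOR_MS = 250.0


@dataclass(frozen=True)
class RRGenParams:
    """Parameters of the sinusoidal RR generator.

    Amplitudes in ms, frequencies in Hz.  Frequencies must stay below the
    beat-rate Nyquist ``0.5 / (mean_rr_ms / 1000)`` and the mean must exceed
    the summed amplitudes so RR stays positive without relying on the floor.
    """

    duration_s: float
    mean_rr_ms: float
    lf_amp_ms: float = 0.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 0.0
    hf_freq_hz: float = 0.25
    vlf_amp_ms: float = 0.0
    vlf_freq_hz: float = 0.02
    noise_sd_ms: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        for name in ("lf_amp_ms", "hf_amp_ms", "vlf_amp_ms", "noise_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        nyquist = 0.5 / (self.mean_rr_ms / 1000.0)
        for fname, aname in (
            ("lf_freq_hz", "lf_amp_ms"),
            ("hf_freq_hz", "hf_amp_ms"),
            ("vlf_freq_hz", "vlf_amp_ms"),
        ):
            f = getattr(self, fname)
            if getattr(self, aname) > 0 and not 0.0 < f < nyquist:
                raise ValueError(
                    f"{fname}={f} must lie in (0, {nyquist:.3f}) Hz, the beat-rate Nyquist"
                )
        if self.mean_rr_ms <= self.lf_amp_ms + self.hf_amp_ms + self.vlf_amp_ms:
            raise ValueError("mean_rr_ms must exceed the sum of modulation amplitudes")


def _rr_loop(
    params: RRGenParams,
    rng: np.random.Generator,
    *,
    duration_s: float | None = None,
    slow_gain_after_s: float | None = None,
    slow_gain: float = 1.0,
) -> RRSeries:
    """Sequential beat-clock loop shared by the plain and cohort generators.

    ``slow_gain`` multiplies the VLF and LF amplitudes once the beat clock
    passes ``slow_gain_after_s`` (the RIC after-effect switch).
    """
    dur = params.duration_s if duration_s is None else duration_s
    mean = params.mean_rr_ms
    va, la, ha = params.vlf_amp_ms, params.lf_amp_ms, params.hf_amp_ms
    wv = 2.0 * math.pi * params.vlf_freq_hz
    wl = 2.0 * math.pi * params.lf_freq_hz
    wh = 2.0 * math.pi * params.hf_freq_hz
    # hard upper bound on beat count set by the RR floor
    n_max = int(dur * 1000.0 / RR_FLOOR_MS) + 16
    if params.noise_sd_ms > 0:
        noise = rng.normal(0.0, params.noise_sd_ms, size=n_max)
    else:
        noise = np.zeros(n_max)
    sin = math.sin
    times = np.empty(n_max)
    rrs = np.empty(n_max)
    t = 0.0
    k = 0
    switch = slow_gain_after_s
    while t < dur:
        g = slow_gain if (switch is not None and t >= switch) else 1.0
        rr = mean + noise[k]
        if va:
            rr += g * va * sin(wv * t)
        if la:
            rr += g * la * sin(wl * t)
        if ha:
            rr += ha * sin(wh * t)
        if rr < RR_FLOOR_MS:
            rr = RR_FLOOR_MS
        t += rr / 1000.0
        times[k] = t
        rrs[k] = rr
        k += 1
    return RRSeries(times[:k].copy(), rrs[:k].copy())


def generate_rr_series(params: RRGenParams) -> RRSeries:
    """Generate a seeded RR tachogram from the sinusoidal model.

    The first beat sits at t = 0 and is not listed; the series continues
    until the beat clock reaches ``duration_s``, so it always spans at least
    that long.  Identical parameters (including seed) give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    return _rr_loop(params, rng)


# ---------------------------------------------------------------------------
# ECG synthesis

# PQRST template geometry (seconds / fractions of the R amplitude); the QRS
# complex is a biphasic wavelet of ~100 ms support, P and T are broad
# low-amplitude deflections that exercise the detector's T-wave rejection.
_QRS_R_SIGMA_S = 0.010
_QRS_Q = (-0.024, -0.10, 0.008)  # (offset_s, relative amp, sigma_s)
_QRS_S = (0.032, -0.30, 0.014)
_P_WAVE = (-0.160, 0.12, 0.022)
_T_WAVE = (0.240, 0.24, 0.045)
_BASELINE_WANDER_HZ = 0.22


def _pqrst_template(fs_hz: float, include_pt: bool) -> tuple[np.ndarray, int]:
    """Sampled template and the index of its R peak; peak value is 1.0."""
    span = (0.30, 0.40) if include_pt else (0.08, 0.08)
    t = np.arange(-round(span[0] * fs_hz), round(span[1] * fs_hz) + 1) / fs_hz
    y = np.exp(-0.5 * (t / _QRS_R_SIGMA_S) ** 2)
    waves = [_QRS_Q, _QRS_S] + ([_P_WAVE, _T_WAVE] if include_pt else [])
    for off, amp, sig in waves:
        y += amp * np.exp(-0.5 * ((t - off) / sig) ** 2)
    y /= np.max(y)  # R peak exactly 1.0 despite overlapping lobes
    return y, int(np.argmax(y))


def generate_ecg(
    rr: RRSeries,
    fs_hz: float = 1000.0,
    qrs_amp_mv: float = 1.0,
    noise_sd_mv: float = 0.0,
    baseline_wander_amp_mv: float = 0.0,
    seed: int = 0,
    include_pt_waves: bool = True,
    subject: SubjectInfo | None = None,
) -> ECGRecord:
    """Render an RR series as a single-lead ECG with known R-peak times.

    A fixed PQRST-like template is centred at every beat time; optional
    Gaussian noise and a slow (< 0.5 Hz) sinusoidal baseline wander are
    added.  With zero noise the global maximum near each beat time is that
    beat's R peak, so the beat times are exact detection ground truth.
    """
    if fs_hz < 250:
        raise ValueError("fs_hz must be at least 250 Hz for QRS synthesis")
    if rr.n_intervals == 0:
        raise ValueError("rr must contain at least one interval")
    rng = np.random.default_rng(seed)
    # reconstruct the full beat list including the opening beat
    beats = np.concatenate(([rr.beat_time_s[0] - rr.rr_ms[0] / 1000.0], rr.beat_time_s))
    t0 = beats[0]
    # flat lead-in/lead-out so edge beats render completely and filter
    # transients never overlap a QRS complex
    pad_s = 0.5
    beats = beats - t0 + pad_s
    tmpl, r_idx = _pqrst_template(fs_hz, include_pt_waves)
    n = int(math.ceil((beats[-1] + pad_s) * fs_hz)) + tmpl.size
    x = np.zeros(n)
    for bt in beats:
        c = int(round(bt * fs_hz))
        lo = c - r_idx
        hi = lo + tmpl.size
        a = max(lo, 0)
        b = min(hi, n)
        x[a:b] += tmpl[a - lo : b - lo]
    x *= qrs_amp_mv
    if baseline_wander_amp_mv > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        tt = np.arange(n) / fs_hz
        x += baseline_wander_amp_mv * np.sin(2 * math.pi * _BASELINE_WANDER_HZ * tt + phase)
    if noise_sd_mv > 0:
        x += rng.normal(0.0, noise_sd_mv, size=n)
    return ECGRecord(x, fs_hz, start_time_s=t0 - pad_s, subject=subject)


# ---------------------------------------------------------------------------
# Ectopic injection


def inject_ectopic_beats(
    rr: RRSeries,
    rate: float,
    displacement_frac: float = 0.4,
    seed: int = 0,
) -> tuple[RRSeries, list[int]]:
    """Displace isolated beats early, creating premature-beat couplets.

    A selected beat k is moved earlier by ``displacement_frac`` of the local
    interval: RR_k shrinks by that fraction and RR_{k+1} grows by the same
    absolute amount (compensatory pause), so total duration is preserved
    exactly.  Selections keep at least two untouched intervals between
    couplets, so ectopics are always isolated.  Returns the modified series
    and the selected interval indices.
    """
    if not 0.0 <= rate < 0.1:
        raise ValueError("rate must lie in [0, 0.1): higher rates cannot stay isolated")
    if not 0.0 < displacement_frac < 0.9:
        raise ValueError("displacement_frac must lie in (0, 0.9)")
    n = rr.n_intervals
    if rate == 0.0 or n < 5:
        return RRSeries(rr.beat_time_s.copy(), rr.rr_ms.copy()), []
    rng = np.random.default_rng(seed)
    draws = rng.random(n)
    chosen: list[int] = []
    # k indexes the shortened interval; k+1 takes the compensatory pause
    for k in range(1, n - 2):
        if draws[k] < rate and (not chosen or k - chosen[-1] >= 3):
            chosen.append(k)
    times = rr.beat_time_s.copy()
    rrs = rr.rr_ms.copy()
    for k in chosen:
        shift_ms = displacement_frac * rrs[k]
        rrs[k] -= shift_ms
        rrs[k + 1] += shift_ms
        times[k] -= shift_ms / 1000.0
    return RRSeries(times, rrs), chosen


# ---------------------------------------------------------------------------
# Cohort generation

#: default young-adult baseline: higher variability in every band
YOUNG_BASELINE = RRGenParams(
    duration_s=3300.0,
    mean_rr_ms=800.0,
    vlf_amp_ms=35.0,
    lf_amp_ms=30.0,
    hf_amp_ms=25.0,
    noise_sd_ms=10.0,
)

#: default senior baseline: lower overall variability, slower rate
SENIOR_BASELINE = RRGenParams(
    duration_s=3300.0,
    mean_rr_ms=900.0,
    vlf_amp_ms=18.0,
    lf_amp_ms=14.0,
    hf_amp_ms=10.0,
    noise_sd_ms=6.0,
)

_REQUIRED_PHASES = (
    ["baseline_1", "baseline_2"]
    + [f"occlusion_{k}" for k in range(1, 5)]
    + [f"non_occlusion_{k}" for k in range(1, 5)]
    + ["post_rest"]
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic RIC cohort.

    ``post_effect_multiplier`` scales the slow-band (VLF+LF) amplitudes in
    every phase after the last occlusion, emulating the reported post-RIC
    rise in long-term variability (SD2); 1.0 gives an exchangeable null
    cohort.
    """

    n_young: int
    n_senior: int
    timeline: ProtocolTimeline
    young_params: RRGenParams = YOUNG_BASELINE
    senior_params: RRGenParams = SENIOR_BASELINE
    post_effect_multiplier: float = 1.5
    ectopic_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_young < 0 or self.n_senior < 0 or self.n_young + self.n_senior < 2:
            raise ValueError("cohort needs n_young + n_senior >= 2")
        if self.post_effect_multiplier <= 0:
            raise ValueError("post_effect_multiplier must be positive")
        if not 0.0 <= self.ectopic_rate < 0.1:
            raise ValueError("ectopic_rate must lie in [0, 0.1)")
        missing = [p for p in _REQUIRED_PHASES if p not in self.timeline.labels]
        if missing:
            raise ValueError(f"timeline missing required phases: {missing}")


@dataclass
class SubjectRecord:
    """One synthetic subject: metadata plus the continuous tachogram."""

    subject: SubjectInfo
    rr: RRSeries
    ectopic_indices: list[int] = field(default_factory=list)


def generate_ric_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a full synthetic RIC cohort, one continuous record each.

    Per-subject randomness is derived from ``(spec.seed, subject index)``
    via a counter-based seed sequence, so adding subjects never perturbs
    existing ones.  Young ages are drawn in [20, 60), senior in (60, 86);
    senior subjects use the lower-variability baseline parameters.
    """
    spec.validate()
    last_occ_end = spec.timeline.phase("occlusion_4").end_s
    duration = spec.timeline.end_s
    records: list[SubjectRecord] = []
    for i in range(spec.n_young + spec.n_senior):
        is_senior = i >= spec.n_young
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        age = int(rng.integers(61, 86)) if is_senior else int(rng.integers(20, 60))
        sex = "F" if rng.random() < 0.5 else "M"
        base = spec.senior_params if is_senior else spec.young_params
        base.validate()
        rr = _rr_loop(
            replace(base, duration_s=duration),
            rng,
            slow_gain_after_s=last_occ_end,
            slow_gain=spec.post_effect_multiplier,
        )
        ectopics: list[int] = []
        if spec.ectopic_rate > 0:
            rr, ectopics = inject_ectopic_beats(
                rr, spec.ectopic_rate, seed=int(rng.integers(0, 2**31 - 1))
            )
        info = SubjectInfo(
            subject_id=f"S{i + 1:02d}",
            age=age,
            sex=sex,
            subset="senior" if is_senior else "young",
        )
        records.append(SubjectRecord(info, rr, ectopics))
    return records
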