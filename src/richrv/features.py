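"""HRV feature extraction: time domain, frequency domain, Poincaré.

Time domain
    mean/median/SD of RR, successive-difference statistics (SDSD, rMSSD,
    NN50, pNN50).  All standard deviations use the population (divide-by-N)
    convention so the Poincaré identity below holds exactly and a constant
    series scores 0 on every variability index.  pNN50's denominator is the
    number of RR intervals (a ``denominator="diffs"`` switch restores the
    N-1 convention used elsewhere in the literature).

Frequency domain
    The tachogram is cleaned of isolated ectopic beats (linear
    interpolation), resampled at 10 Hz with a cubic spline, mean-subtracted,
    and fed to Welch's method with a 256-sample Hann window at 50% overlap.
    Band powers (VLF < 0.04, LF 0.04-0.15, HF 0.15-0.4 Hz) come from
    trapezoidal integration of the density; normalized powers divide by
    (total - VLF) so nuLF + nuHF = 100.

Poincaré (non-linear)
    SD1^2 = Var(RR_n - RR_{n+1}) / 2 = SDSD^2 / 2 and
    SD2^2 = 2 SDRR^2 - SDSD^2 / 2 (Brennan's ellipse-fit identities).
    SD1^2 + SD2^2 = 2 SDRR^2 follows algebraically and is enforced by test.
    A negative SD2^2 (possible on short alternating series) is clamped to 0
    with a ``sd2_clamped`` QC flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter
from scipy.signal import welch as _welch

from .segmentation import segment_rr
from .types import FEATURE_COLUMNS, HRVFeatures, ProtocolTimeline, RRSeries, Segment

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "time_domain",
    "correct_ectopics",
    "resample_tachogram",
    "welch_psd",
    "band_powers",
    "poincare",
    "PoincareResult",
    "compute_all",
    "cohort_feature_table",
    "WELCH_NPERSEG",
]

WELCH_NPERSEG = 256
TACHOGRAM_FS_HZ = 10.0
NN_THRESHOLD_MS = 50.0
ECTOPIC_WINDOW = 11  # centred running-median window, in intervals
ECTOPIC_REL_THRESHOLD = 0.30
ECTOPIC_LOAD_LIMIT = 0.05


@dataclass(frozen=True)
class BandDefinition:
    """Half-open spectral bands [low, high) in Hz; total = VLF + LF + HF."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        for name in ("vlf", "lf", "hf"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo < hi:
                raise ValueError(f"band {name} must satisfy 0 <= low < high")
        if self.vlf[1] != self.lf[0] or self.lf[1] != self.hf[0]:
            raise ValueError("bands must be contiguous: vlf|lf|hf")


DEFAULT_BANDS = BandDefinition()


def _pop_std(x: np.ndarray) -> float:
    return float(np.std(x))  # numpy default ddof=0 = population convention


# ---------------------------------------------------------------------------
# Time domain


def time_domain(rr: RRSeries, denominator: str = "intervals") -> dict[str, float]:
    """Time-domain statistics of one segment.

    ``denominator`` selects the pNN50 divisor: ``"intervals"`` (number of RR
    intervals) or ``"diffs"`` (number of successive differences, N-1).
    """
    if rr.n_intervals < 3:
        raise ValueError("time_domain needs at least 3 intervals")
    if denominator not in ("intervals", "diffs"):
        raise ValueError("denominator must be 'intervals' or 'diffs'")
    x = rr.rr_ms
    d = np.diff(x)
    nn50 = int(np.sum(np.abs(d) > NN_THRESHOLD_MS))
    denom = x.size if denominator == "intervals" else d.size
    return {
        "mean_rr_ms": float(np.mean(x)),
        "median_rr_ms": float(np.median(x)),
        "sdrr_ms": _pop_std(x),
        "sdsd_ms": _pop_std(d),
        "rmssd_ms": float(np.sqrt(np.mean(d**2))),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / denom,
    }


# ---------------------------------------------------------------------------
# Ectopic correction (frequency-domain path only)


def correct_ectopics(rr: RRSeries) -> tuple[RRSeries, list[int], set[str]]:
    """Detect and linearly interpolate isolated ectopic beats.

    An interval is *deviant* when it differs from the median of its
    11-interval centred window by more than 30%.  Two patterns are
    corrected:

    * an isolated deviant interval (both neighbours clean) is replaced by
      the mean of its neighbours;
    * a premature-beat couplet — a deviant short interval followed by a
      deviant long one, clean on both sides — is re-interpolated across
      both intervals (the signature left by an early beat with a
      compensatory pause).

    Same-sign adjacent deviations and runs of three or more are left
    untouched with an ``unresolved_ectopic_run`` QC flag; a deviant
    fraction above 5% adds ``high_ectopic_load``.  Returns the corrected
    series, the corrected interval indices, and the QC flags.
    """
    if rr.n_intervals < 5:
        raise ValueError("correct_ectopics needs at least 5 intervals")
    x = rr.rr_ms.copy()
    med = median_filter(rr.rr_ms, size=ECTOPIC_WINDOW, mode="nearest")
    dev = (rr.rr_ms - med) / med
    flagged = np.abs(dev) > ECTOPIC_REL_THRESHOLD
    qc: set[str] = set()
    if np.mean(flagged) > ECTOPIC_LOAD_LIMIT:
        qc.add("high_ectopic_load")
    corrected: list[int] = []
    n = x.size
    k = 0
    while k < n:
        if not flagged[k]:
            k += 1
            continue
        run_end = k
        while run_end + 1 < n and flagged[run_end + 1]:
            run_end += 1
        run_len = run_end - k + 1
        left_ok = k - 1 >= 0 and not flagged[k - 1]
        right_ok = run_end + 1 < n and not flagged[run_end + 1]
        if run_len == 1 and left_ok and right_ok:
            x[k] = 0.5 * (x[k - 1] + x[k + 1])
            corrected.append(k)
        elif (
            run_len == 2
            and left_ok
            and right_ok
            and dev[k] < 0 < dev[k + 1]  # short then compensatory long
        ):
            lo, hi = x[k - 1], x[k + 2]
            x[k] = lo + (hi - lo) / 3.0
            x[k + 1] = lo + 2.0 * (hi - lo) / 3.0
            corrected.extend([k, k + 1])
        else:
            qc.add("unresolved_ectopic_run")
        k = run_end + 1
    return RRSeries(rr.beat_time_s.copy(), x, check_consistency=False), corrected, qc


# ---------------------------------------------------------------------------
# Spectral pipeline


def resample_tachogram(
    rr: RRSeries, fs_hz: float = TACHOGRAM_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample of the tachogram onto a uniform grid.

    The spline interpolates the (beat time, RR) knots and is evaluated on a
    1/fs grid from the first to the last knot (no extrapolation); the mean
    is subtracted.  Returns (time grid, zero-mean tachogram in ms).
    """
    if rr.n_intervals < 4:
        raise ValueError("resample_tachogram needs at least 4 intervals (spline knots)")
    t0, t1 = rr.beat_time_s[0], rr.beat_time_s[-1]
    spline = CubicSpline(rr.beat_time_s, rr.rr_ms)
    grid = t0 + np.arange(int(np.floor((t1 - t0) * fs_hz)) + 1) / fs_hz
    x = spline(grid)
    return grid, x - np.mean(x)


def welch_psd(
    tachogram: np.ndarray, fs_hz: float = TACHOGRAM_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch density of the resampled tachogram (ms^2/Hz).

    256-sample Hann windows, 50% overlap, per-window mean removal; the
    integral of the density over frequency approximates the signal variance
    (Parseval).
    """
    x = np.asarray(tachogram, dtype=float)
    if x.size < WELCH_NPERSEG:
        raise ValueError(
            f"tachogram too short: need at least {WELCH_NPERSEG} samples "
            f"({WELCH_NPERSEG / fs_hz:.1f} s at {fs_hz} Hz), got {x.size}"
        )
    f, pxx = _welch(
        x,
        fs=fs_hz,
        window="hann",
        nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NPERSEG // 2,
        detrend="constant",
        scaling="density",
    )
    return f, pxx


def _band_integral(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [low, high).

    The density is treated as piecewise linear between grid points and
    integrated over the exact band limits (values at the band edges are
    interpolated), so contiguous bands tile the spectrum without losing the
    half-bins at their boundaries — essential here because the Welch grid
    (10/256 Hz) puts only a few points inside the LF band.
    """
    lo = max(band[0], float(f[0]))
    hi = min(band[1], float(f[-1]))
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fs_band = np.concatenate(([lo], f[inner], [hi]))
    ps_band = np.concatenate(([np.interp(lo, f, pxx)], pxx[inner], [np.interp(hi, f, pxx)]))
    return float(np.trapezoid(ps_band, fs_band))


def band_powers(
    f: np.ndarray,
    pxx: np.ndarray,
    bands: BandDefinition = DEFAULT_BANDS,
) -> tuple[dict[str, float], set[str]]:
    """Absolute and normalized band powers from a PSD.

    nuLF = 100 * LF / (total - VLF) and likewise nuHF, with
    total = VLF + LF + HF, so the two normalized powers sum to 100.
    Degenerate spectra (total - VLF <= 0, or HF = 0 for the ratio) yield
    NaN with a QC flag instead of raising.
    """
    if f[-1] < bands.hf[1] - 1e-9:
        raise ValueError(f"PSD must cover the HF band up to {bands.hf[1]} Hz")
    vlf = _band_integral(f, pxx, bands.vlf)
    lf = _band_integral(f, pxx, bands.lf)
    hf = _band_integral(f, pxx, bands.hf)
    out = {"vlf_power": vlf, "lf_power": lf, "hf_power": hf}
    qc: set[str] = set()
    denom = lf + hf  # total - VLF with total = vlf+lf+hf
    if denom <= 0:
        out.update(nu_lf=float("nan"), nu_hf=float("nan"), lf_hf=float("nan"))
        qc.add("zero_normalizable_power")
        return out, qc
    out["nu_lf"] = 100.0 * lf / denom
    out["nu_hf"] = 100.0 * hf / denom
    if hf <= 0:
        out["lf_hf"] = float("nan")
        qc.add("zero_hf_power")
    else:
        out["lf_hf"] = lf / hf
    return out, qc


# ---------------------------------------------------------------------------
# Poincaré descriptors


@dataclass(frozen=True)
class PoincareResult:
    sd1_ms: float
    sd2_ms: float
    sd1_sd2: float
    sd2_sq_raw_ms2: float  # before clamping, can be negative
    qc_flags: frozenset[str]


def poincare(rr: RRSeries) -> PoincareResult:
    """SD1/SD2 of the Poincaré plot via Brennan's variance identities.

    Population variance throughout.  SD2^2 is clamped at zero (QC flag
    ``sd2_clamped``) when the raw identity goes negative; the ratio is NaN
    when SD2 = 0.
    """
    if rr.n_intervals < 3:
        raise ValueError("poincare needs at least 3 intervals")
    x = rr.rr_ms
    sdsd_sq = float(np.var(np.diff(x)))
    sdrr_sq = float(np.var(x))
    sd1 = float(np.sqrt(0.5 * sdsd_sq))
    sd2_sq = 2.0 * sdrr_sq - 0.5 * sdsd_sq
    qc: set[str] = set()
    if sd2_sq < 0:
        qc.add("sd2_clamped")
        sd2 = 0.0
    else:
        sd2 = float(np.sqrt(sd2_sq))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    if sd2 == 0.0 and "sd2_clamped" not in qc and sd1 > 0:
        qc.add("zero_sd2")
    return PoincareResult(sd1, sd2, ratio, sd2_sq, frozenset(qc))


# ---------------------------------------------------------------------------
# Full per-segment feature row


def compute_all(
    segment: Segment,
    bands: BandDefinition = DEFAULT_BANDS,
    pnn50_denominator: str = "intervals",
    domains: tuple[str, ...] = ("time", "frequency", "poincare"),
) -> HRVFeatures:
    """All HRV features of one segment.

    Time-domain and Poincaré features are computed on the raw RR slice; the
    frequency domain runs ectopic correction -> spline resampling -> Welch
    -> band powers.  Stage errors are re-raised with the segment label;
    degenerate spectra become NaN + QC flags.
    """
    feats = HRVFeatures()
    feats.qc_flags |= segment.qc_flags
    try:
        if "time" in domains:
            for k, v in time_domain(segment.rr, pnn50_denominator).items():
                setattr(feats, k, v)
        if "poincare" in domains:
            p = poincare(segment.rr)
            feats.sd1_ms, feats.sd2_ms, feats.sd1_sd2 = p.sd1_ms, p.sd2_ms, p.sd1_sd2
            feats.qc_flags |= p.qc_flags
        if "frequency" in domains:
            clean, _, qc = correct_ectopics(segment.rr)
            feats.qc_flags |= qc
            _, tach = resample_tachogram(clean)
            f, pxx = welch_psd(tach)
            powers, qc = band_powers(f, pxx, bands)
            feats.qc_flags |= qc
            for k, v in powers.items():
                setattr(feats, k, v)
    except ValueError as exc:
        raise ValueError(f"segment {segment.label!r}: {exc}") from exc
    return feats


def cohort_feature_table(
    records,
    timeline: ProtocolTimeline,
    bands: BandDefinition = DEFAULT_BANDS,
    min_beats: int = 100,
    pnn50_denominator: str = "intervals",
    domains: tuple[str, ...] = ("time", "frequency", "poincare"),
    phases: list[str] | None = None,
) -> pd.DataFrame:
    """One feature row per (subject, phase) for a cohort of records.

    ``records`` is an iterable of objects with ``subject`` (SubjectInfo) and
    ``rr`` (RRSeries) attributes, e.g. the output of
    :func:`richrv.synthetic.generate_ric_cohort`.  ``phases`` restricts the
    table to a subset of phase labels (all by default).
    """
    rows = []
    keep = set(phases) if phases is not None else None
    for rec in records:
        for seg in segment_rr(rec.rr, timeline, min_beats=min_beats):
            if keep is not None and seg.label not in keep:
                continue
            feats = compute_all(seg, bands, pnn50_denominator, domains)
            row: dict = {
                "subject_id": rec.subject.subject_id,
                "age": rec.subject.age,
                "subset": rec.subject.subset,
                "phase": seg.label,
            }
            row.update(feats.as_dict())
            rows.append(row)
    cols = ["subject_id", "age", "subset", "phase", *FEATURE_COLUMNS, "qc_flags"]
    return pd.DataFrame(rows, columns=cols)
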