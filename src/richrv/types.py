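"""Core data containers shared across the pipeline.

Everything downstream of the recording hardware is expressed in three
containers: the raw single-lead ECG (:class:`ECGRecord`), the detected beat
series (:class:`RPeakSeries`) and the tachogram of R-R intervals
(:class:`RRSeries`).  The remote-ischemic-conditioning protocol itself is a
:class:`ProtocolTimeline` of labelled 5-minute phases, and each analysis
window is a :class:`Segment` carrying its slice of the tachogram plus QC
flags.  Statistical outputs travel as :class:`TestResult` /
:class:`CorrelationResult` rows.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field

import numpy as np

__all__ = [
    "SubjectInfo",
    "ECGRecord",
    "RPeakSeries",
    "RRSeries",
    "Phase",
    "ProtocolTimeline",
    "Segment",
    "HRVFeatures",
    "TestResult",
    "CorrelationResult",
]


@dataclass(frozen=True)
class SubjectInfo:
    """Identity and demographics of one recorded subject."""

    subject_id: str
    age: float | None = None
    sex: str | None = None
    subset: str | None = None  # "young" / "senior"


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG.

    Amplitudes are in millivolt, sampling in Hz.  At least two seconds of
    signal are required before R-peak detection makes sense.
    """

    samples_mv: np.ndarray
    fs_hz: float
    start_time_s: float = 0.0
    subject: SubjectInfo | None = None

    def __post_init__(self) -> None:
        self.samples_mv = np.asarray(self.samples_mv, dtype=float)
        if self.samples_mv.ndim != 1:
            raise ValueError("samples_mv must be one-dimensional")
        if not np.all(np.isfinite(self.samples_mv)):
            raise ValueError("samples_mv contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples_mv.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs_hz


@dataclass
class RPeakSeries:
    """Sample indices of detected R peaks, strictly increasing."""

    peak_indices: np.ndarray
    fs_hz: float
    start_time_s: float = 0.0
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.peak_indices.ndim != 1:
            raise ValueError("peak_indices must be one-dimensional")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak_indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size

    def times_s(self) -> np.ndarray:
        return self.start_time_s + self.peak_indices / self.fs_hz


@dataclass
class RRSeries:
    """R-R interval tachogram.

    ``rr_ms[k]`` is the interval *ending* at ``beat_time_s[k]``; the beat
    opening the first interval is not listed.  Consecutive entries must be
    self-consistent: ``beat_time_s[k] - beat_time_s[k-1]`` equals
    ``rr_ms[k] / 1000`` to within 1 ms.  Derived series whose values were
    edited in place (e.g. ectopic-corrected tachograms, where the knot
    times intentionally keep their measured positions) may pass
    ``check_consistency=False``.
    """

    beat_time_s: np.ndarray
    rr_ms: np.ndarray
    check_consistency: InitVar[bool] = True

    def __post_init__(self, check_consistency: bool = True) -> None:
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_time_s.shape != self.rr_ms.shape or self.beat_time_s.ndim != 1:
            raise ValueError("beat_time_s and rr_ms must be 1-d arrays of equal length")
        if self.rr_ms.size:
            if np.any(self.rr_ms <= 0):
                raise ValueError("rr_ms must be strictly positive")
            dt_ms = np.diff(self.beat_time_s) * 1000.0
            if dt_ms.size and np.any(dt_ms <= 0):
                raise ValueError("beat_time_s must be strictly increasing")
            if (
                check_consistency
                and dt_ms.size
                and np.max(np.abs(dt_ms - self.rr_ms[1:])) > 1.0
            ):
                raise ValueError("rr_ms inconsistent with beat_time_s (>1 ms mismatch)")

    @property
    def n_intervals(self) -> int:
        return self.rr_ms.size

    def slice_window(self, start_s: float, end_s: float) -> "RRSeries":
        """Intervals whose terminating beat lies in the half-open [start, end)."""
        mask = (self.beat_time_s >= start_s) & (self.beat_time_s < end_s)
        return RRSeries(self.beat_time_s[mask], self.rr_ms[mask])


@dataclass(frozen=True)
class Phase:
    """One protocol phase: half-open window [start_s, end_s)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"phase {self.label!r}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ProtocolTimeline:
    """Ordered, contiguous, non-overlapping protocol phases."""

    phases: list[Phase]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError("phase labels must be unique")
        for prev, cur in zip(self.phases, self.phases[1:]):
            if abs(cur.start_s - prev.end_s) > 1e-9:
                raise ValueError(
                    f"phases must be contiguous: {prev.label!r} ends at "
                    f"{prev.end_s}, {cur.label!r} starts at {cur.start_s}"
                )

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.phases]

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(f"no phase labelled {label!r}")


@dataclass
class Segment:
    """A labelled slice of the tachogram (one 5-min analysis window)."""

    label: str
    rr: RRSeries
    qc_flags: set[str] = field(default_factory=set)

    @property
    def n_beats(self) -> int:
        return self.rr.n_intervals


#: canonical feature column order for tables
FEATURE_COLUMNS = [
    "mean_rr_ms",
    "median_rr_ms",
    "sdrr_ms",
    "sdsd_ms",
    "rmssd_ms",
    "nn50",
    "pnn50",
    "vlf_power",
    "lf_power",
    "hf_power",
    "nu_lf",
    "nu_hf",
    "lf_hf",
    "sd1_ms",
    "sd2_ms",
    "sd1_sd2",
]


@dataclass
class HRVFeatures:
    """One segment's HRV features across the three domains.

    Missing values (e.g. normalized powers of a zero-variance segment) are
    NaN with an explanatory entry in ``qc_flags``.
    """

    mean_rr_ms: float = float("nan")
    median_rr_ms: float = float("nan")
    sdrr_ms: float = float("nan")
    sdsd_ms: float = float("nan")
    rmssd_ms: float = float("nan")
    nn50: float = float("nan")
    pnn50: float = float("nan")
    vlf_power: float = float("nan")
    lf_power: float = float("nan")
    hf_power: float = float("nan")
    nu_lf: float = float("nan")
    nu_hf: float = float("nan")
    lf_hf: float = float("nan")
    sd1_ms: float = float("nan")
    sd2_ms: float = float("nan")
    sd1_sd2: float = float("nan")
    qc_flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {c: getattr(self, c) for c in FEATURE_COLUMNS}
        d["qc_flags"] = ";".join(sorted(self.qc_flags))
        return d


@dataclass(frozen=True)
class TestResult:
    """One paired Wilcoxon signed-rank comparison for one feature."""

    feature: str
    comparison: str
    subset: str
    n_pairs: int
    statistic: float
    p_value: float
    direction: int  # sign of the median paired difference
    significant: bool
    alpha: float = 0.05
    note: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    """Rank correlation between per-subject changes of two features."""

    feature_a: str
    feature_b: str
    n: int
    rho: float
    p_value: float
    method: str = "spearman"
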