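"""Protocol timelines and 5-min RR segmentation.

The RIC protocol is 10 min of resting baseline, four cycles of 5-min cuff
occlusion / 5-min reperfusion, and a final 5-min rest: 11 phases, 55 min.
HRV features are conventionally computed on 5-min windows, so the 10-min
baseline is represented as two 5-min segments (``baseline_1``/``baseline_2``)
and the post-procedure window as ``non_occlusion_4`` + ``post_rest``.

An interval belongs to the phase whose half-open window [start, end)
contains its *terminating* beat time; this rule is deterministic and assigns
no interval twice.
"""

from __future__ import annotations

from .types import Phase, ProtocolTimeline, RPeakSeries, RRSeries, Segment

__all__ = ["build_timeline", "rr_from_peaks", "segment_rr", "DEFAULT_MIN_BEATS"]

#: 5-min segments with fewer beats than this (~33 bpm) are flagged, not dropped
DEFAULT_MIN_BEATS = 100


def build_timeline(
    baseline_min: float = 10.0,
    n_cycles: int = 4,
    phase_min: float = 5.0,
    post_min: float = 5.0,
) -> ProtocolTimeline:
    """Construct the RIC phase timeline.

    Defaults give the standard protocol: ``baseline_1`` [0, 300),
    ``baseline_2`` [300, 600), then ``occlusion_k`` / ``non_occlusion_k``
    alternating for k = 1..n_cycles, and ``post_rest`` ending at 3300 s.
    The baseline is split into ``phase_min`` sub-segments, so
    ``baseline_min`` must be an integer multiple of ``phase_min``.
    """
    if baseline_min <= 0 or phase_min <= 0 or post_min <= 0:
        raise ValueError("all durations must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    n_base = baseline_min / phase_min
    if abs(n_base - round(n_base)) > 1e-9:
        raise ValueError("baseline_min must be a multiple of phase_min")
    n_base = int(round(n_base))
    phases: list[Phase] = []
    t = 0.0
    for k in range(1, n_base + 1):
        phases.append(Phase(f"baseline_{k}", t, t + phase_min * 60.0))
        t += phase_min * 60.0
    for k in range(1, n_cycles + 1):
        phases.append(Phase(f"occlusion_{k}", t, t + phase_min * 60.0))
        t += phase_min * 60.0
        phases.append(Phase(f"non_occlusion_{k}", t, t + phase_min * 60.0))
        t += phase_min * 60.0
    phases.append(Phase("post_rest", t, t + post_min * 60.0))
    return ProtocolTimeline(phases)


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """Differences of consecutive R-peak times, assigned to the later beat."""
    if peaks.n_peaks < 2:
        raise ValueError("need at least 2 peaks to form an RR interval")
    t = peaks.times_s()
    return RRSeries(t[1:], (t[1:] - t[:-1]) * 1000.0)


def segment_rr(
    rr: RRSeries,
    timeline: ProtocolTimeline,
    min_beats: int = DEFAULT_MIN_BEATS,
) -> list[Segment]:
    """Split a tachogram into one labelled segment per protocol phase.

    Intervals are assigned by terminating beat time to the half-open phase
    window; a beat exactly on a boundary belongs to the later phase.
    Segments with fewer than ``min_beats`` intervals get the
    ``low_beat_count`` QC flag but are never silently dropped.
    """
    if rr.n_intervals == 0:
        raise ValueError("rr series is empty")
    segments: list[Segment] = []
    for phase in timeline.phases:
        piece = rr.slice_window(phase.start_s, phase.end_s)
        flags: set[str] = set()
        if piece.n_intervals < min_beats:
            flags.add("low_beat_count")
        segments.append(Segment(phase.label, piece, flags))
    return segments
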