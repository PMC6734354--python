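"""Plain-text file dialects for every pipeline artifact.

Everything is tab-separated text with a single header line, plus YAML for
structured metadata (timelines, cohort manifests, pipeline configs).  The
dialects are deliberately trivial so fixtures are diffable and the whole
pipeline runs offline:

* ECG: columns ``time_s`` ``ecg_mv``; sampling rate and subject metadata in
  a ``<name>.meta.yaml`` sidecar.
* RR: columns ``beat_time_s`` ``rr_ms``.
* Timeline: YAML list of ``{label, start_s, end_s}``.
* Cohort manifest: YAML with one entry per subject (id, age, sex, subset,
  file path).

Readers validate as they parse and report the offending line number.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ECGRecord, Phase, ProtocolTimeline, RRSeries, SubjectInfo

__all__ = [
    "read_ecg",
    "write_ecg",
    "read_rr",
    "write_rr",
    "read_timeline",
    "write_timeline",
    "read_manifest",
    "write_manifest",
    "write_features",
    "read_features",
    "write_results",
]

_FLOAT_FMT = "%.6f"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.yaml")


def _parse_two_columns(path: Path, names: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: no records")
    header = lines[0].split("\t")
    if [h.strip() for h in header] != list(names):
        raise ValueError(
            f"{path}: expected header {names[0]}\\t{names[1]}, got {lines[0]!r}"
        )
    a = np.empty(len(lines) - 1)
    b = np.empty(len(lines) - 1)
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            a[i - 2] = float(parts[0])
            b[i - 2] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
    if a.size == 0:
        raise ValueError(f"{path}: no records")
    return a, b


def _write_two_columns(path: Path, names: tuple[str, str], a: np.ndarray, b: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f"{names[0]}\t{names[1]}\n")
        for x, y in zip(a, b):
            fh.write(f"{_FLOAT_FMT % x}\t{_FLOAT_FMT % y}\n")


# ---------------------------------------------------------------------------
# ECG


def write_ecg(record: ECGRecord, path: str | os.PathLike) -> None:
    path = Path(path)
    _write_two_columns(path, ("time_s", "ecg_mv"), record.time_s(), record.samples_mv)
    meta: dict = {"fs_hz": float(record.fs_hz), "start_time_s": float(record.start_time_s)}
    if record.subject is not None:
        s = record.subject
        meta.update(subject_id=s.subject_id, age=s.age, sex=s.sex, subset=s.subset)
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_ecg(path: str | os.PathLike) -> ECGRecord:
    path = Path(path)
    t, x = _parse_two_columns(path, ("time_s", "ecg_mv"))
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise ValueError(f"{path}: missing sidecar header {meta_file.name}")
    meta = yaml.safe_load(meta_file.read_text())
    subject = None
    if "subject_id" in meta:
        subject = SubjectInfo(
            subject_id=str(meta["subject_id"]),
            age=meta.get("age"),
            sex=meta.get("sex"),
            subset=meta.get("subset"),
        )
    return ECGRecord(
        x,
        fs_hz=float(meta["fs_hz"]),
        start_time_s=float(meta.get("start_time_s", t[0] if t.size else 0.0)),
        subject=subject,
    )


# ---------------------------------------------------------------------------
# RR


def write_rr(rr: RRSeries, path: str | os.PathLike) -> None:
    _write_two_columns(Path(path), ("beat_time_s", "rr_ms"), rr.beat_time_s, rr.rr_ms)


def read_rr(path: str | os.PathLike) -> RRSeries:
    path = Path(path)
    t, rr = _parse_two_columns(path, ("beat_time_s", "rr_ms"))
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3  # +2 header/1-base, +1 second row
        raise ValueError(f"{path}:{bad}: beat times not strictly increasing")
    # file precision is 1 us on times but RR is stored independently; accept
    # the written rounding
    return RRSeries(t, rr, check_consistency=False)


# ---------------------------------------------------------------------------
# Timeline


def write_timeline(timeline: ProtocolTimeline, path: str | os.PathLike) -> None:
    data = [
        {"label": p.label, "start_s": float(p.start_s), "end_s": float(p.end_s)}
        for p in timeline.phases
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_timeline(path: str | os.PathLike) -> ProtocolTimeline:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: expected a non-empty list of phases")
    phases = [Phase(str(d["label"]), float(d["start_s"]), float(d["end_s"])) for d in data]
    return ProtocolTimeline(phases)


# ---------------------------------------------------------------------------
# Cohort manifest


def write_manifest(entries: list[dict], path: str | os.PathLike) -> None:
    """Entries: dicts with subject_id/age/sex/subset and rr_path or ecg_path."""
    Path(path).write_text(yaml.safe_dump({"subjects": entries}, sort_keys=False))


def read_manifest(path: str | os.PathLike) -> list[dict]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "subjects" not in data or not data["subjects"]:
        raise ValueError(f"{path}: expected a mapping with a non-empty 'subjects' list")
    return list(data["subjects"])


# ---------------------------------------------------------------------------
# Feature and result tables


def write_features(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_features(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise ValueError(f"{path}: no records")
    required = {"subject_id", "phase"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required)}")
    return table


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")
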