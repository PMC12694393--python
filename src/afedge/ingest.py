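"""Reading rhythm-annotated beat streams and extracting plausible RR series.

A long-term ECG record carries two annotation streams: beat annotations
(one event per detected QRS complex) and rhythm annotations (interval-valued
labels such as ``(N`` for sinus rhythm or ``(AFIB`` for atrial fibrillation
that stay in force until the next label).  This module turns the two streams
into per-subject, per-rhythm series of inter-beat (RR) intervals in seconds,
keeping only sinus-rhythm and AF segments and removing physiologically
implausible intervals outside [0.25, 2] s (30-240 bpm) — such intervals
typically arise from differencing across non-contiguous rhythm segments.

Reading actual WFDB records requires the optional ``wfdb`` package; every
other operation works on plain parsed structures.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RR_LO_S = 0.25
RR_HI_S = 2.0

#: Rhythm-annotation vocabulary of the MIT-BIH Atrial Fibrillation Database.
KNOWN_RHYTHM_LABELS = {"(N", "(AFIB", "(AFL", "(J"}


class Rhythm(str, Enum):
    """Rhythm class in force over a segment of the recording."""

    SR = "SR"
    AF = "AF"
    OTHER = "OTHER"


#: Mapping from aux rhythm labels to rhythm classes; anything else is OTHER.
RHYTHM_LABEL_MAP = {"(N": Rhythm.SR, "(AFIB": Rhythm.AF}


@dataclass(frozen=True)
class BeatEvent:
    """One detected heartbeat."""

    subject_id: str
    sample_index: int
    time_s: float
    symbol: str = "N"


@dataclass(frozen=True)
class RhythmSegment:
    """A half-open time interval [start_s, end_s) with a single rhythm."""

    subject_id: str
    start_s: float
    end_s: float
    rhythm: Rhythm

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"segment must have start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RRSeries:
    """Ordered inter-beat intervals of one subject under one rhythm."""

    subject_id: str
    rhythm: Rhythm
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return float(self.values.sum()) if len(self.values) else 0.0


def list_usable_records(
    record_ids: Sequence[str], has_signal: dict[str, bool]
) -> list[str]:
    """Keep records that carry both rhythm annotations and signal/beat data.

    The MIT-BIH AF database ships 25 records of which two (00735, 03665)
    contain only rhythm annotations, leaving 23 usable subjects.  Order of
    ``record_ids`` is preserved.

    Raises
    ------
    ValueError
        If ``record_ids`` is empty or no record is usable.
    """
    if not record_ids:
        raise ValueError("record_ids is empty")
    usable = [r for r in record_ids if has_signal.get(r, False)]
    if not usable:
        raise ValueError("no usable records: every record lacks signal/beat data")
    return usable


def parse_rhythm_annotations(
    aux_labels: Sequence[tuple[float, str]],
    duration_s: float,
    subject_id: str = "",
) -> list[RhythmSegment]:
    """Turn interval-valued rhythm labels into contiguous segments.

    Each label opens a segment that is closed by the next label, or by the
    record end.  ``(N`` maps to sinus rhythm, ``(AFIB`` to atrial
    fibrillation; every other label (``(AFL``, ``(J``, dialects) maps to
    OTHER — unknown labels are tolerated with a warning rather than an
    error.

    Raises
    ------
    ValueError
        If labels are not ordered by time or extend past ``duration_s``.
    """
    if not aux_labels:
        return []
    times = [t for t, _ in aux_labels]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("rhythm labels must be ordered by time")
    if times[-1] >= duration_s:
        raise ValueError("rhythm label at or past the record end")

    segments: list[RhythmSegment] = []
    for (t, label), end in zip(aux_labels, times[1:] + [duration_s]):
        if label not in KNOWN_RHYTHM_LABELS:
            logger.warning(
                "unknown rhythm label %r in record %s; mapped to OTHER", label, subject_id
            )
        rhythm = RHYTHM_LABEL_MAP.get(label, Rhythm.OTHER)
        if end > t:  # zero-length segments (duplicate timestamps) are dropped
            segments.append(RhythmSegment(subject_id, t, end, rhythm))
    return segments


def extract_rr(
    beats: Sequence[BeatEvent],
    segments: Sequence[RhythmSegment],
    rhythm: Rhythm,
    within_segment_only: bool = False,
) -> RRSeries:
    """Compute the raw RR series of one rhythm from beat and segment streams.

    Beats falling inside segments of the requested rhythm are concatenated
    in time order across segments and successive time differences form the
    RR values.  By default differencing runs across segment boundaries, so a
    gap between two same-rhythm segments shows up as one implausibly long
    interval that the [0.25, 2] s range filter removes downstream.  With
    ``within_segment_only`` differencing restarts in every segment and no
    cross-segment interval is produced.

    Fewer than two qualifying beats yield an empty series.
    """
    subject = beats[0].subject_id if beats else (segments[0].subject_id if segments else "")
    wanted = sorted(
        (s for s in segments if s.rhythm == rhythm), key=lambda s: s.start_s
    )
    if within_segment_only:
        chunks = []
        for seg in wanted:
            t = np.array([b.time_s for b in beats if seg.contains(b.time_s)])
            if len(t) >= 2:
                chunks.append(np.diff(np.sort(t)))
        values = np.concatenate(chunks) if chunks else np.empty(0)
        return RRSeries(subject, rhythm, values)

    times = np.sort(
        np.array([b.time_s for b in beats if any(s.contains(b.time_s) for s in wanted)])
    )
    values = np.diff(times) if len(times) >= 2 else np.empty(0)
    return RRSeries(subject, rhythm, values)


def filter_rr_range(
    rr: RRSeries, lo_s: float = RR_LO_S, hi_s: float = RR_HI_S
) -> RRSeries:
    """Keep RR values in the closed interval [lo_s, hi_s], preserving order.

    The defaults correspond to 30-240 bpm; values outside mostly stem from
    transitions between non-contiguous rhythm segments or detector errors.
    """
    if not lo_s < hi_s:
        raise ValueError(f"need lo_s < hi_s, got {lo_s} >= {hi_s}")
    v = rr.values
    kept = v[(v >= lo_s) & (v <= hi_s)]
    return RRSeries(rr.subject_id, rr.rhythm, kept)


def rr_to_bpm(rr_s: float) -> float:
    """Convert an RR interval in seconds to instantaneous heart rate in bpm."""
    if rr_s <= 0:
        raise ValueError(f"RR interval must be positive, got {rr_s}")
    return 60.0 / rr_s


# ---------------------------------------------------------------------------
# WFDB access (optional dependency) and CSV persistence
# ---------------------------------------------------------------------------


def load_wfdb_record(
    data_dir: str | Path,
    record_id: str,
    beat_ext: str = "qrs",
    rhythm_ext: str = "atr",
) -> tuple[list[BeatEvent], list[RhythmSegment]]:
    """Read beat and rhythm annotation streams of one WFDB record.

    Requires the optional ``wfdb`` package.  Beat annotations are used
    verbatim (no beat-type filtering); rhythm aux labels are parsed with
    :func:`parse_rhythm_annotations`.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); all other operations accept parsed structures"
        ) from exc

    path = str(Path(data_dir) / record_id)
    header = wfdb.rdheader(path)
    fs = float(header.fs)
    duration_s = header.sig_len / fs

    beat_ann = wfdb.rdann(path, beat_ext)
    beats = [
        BeatEvent(record_id, int(s), int(s) / fs, sym)
        for s, sym in zip(beat_ann.sample, beat_ann.symbol)
    ]

    rhythm_ann = wfdb.rdann(path, rhythm_ext)
    aux = [
        (int(s) / fs, (a or "").rstrip("\x00"))
        for s, a in zip(rhythm_ann.sample, rhythm_ann.aux_note)
        if a
    ]
    segments = parse_rhythm_annotations(aux, duration_s, subject_id=record_id)
    return beats, segments


def write_rr_csv(series: RRSeries, path: str | Path) -> None:
    """Write one RR series as a two-column CSV (rr_s, rhythm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rr_s", "rhythm"])
        for v in series.values:
            w.writerow([f"{v:.6f}", series.rhythm.value])


def read_rr_csv(path: str | Path, subject_id: str | None = None) -> list[RRSeries]:
    """Read a two-column RR CSV back into per-rhythm series."""
    path = Path(path)
    subject = subject_id if subject_id is not None else path.stem
    by_rhythm: dict[Rhythm, list[float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            by_rhythm.setdefault(Rhythm(row["rhythm"]), []).append(float(row["rr_s"]))
    return [RRSeries(subject, r, np.array(v)) for r, v in by_rhythm.items()]


def ingest_records(
    data_dir: str | Path,
    out_dir: str | Path,
    record_ids: Sequence[str],
    exclude: Iterable[str] = ("00735", "03665"),
    lo_s: float = RR_LO_S,
    hi_s: float = RR_HI_S,
) -> dict:
    """Run the full ingest stage over a directory of WFDB records.

    For every non-excluded record the SR and AF RR series are extracted,
    range-filtered and written as ``<record>.csv``; a JSON manifest with
    per-record counts and per-rhythm hours is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    excluded = set(exclude)
    manifest: dict = {"records": {}, "lo_s": lo_s, "hi_s": hi_s}
    for rid in record_ids:
        if rid in excluded:
            continue
        beats, segments = load_wfdb_record(data_dir, rid)
        entry = {}
        parts = []
        for rhythm in (Rhythm.SR, Rhythm.AF):
            rr = filter_rr_range(extract_rr(beats, segments, rhythm), lo_s, hi_s)
            parts.append(rr)
            entry[rhythm.value] = {
                "n_intervals": int(len(rr)),
                "hours": rr.duration_s / 3600.0,
            }
        csv_path = out_dir / f"{rid}.csv"
        _write_rr_pair_csv(parts, csv_path)
        manifest["records"][rid] = entry
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_rr_pair_csv(series_list: Sequence[RRSeries], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rr_s", "rhythm"])
        for series in series_list:
            for v in series.values:
                w.writerow([f"{v:.6f}", series.rhythm.value])
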