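"""Desk-scale simulator of the embedded AF-detection signal flow.

Mirrors the firmware loop of the wearable prototype: incoming RR intervals
(and the ECG samples spanning them, sampled at 125 Hz) accumulate in
independent buffers; when the RR buffer reaches the configured window
length the network runs one inference, an event is emitted, and both
buffers are cleared so that the next acquisition cycle starts fresh.  A
window classified as atrial fibrillation additionally produces a
JSON-formatted payload — the RR window, the corresponding ECG samples and
the AF probability — delivered to a pluggable sink (a directory of JSON
files by default, standing in for the device's MQTT uplink).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ECG_FS_HZ = 125.0


@dataclass(frozen=True)
class StreamEvent:
    """Result of one buffer-triggered inference."""

    classification: str  # "SR" or "AF"
    af_probability: float
    inference_index: int
    buffer_span_s: float


@dataclass(frozen=True)
class AFEventPayload:
    """The JSON payload published when a window is classified as AF."""

    stream_id: str
    event_time_s: float
    window_length: int
    rr_values: tuple[float, ...]
    ecg_samples: tuple[float, ...]
    sampling_rate_hz: float
    af_probability: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "stream_id": self.stream_id,
                "event_time_s": self.event_time_s,
                "window_length": self.window_length,
                "rr_values": list(self.rr_values),
                "ecg_samples": list(self.ecg_samples),
                "sampling_rate_hz": self.sampling_rate_hz,
                "af_probability": self.af_probability,
            },
            sort_keys=True,
        )


class Sink(Protocol):
    def deliver(self, payload: AFEventPayload) -> None: ...


class DirectorySink:
    """Writes each payload as a JSON file in a directory."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.count = 0

    def deliver(self, payload: AFEventPayload) -> None:
        self.count += 1
        path = self.directory / f"af_event_{self.count:05d}.json"
        path.write_text(payload.to_json())


class ListSink:
    """Collects payloads in memory (testing/inspection)."""

    def __init__(self) -> None:
        self.payloads: list[AFEventPayload] = []

    def deliver(self, payload: AFEventPayload) -> None:
        self.payloads.append(payload)


class StreamEngine:
    """RR/ECG buffering and window-triggered inference.

    ``model`` is anything with a ``predict_proba(windows)`` contract (the
    float32 or the INT8 model); ``n`` is the RR window length that triggers
    inference.  Both buffers are cleared after every inference, so analysis
    windows never overlap.
    """

    def __init__(
        self,
        model,
        n: int,
        sink: Sink | None = None,
        stream_id: str = "stream",
        fs_hz: float = ECG_FS_HZ,
        af_threshold: float = 0.5,
    ):
        self.model = model
        self.n = n
        self.sink = sink
        self.stream_id = stream_id
        self.fs_hz = fs_hz
        self.af_threshold = af_threshold
        self._rr: list[float] = []
        self._ecg: list[float] = []
        self._time_s = 0.0
        self._inference_index = 0
        self.events: list[StreamEvent] = []

    def push_rr(
        self, rr_s: float, ecg_chunk: Sequence[float] | None = None
    ) -> StreamEvent | None:
        """Feed one RR interval (and the ECG samples spanning it).

        Returns the StreamEvent when this interval fills the buffer,
        otherwise ``None``.  Non-positive intervals are rejected with a
        warning and leave the buffers untouched.
        """
        if rr_s <= 0:
            logger.warning("rejected non-positive RR interval %r", rr_s)
            return None
        self._rr.append(float(rr_s))
        self._time_s += float(rr_s)
        if ecg_chunk is not None:
            self._ecg.extend(float(v) for v in ecg_chunk)
        if len(self._rr) < self.n:
            return None

        window = np.asarray(self._rr)
        af_p = float(self.model.predict_proba(window[None, :])[0, 1])
        classification = "AF" if af_p >= self.af_threshold else "SR"
        self._inference_index += 1
        event = StreamEvent(
            classification=classification,
            af_probability=af_p,
            inference_index=self._inference_index,
            buffer_span_s=float(window.sum()),
        )
        self.events.append(event)
        # payload must be built from the just-cleared window's data
        self.handle_event(event, window, np.asarray(self._ecg))
        self._rr.clear()
        self._ecg.clear()
        return event

    def handle_event(
        self,
        event: StreamEvent,
        rr_window: np.ndarray,
        ecg_samples: np.ndarray,
    ) -> AFEventPayload | None:
        """Publish an AF payload; a sinus-rhythm event produces nothing."""
        if event.classification != "AF":
            return None
        payload = AFEventPayload(
            stream_id=self.stream_id,
            event_time_s=self._time_s,
            window_length=self.n,
            rr_values=tuple(round(v, 6) for v in rr_window),
            ecg_samples=tuple(round(v, 6) for v in ecg_samples),
            sampling_rate_hz=self.fs_hz,
            af_probability=event.af_probability,
        )
        if self.sink is not None:
            try:
                self.sink.deliver(payload)
            except Exception:
                fallback = Path(f"{self.stream_id}_event_{event.inference_index:05d}.json")
                fallback.write_text(payload.to_json())
                logger.exception("sink delivery failed; payload persisted to %s", fallback)
        return payload

    def run(
        self,
        rr_stream: Sequence[float],
        ecg_chunks: Sequence[Sequence[float]] | None = None,
    ) -> list[StreamEvent]:
        """Replay a whole RR stream (with optional per-interval ECG chunks)."""
        events = []
        for i, rr in enumerate(rr_stream):
            chunk = ecg_chunks[i] if ecg_chunks is not None else None
            ev = self.push_rr(rr, chunk)
            if ev is not None:
                events.append(ev)
        return events

    def write_event_log(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["inference_index", "classification", "af_probability", "buffer_span_s"])
            for ev in self.events:
                w.writerow(
                    [ev.inference_index, ev.classification,
                     f"{ev.af_probability:.6f}", f"{ev.buffer_span_s:.6f}"]
                )


def fifo_period(n_samples: int = 32, fs_hz: float = ECG_FS_HZ) -> float:
    """Fill time of the front-end FIFO in milliseconds (32 x 8 ms = 256 ms)."""
    if fs_hz <= 0:
        raise ValueError("sampling frequency must be positive")
    return n_samples * 1000.0 / fs_hz


def mean_hr_bpm(rr_values: Sequence[float]) -> int:
    """Mean heart rate in bpm, rounded to the nearest integer for display."""
    rr = np.asarray(rr_values, dtype=float)
    if rr.size == 0:
        raise ValueError("empty RR sequence")
    if np.any(rr <= 0):
        raise ValueError("RR values must be positive")
    return int(round(60.0 / float(rr.mean())))
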