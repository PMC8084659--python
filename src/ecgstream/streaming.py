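"""In-process micro-batch engine with exactly-once delivery.

The engine reproduces the semantics of a structured-streaming continuous
query on a file source: packets are processed in order at a 5-second trigger
interval (back-to-back unless ``realtime`` pacing is requested), each batch
runs the denoise -> R-peak -> segment -> features -> classify pipeline, and
results are appended to an output sink exactly once, surviving crashes at
any stage boundary via an idempotent sink plus a committed-index checkpoint.

Carry-over mode (default) treats the stream as an unbounded table: the raw
signal accumulates across packets and the causal R-peak detector re-scans
the prefix each trigger.  A beat is committed in the first batch whose
accumulated signal covers the beat's full 130-sample right context plus the
detector's bounded lookahead (``COMMIT_MARGIN`` samples); the final batch
flushes the remainder.  Because the detector is prefix-stable, the union of
all batches equals a single batch run over the concatenated record,
beat-for-beat.  With carry-over disabled each packet is processed in
isolation and beats straddling packet edges are dropped.
"""

from __future__ import annotations

import json
import os
import sqlite3
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io as ecg_io
from .classify import TrainedModel, load_model, predict
from .core import EpochPacket
from .errors import SinkError, SpecificationError
from .features import extract_features, features_matrix
from .preprocess import FilterSpec, bandpass_fir, detect_r_peaks, segment_beats
from .study import FS_HZ, SEGMENT_POST, SEGMENT_PRE

#: samples of right context a beat needs before it may be committed mid-stream:
#: 130 post-R segmentation context plus the detector lookahead and the
#: denoising filter half-length, rounded up with a little slack.
COMMIT_MARGIN = 145

ENGINE_VERSION = 1

Failpoint = Callable[[str, int], None]
STAGES = ("read", "compute", "sink", "checkpoint")


@dataclass
class QueryConfig:
    source_dir: str
    sink_uri: str
    checkpoint_path: str
    model_path: str = ""
    trigger_interval: float = 5.0
    carry_over: bool = True
    realtime: bool = False
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    refractory_s: float = 0.2
    wavelet: str = "db4"

    def __post_init__(self) -> None:
        if self.trigger_interval <= 0:
            raise SpecificationError("trigger_interval must be positive")


@dataclass
class BatchResult:
    packet_index: int
    record_id: str
    n_beats: int
    r_indices: list[int]
    labels: list[str]
    scores: np.ndarray | None
    timings: dict[str, float]
    quarantined: bool = False

    def rows(self) -> list[dict]:
        ts = datetime.now(timezone.utc).isoformat()
        return [
            {
                "packet_index": self.packet_index,
                "record": self.record_id,
                "r_index": int(r),
                "label": str(l),
                "ts": ts,
            }
            for r, l in zip(self.r_indices, self.labels)
        ]


class Checkpoint:
    """Committed-batch marker persisted with atomic replace."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def last_committed(self) -> int:
        if not self.path.exists():
            return -1
        state = json.loads(self.path.read_text())
        if state.get("engine_version") != ENGINE_VERSION:
            raise SpecificationError("checkpoint written by a different engine version")
        return int(state["last_committed_packet_index"])

    def commit(self, packet_index: int) -> None:
        prev = self.last_committed()
        if packet_index < prev:
            raise SpecificationError("committed index must not decrease")
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(
            json.dumps(
                {
                    "last_committed_packet_index": packet_index,
                    "engine_version": ENGINE_VERSION,
                }
            )
        )
        os.replace(tmp, self.path)


# ------------------------------------------------------------------- sinks


class CsvDirSink:
    """Directory of per-batch CSV files; atomic rename makes writes
    idempotent and crash-safe (a half-written batch is never visible)."""

    COLUMNS = ["packet_index", "record", "r_index", "label", "ts"]

    def __init__(self, directory: str | Path):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    def _batch_path(self, packet_index: int) -> Path:
        return self.dir / f"batch_{packet_index:05d}.csv"

    def committed(self) -> set[int]:
        return {
            int(p.stem.split("_")[1]) for p in self.dir.glob("batch_*.csv")
        }

    def write(self, packet_index: int, rows: list[dict]) -> str:
        path = self._batch_path(packet_index)
        if path.exists():
            return f"dup:{packet_index}"
        tmp = path.with_suffix(".tmp")
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(tmp, index=False)
        os.replace(tmp, path)
        return f"ok:{packet_index}"

    def read_rows(self) -> pd.DataFrame:
        paths = sorted(self.dir.glob("batch_*.csv"))
        frames = [pd.read_csv(p) for p in paths if p.stat().st_size > 0]
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=self.COLUMNS)
        return pd.concat(frames, ignore_index=True)


class SqliteSink:
    """Embedded relational sink; one transaction per batch gives atomic,
    idempotent commits keyed on packet_index."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with self._conn() as con:
            con.execute(
                "CREATE TABLE IF NOT EXISTS detections ("
                "packet_index INTEGER, record TEXT, r_index INTEGER, "
                "label TEXT, ts TEXT)"
            )
            con.execute(
                "CREATE TABLE IF NOT EXISTS committed_batches ("
                "packet_index INTEGER PRIMARY KEY)"
            )

    def _conn(self) -> sqlite3.Connection:
        return sqlite3.connect(self.path)

    def committed(self) -> set[int]:
        with self._conn() as con:
            return {
                r[0]
                for r in con.execute("SELECT packet_index FROM committed_batches")
            }

    def write(self, packet_index: int, rows: list[dict]) -> str:
        with self._conn() as con:
            done = con.execute(
                "SELECT 1 FROM committed_batches WHERE packet_index=?",
                (packet_index,),
            ).fetchone()
            if done:
                return f"dup:{packet_index}"
            con.executemany(
                "INSERT INTO detections VALUES (?,?,?,?,?)",
                [
                    (
                        r["packet_index"],
                        r["record"],
                        r["r_index"],
                        r["label"],
                        r["ts"],
                    )
                    for r in rows
                ],
            )
            con.execute(
                "INSERT INTO committed_batches VALUES (?)", (packet_index,)
            )
        return f"ok:{packet_index}"

    def read_rows(self) -> pd.DataFrame:
        with self._conn() as con:
            return pd.read_sql_query(
                "SELECT packet_index, record, r_index, label, ts FROM detections "
                "ORDER BY packet_index, r_index",
                con,
            )


def make_sink(uri: str | Path) -> CsvDirSink | SqliteSink:
    s = str(uri)
    if s.startswith("sqlite://"):
        return SqliteSink(s[len("sqlite://") :])
    if s.endswith((".db", ".sqlite")):
        return SqliteSink(s)
    return CsvDirSink(s)


def sink_write(
    sink: CsvDirSink | SqliteSink, packet_index: int, rows: list[dict]
) -> str:
    """Idempotent append of one batch; re-delivery is a no-op."""
    try:
        return sink.write(packet_index, rows)
    except (OSError, sqlite3.Error) as exc:
        raise SinkError(f"sink write failed for batch {packet_index}: {exc}") from exc


# ------------------------------------------------------------------- engine


def _classify_beats(beats, wavelet: str, model: TrainedModel):
    if not beats:
        return [], [], None
    feats = [extract_features(b, wavelet=wavelet) for b in beats]
    labels, scores = predict(model, features_matrix(feats))
    return [b.r_index for b in beats], [str(l) for l in labels], scores


def run_query(
    config: QueryConfig,
    model: TrainedModel | None = None,
    failpoint: Failpoint | None = None,
    sink_retries: int = 2,
) -> list[BatchResult]:
    """Execute the continuous query until the file source is exhausted.

    Returns one :class:`BatchResult` per processed batch.  Batches already
    committed in the checkpoint are skipped (their raw samples are still
    read in carry-over mode to rebuild the accumulated signal).  An optional
    ``failpoint(stage, packet_index)`` hook is invoked after each stage and
    may raise to simulate a crash.
    """
    if model is None:
        model = load_model(config.model_path)
    sink = make_sink(config.sink_uri)
    checkpoint = Checkpoint(config.checkpoint_path)
    last = checkpoint.last_committed()

    packets = list(ecg_io.open_stream(config.source_dir, quarantine=True))
    n_packets = len(packets)
    results: list[BatchResult] = []
    if n_packets == 0:
        return results

    accumulated: list[np.ndarray] = []
    prev_limit = -1  # greatest committed r-index bound (carry-over mode)
    cum_len = 0

    for packet in packets:
        k = packet.packet_index
        is_final = k == n_packets - 1
        t0 = time.perf_counter()
        accumulated.append(packet.samples)
        cum_len += len(packet)
        limit = cum_len if is_final else cum_len - COMMIT_MARGIN

        if k <= last:
            # already delivered before a restart: advance state only
            if config.carry_over:
                prev_limit = limit
            continue

        t_read = time.perf_counter()
        if failpoint:
            failpoint("read", k)

        if packet.quarantined:
            r_idx: list[int] = []
            labels: list[str] = []
            scores = None
        elif config.carry_over:
            signal = np.concatenate(accumulated)
            filtered = bandpass_fir(signal, config.filter_spec)
            peaks = detect_r_peaks(
                filtered, fs=FS_HZ, refractory_s=config.refractory_s
            )
            emit = [r for r in peaks if prev_limit < r <= limit]
            seg = segment_beats(filtered, emit, source_record=packet.record_id)
            r_idx, labels, scores = _classify_beats(
                seg.beats, config.wavelet, model
            )
        else:
            if len(packet) > config.filter_spec.num_taps:
                filtered = bandpass_fir(packet.samples, config.filter_spec)
                peaks = detect_r_peaks(
                    filtered, fs=FS_HZ, refractory_s=config.refractory_s
                )
                seg = segment_beats(
                    filtered, peaks, source_record=packet.record_id
                )
                for b in seg.beats:
                    b.r_index += packet.start_sample
                r_idx, labels, scores = _classify_beats(
                    seg.beats, config.wavelet, model
                )
            else:
                r_idx, labels, scores = [], [], None
        t_compute = time.perf_counter()
        if failpoint:
            failpoint("compute", k)

        result = BatchResult(
            packet_index=k,
            record_id=packet.record_id,
            n_beats=len(r_idx),
            r_indices=[int(r) for r in r_idx],
            labels=labels,
            scores=scores,
            timings={},
            quarantined=packet.quarantined,
        )
        attempts = 0
        while True:
            try:
                sink_write(sink, k, result.rows())
                break
            except SinkError:
                attempts += 1
                if attempts > sink_retries:
                    raise
        t_sink = time.perf_counter()
        if failpoint:
            failpoint("sink", k)

        checkpoint.commit(k)
        if failpoint:
            failpoint("checkpoint", k)

        if config.carry_over:
            prev_limit = limit
        t_end = time.perf_counter()
        result.timings = {
            "read_ms": 1e3 * (t_read - t0),
            "compute_ms": 1e3 * (t_compute - t_read),
            "sink_ms": 1e3 * (t_sink - t_compute),
            "total_ms": 1e3 * (t_end - t0),
        }
        results.append(result)

        if config.realtime:
            elapsed = t_end - t0
            if elapsed < config.trigger_interval:
                time.sleep(config.trigger_interval - elapsed)
    return results


def progress_report(
    results: Sequence[BatchResult], csv_path: str | Path | None = None
) -> pd.DataFrame:
    """Per-batch timing table (read / compute / sink / total) plus the mean."""
    if not results:
        raise SpecificationError("progress report needs at least one batch")
    df = pd.DataFrame(
        [
            {
                "packet_index": r.packet_index,
                "n_beats": r.n_beats,
                **r.timings,
            }
            for r in results
        ]
    )
    df.attrs["mean_total_ms"] = float(df["total_ms"].mean())
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df
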