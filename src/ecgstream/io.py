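"""Record / packet I/O: CSV dialect, WFDB dialect, streaming file source.

CSV dialect
-----------
A record or packet file is plain text: an optional comment header line
``# fs=360 start_sample=<k> record=<id>``, an optional ``value_mv`` column
header, then one sample per line in mV (full float precision, so write→read
round-trips are exact).  A bare comma- or newline-separated list of numbers
is also accepted.  Annotations travel in a ``<stem>.truth.csv`` sidecar with
columns ``r_index,label``.

Streaming source layout
-----------------------
A packet directory holds ``packet_00000.csv`` … plus ``manifest.yaml``
listing the packet filenames in stream order; the manifest wins over
lexicographic order when both disagree.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .core import ECGRecord, EpochPacket, GroundTruth
from .errors import FsMismatchError, SpecificationError, StreamIntegrityError
from .study import FS_HZ
from .study import PACKET_SECONDS as PACKET_SECONDS_DEFAULT

MANIFEST_NAME = "manifest.yaml"
TRUTH_NAME = "truth.csv"


# ---------------------------------------------------------------- CSV dialect


def _format_header(fs: float, start_sample: int, record_id: str) -> str:
    return f"# fs={fs:g} start_sample={start_sample} record={record_id}"


def _parse_header(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def _write_samples_csv(
    path: Path, samples: np.ndarray, fs: float, start_sample: int, record_id: str
) -> None:
    with open(path, "w") as fh:
        fh.write(_format_header(fs, start_sample, record_id) + "\n")
        fh.write("value_mv\n")
        for v in samples:
            fh.write(f"{v:.17g}\n")


def _read_samples_csv(path: Path) -> tuple[np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_parse_header(line))
                continue
            if line.lower() == "value_mv":
                continue
            for tok in line.split(","):
                tok = tok.strip()
                if tok:
                    values.append(float(tok))
    return np.asarray(values, dtype=np.float64), meta


def read_truth(path: Path) -> GroundTruth:
    rows = list(csv.DictReader(open(path)))
    r = np.asarray([int(row["r_index"]) for row in rows], dtype=np.int64)
    labels = [row["label"] for row in rows]
    return GroundTruth(r, labels)


def write_truth(truth: GroundTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("r_index,label\n")
        for r, lab in zip(truth.r_indices, truth.labels):
            fh.write(f"{int(r)},{lab}\n")


def write_record(record: ECGRecord, path: str | Path) -> Path:
    """Write a record in the CSV dialect (+ truth sidecar when annotated)."""
    path = Path(path)
    _write_samples_csv(path, record.samples, record.fs, 0, record.record_id)
    if record.annotations is not None:
        write_truth(record.annotations, path.with_suffix(".truth.csv"))
    return path


def read_record(
    path: str | Path, dialect: str = "csv", allow_fs: bool = False, channel: int = 0
) -> ECGRecord:
    """Read a record in either supported dialect.

    The pipeline is calibrated for 360 Hz; a record at any other rate raises
    :class:`FsMismatchError` unless ``allow_fs`` is set (then it only warns —
    no resampling is attempted).
    """
    path = Path(path)
    if dialect == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        samples, meta = _read_samples_csv(path)
        if samples.size == 0:
            raise SpecificationError(f"no samples in {path}")
        fs = float(meta.get("fs", FS_HZ))
        record_id = meta.get("record", path.stem)
        truth_path = path.with_suffix(".truth.csv")
        annotations = read_truth(truth_path) if truth_path.exists() else None
        record = ECGRecord(record_id, fs, samples, annotations)
    elif dialect == "wfdb":
        from . import _wfdb

        record = _wfdb.read_wfdb(path, channel=channel)
    else:
        raise SpecificationError(f"unknown dialect {dialect!r}")

    if record.fs != FS_HZ:
        msg = f"record {record.record_id} sampled at {record.fs:g} Hz, expected {FS_HZ}"
        if not allow_fs:
            raise FsMismatchError(msg)
        warnings.warn(msg, stacklevel=2)
    return record


# ------------------------------------------------------------- packet source


def write_packets(
    record: ECGRecord, out_dir: str | Path, packet_seconds: float = 5.0
) -> Path:
    """Split a record into consecutive packet files plus manifest and truth."""
    if packet_seconds <= 0:
        raise SpecificationError("packet_seconds must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    step = round(packet_seconds * record.fs)
    names: list[str] = []
    for k, start in enumerate(range(0, len(record), step)):
        chunk = record.samples[start : start + step]
        name = f"packet_{k:05d}.csv"
        _write_samples_csv(out_dir / name, chunk, record.fs, start, record.record_id)
        names.append(name)
    last_short = (len(record) % step) != 0
    manifest = {
        "record": record.record_id,
        "fs": record.fs,
        "packet_samples": step,
        "total_samples": len(record),
        "last_packet_short": last_short,
        "packets": names,
    }
    with open(out_dir / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if record.annotations is not None:
        write_truth(record.annotations, out_dir / TRUTH_NAME)
    return out_dir


def open_stream(
    source_dir: str | Path, quarantine: bool = False
) -> Iterator[EpochPacket]:
    """Iterate the packet files of a streaming source in stream order.

    Manifest order wins when a manifest is present; otherwise packet files
    are taken in lexicographic order.  Packets are yielded exactly once with
    contiguous ``packet_index`` from 0; a gap in the sample offsets raises
    :class:`StreamIntegrityError`.

    With ``quarantine`` enabled an unparseable packet file is substituted by
    a zero-filled packet flagged ``quarantined`` (offsets are preserved using
    the manifest packet size) instead of aborting the stream.
    """
    source_dir = Path(source_dir)
    manifest_path = source_dir / MANIFEST_NAME
    packet_samples = None
    if manifest_path.exists():
        manifest = yaml.safe_load(open(manifest_path))
        names = list(manifest.get("packets", []))
        packet_samples = manifest.get("packet_samples")
    else:
        names = sorted(
            p.name
            for p in source_dir.glob("*.csv")
            if p.name != TRUTH_NAME and not p.name.endswith(".truth.csv")
        )
    nominal = int(packet_samples or round(PACKET_SECONDS_DEFAULT * FS_HZ))

    def _iter() -> Iterator[EpochPacket]:
        expected_start = 0
        for k, name in enumerate(names):
            bad = False
            try:
                samples, meta = _read_samples_csv(source_dir / name)
            except (ValueError, OSError) as exc:
                if not quarantine:
                    raise
                warnings.warn(f"quarantined packet {name}: {exc}", stacklevel=2)
                samples, meta = np.zeros(nominal), {}
                bad = True
            start = int(meta.get("start_sample", expected_start))
            if start != expected_start:
                raise StreamIntegrityError(
                    f"packet {name}: starts at sample {start}, expected {expected_start}"
                )
            yield EpochPacket(
                packet_index=k,
                start_sample=start,
                samples=samples,
                record_id=meta.get("record", ""),
                quarantined=bad,
            )
            expected_start = start + len(samples)

    return _iter()


def read_stream_truth(source_dir: str | Path) -> GroundTruth | None:
    path = Path(source_dir) / TRUTH_NAME
    return read_truth(path) if path.exists() else None
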