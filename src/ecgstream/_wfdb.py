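"""Minimal WFDB codec: headers, format-212 signals, MIT annotation files.

Covers exactly what the MIT/BIH arrhythmia dialect needs — ``.hea`` headers,
12-bit packed format-212 ``.dat`` signals (1 or 2 channels) and ``.atr``
annotations (beat symbols, rhythm changes with aux strings, SKIP/AUX escape
words).  Both directions are implemented so round-trips are testable on
synthetic records without any download.

Annotation symbol table used for class mapping:

========  ===============================  ==========
code      MIT meaning                      class
========  ===============================  ==========
1 (N)     normal beat                      NORMAL
3 (R)     right bundle branch block beat   RBBB
8 (A)     atrial premature beat            AF
others    any other beat symbol            OTHER
========  ===============================  ==========

Beats of any symbol that fall inside an ``(AFIB`` rhythm span (rhythm-change
annotations, code 40 with aux) are relabeled AF: MIT/BIH marks atrial
fibrillation as a rhythm, not a beat symbol.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import ECGRecord, GroundTruth
from .errors import SpecificationError
from .study import BeatClass

_BEAT_CODES = set(range(1, 14)) | {25, 34, 35, 38}
_CODE_RHYTHM = 40
_CODE_SKIP = 59
_CODE_NUM = 60
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_AUX = 63

_CODE_TO_CLASS = {
    1: BeatClass.NORMAL.value,
    3: BeatClass.RBBB.value,
    8: BeatClass.AF.value,
}
_CLASS_TO_CODE = {v: k for k, v in _CODE_TO_CLASS.items()}

_DEFAULT_GAIN = 200.0  # adu per mV
_DEFAULT_BASELINE = 1024


def _sign_extend_12(v: np.ndarray) -> np.ndarray:
    return np.where(v >= 2048, v - 4096, v)


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack 12-bit sample pairs from 3-byte groups."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_groups = (n_values + 1) // 2
    if len(b) < 3 * n_groups:
        raise SpecificationError("format-212 signal file truncated")
    b = b[: 3 * n_groups].reshape(-1, 3).astype(np.int64)
    first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(2 * n_groups, dtype=np.int64)
    out[0::2] = _sign_extend_12(first)
    out[1::2] = _sign_extend_12(second)
    return out[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int64)
    if np.any(v < -2048) or np.any(v > 2047):
        raise SpecificationError("sample out of 12-bit range for format 212")
    if len(v) % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).reshape(-1, 2)
    out = np.empty((len(v), 3), dtype=np.uint8)
    out[:, 0] = v[:, 0] & 0xFF
    out[:, 1] = ((v[:, 0] >> 8) & 0x0F) | (((v[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = v[:, 1] & 0xFF
    return out.tobytes()


def _parse_gain(token: str) -> tuple[float, int | None]:
    """Parse a header gain token like ``200``, ``200/mV`` or ``200(1024)/mV``."""
    token = token.split("/", 1)[0]
    baseline = None
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    return (gain if gain != 0 else 200.0), baseline


def read_wfdb(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read ``<base>.hea`` / ``.dat`` / ``.atr`` into an annotated record."""
    base = Path(path)
    if base.suffix:  # accept record base name, .hea or .dat
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)

    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tok = lines[0].split()
    record_id = rec_tok[0].split("/")[0]
    nsig = int(rec_tok[1])
    fs = float(rec_tok[2].split("/")[0]) if len(rec_tok) > 2 else 250.0
    nsamp = int(rec_tok[3]) if len(rec_tok) > 3 else 0
    if not (1 <= nsig <= 2):
        raise SpecificationError(f"unsupported number of signals: {nsig}")
    if channel >= nsig:
        raise SpecificationError(f"channel {channel} not in record ({nsig} signals)")

    sig_specs = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0]
        if fmt != "212":
            raise SpecificationError(f"unsupported signal format {fmt!r}")
        gain, baseline = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, None)
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        sig_specs.append((fname, gain, baseline))

    dat_path = base.parent / sig_specs[0][0]
    raw = dat_path.read_bytes()
    total = nsamp * nsig if nsamp else (len(raw) // 3) * 2
    flat = _unpack_212(raw, total)
    sig = flat[channel::nsig] if nsig > 1 else flat
    _, gain, baseline = sig_specs[channel]
    samples = (sig - baseline) / gain

    atr_path = base.with_suffix(".atr")
    annotations = read_annotations(atr_path) if atr_path.exists() else None
    return ECGRecord(record_id, fs, samples, annotations)


def read_annotations(path: str | Path) -> GroundTruth:
    """Decode a MIT annotation file into beat positions and class labels."""
    raw = Path(path).read_bytes()
    pos = 0
    time = 0
    beats: list[tuple[int, int]] = []  # (sample, code)
    rhythm_changes: list[tuple[int, str]] = []  # (sample, aux string)
    pending_interval = 0
    while pos + 1 < len(raw):
        word = struct.unpack_from("<H", raw, pos)[0]
        pos += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _CODE_SKIP:
            high, low = struct.unpack_from("<hH", raw, pos)[0], struct.unpack_from(
                "<H", raw, pos + 2
            )[0]
            pending_interval += (high << 16) | low
            pos += 4
            continue
        if code == _CODE_AUX:
            pos += delta + (delta & 1)
            continue
        if code in (_CODE_NUM, _CODE_SUB, _CODE_CHN):
            continue
        time += delta + pending_interval
        pending_interval = 0
        if code == _CODE_RHYTHM:
            # aux string follows as an AUX word
            if pos + 1 < len(raw):
                nxt = struct.unpack_from("<H", raw, pos)[0]
                if (nxt >> 10) == _CODE_AUX:
                    alen = nxt & 0x3FF
                    aux = raw[pos + 2 : pos + 2 + alen].decode("ascii", "replace")
                    rhythm_changes.append((time, aux.strip("\x00")))
                    pos += 2 + alen + (alen & 1)
                    continue
            rhythm_changes.append((time, ""))
        elif code in _BEAT_CODES:
            beats.append((time, code))

    r_indices, labels = [], []
    for sample, code in beats:
        label = _CODE_TO_CLASS.get(code, BeatClass.OTHER.value)
        current = ""
        for t0, aux in rhythm_changes:
            if t0 <= sample:
                current = aux
        if current.startswith("(AFIB"):
            label = BeatClass.AF.value
        r_indices.append(sample)
        labels.append(label)
    return GroundTruth(np.asarray(r_indices, dtype=np.int64), labels)


def _annotation_words(entries: list[tuple[int, int, str | None]]) -> bytes:
    """Encode (sample, code, aux) entries in time order."""
    out = bytearray()
    prev = 0
    for sample, code, aux in entries:
        delta = sample - prev
        if delta < 0:
            raise SpecificationError("annotations must be time-ordered")
        if delta >= 1024:
            out += struct.pack("<H", _CODE_SKIP << 10)
            out += struct.pack("<hH", delta >> 16, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        if aux:
            data = aux.encode("ascii")
            out += struct.pack("<H", (_CODE_AUX << 10) | len(data))
            out += data
            if len(data) & 1:
                out += b"\x00"
        prev = sample
    out += struct.pack("<H", 0)  # EOF
    return bytes(out)


def write_wfdb(
    record: ECGRecord,
    base: str | Path,
    gain: float = _DEFAULT_GAIN,
    baseline: int = _DEFAULT_BASELINE,
) -> Path:
    """Write a single-channel record as ``.hea``/``.dat`` (+ ``.atr``).

    AF beats are written as atrial-premature symbols inside an ``(AFIB``
    rhythm span so the class mapping round-trips.
    """
    base = Path(base)
    adu = np.rint(record.samples * gain).astype(np.int64) + baseline
    adu = np.clip(adu, -2048, 2047)
    base.with_suffix(".dat").write_bytes(_pack_212(adu))
    first = int(adu[0])
    header = (
        f"{base.name} 1 {record.fs:g} {len(record)}\n"
        f"{base.name}.dat 212 {gain:g}({baseline})/mV 12 {baseline} {first} 0 0 ECG\n"
    )
    base.with_suffix(".hea").write_text(header)

    truth = record.annotations
    if truth is not None:
        entries: list[tuple[int, int, str | None]] = []
        in_afib = False
        for r, lab in zip(truth.r_indices, truth.labels):
            is_af = lab == BeatClass.AF.value
            if is_af and not in_afib:
                entries.append((max(0, int(r) - 1), _CODE_RHYTHM, "(AFIB"))
                in_afib = True
            elif not is_af and in_afib:
                entries.append((max(0, int(r) - 1), _CODE_RHYTHM, "(N"))
                in_afib = False
            entries.append((int(r), _CLASS_TO_CODE.get(lab, 13), None))
        base.with_suffix(".atr").write_bytes(_annotation_words(entries))
    return base
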