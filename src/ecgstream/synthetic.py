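"""Synthetic single-lead ECG with known beat classes and R-peak positions.

The generator sums Gaussian bumps for the P wave, QRS complex and T wave —
the standard device for controllable synthetic ECG — on a 360 Hz grid, then
adds baseline wander (slow sinusoid), optional powerline interference and
white noise.  Three beat morphologies are provided:

* ``NORMAL`` — P/QRS/T with a narrow (~80 ms) QRS;
* ``RBBB``   — widened (~140 ms), notched QRS (second delayed R bump);
* ``AF``     — suppressed P wave combined with high RR-interval jitter
  (irregularly irregular rhythm), the two classic AF signatures.

Every beat's true R-peak sample index and class label are recorded, so the
detector, segmenter and classifier can all be validated without any external
recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ECGRecord, GroundTruth
from .errors import SpecificationError
from .study import FS_HZ, SEGMENT_POST, SEGMENT_PRE, BeatClass

# template grid spans [-0.25 s, +0.40 s] around the nominal R sample
_SPAN_PRE_S = 0.25
_SPAN_POST_S = 0.40


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat class as a sum of Gaussian bumps."""

    class_label: str
    qrs_width: float  # seconds, total QRS duration
    qrs_amplitude: float  # mV, R-wave height
    p_wave_present: bool
    t_wave_amplitude: float  # mV
    p_amplitude: float = 0.15  # mV (ignored when p_wave_present is False)
    notched: bool = False  # RBBB-style second R bump

    def __post_init__(self) -> None:
        if self.qrs_width <= 0:
            raise SpecificationError("qrs_width must be positive")
        for v in (self.qrs_amplitude, self.t_wave_amplitude, self.p_amplitude):
            if not math.isfinite(v):
                raise SpecificationError("template amplitudes must be finite")
        if self.class_label == BeatClass.AF.value and self.p_wave_present:
            raise SpecificationError("AF templates must suppress the P wave")

    def components(self) -> list[tuple[float, float, float]]:
        """(time offset s, amplitude mV, Gaussian sd s) for each bump."""
        qa = self.qrs_amplitude
        r_sd = self.qrs_width / 6.5
        comps: list[tuple[float, float, float]] = []
        if self.p_wave_present:
            comps.append((-0.16, self.p_amplitude, 0.022))
        comps.append((-0.45 * self.qrs_width, -0.12 * qa, 0.010))  # Q
        comps.append((0.0, qa, r_sd))  # R
        if self.notched:
            comps.append((0.45 * self.qrs_width, 0.6 * qa, 0.8 * r_sd))  # R'
            comps.append((0.75 * self.qrs_width, -0.25 * qa, 0.012))  # late S
        else:
            comps.append((0.40 * self.qrs_width, -0.20 * qa, 0.012))  # S
        comps.append((0.30, self.t_wave_amplitude, 0.055))  # T
        return comps

    def waveform(self, fs: float = FS_HZ) -> tuple[np.ndarray, int]:
        """Sampled template and the argmax offset relative to the R sample.

        The returned offset is normally 0 (the R bump dominates); it is
        recorded explicitly so ground-truth R indices always coincide with
        the discrete sample-level maximum of the noise-free waveform.
        """
        pre = round(_SPAN_PRE_S * fs)
        post = round(_SPAN_POST_S * fs)
        t = (np.arange(-pre, post + 1)) / fs
        wave = np.zeros_like(t)
        for t0, amp, sd in self.components():
            wave += amp * np.exp(-0.5 * ((t - t0) / sd) ** 2)
        return wave, int(np.argmax(wave)) - pre


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm and noise parameters for one generated record."""

    mean_rr: float  # seconds
    rr_jitter: float  # coefficient of variation of RR intervals
    duration: float  # seconds
    noise_sd: float = 0.0  # mV, additive white noise
    baseline_wander_amp: float = 0.0  # mV, 0.3 Hz sinusoid
    powerline_amp: float = 0.0  # mV, 50 Hz sinusoid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise SpecificationError("mean_rr must be positive")
        if self.duration <= 0:
            raise SpecificationError("duration must be positive")
        if self.rr_jitter < 0 or self.noise_sd < 0 or self.baseline_wander_amp < 0:
            raise SpecificationError("jitter/noise parameters must be non-negative")


_TEMPLATES: dict[str, BeatTemplate] = {
    BeatClass.NORMAL.value: BeatTemplate(
        class_label=BeatClass.NORMAL.value,
        qrs_width=0.08,
        qrs_amplitude=1.1,
        p_wave_present=True,
        t_wave_amplitude=0.30,
    ),
    BeatClass.RBBB.value: BeatTemplate(
        class_label=BeatClass.RBBB.value,
        qrs_width=0.14,
        qrs_amplitude=1.0,
        p_wave_present=True,
        t_wave_amplitude=0.25,
        notched=True,
    ),
    BeatClass.AF.value: BeatTemplate(
        class_label=BeatClass.AF.value,
        qrs_width=0.08,
        qrs_amplitude=1.05,
        p_wave_present=False,
        t_wave_amplitude=0.22,
    ),
}

#: mean RR (s) and RR jitter per class; AF uses jitter >= 0.15 (irregular RR)
_RHYTHMS: dict[str, tuple[float, float]] = {
    BeatClass.NORMAL.value: (0.80, 0.03),
    BeatClass.RBBB.value: (0.90, 0.05),
    BeatClass.AF.value: (0.75, 0.20),
}


def template_for(class_label: str) -> BeatTemplate:
    """Default morphology template for a beat class."""
    try:
        return _TEMPLATES[str(class_label)]
    except KeyError:
        raise SpecificationError(f"no template for class {class_label!r}") from None


def rhythm_for(
    class_label: str,
    duration: float,
    seed: int,
    noise_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
) -> RhythmSpec:
    """Default rhythm spec (class-typical RR statistics) for a beat class."""
    mean_rr, jitter = _RHYTHMS[str(class_label)]
    return RhythmSpec(
        mean_rr=mean_rr,
        rr_jitter=jitter,
        duration=duration,
        noise_sd=noise_sd,
        baseline_wander_amp=baseline_wander_amp,
        seed=seed,
    )


def generate_record(
    rhythm: RhythmSpec, template: BeatTemplate
) -> tuple[ECGRecord, GroundTruth]:
    """Generate one record: beats at jittered RR intervals plus noise.

    The first beat is placed one mean RR interval after the record start;
    subsequent intervals are ``mean_rr * (1 + rr_jitter * z)`` with standard
    normal ``z`` (floored at 0.3 * mean_rr so beats never collide).  All
    randomness flows through one ``numpy`` generator seeded from the spec, so
    identical specs give bit-identical output.
    """
    if rhythm.duration < 2.0:
        raise SpecificationError("duration must be at least 2 s")
    fs = FS_HZ
    n = round(rhythm.duration * fs)
    rng = np.random.default_rng(rhythm.seed)

    wave, r_off = template.waveform(fs)
    w_pre = round(_SPAN_PRE_S * fs)

    centers: list[int] = []
    t = rhythm.mean_rr
    while t < rhythm.duration - 0.05:
        centers.append(round(t * fs))
        step = rhythm.mean_rr * (1.0 + rhythm.rr_jitter * rng.standard_normal())
        t += max(0.3 * rhythm.mean_rr, step)

    signal = np.zeros(n)
    r_indices: list[int] = []
    for c in centers:
        lo = c - w_pre
        a = max(0, lo)
        b = min(n, lo + len(wave))
        if b <= a:
            continue
        signal[a:b] += wave[a - lo : b - lo]
        r = c + r_off
        if 0 <= r < n:
            r_indices.append(r)

    # noise terms (phases drawn unconditionally to keep the draw sequence fixed)
    tgrid = np.arange(n) / fs
    phase_bw, phase_pl = rng.uniform(0.0, 2.0 * np.pi, size=2)
    if rhythm.baseline_wander_amp > 0:
        signal += rhythm.baseline_wander_amp * np.sin(2 * np.pi * 0.3 * tgrid + phase_bw)
    if rhythm.powerline_amp > 0:
        signal += rhythm.powerline_amp * np.sin(2 * np.pi * 50.0 * tgrid + phase_pl)
    if rhythm.noise_sd > 0:
        signal += rhythm.noise_sd * rng.standard_normal(n)

    r_arr = np.asarray(r_indices, dtype=np.int64)
    boundary = (r_arr < SEGMENT_PRE) | (r_arr + SEGMENT_POST >= n)
    truth = GroundTruth(r_arr, [template.class_label] * len(r_arr), boundary)
    record = ECGRecord(record_id=f"syn-{rhythm.seed}", fs=float(fs), samples=signal)
    return record, truth


def concatenate(
    parts: list[tuple[ECGRecord, GroundTruth]], record_id: str = "syn-stream"
) -> tuple[ECGRecord, GroundTruth]:
    """Concatenate generated records into one stream with shifted truth."""
    if not parts:
        raise SpecificationError("nothing to concatenate")
    sigs, r_all, labels = [], [], []
    offset = 0
    for rec, truth in parts:
        sigs.append(rec.samples)
        r_all.append(truth.r_indices + offset)
        labels.extend(truth.labels)
        offset += len(rec)
    signal = np.concatenate(sigs)
    r = np.concatenate(r_all) if r_all else np.array([], dtype=np.int64)
    boundary = (r < SEGMENT_PRE) | (r + SEGMENT_POST >= len(signal))
    truth = GroundTruth(r, labels, boundary)
    return ECGRecord(record_id=record_id, fs=float(FS_HZ), samples=signal), truth


def generate_dataset(
    specs: list[tuple[RhythmSpec, BeatTemplate]],
    out_dir: str | Path,
    packet_seconds: float = 5.0,
) -> Path:
    """Generate records, concatenate, and write a streaming packet directory.

    The directory holds consecutive non-overlapping packet CSV files (the
    last may be short), a YAML manifest fixing stream order, and a
    ``truth.csv`` with the ground-truth R indices and labels.
    """
    from . import io as ecg_io  # deferred: io depends only on core

    if not specs:
        raise SpecificationError("spec list is empty")
    if packet_seconds <= 0:
        raise SpecificationError("packet_seconds must be positive")
    parts = [generate_record(r, t) for r, t in specs]
    record, truth = concatenate(parts)
    record.annotations = truth
    return ecg_io.write_packets(record, Path(out_dir), packet_seconds=packet_seconds)
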