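"""Core in-memory containers shared across the toolkit."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecificationError
from .study import FS_HZ, PACKET_SECONDS, SEGMENT_POST, SEGMENT_PRE


@dataclass
class GroundTruth:
    """Known R-peak positions and per-beat class labels.

    ``boundary`` flags beats that lack the full 69-sample left / 130-sample
    right context inside their source record and therefore cannot be cut to a
    complete 200-sample beat.
    """

    r_indices: np.ndarray
    labels: list[str]
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)
        if len(self.labels) != len(self.r_indices):
            raise SpecificationError("labels and r_indices must align")
        if len(self.r_indices) > 1 and not np.all(np.diff(self.r_indices) > 0):
            raise SpecificationError("r_indices must be strictly increasing")
        if self.boundary is None:
            self.boundary = np.zeros(len(self.r_indices), dtype=bool)
        else:
            self.boundary = np.asarray(self.boundary, dtype=bool)

    def __len__(self) -> int:
        return len(self.r_indices)

    def interior(
        self, n_samples: int, pre: int = SEGMENT_PRE, post: int = SEGMENT_POST
    ) -> "GroundTruth":
        """Truth restricted to beats with full segmentation context."""
        keep = (self.r_indices >= pre) & (self.r_indices + post < n_samples)
        return GroundTruth(
            self.r_indices[keep],
            [l for l, k in zip(self.labels, keep) if k],
            np.zeros(int(keep.sum()), dtype=bool),
        )

    def shifted(self, offset: int) -> "GroundTruth":
        return GroundTruth(self.r_indices + offset, list(self.labels), self.boundary.copy())


@dataclass
class ECGRecord:
    """A sampled single-lead ECG signal in millivolts."""

    record_id: str
    fs: float
    samples: np.ndarray
    annotations: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise SpecificationError("sampling rate must be positive")
        if self.samples.size == 0:
            raise SpecificationError("record has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise SpecificationError("record contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EpochPacket:
    """One streaming unit: nominally 5 s (1800 samples at 360 Hz)."""

    packet_index: int
    start_sample: int
    samples: np.ndarray
    record_id: str = ""
    nominal_seconds: float = float(PACKET_SECONDS)
    quarantined: bool = False  # unparseable on read; samples substituted with zeros

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def is_short(self) -> bool:
        return len(self.samples) < round(self.nominal_seconds * FS_HZ)

    def __len__(self) -> int:
        return len(self.samples)
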