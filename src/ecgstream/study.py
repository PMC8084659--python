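"""Reference study design: sampling arithmetic and MIT/BIH record layout.

The pipeline is built around single-lead ECG sampled at 360 Hz, processed in
5-second micro-batch packets, with beats cut to a fixed 200-sample window
(69 samples before the R-peak, the R-peak sample, 130 samples after).  The
reference train/test design draws on five MIT/BIH arrhythmia-database
records; the per-class sample budgets below define the size of the training
matrix (``M`` labeled beats of width 200 samples).
"""

from __future__ import annotations

from enum import Enum

FS_HZ: int = 360
PACKET_SECONDS: int = 5
PACKET_SAMPLES: int = PACKET_SECONDS * FS_HZ  # 1800

#: beat window around the R-peak: PRE samples + the R sample + POST samples
SEGMENT_PRE: int = 69
SEGMENT_POST: int = 130
BEAT_SAMPLES: int = SEGMENT_PRE + 1 + SEGMENT_POST  # 200

N_FEATURES: int = 25
N_CLASSES: int = 3


class BeatClass(str, Enum):
    """The three target rhythm/beat classes, plus OTHER for unmapped symbols."""

    NORMAL = "NORMAL"
    RBBB = "RBBB"
    AF = "AF"
    OTHER = "OTHER"

    def __str__(self) -> str:  # plain value in CSV / reports
        return self.value


#: fixed class ordering used everywhere (vote tie-breaks, score columns)
CLASS_ORDER: tuple[str, str, str] = (
    BeatClass.NORMAL.value,
    BeatClass.RBBB.value,
    BeatClass.AF.value,
)

#: training budget: class -> (MIT/BIH record id, number of 360 Hz samples)
TRAIN_DESIGN: dict[str, tuple[str, int]] = {
    BeatClass.NORMAL.value: ("205", 400_000),
    BeatClass.RBBB.value: ("118", 400_200),
    BeatClass.AF.value: ("232", 311_600),
}

#: test budget: class -> (MIT/BIH record id, number of 360 Hz samples)
TEST_DESIGN: dict[str, tuple[str, int]] = {
    BeatClass.NORMAL.value: ("115", 104_400),
    BeatClass.RBBB.value: ("124", 129_600),
    BeatClass.AF.value: ("232", 124_200),
}


def total_samples(design: dict[str, tuple[str, int]]) -> int:
    """Total number of annotated samples across the per-class budgets."""
    return sum(n for _, n in design.values())


def beat_budget(design: dict[str, tuple[str, int]]) -> int:
    """Number of fixed-width training tuples implied by a sample budget.

    Each labeled beat occupies exactly ``BEAT_SAMPLES`` (200) samples, so the
    tuple count is the integer quotient of the sample budget.
    """
    return total_samples(design) // BEAT_SAMPLES
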