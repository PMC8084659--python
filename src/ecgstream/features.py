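"""Dyadic subband wavelet reduction of 200-sample beats to 25 coefficients.

One decomposition level convolves the signal with a high-pass and a low-pass
analysis filter and keeps every second output (Nyquist: half the samples are
removed at each level):

    Y_high[k] = sum_n S[n] * H[2k - n],      Y_low[k] = sum_n S[n] * L[2k - n]

evaluated under periodic extension of ``S`` with the filter origin placed at
half the filter length, so every level halves the length *exactly* and, for
orthonormal filters, conserves energy (Parseval).  The low-pass
(approximation) branch is fed forward: 200 -> 100 -> 50 -> 25, and the final
25-coefficient approximation is the beat's feature vector.

With this origin convention the step coincides exactly with PyWavelets'
``mode="periodization"`` single-level DWT, which tests use as an independent
cross-check; for Haar it reduces to ``(S[2k] + S[2k+1]) / sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import SpecificationError
from .preprocess import Beat
from .study import N_FEATURES

DEFAULT_WAVELET = "db4"


@dataclass
class FeatureVector:
    """The 25 approximation coefficients describing one beat."""

    values: np.ndarray
    label: str | None = None
    source_r_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != N_FEATURES:
            raise SpecificationError(
                f"feature vector must have {N_FEATURES} coefficients"
            )
        if not np.all(np.isfinite(self.values)):
            raise SpecificationError("feature vector contains non-finite values")


def wavelet_filters(wavelet: str = DEFAULT_WAVELET) -> tuple[np.ndarray, np.ndarray]:
    """Analysis (decomposition) low-pass and high-pass filter taps."""
    w = pywt.Wavelet(wavelet)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(
        w.dec_hi, dtype=np.float64
    )


def subband_step(
    signal: np.ndarray, low_taps: np.ndarray, high_taps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One decomposition level: (approximation, detail), each half length.

    Requires an even-length input (guaranteed along the 200->100->50->25
    chain by periodized boundary handling).
    """
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    if n % 2:
        raise SpecificationError("subband step requires an even-length signal")
    low = np.asarray(low_taps, dtype=np.float64)
    high = np.asarray(high_taps, dtype=np.float64)
    if len(low) != len(high):
        raise SpecificationError("analysis filters must have equal length")
    half = len(low) // 2

    def _branch(f: np.ndarray) -> np.ndarray:
        # y[k] = sum_j f[j] * x[(2k + half - j) mod n]
        acc = np.zeros(n)
        for j, fj in enumerate(f):
            acc += fj * np.roll(x, j - half)
        return acc[0::2].copy()

    return _branch(low), _branch(high)


def extract_features(
    beat: Beat | np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    target_len: int = N_FEATURES,
) -> FeatureVector:
    """Reduce a 200-sample beat to its ``target_len`` approximation vector.

    The approximation branch is halved until its length reaches
    ``target_len``; for the 200-sample beat window and the default target of
    25 this is exactly three halvings.  ``target_len`` must be reachable from
    the beat length by repeated halving.
    """
    if isinstance(beat, Beat):
        x = beat.samples
        label = beat.label
        r_index = beat.r_index
    else:
        x = np.asarray(beat, dtype=np.float64)
        label = None
        r_index = -1

    n = len(x)
    m, levels = n, 0
    while m > target_len and m % 2 == 0:
        m //= 2
        levels += 1
    if m != target_len:
        raise SpecificationError(
            f"target length {target_len} is not reachable from {n} by halving"
        )

    low, high = wavelet_filters(wavelet)
    approx = x
    for _ in range(levels):
        approx, _detail = subband_step(approx, low, high)
    return FeatureVector(values=approx, label=label, source_r_index=r_index)


def features_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    if not vectors:
        raise SpecificationError("no feature vectors")
    return np.stack([v.values for v in vectors])
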