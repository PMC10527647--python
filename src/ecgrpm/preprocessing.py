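"""Wavelet denoising and beat/window segmentation.

Denoising decomposes the signal with a db6 discrete wavelet transform
(5 levels by default), shrinks detail coefficients with the compromise
soft-hard threshold function, and reconstructs. The compromise function
interpolates between hard thresholding (alpha = 0, coefficients above the
threshold kept untouched) and soft thresholding (alpha = 1, coefficients
shrunk by the full threshold):

    f(Y) = sign(Y) * (|Y| - alpha * lam)   if |Y| >= lam
         = 0                               otherwise

Segmentation turns an annotated record into fixed-length excerpts: a
300-sample window around each annotated R peak (99 samples before, the
peak, 200 after), and non-overlapping 5-second windows labeled N when
every beat inside them is normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np
import pywt

from .io import CLASSES, ECGRecord

logger = logging.getLogger(__name__)

#: Samples taken before / after the annotated R peak for a single beat.
BEAT_PRE, BEAT_POST = 99, 200
BEAT_LEN = BEAT_PRE + 1 + BEAT_POST          # 300 samples
FIVE_SECOND_S = 5.0                          # window duration in seconds


class SegmentKind(str, Enum):
    SINGLE_BEAT = "single_beat"
    FIVE_SECOND = "five_second"


@dataclass(frozen=True)
class Segment:
    """A fixed-length labeled 1-D excerpt of an ECG record."""

    samples: np.ndarray
    label: str
    kind: SegmentKind
    source_record: str
    anchor_index: int      # R-peak index (single beat) or window start (5 s)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.kind is SegmentKind.SINGLE_BEAT and len(self.samples) != BEAT_LEN:
            raise ValueError(f"single beat must have {BEAT_LEN} samples")
        if self.kind is SegmentKind.FIVE_SECOND and self.label != "N":
            raise ValueError("five-second segments carry label N only")


@dataclass(frozen=True)
class DenoiseParams:
    """Parameters of the compromise soft-hard wavelet denoiser.

    wavelet : str
        Wavelet family; db6 matches QRS morphology well.
    levels : int
        Decomposition depth; 5 levels cover the ECG energy band at 360 Hz.
    alpha : float
        Compromise weight in [0, 1]; 0 = hard, 1 = soft, 0.5 = balanced.
    threshold_rule : {"universal", "none"}
        Per-level threshold magnitude: "universal" uses
        lam = sigma * sqrt(2 ln N) with sigma the robust MAD estimate from
        the finest detail level; "none" forces lam = 0 (identity filter).
    mode : str
        DWT boundary extension mode.
    """

    wavelet: str = "db6"
    levels: int = 5
    alpha: float = 0.5
    threshold_rule: Literal["universal", "none"] = "universal"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def compromise_threshold(coefficient, lam: float, alpha: float):
    """Compromise soft-hard shrinkage of wavelet coefficient(s).

    Vectorized over ``coefficient``. ``alpha = 1`` reproduces soft
    thresholding, ``alpha = 0`` hard thresholding.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    y = np.asarray(coefficient, dtype=float)
    shrunk = np.where(np.abs(y) >= lam, np.sign(y) * (np.abs(y) - alpha * lam), 0.0)
    return shrunk if shrunk.ndim else float(shrunk)


def denoise(signal, params: DenoiseParams = DenoiseParams()) -> np.ndarray:
    """Denoise a 1-D signal; output has the same length as the input.

    Detail coefficients at every level are shrunk with
    :func:`compromise_threshold`; approximation coefficients pass through.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    levels = params.levels
    max_lev = pywt.dwt_max_level(len(x), pywt.Wavelet(params.wavelet).dec_len)
    if max_lev < levels:
        logger.warning("signal of length %d supports only %d levels (requested %d)",
                       len(x), max_lev, levels)
        levels = max(max_lev, 1)
    coeffs = pywt.wavedec(x, params.wavelet, level=levels, mode=params.mode)
    if params.threshold_rule == "none":
        lam = 0.0
    else:
        # robust noise estimate from the finest-scale detail coefficients
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        lam = sigma * np.sqrt(2.0 * np.log(len(x)))
    shrunk = [coeffs[0]] + [compromise_threshold(d, lam, params.alpha)
                            for d in coeffs[1:]]
    return pywt.waverec(shrunk, params.wavelet, mode=params.mode)[: len(x)]


def denoise_record(record: ECGRecord,
                   params: DenoiseParams = DenoiseParams()) -> ECGRecord:
    """Denoise a whole record's signal, keeping annotations untouched."""
    from dataclasses import replace
    return replace(record, samples=denoise(record.samples, params))


def segment_single_beats(record: ECGRecord) -> list[Segment]:
    """One 300-sample segment per labeled annotation, centered on the R peak.

    Each annotation at index ``r`` yields samples ``[r-99, r+200]``
    inclusive; beats too close to either record edge are dropped (logged).
    """
    n = len(record.samples)
    out: list[Segment] = []
    dropped = 0
    for r, label in record.annotations:
        lo, hi = r - BEAT_PRE, r + BEAT_POST
        if lo < 0 or hi >= n:
            dropped += 1
            continue
        out.append(Segment(
            samples=record.samples[lo: hi + 1],
            label=label, kind=SegmentKind.SINGLE_BEAT,
            source_record=record.record_id, anchor_index=r,
        ))
    if dropped:
        logger.info("record %s: dropped %d out-of-bounds beats",
                    record.record_id, dropped)
    return out


def segment_five_second(record: ECGRecord) -> list[Segment]:
    """Non-overlapping 5-s windows from sample 0, kept iff all-normal.

    A window is retained, labeled N, iff it contains at least one
    annotation and every annotation inside it has class N. The trailing
    partial window is discarded.
    """
    win = int(round(FIVE_SECOND_S * record.fs))
    n = len(record.samples)
    ann = record.annotations
    out: list[Segment] = []
    for start in range(0, n - win + 1, win):
        inside = [lab for idx, lab in ann if start <= idx < start + win]
        if inside and all(lab == "N" for lab in inside):
            out.append(Segment(
                samples=record.samples[start: start + win],
                label="N", kind=SegmentKind.FIVE_SECOND,
                source_record=record.record_id, anchor_index=start,
            ))
    return out
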