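"""Time-series-to-image encoders for ECG segments.

A 1-D segment is z-scored, optionally reduced with Piecewise Aggregate
Approximation (PAA), and mapped to an m x m matrix by one of four
encoders:

* **RPM** (relative position matrix): ``M[i, j] = x~_j - x~_i``, each row
  redrawing the whole series relative to one reference time step;
* **GASF** (Gramian angular summation field): the series rescaled to
  [-1, 1] is embedded as angles ``phi = arccos(x)`` and
  ``G[i, j] = cos(phi_i + phi_j)``;
* **RP** (recurrence plot): binary similarity ``|x~_i - x~_j| <= eps``
  with eps an empirical distance quantile, black where recurrent;
* **MTF** (Markov transition field): ``T[i, j]`` is the first-order
  transition probability between the quantile bins of ``x~_i`` and
  ``x~_j``.

Real-valued matrices are min-max scaled to 8-bit gray levels and can be
rendered to a fixed pixel resolution with bilinear resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .preprocessing import Segment, SegmentKind

logger = logging.getLogger(__name__)

ENCODERS = ("RPM", "GASF", "RP", "MTF")


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the segment-to-image pipeline.

    encoder : {"RPM", "GASF", "RP", "MTF"}
    paa_length : int or None
        Target series length m before encoding; None keeps the native
        length. PAA is applied only when the segment is longer than m.
        Five-second windows (1800 samples) default to m = 300.
    render_px : int
        Output raster resolution (square), default 224.
    rp_epsilon_quantile : float
        Recurrence threshold as a quantile of off-diagonal distances.
    mtf_bins : int
        Number of quantile bins Q for the transition field.
    """

    encoder: str = "RPM"
    paa_length: Optional[int] = None
    render_px: int = 224
    rp_epsilon_quantile: float = 0.10
    mtf_bins: int = 8

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}; choose from {ENCODERS}")
        if self.paa_length is not None and self.paa_length < 2:
            raise ValueError("paa_length must be >= 2")
        if self.render_px < 8:
            raise ValueError("render_px must be >= 8")
        if not 0.0 < self.rp_epsilon_quantile < 1.0:
            raise ValueError("rp_epsilon_quantile must be in (0, 1)")
        if self.mtf_bins < 2:
            raise ValueError("mtf_bins must be >= 2")


@dataclass(frozen=True)
class GrayImage:
    """An m x m 8-bit gray-level matrix plus its fixed-resolution raster."""

    matrix: np.ndarray          # m x m uint8
    encoder: str
    source: dict
    rendered: np.ndarray        # render_px x render_px uint8


def zscore(series) -> np.ndarray:
    """Standardize to mean 0 and population standard deviation 1.

    A constant series maps to all zeros (with a logged warning).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    sigma = x.std()          # population sigma (ddof=0)
    if sigma == 0:
        logger.warning("constant series: z-score returns zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sigma


def paa(series, m: int) -> np.ndarray:
    """Piecewise aggregate approximation to length m by block means.

    Frame k averages samples with indices in [floor(k*n/m),
    floor((k+1)*n/m)); m = n returns the series unchanged.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not 2 <= m <= n:
        raise ValueError(f"need 2 <= m <= len(series); got m={m}, n={n}")
    if m == n:
        return x.copy()
    edges = (np.arange(m + 1) * n) // m
    return np.array([x[edges[k]: edges[k + 1]].mean() for k in range(m)])


def rpm_matrix(normalized) -> np.ndarray:
    """Relative position matrix: ``M[i, j] = x~_j - x~_i`` (anti-symmetric)."""
    x = np.asarray(normalized, dtype=float)
    return x[None, :] - x[:, None]


def gasf_matrix(normalized) -> np.ndarray:
    """Gramian angular summation field of a series rescaled to [-1, 1]."""
    x = np.asarray(normalized, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        r = np.zeros_like(x)
    else:
        r = 2.0 * (x - lo) / (hi - lo) - 1.0
    r = np.clip(r, -1.0, 1.0)
    phi = np.arccos(r)
    # cos(phi_i + phi_j) expanded to avoid building an angle-sum grid
    c, s = np.cos(phi), np.sin(phi)
    return np.outer(c, c) - np.outer(s, s)


def rp_matrix(normalized, epsilon_quantile: float = 0.10,
              binarize: bool = True) -> np.ndarray:
    """Recurrence structure of a series.

    Binarized (default): 1 where ``|x~_i - x~_j|`` is within the
    ``epsilon_quantile`` quantile of off-diagonal distances. With
    ``binarize=False`` the raw distance matrix is returned instead.
    """
    x = np.asarray(normalized, dtype=float)
    d = np.abs(x[None, :] - x[:, None])
    if not binarize:
        return d
    off = d[~np.eye(len(x), dtype=bool)]
    eps = np.quantile(off, epsilon_quantile) if off.size else 0.0
    return (d <= eps).astype(float)


def mtf_matrix(normalized, n_bins: int = 8) -> np.ndarray:
    """Markov transition field over empirical quantile bins.

    Bin edges are quantiles of the series itself; values on a boundary go
    to the lower bin. ``T[i, j]`` is the row-normalized first-order
    transition probability from the bin of ``x~_i`` to the bin of
    ``x~_j``; rows from never-left bins are zero.
    """
    x = np.asarray(normalized, dtype=float)
    q = min(n_bins, len(np.unique(x)))
    edges = np.quantile(x, np.linspace(0, 1, q + 1)[1:-1]) if q > 1 else []
    # side="left": a value equal to an edge falls in the lower bin
    bins = np.searchsorted(edges, x, side="left") if q > 1 else np.zeros(len(x), int)
    w = np.zeros((q, q))
    np.add.at(w, (bins[:-1], bins[1:]), 1.0)
    rowsum = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(rowsum > 0, w / rowsum, 0.0)
    return w[np.ix_(bins, bins)]


def to_gray(matrix) -> np.ndarray:
    """Min-max scale a real matrix to integer gray levels in [0, 255].

    Rounding is half-up; a constant matrix maps to all zeros (logged).
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix")
    lo, hi = m.min(), m.max()
    if hi == lo:
        logger.warning("degenerate matrix range: gray image is all zeros")
        return np.zeros(m.shape, dtype=np.uint8)
    # divide before multiplying: for an anti-symmetric matrix (lo = -hi)
    # the diagonal then hits 0.5 exactly and rounds half-up to 128
    scaled = 255.0 * ((m - lo) / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)       # round half up


def render(matrix, px: int) -> np.ndarray:
    """Bilinear resample an 8-bit gray matrix to px x px."""
    if px < 8:
        raise ValueError("px must be >= 8")
    m = np.asarray(matrix, dtype=np.uint8)
    if m.shape == (px, px):
        return m.copy()
    img = Image.fromarray(m, mode="L").resize((px, px), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def encode(segment: Segment, config: EncoderConfig = EncoderConfig()) -> GrayImage:
    """Full segment-to-image pipeline: z-score, PAA, encoder, gray, render."""
    x = zscore(segment.samples)
    m = config.paa_length
    if m is None and segment.kind is SegmentKind.FIVE_SECOND:
        m = 300
    if m is not None and len(x) > m:
        x = paa(x, m)
    elif m is not None and len(x) < m:
        raise ValueError(f"segment length {len(x)} < paa_length {m}")

    if config.encoder == "RPM":
        gray = to_gray(rpm_matrix(x))
    elif config.encoder == "GASF":
        gray = to_gray(gasf_matrix(x))
    elif config.encoder == "RP":
        rec = rp_matrix(x, config.rp_epsilon_quantile)
        gray = np.where(rec > 0, 0, 255).astype(np.uint8)   # black = similar
    else:  # MTF
        gray = to_gray(mtf_matrix(x, config.mtf_bins))

    source = {
        "record": segment.source_record,
        "kind": segment.kind.value,
        "label": segment.label,
        "anchor_index": segment.anchor_index,
        "m": int(gray.shape[0]),
    }
    return GrayImage(matrix=gray, encoder=config.encoder, source=source,
                     rendered=render(gray, config.render_px))


def save_png(image: GrayImage, path: str | Path) -> Path:
    """Write the rendered raster as an 8-bit grayscale PNG."""
    path = Path(path)
    Image.fromarray(image.rendered, mode="L").save(path, format="PNG")
    return path
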