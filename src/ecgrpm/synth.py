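"""Seeded synthetic annotated ECG with five distinguishable beat types.

Beat templates are sums of Gaussian bumps parameterized per class to
echo the textbook morphologies — normal (N): P wave, narrow QRS, upright
T; left/right bundle branch block (L/R): widened, slurred QRS with
discordant repolarization; atrial premature beat (A): altered P wave on
a narrow QRS; ventricular premature beat (V): wide, large-amplitude
biphasic complex without a P wave. Realism is not the goal: the classes
are built to be mutually distinct relative to the within-class jitter,
so they exercise the full pipeline. The R peak sits exactly at sample 99
of every 300-sample template, matching the beat segmentation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .io import CLASSES, ECGRecord
from .preprocessing import BEAT_LEN, BEAT_PRE

#: (center offset from R peak, amplitude in mV, width in samples) per bump.
#: Widths assume 360 Hz sampling.
TEMPLATE_BUMPS: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "N": ((-54, 0.15, 10), (-3, -0.10, 2.5), (0, 1.00, 3), (4, -0.20, 3),
          (100, 0.30, 22)),
    "L": ((0, 1.00, 12), (26, 0.40, 8), (105, -0.35, 24)),
    "R": ((-10, 0.25, 3), (0, 1.00, 4), (16, -0.55, 9), (34, 0.35, 11),
          (105, 0.20, 20)),
    "A": ((-40, -0.20, 7), (-3, -0.10, 2.5), (0, 0.95, 3), (4, -0.18, 3),
          (95, 0.18, 18)),
    "V": ((0, 1.30, 10), (40, -0.85, 14), (115, -0.25, 20)),
}


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic record.

    fs : sampling rate in Hz (360 matches the target database).
    n_beats : beats per class, keyed by class label.
    rr_interval : mean R-to-R spacing in samples (320 ~ 67 bpm at 360 Hz).
    rr_jitter : fractional standard deviation of the spacing.
    amp_jitter : fractional within-class morphology jitter.
    noise_snr_db : additive white-noise level relative to the clean
        signal power; None disables noise.
    baseline_wander_mv / baseline_wander_hz : slow sinusoidal drift.
    """

    fs: float = 360.0
    n_beats: Mapping[str, int] = field(
        default_factory=lambda: {c: 50 for c in CLASSES})
    rr_interval: int = 320
    rr_jitter: float = 0.03
    amp_jitter: float = 0.05
    noise_snr_db: Optional[float] = 20.0
    baseline_wander_mv: float = 0.05
    baseline_wander_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rr_interval <= 300:
            raise ValueError("rr_interval must exceed 300 samples so beat "
                             "windows can stay disjoint")
        if any(v < 0 for v in self.n_beats.values()):
            raise ValueError("beat counts must be >= 0")


def _bump(t: np.ndarray, center: float, amp: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def synth_beat(label: str, fs: float = 360.0,
               rng: np.random.Generator | None = None,
               amp_jitter: float = 0.0) -> np.ndarray:
    """One 300-sample beat template of the given class, R peak at index 99.

    With ``amp_jitter`` > 0 each bump's amplitude and width are perturbed
    multiplicatively (the R bump keeps its dominance so the peak index
    stays at 99).
    """
    if label not in TEMPLATE_BUMPS:
        raise ValueError(f"unknown label {label!r}; choose from {CLASSES}")
    rng = rng or np.random.default_rng()
    scale = fs / 360.0                    # widths/offsets defined at 360 Hz
    t = np.arange(BEAT_LEN, dtype=float) - BEAT_PRE
    beat = np.zeros(BEAT_LEN)
    for center, amp, width in TEMPLATE_BUMPS[label]:
        if amp_jitter > 0:
            amp = amp * (1.0 + amp_jitter * rng.standard_normal())
            width = width * (1.0 + 0.5 * amp_jitter * rng.standard_normal())
        beat += _bump(t, center * scale, amp, max(width * scale, 0.5))
    return beat


def synth_record(spec: SynthSpec = SynthSpec()) -> ECGRecord:
    """Assemble an annotated record from jittered, interleaved beats.

    Beats are placed at jittered RR spacing (clamped so the 300-sample
    windows stay disjoint), annotations at each R peak, then baseline
    wander and white noise are added at the configured level.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [c for c in CLASSES for _ in range(spec.n_beats.get(c, 0))]
    if not labels:
        raise ValueError("at least one beat required")
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    positions: list[int] = []
    pos = BEAT_PRE + 51                   # margin so the first window fits
    for _ in labels:
        positions.append(pos)
        gap = spec.rr_interval * (1.0 + spec.rr_jitter * rng.standard_normal())
        pos += max(int(round(gap)), BEAT_LEN + 1)
    n = positions[-1] + (BEAT_LEN - BEAT_PRE) + 51

    clean = np.zeros(n)
    annotations: list[tuple[int, str]] = []
    for p, lab in zip(positions, labels):
        clean[p - BEAT_PRE: p - BEAT_PRE + BEAT_LEN] += synth_beat(
            lab, spec.fs, rng, spec.amp_jitter)
        annotations.append((p, lab))

    signal = clean.copy()
    if spec.baseline_wander_mv > 0:
        tt = np.arange(n) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + spec.baseline_wander_mv * np.sin(
            2 * np.pi * spec.baseline_wander_hz * tt + phase)
    if spec.noise_snr_db is not None and np.isfinite(spec.noise_snr_db):
        p_sig = float(np.mean(clean ** 2))
        sigma = np.sqrt(p_sig / (10.0 ** (spec.noise_snr_db / 10.0)))
        signal = signal + sigma * rng.standard_normal(n)

    return ECGRecord(record_id=f"synth{spec.seed}", fs=spec.fs, lead="MLII",
                     samples=signal, annotations=annotations)


def add_noise(signal: np.ndarray, snr_db: float,
              rng: np.random.Generator) -> np.ndarray:
    """Additive white Gaussian noise at the given SNR relative to signal power."""
    x = np.asarray(signal, dtype=float)
    sigma = np.sqrt(float(np.mean(x ** 2)) / (10.0 ** (snr_db / 10.0)))
    return x + sigma * rng.standard_normal(len(x))


def snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """SNR of ``noisy`` against the reference ``clean``, in dB."""
    clean = np.asarray(clean, dtype=float)
    err = np.asarray(noisy, dtype=float) - clean
    return 10.0 * np.log10(float(np.mean(clean ** 2)) / float(np.mean(err ** 2)))
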