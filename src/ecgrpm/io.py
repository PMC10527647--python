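"""Annotated single-lead ECG record I/O.

Supports two on-disk dialects:

* the WFDB triple (``.hea`` text header, ``.dat`` signal in format 16 or
  212, ``.atr`` MIT annotation file), the native format of the MIT-BIH
  Arrhythmia Database;
* a plain-text CSV dialect: one column ``sample`` of amplitudes in mV,
  with a companion annotation CSV of columns ``index,symbol``.

All annotation indices are 0-based offsets into the stored signal.
"""

from __future__ import annotations

import csv
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Beat classes retained for five-class arrhythmia classification.
CLASSES = ("N", "L", "R", "A", "V")

#: Sentinel outcome for annotation symbols that are dropped.
DISCARD = "DISCARD"

# MIT annotation code <-> symbol, restricted to the codes this package
# needs (beat annotations plus a few common non-beat codes).
_ATR_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 38: "+", 14: "~",
    16: "|", 28: '"',
}
_SYMBOL_TO_ATR_CODE = {s: c for c, s in _ATR_CODE_TO_SYMBOL.items()}


@dataclass(frozen=True)
class ECGRecord:
    """A single-lead sampled ECG signal with beat annotations.

    Attributes
    ----------
    record_id : str
        Record identifier (e.g. the MIT-BIH record number).
    fs : float
        Sampling rate in Hz; must be positive.
    lead : str
        Lead name, e.g. ``"MLII"``.
    samples : numpy.ndarray
        1-D float array of amplitudes in mV.
    annotations : list of (int, str)
        ``(sample_index, symbol)`` pairs, 0-based, sorted ascending.
    """

    record_id: str
    fs: float
    lead: str
    samples: np.ndarray
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        n = len(self.samples)
        anns = sorted(((int(i), str(s)) for i, s in self.annotations))
        for i, _ in anns:
            if not 0 <= i < n:
                raise ValueError(f"annotation index {i} outside signal of length {n}")
        object.__setattr__(self, "annotations", anns)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class LabelScheme:
    """Maps raw annotation symbols to the five beat classes or DISCARD."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        retained = {v for v in self.mapping.values() if v != DISCARD}
        if not retained <= set(CLASSES):
            raise ValueError(f"retained classes {retained} not within {CLASSES}")

    def outcome(self, symbol: str) -> str:
        """Class label for ``symbol``, or DISCARD (default for unknowns)."""
        return self.mapping.get(symbol, DISCARD)


#: Default scheme: the five MIT-BIH beat symbols map to themselves,
#: everything else is discarded.
DEFAULT_SCHEME = LabelScheme({c: c for c in CLASSES})


def map_labels(record: ECGRecord, scheme: LabelScheme = DEFAULT_SCHEME) -> ECGRecord:
    """Apply a label scheme to a record's annotations.

    Annotations whose symbol maps to DISCARD are removed (unknown symbols
    are discarded with a logged warning); the rest have their symbol
    replaced by the class label. Order and sample indices are preserved.
    """
    kept: list[tuple[int, str]] = []
    unknown: set[str] = set()
    for idx, sym in record.annotations:
        out = scheme.outcome(sym)
        if out == DISCARD:
            if sym not in scheme.mapping:
                unknown.add(sym)
            continue
        kept.append((idx, out))
    if unknown:
        logger.warning(
            "record %s: discarding unmapped annotation symbols %s",
            record.record_id, sorted(unknown),
        )
    return replace(record, annotations=kept)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_record(
    signal_path: str | Path,
    annotation_path: str | Path | None = None,
    *,
    fs: float = 360.0,
    lead: str = "MLII",
    record_id: str | None = None,
) -> ECGRecord:
    """Read the plain-CSV dialect (column ``sample``; sidecar ``index,symbol``).

    If ``annotation_path`` is None, ``<signal stem>.ann.csv`` next to the
    signal file is used when present.
    """
    signal_path = Path(signal_path)
    with open(signal_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample" not in reader.fieldnames:
            raise ValueError(f"{signal_path}: CSV must have a 'sample' column")
        samples = np.array([float(row["sample"]) for row in reader])

    if annotation_path is None:
        cand = signal_path.with_suffix("").with_suffix(".ann.csv")
        annotation_path = cand if cand.exists() else None
    annotations: list[tuple[int, str]] = []
    if annotation_path is not None:
        with open(annotation_path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                annotations.append((int(row["index"]), row["symbol"]))

    rec = ECGRecord(
        record_id=record_id or signal_path.stem,
        fs=fs, lead=lead, samples=samples, annotations=annotations,
    )
    _log_record(rec)
    return rec


def write_csv_record(record: ECGRecord, signal_path: str | Path) -> tuple[Path, Path]:
    """Write a record as ``<path>`` plus ``<stem>.ann.csv``; returns both paths."""
    signal_path = Path(signal_path)
    with open(signal_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample"])
        for v in record.samples:
            writer.writerow([repr(float(v))])
    ann_path = signal_path.with_suffix("").with_suffix(".ann.csv")
    with open(ann_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "symbol"])
        for idx, sym in record.annotations:
            writer.writerow([idx, sym])
    return signal_path, ann_path


# ---------------------------------------------------------------------------
# WFDB triple (.hea / .dat / .atr)
# ---------------------------------------------------------------------------

@dataclass
class _SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = []
    with open(hea_path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    if not lines:
        raise ValueError(f"{hea_path}: empty header")
    head = lines[0].split()
    try:
        record_id = head[0].split("/")[0]
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{hea_path}:1: malformed record line: {lines[0]!r}") from exc
    specs: list[_SignalSpec] = []
    for lineno, line in enumerate(lines[1 : 1 + n_sig], start=2):
        tok = line.split()
        try:
            filename, fmt = tok[0], int(tok[1].split("x")[0].split(":")[0].split("+")[0])
            gain_tok = tok[2] if len(tok) > 2 else "200"
            gain_field = gain_tok.split("/")[0]
            if "(" in gain_field:
                gain_s, base_s = gain_field.rstrip(")").split("(")
                gain, baseline = float(gain_s), int(base_s)
            else:
                gain, baseline = float(gain_field), 0
            if gain == 0:
                gain = 200.0
            # description = remaining tokens after the numeric fields
            description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{lineno - 2}"
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{hea_path}:{lineno}: malformed signal line: {line!r}") from exc
        specs.append(_SignalSpec(filename, fmt, gain, baseline, description))
    return record_id, n_sig, fs, n_samples, specs


def _read_dat(dat_path: Path, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        if n_samples:
            flat = flat[: n_samples * n_sig]
        return flat.reshape(-1, n_sig).astype(int)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(int)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * len(b), dtype=int)
        flat[0::2], flat[1::2] = first, second
        if n_samples:
            flat = flat[: n_samples * n_sig]
        return flat.reshape(-1, n_sig)
    raise ValueError(f"{dat_path}: unsupported WFDB format {fmt}")


def _read_atr(atr_path: Path) -> list[tuple[int, str]]:
    raw = atr_path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = struct.unpack_from("<H", raw, i)[0]
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:          # end of file
            break
        if code == 59:                        # SKIP: next 4 bytes = long delta
            if i + 4 > len(raw):
                break
            hi, lo = struct.unpack_from("<HH", raw, i)
            i += 4
            t += (hi << 16) | lo
        elif code == 63:                      # AUX: skip payload (padded to even)
            i += delta + (delta & 1)
        elif code in (60, 61, 62):            # NUM/SUBTYP/CHAN: no time advance
            continue
        else:
            t += delta
            out.append((t, _ATR_CODE_TO_SYMBOL.get(code, "Q")))
    return out


def read_wfdb_record(path: str | Path, lead: str = "MLII") -> ECGRecord:
    """Read one lead of a WFDB record triple ``<path>.{hea,dat,atr}``.

    ``path`` is the record path without extension. Annotation times are
    native WFDB sample indices, already 0-based relative to signal start.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    record_id, n_sig, fs, n_samples, specs = _parse_header(hea)
    leads = [s.description for s in specs]
    if lead not in leads:
        raise ValueError(f"lead not found: {lead!r}; available leads: {leads}")
    ch = leads.index(lead)
    spec = specs[ch]
    dat = base.parent / spec.filename
    digital = _read_dat(dat, spec.fmt, n_sig, n_samples)
    samples = (digital[:, ch] - spec.baseline) / spec.gain
    atr = base.with_suffix(".atr")
    annotations = _read_atr(atr) if atr.exists() else []
    annotations = [(t, s) for t, s in annotations if 0 <= t < len(samples)]
    rec = ECGRecord(record_id=record_id, fs=fs, lead=lead,
                    samples=samples, annotations=annotations)
    _log_record(rec)
    return rec


def write_wfdb_record(record: ECGRecord, path: str | Path, *,
                      gain: float = 200.0) -> Path:
    """Write a single-lead record as a WFDB triple in format 16.

    Samples are quantized to ``round(mV * gain)`` 16-bit integers; the
    declared gain reverses this on read.
    """
    base = Path(path)
    digital = np.clip(np.rint(record.samples * gain), -32768, 32767).astype("<i2")
    dat_name = base.name + ".dat"
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{base.name} 1 {record.fs:g} {len(digital)}\n")
        fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {record.lead}\n")
    base.with_suffix(".dat").write_bytes(digital.tobytes())
    with open(base.with_suffix(".atr"), "wb") as fh:
        prev = 0
        for idx, sym in record.annotations:
            code = _SYMBOL_TO_ATR_CODE.get(sym, 13)
            delta = idx - prev
            while delta > 1023:               # long gap -> SKIP word
                fh.write(struct.pack("<H", 59 << 10))
                fh.write(struct.pack("<HH", delta >> 16, delta & 0xFFFF))
                delta = 0
                prev = idx
            fh.write(struct.pack("<H", (code << 10) | delta))
            prev = idx
        fh.write(struct.pack("<H", 0))
    return base


def read_record(path: str | Path, lead: str = "MLII", **kwargs) -> ECGRecord:
    """Read an ECG record, dispatching on on-disk format.

    A ``.csv`` path (or a path whose ``.hea`` sibling is absent but whose
    ``.csv`` exists) is read as the CSV dialect; otherwise as WFDB.
    """
    p = Path(path)
    if p.suffix == ".csv":
        return read_csv_record(p, lead=lead, **kwargs)
    if p.with_suffix(".hea").exists():
        return read_wfdb_record(p, lead=lead)
    if p.with_suffix(".csv").exists():
        return read_csv_record(p.with_suffix(".csv"), lead=lead, **kwargs)
    raise FileNotFoundError(f"no WFDB header or CSV found for {path}")


def _log_record(rec: ECGRecord) -> None:
    logger.info(
        "read record_id=%s fs=%g lead=%s n_samples=%d n_annotations=%d",
        rec.record_id, rec.fs, rec.lead, len(rec.samples), len(rec.annotations),
    )
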