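"""Stage orchestration: synth -> segment -> encode -> train -> evaluate.

Stages communicate through a run directory with CSV manifests and
sidecar JSON, so any stage can be re-run in isolation. Each stage logs a
hash of its configuration; reruns with identical config and seed are
bit-identical wherever the stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as ecg_io
from .evaluation import confusion, evaluate
from .imaging import EncoderConfig, encode, save_png
from .model import (NetworkSpec, TrainConfig, load_checkpoint, predict_proba,
                    save_checkpoint, train)
from .preprocessing import (DenoiseParams, SegmentKind, denoise_record,
                            segment_five_second, segment_single_beats)
from .synth import SynthSpec, synth_record

logger = logging.getLogger(__name__)

STAGES = ("synth", "segment", "denoise", "encode", "train", "evaluate",
          "reproduce-counts")


@dataclass
class PipelineConfig:
    """Everything a run needs, loadable from one YAML file."""

    out_dir: Path = Path("run")
    records: list[str] = field(default_factory=list)   # paths for real data
    lead: str = "MLII"
    synth: SynthSpec = field(default_factory=SynthSpec)
    denoise: Optional[DenoiseParams] = field(default_factory=DenoiseParams)
    segment_kinds: tuple[str, ...] = ("single_beat",)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "out_dir" in raw:
            kw["out_dir"] = Path(raw["out_dir"])
        for key in ("records", "lead", "segment_kinds"):
            if key in raw:
                kw[key] = raw[key]
        if "segment_kinds" in kw:
            kw["segment_kinds"] = tuple(kw["segment_kinds"])
        for key, typ in (("synth", SynthSpec), ("encoder", EncoderConfig),
                         ("network", NetworkSpec), ("training", TrainConfig)):
            if key in raw:
                sub = dict(raw[key])
                if key == "network" and "attention_sites" in sub:
                    sub["attention_sites"] = tuple(sub["attention_sites"])
                kw[key] = typ(**sub)
        if "denoise" in raw:
            kw["denoise"] = (DenoiseParams(**raw["denoise"])
                             if raw["denoise"] is not None else None)
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> Path:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        data = {
            "out_dir": str(self.out_dir), "records": list(self.records),
            "lead": self.lead, "synth": enc(self.synth),
            "denoise": enc(self.denoise) if self.denoise else None,
            "segment_kinds": list(self.segment_kinds),
            "encoder": enc(self.encoder), "network": enc(self.network),
            "training": enc(self.training),
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(
            self.to_dict(), default=str)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir), "records": list(self.records),
            "lead": self.lead, "synth": dataclasses.asdict(self.synth),
            "denoise": dataclasses.asdict(self.denoise) if self.denoise else None,
            "segment_kinds": list(self.segment_kinds),
            "encoder": dataclasses.asdict(self.encoder),
            "network": dataclasses.asdict(self.network),
            "training": dataclasses.asdict(self.training),
        }


# ---------------------------------------------------------------------------
# In-memory dataset builder (used by stages, tests and the demo script)
# ---------------------------------------------------------------------------

def build_image_dataset(spec: SynthSpec,
                        encoder: EncoderConfig = EncoderConfig(),
                        denoise_params: Optional[DenoiseParams] = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a record and return (images, labels) for training.

    images: uint8 (N, render_px, render_px); labels: array of class strings.
    """
    record = ecg_io.map_labels(synth_record(spec))
    if denoise_params is not None:
        record = denoise_record(record, denoise_params)
    segments = segment_single_beats(record)
    images = np.stack([encode(s, encoder).rendered for s in segments])
    labels = np.array([s.label for s in segments])
    return images, labels


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"{needed_by}: missing upstream artifact {path}; "
            f"run the '{stage}' stage first")


def _load_records(config: PipelineConfig) -> list[ecg_io.ECGRecord]:
    if config.records:
        return [ecg_io.read_record(p, lead=config.lead)
                for p in config.records]
    manifest = config.out_dir / "records.csv"
    _require(manifest, "synth", "segment")
    df = pd.read_csv(manifest)
    return [ecg_io.read_record(p, lead=config.lead) for p in df["path"]]


def stage_synth(config: PipelineConfig) -> Path:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    record = synth_record(config.synth)
    base = out / "records" / record.record_id
    base.parent.mkdir(exist_ok=True)
    ecg_io.write_wfdb_record(record, base)
    manifest = out / "records.csv"
    pd.DataFrame([{"path": str(base), "record_id": record.record_id,
                   "fs": record.fs, "n_annotations": len(record.annotations)}]
                 ).to_csv(manifest, index=False)
    logger.info("synth [%s]: wrote %s", config.config_hash(), base)
    return manifest


def stage_segment(config: PipelineConfig) -> Path:
    """Denoise (optional) and segment all records; store arrays + manifest."""
    out = config.out_dir
    records = [ecg_io.map_labels(r) for r in _load_records(config)]
    if config.denoise is not None:
        records = [denoise_record(r, config.denoise) for r in records]
    rows, arrays = [], {}
    for rec in records:
        segs = []
        if "single_beat" in config.segment_kinds:
            segs += segment_single_beats(rec)
        if "five_second" in config.segment_kinds:
            segs += segment_five_second(rec)
        for k, s in enumerate(segs):
            key = f"{rec.record_id}_{s.kind.value}_{k}"
            arrays[key] = s.samples
            rows.append({"key": key, "record_id": rec.record_id,
                         "kind": s.kind.value, "label": s.label,
                         "anchor_index": s.anchor_index, "fs": rec.fs})
    np.savez(out / "segments.npz", **arrays)
    manifest = out / "segments.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    logger.info("segment [%s]: %d segments", config.config_hash(), len(rows))
    return manifest


def stage_encode(config: PipelineConfig) -> Path:
    out = config.out_dir
    _require(out / "segments.csv", "segment", "encode")
    meta = pd.read_csv(out / "segments.csv")
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    with np.load(out / "segments.npz") as data:
        for _, row in meta.iterrows():
            from .preprocessing import Segment
            seg = Segment(samples=data[row["key"]], label=row["label"],
                          kind=SegmentKind(row["kind"]),
                          source_record=str(row["record_id"]),
                          anchor_index=int(row["anchor_index"]))
            image = encode(seg, config.encoder)
            png = img_dir / f"{row['key']}.png"
            save_png(image, png)
            sidecar = {"encoder": image.encoder, "m": image.source["m"],
                       "render_px": config.encoder.render_px,
                       "label": row["label"], "source": image.source}
            png.with_suffix(".json").write_text(json.dumps(sidecar))
            rows.append({"path": str(png), "label": row["label"],
                         "kind": row["kind"]})
    manifest = out / "images.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    logger.info("encode [%s]: %d images", config.config_hash(), len(rows))
    return manifest


def _load_images(manifest: Path) -> tuple[np.ndarray, np.ndarray]:
    from PIL import Image
    df = pd.read_csv(manifest)
    images = np.stack([np.asarray(Image.open(p), dtype=np.uint8)
                       for p in df["path"]])
    return images, df["label"].to_numpy()


def stage_train(config: PipelineConfig) -> Path:
    out = config.out_dir
    _require(out / "images.csv", "encode", "train")
    images, labels = _load_images(out / "images.csv")
    net, hist, split = train(images, labels, config.network, config.training)
    save_checkpoint(net, config.network, out / "model")
    hist.to_frame().to_csv(out / "history.csv", index=False)
    np.savez(out / "split.npz",
             **{k: v for k, v in split.items()})
    config.to_yaml(out / "config.yaml")
    (out / "seed.log").write_text(f"seed={config.training.seed}\n")
    logger.info("train [%s]: best epoch %d val_acc=%.3f",
                config.config_hash(), hist.best_epoch,
                max(hist.val_acc) if hist.val_acc else float("nan"))
    return out / "model.npz"


def stage_evaluate(config: PipelineConfig) -> Path:
    out = config.out_dir
    _require(out / "model.npz", "train", "evaluate")
    net, spec = load_checkpoint(out / "model.npz")
    images, labels = _load_images(out / "images.csv")
    with np.load(out / "split.npz", allow_pickle=False) as data:
        test_idx = data["test"]
        classes = [str(c) for c in data["classes"]]
    scores = predict_proba(net, images[test_idx], spec,
                           config.training.batch_size)
    y_true = labels[test_idx]
    y_pred = np.array(classes)[scores.argmax(axis=1)]
    report = evaluate(y_true, y_pred, classes, scores)
    report.to_json(out / "report.json")
    cm = confusion(y_true, y_pred, classes)
    pd.DataFrame(cm.counts, index=classes, columns=classes
                 ).to_csv(out / "confusion.csv")
    logger.info("evaluate [%s]: test accuracy %.3f",
                config.config_hash(), report.accuracy)
    return out / "report.json"


def stage_reproduce_counts(config: PipelineConfig) -> Path:
    """Per-class beat counts and all-normal 5-s window count per record."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in _load_records(config):
        mapped = ecg_io.map_labels(rec)
        beats = segment_single_beats(mapped)
        five = segment_five_second(mapped)
        row = {"record_id": rec.record_id}
        for c in ecg_io.CLASSES:
            row[c] = sum(1 for s in beats if s.label == c)
        row["five_second_N"] = len(five)
        rows.append(row)
    df = pd.DataFrame(rows)
    total = df.drop(columns="record_id").sum()
    df = pd.concat([df, pd.DataFrame([{"record_id": "TOTAL", **total}])],
                   ignore_index=True)
    path = out / "counts.csv"
    df.to_csv(path, index=False)
    logger.info("reproduce-counts [%s]: %d records", config.config_hash(),
                len(rows))
    return path


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Dispatch one named pipeline stage; returns its primary artifact."""
    table = {
        "synth": stage_synth, "segment": stage_segment,
        "denoise": stage_segment,     # denoising happens inside segment
        "encode": stage_encode, "train": stage_train,
        "evaluate": stage_evaluate,
        "reproduce-counts": stage_reproduce_counts,
    }
    if stage not in table:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    return table[stage](config)
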