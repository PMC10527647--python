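"""Gam-ResNet18 classifier: construction, training protocol, inference.

Training follows an 8:2 stratified train/test split with 20% of the
training portion held out for validation, Adam optimization, and
best-validation-accuracy checkpointing. The test split is produced but
never touched during training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .nnet import Adam, ChannelGate, GamResNet18, softmax, softmax_cross_entropy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the attention-augmented classifier.

    attention_sites lists the residual stages (0..3) after which a
    channel-attention gate is inserted; reduction r sets the attention
    MLP bottleneck width C // r.
    """

    num_classes: int = 5
    input_px: int = 224
    attention_reduction: int = 16
    attention_sites: tuple[int, ...] = (0, 1, 2, 3)
    pretrained_init: bool = False

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        for s in self.attention_sites:
            if not 0 <= s < 4:
                raise ValueError(f"invalid attention site {s}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 20
    test_fraction: float = 0.2
    val_fraction: float = 0.2      # of the training portion
    seed: int = 0
    class_stratified: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.test_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "train_acc": self.train_acc, "val_acc": self.val_acc,
        })


def gam_attention(features: np.ndarray, r: int = 16,
                  gate: ChannelGate | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a channel-attention gate to a (C, H, W) or (N, C, H, W) map.

    A fresh randomly initialized gate is used unless one is supplied;
    output shape always equals input shape.
    """
    x = np.asarray(features, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if gate is None:
        gate = ChannelGate(x.shape[1], r, rng=rng)
    out = gate.forward(x)
    return out[0] if squeeze else out


def build_network(spec: NetworkSpec, seed: int = 0) -> GamResNet18:
    """Construct the classifier with seeded parameter initialization.

    Grayscale input is a single channel; with ``pretrained_init`` the
    input is replicated to three channels (initialization from external
    pretrained weights is not performed — weights are always fresh, the
    flag only fixes the input convention).
    """
    rng = np.random.default_rng(seed)
    in_ch = 3 if spec.pretrained_init else 1
    return GamResNet18(
        num_classes=spec.num_classes, in_channels=in_ch,
        attention_sites=spec.attention_sites,
        reduction=spec.attention_reduction, rng=rng,
    )


def _prepare(images: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """uint8 (N, px, px) gray images -> float32 (N, C, px, px) in [0, 1]."""
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[-1] != spec.input_px or x.shape[-2] != spec.input_px:
        raise ValueError(
            f"images are {x.shape[-2]}x{x.shape[-1]}, spec expects "
            f"{spec.input_px}x{spec.input_px}")
    x = x.astype(np.float32) / 255.0
    want = 3 if spec.pretrained_init else 1
    if x.shape[1] == 1 and want == 3:
        x = np.repeat(x, 3, axis=1)
    return x


def split_dataset(n: int, labels: np.ndarray, config: TrainConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic stratified (train, val, test) index split."""
    idx = np.arange(n)
    strat = labels if config.class_stratified else None
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, random_state=config.seed,
        stratify=strat)
    strat2 = labels[train_idx] if config.class_stratified else None
    tr_idx, val_idx = train_test_split(
        train_idx, test_size=config.val_fraction,
        random_state=config.seed + 1, stratify=strat2)
    return tr_idx, val_idx, test_idx


def _evaluate(net: GamResNet18, x: np.ndarray, y: np.ndarray,
              batch: int) -> tuple[float, float]:
    net.set_training(False)
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits = net.forward(x[i: i + batch])
        loss, _ = softmax_cross_entropy(logits, y[i: i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i: i + batch]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(images: np.ndarray, labels: np.ndarray, spec: NetworkSpec,
          config: TrainConfig) -> tuple[GamResNet18, TrainHistory, dict]:
    """Train the classifier; returns (network, history, split indices).

    The returned network carries the parameters of the epoch with the
    best validation accuracy. ``split`` maps "train"/"val"/"test" to the
    index arrays used, so the caller can evaluate on the untouched test
    split.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    y = np.searchsorted(classes, labels)
    x = _prepare(images, spec)

    tr_idx, val_idx, test_idx = split_dataset(len(x), labels, config)
    for name, part in (("train", tr_idx), ("val", val_idx), ("test", test_idx)):
        present = set(y[part])
        missing = [str(classes[c]) for c in range(len(classes)) if c not in present]
        if missing:
            raise ValueError(f"class(es) {missing} empty in the {name} split")

    net = build_network(spec, seed=config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    hist = TrainHistory()
    best_state, best_acc = None, -1.0

    xt, yt = x[tr_idx], y[tr_idx]
    for epoch in range(config.max_epochs):
        net.set_training(True)
        order = rng.permutation(len(xt))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(xt), config.batch_size):
            sel = order[i: i + config.batch_size]
            xb, yb = xt[sel], yt[sel]
            opt.zero_grad()
            logits = net.forward(xb)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(xb)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(net, x[val_idx], y[val_idx],
                                      config.batch_size)
        hist.train_loss.append(ep_loss / len(xt))
        hist.train_acc.append(ep_correct / len(xt))
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state = val_acc, net.state_dict()
            hist.best_epoch = epoch
        logger.info("epoch %d: train_loss=%.4f train_acc=%.3f "
                    "val_loss=%.4f val_acc=%.3f", epoch,
                    hist.train_loss[-1], hist.train_acc[-1], val_loss, val_acc)

    if best_state is not None:
        net.load_state_dict(best_state)
    net.set_training(False)
    split = {"train": tr_idx, "val": val_idx, "test": test_idx,
             "classes": classes}
    return net, hist, split


def predict_proba(net: GamResNet18, images: np.ndarray, spec: NetworkSpec,
                  batch_size: int = 32) -> np.ndarray:
    """Per-class probability rows (softmax over logits), evaluation mode."""
    x = _prepare(images, spec)
    net.set_training(False)
    rows = []
    for i in range(0, len(x), batch_size):
        rows.append(softmax(net.forward(x[i: i + batch_size])))
    return np.vstack(rows)


def save_checkpoint(net: GamResNet18, spec: NetworkSpec,
                    path: str | Path) -> Path:
    path = Path(path)
    state = net.state_dict()
    np.savez(path, __spec__=json.dumps(asdict(spec)), **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[GamResNet18, NetworkSpec]:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                 else path, allow_pickle=False) as data:
        meta = json.loads(str(data["__spec__"]))
        meta["attention_sites"] = tuple(meta["attention_sites"])
        spec = NetworkSpec(**meta)
        net = build_network(spec, seed=0)
        state = {k: data[k] for k in data.files if k != "__spec__"}
    net.load_state_dict(state)
    return net, spec
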