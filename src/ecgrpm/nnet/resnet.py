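"""Attention-augmented 18-layer residual network.

Topology: 7x7/2 stem convolution, 3x3/2 max pool, four stages of two
basic residual blocks (64/128/256/512 channels, spatial stride 2 between
stages), an optional channel-attention gate after each stage, global
average pooling and a linear classifier head.

The channel gate pools each channel to a scalar, passes the pooled
descriptor through a two-layer perceptron with reduction ratio r and a
sigmoid, and fuses the resulting per-channel weights additively:
``out = x + w (.) x``.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d, Conv2d, GlobalAvgPool, Layer, Linear, MaxPool2d,
    Param, ReLU, Sequential,
)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class ChannelGate(Layer):
    """Channel attention: sigmoid-MLP weights fused additively.

    ``w = sigmoid(W2 relu(W1 gap(x)))`` with hidden width max(C // r, 1);
    output is ``x + w[:, :, None, None] * x``, so each channel is scaled
    by 1 + w with w in (0, 1).
    """

    def __init__(self, c: int, r: int = 16,
                 rng: np.random.Generator | None = None,
                 name: str = "gate") -> None:
        hidden = max(c // r, 1)
        self.fc1 = Linear(c, hidden, rng=rng, name=name + ".fc1")
        self.fc2 = Linear(hidden, c, rng=rng, name=name + ".fc2")
        self.c, self.r = c, r
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x.mean(axis=(2, 3))                       # (N, C) pooled descriptor
        h = self.fc1.forward(z)
        hr = np.where(h > 0, h, 0.0)
        w = _sigmoid(self.fc2.forward(hr))            # (N, C) channel weights
        self._cache = (x, h, w)
        return x + w[:, :, None, None] * x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, h, w = self._cache
        n, c, hh, ww = x.shape
        dx_direct = dout * (1.0 + w[:, :, None, None])
        dw = (dout * x).sum(axis=(2, 3))              # (N, C)
        dlogit = dw * w * (1.0 - w)
        dhr = self.fc2.backward(dlogit)
        dh = np.where(h > 0, dhr, 0.0)
        dz = self.fc1.backward(dh)
        return dx_direct + dz[:, :, None, None] / (hh * ww)


class BasicBlock(Layer):
    """Two 3x3 conv+BN layers with identity (or projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator | None = None,
                 name: str = "block") -> None:
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng, name + ".conv1")
        self.bn1 = BatchNorm2d(c_out, name=name + ".bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng, name + ".conv2")
        self.bn2 = BatchNorm2d(c_out, name=name + ".bn2")
        if stride != 1 or c_in != c_out:
            self.down_conv = Conv2d(c_in, c_out, 1, stride, 0, rng, name + ".down")
            self.down_bn = BatchNorm2d(c_out, name=name + ".down_bn")
        else:
            self.down_conv = self.down_bn = None
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.down_conv is not None:
            out += self.down_conv.params() + self.down_bn.params()
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2,
                      self.down_conv, self.down_bn):
            if layer is not None:
                layer.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        short = x if self.down_conv is None \
            else self.down_bn.forward(self.down_conv.forward(x))
        y = out + short
        self._mask = y > 0
        return np.where(self._mask, y, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = np.where(self._mask, dout, 0.0)
        dmain = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))))
        if self.down_conv is None:
            dshort = dy
        else:
            dshort = self.down_conv.backward(self.down_bn.backward(dy))
        return dmain + dshort


class GamResNet18(Layer):
    """18-layer residual classifier with per-stage channel attention."""

    STAGE_CHANNELS = (64, 128, 256, 512)

    def __init__(self, num_classes: int = 5, in_channels: int = 1,
                 attention_sites: tuple[int, ...] = (0, 1, 2, 3),
                 reduction: int = 16,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        for s in attention_sites:
            if not 0 <= s < 4:
                raise ValueError(f"invalid attention site {s}; stages are 0..3")
        self.stem = Sequential(
            Conv2d(in_channels, 64, 7, 2, 3, rng, "stem.conv"),
            BatchNorm2d(64, name="stem.bn"),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        self.stages: list[Sequential] = []
        c_in = 64
        for i, c_out in enumerate(self.STAGE_CHANNELS):
            stride = 1 if i == 0 else 2
            layers: list[Layer] = [
                BasicBlock(c_in, c_out, stride, rng, f"stage{i}.block0"),
                BasicBlock(c_out, c_out, 1, rng, f"stage{i}.block1"),
            ]
            if i in attention_sites:
                layers.append(ChannelGate(c_out, reduction, rng, f"stage{i}.gate"))
            self.stages.append(Sequential(*layers))
            c_in = c_out
        self.pool = GlobalAvgPool()
        self.head = Linear(512, num_classes, rng, "head")
        self.num_classes = num_classes
        self.attention_sites = tuple(attention_sites)

    def params(self) -> list[Param]:
        out = self.stem.params()
        for st in self.stages:
            out += st.params()
        return out + self.head.params()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.stem.set_training(flag)
        for st in self.stages:
            st.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.stem.forward(x)
        for st in self.stages:
            x = st.forward(x)
        return self.head.forward(self.pool.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = self.pool.backward(self.head.backward(dout))
        for st in reversed(self.stages):
            dout = st.backward(dout)
        return self.stem.backward(dout)

    # --- checkpoint helpers -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.params()}
        for i, layer in enumerate(self._bn_layers()):
            state[f"_bn{i}.running_mean"] = layer.running_mean.copy()
            state[f"_bn{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data = state[p.name].copy()
        for i, layer in enumerate(self._bn_layers()):
            layer.running_mean = state[f"_bn{i}.running_mean"].copy()
            layer.running_var = state[f"_bn{i}.running_var"].copy()

    def _bn_layers(self) -> list[BatchNorm2d]:
        found: list[BatchNorm2d] = []

        def walk(layer: Layer) -> None:
            if isinstance(layer, BatchNorm2d):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, BasicBlock):
                for sub in (layer.bn1, layer.bn2, layer.down_bn):
                    if sub is not None:
                        found.append(sub)

        walk(self.stem)
        for st in self.stages:
            walk(st)
        return found
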