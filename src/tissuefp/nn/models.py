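"""Fingerprint network backbones.

A fingerprint network maps a batch of 224x224x3 inputs to

* a classification vector over the training identities (core indices), and
* a fingerprint: the globally average-pooled feature vector of the last
  convolutional stage, taken *before* the identity head.

Two backbone profiles ship:

* ``tiny`` — a three-block CNN (configurable fingerprint dimension) sized for
  CPU training on synthetic cohorts;
* ``resnet34`` — the standard 34-layer residual architecture whose pooled
  feature vector is 512-dimensional.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPool2d,
    GlobalMomentPool,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = ["FingerprintNetwork", "build_tiny_cnn", "build_resnet34", "BasicBlock"]


class BasicBlock(Layer):
    """Two 3x3 conv/BN/ReLU stages with an identity or projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, bias=False, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.down = None

    def _parts(self):
        parts = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.down is not None:
            parts.append(("down", self.down))
        return parts

    def parameters(self):
        for prefix, layer in self._parts():
            for name, p, g in layer.parameters():
                yield f"{prefix}.{name}", p, g

    def buffers(self):
        for prefix, layer in self._parts():
            for name, b in layer.buffers():
                yield f"{prefix}.{name}", b

    def forward(self, x, train=False):
        y, c1 = self.conv1.forward(x, train)
        y, c2 = self.bn1.forward(y, train)
        y, c3 = self.relu1.forward(y, train)
        y, c4 = self.conv2.forward(y, train)
        y, c5 = self.bn2.forward(y, train)
        if self.down is not None:
            short, cd = self.down.forward(x, train)
        else:
            short, cd = x, None
        y = y + short
        y, c6 = self.relu2.forward(y, train)
        return y, (c1, c2, c3, c4, c5, c6, cd)

    def backward(self, grad, cache):
        c1, c2, c3, c4, c5, c6, cd = cache
        grad = self.relu2.backward(grad, c6)
        g_main = self.bn2.backward(grad, c5)
        g_main = self.conv2.backward(g_main, c4)
        g_main = self.relu1.backward(g_main, c3)
        g_main = self.bn1.backward(g_main, c2)
        g_main = self.conv1.backward(g_main, c1)
        if self.down is not None:
            g_short = self.down.backward(grad, cd)
        else:
            g_short = grad
        return g_main + g_short


class FingerprintNetwork:
    """Backbone + identity head; exposes logits and fingerprints jointly."""

    def __init__(self, backbone: Sequential, fingerprint_dim: int, n_identities: int,
                 profile: str, rng: np.random.Generator | None = None,
                 grayscale_input: bool = True):
        rng = rng or np.random.default_rng()
        self.backbone = backbone
        self.head = Linear(fingerprint_dim, n_identities, rng=rng)
        self.fingerprint_dim = fingerprint_dim
        self.n_identities = n_identities
        self.profile = profile
        #: whether inputs are collapsed to luminance (replicated to 3 channels)
        #: before entering the network; applied by the preprocessing helpers.
        self.grayscale_input = grayscale_input

    def parameters(self):
        for name, p, g in self.backbone.parameters():
            yield f"backbone.{name}", p, g
        for name, p, g in self.head.parameters():
            yield f"head.{name}", p, g

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (N,3,224,224) float32 in [0,1] -> (logits (N,K), fps (N,D), cache)."""
        fps, cache_b = self.backbone.forward(x.astype(np.float32, copy=False), train=train)
        logits, cache_h = self.head.forward(fps, train=train)
        return logits, fps, (cache_b, cache_h)

    def backward(self, dlogits: np.ndarray, dfps: np.ndarray | None, cache) -> None:
        cache_b, cache_h = cache
        grad = self.head.backward(dlogits, cache_h)
        if dfps is not None:
            grad = grad + dfps
        self.backbone.backward(grad, cache_b, need_input=False)

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def buffers(self):
        for name, b in self.backbone.buffers():
            yield f"backbone.{name}", b

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus non-learnable buffers (BN stats)."""
        state = {name: p.copy() for name, p, _ in self.parameters()}
        state.update({f"buf.{name}": b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            p[...] = state[name]
        for name, b in self.buffers():
            b[...] = state[f"buf.{name}"]


def build_tiny_cnn(n_identities: int, fingerprint_dim: int = 32,
                   seed: int = 0, grayscale_input: bool = True,
                   stem_pool: int = 2) -> FingerprintNetwork:
    """Three conv-BN-ReLU stride-2 blocks over an average-pooled stem.

    The stem pool trades spatial detail for speed (2x keeps nuclei and
    stromal texture resolvable); batch normalization keeps the identity
    loss trainable alongside the fingerprint-distance term, which would
    otherwise favour collapsed (constant) features early in training.
    """
    if fingerprint_dim % 2:
        raise ValueError("fingerprint_dim must be even (mean + RMS pooling)")
    rng = np.random.default_rng(seed)
    last = fingerprint_dim // 2
    backbone = Sequential(
        AvgPool2d(stem_pool),
        Conv2d(3, 12, 3, stride=2, bias=False, rng=rng), BatchNorm2d(12), ReLU(),
        Conv2d(12, 24, 3, stride=2, bias=False, rng=rng), BatchNorm2d(24), ReLU(),
        Conv2d(24, last, 3, stride=2, bias=False, rng=rng),
        BatchNorm2d(last), ReLU(),
        GlobalMomentPool(),
    )
    return FingerprintNetwork(backbone, fingerprint_dim, n_identities, "tiny",
                              rng=rng, grayscale_input=grayscale_input)


def build_resnet34(n_identities: int, seed: int = 0,
                   grayscale_input: bool = True) -> FingerprintNetwork:
    """Standard 34-layer residual network; 512-dimensional fingerprint."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, pad=1),
    ]
    plan = [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]
    in_ch = 64
    for out_ch, blocks, first_stride in plan:
        for i in range(blocks):
            layers.append(BasicBlock(in_ch, out_ch, first_stride if i == 0 else 1, rng))
            in_ch = out_ch
    layers.append(GlobalAvgPool())
    backbone = Sequential(*layers)
    return FingerprintNetwork(backbone, 512, n_identities, "resnet34",
                              rng=rng, grayscale_input=grayscale_input)
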