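"""Modified Inception-V4 patch classifier.

The network is the canonical Inception-V4 body with a shortened stem that
accommodates 101x101 input patches: three valid 3x3 convolutions (the third
at stride 2) and one 2x2 max-pool, giving the spatial trace
101 -> 99 -> 97 -> 48 -> 23, after which the standard stack follows:
n_a x Inception-A, Reduction-A, n_b x Inception-B, Reduction-B,
n_c x Inception-C, global average pool, dropout, and a 2-class linear/softmax
head.  With the published repeat counts (4, 7, 3) the network contains
exactly 141 convolutional layers and 18 pooling layers.

A ``width_multiplier`` rescales every channel count (ceiling, minimum 1) so
that architecturally identical miniatures can be trained on a CPU in
minutes; ``count_layers`` is exact for any configuration.  Activation is
ReLU by default with a ``sigmoid`` switch mirroring the published table's
caption (a full-depth sigmoid network is essentially untrainable, so both
modes are exposed rather than silently choosing).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

PAPER_REPEATS = (4, 7, 3)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters."""

    patch_size: int = 101
    in_channels: int = 3  # HSV
    n_inception_a: int = 4
    n_inception_b: int = 7
    n_inception_c: int = 3
    width_multiplier: float = 1.0
    activation: str = "relu"
    dropout: float = 0.40
    n_classes: int = 2

    def __post_init__(self):
        if min(self.n_inception_a, self.n_inception_b, self.n_inception_c) < 0:
            raise ValueError("block repeat counts must be >= 0")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError(f"width_multiplier {self.width_multiplier} outside (0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout {self.dropout} outside [0, 1)")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"activation must be 'relu' or 'sigmoid', got {self.activation!r}")

    def width(self, channels: int) -> int:
        """Scale a full-width channel count, minimum one channel."""
        return max(1, math.ceil(self.width_multiplier * channels))


@dataclass
class Prediction:
    """Per-patch output: cancer probability and the raw logit pair."""

    p: float
    logits: tuple[float, float]


# -------------------------------------------------------------------- layers

class Conv2d:
    def __init__(self, in_ch, out_ch, kernel, stride=(1, 1), padding="valid",
                 activation="relu", rng=None, name=""):
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        if activation == "sigmoid":
            std = math.sqrt(1.0 / fan_in)  # Xavier
        else:
            std = math.sqrt(2.0 / fan_in)  # He
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Tensor(rng.normal(0.0, std, (kh, kw, in_ch, out_ch)), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding
        self.activation = activation
        self.out_ch = out_ch
        self.name = name

    def params(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.conv2d(x, self.w, self.b, self.stride, self.padding)
        if self.activation == "relu":
            return ad.relu(out)
        if self.activation == "sigmoid":
            return ad.sigmoid(out)
        return out

    def spatial(self, h, w):
        kh, kw = self.w.data.shape[:2]
        sh, sw = self.stride
        if self.padding == "same":
            return -(-h // sh), -(-w // sw)
        ho, wo = (h - kh) // sh + 1, (w - kw) // sw + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"layer {self.name or 'conv'}: kernel {kh}x{kw} does not fit {h}x{w}")
        return ho, wo


class MaxPool2d:
    def __init__(self, kernel=(2, 2), stride=(2, 2), padding="valid", name=""):
        self.kernel, self.stride, self.padding, self.name = kernel, stride, padding, name

    def params(self):
        return []

    def __call__(self, x):
        return ad.max_pool2d(x, self.kernel, self.stride, self.padding)

    def spatial(self, h, w):
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.padding == "same":
            return -(-h // sh), -(-w // sw)
        ho, wo = (h - kh) // sh + 1, (w - kw) // sw + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"layer {self.name or 'maxpool'}: kernel {kh}x{kw} does not fit {h}x{w}")
        return ho, wo


class AvgPool2d(MaxPool2d):
    def __call__(self, x):
        return ad.avg_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool:
    name = "global_avg_pool"

    def params(self):
        return []

    def __call__(self, x):
        return ad.global_avg_pool(x)

    def spatial(self, h, w):
        if h < 1 or w < 1:
            raise ValueError("global_avg_pool: empty spatial input")
        return 1, 1


class Dense:
    def __init__(self, fin, fout, rng, name="logits"):
        std = math.sqrt(1.0 / fin)
        self.w = Tensor(rng.normal(0.0, std, (fin, fout)), requires_grad=True)
        self.b = Tensor(np.zeros(fout), requires_grad=True)
        self.name = name

    def params(self):
        return [self.w, self.b]

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.w), self.b)


class Branch:
    """A sequential chain of layers forming one branch of an Inception block."""

    def __init__(self, layers):
        self.layers = layers

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class InceptionBlock:
    """Concatenation of parallel branches along the channel axis."""

    def __init__(self, branches, name=""):
        self.branches = branches
        self.name = name

    def __call__(self, x):
        return ad.concat([b(x) for b in self.branches], axis=-1)

    def sublayers(self):
        for b in self.branches:
            yield from b.layers


class SplitBranch:
    """A branch whose tail forks into parallel convolutions (Inception-C)."""

    def __init__(self, stem_layers, fork_layers):
        self.layers = list(stem_layers) + list(fork_layers)  # for walks
        self._stem = stem_layers
        self._fork = fork_layers

    def __call__(self, x):
        for layer in self._stem:
            x = layer(x)
        return ad.concat([f(x) for f in self._fork], axis=-1)


# --------------------------------------------------- canonical block anatomy

def _conv(cfg, rng, i, o, k, s=(1, 1), p="same", name=""):
    return Conv2d(i, o, k, s, p, activation=cfg.activation, rng=rng, name=name)


def _inception_a(cfg, rng, in_ch, name):
    w = cfg.width
    branches = [
        Branch([AvgPool2d((3, 3), (1, 1), "same", name=f"{name}.pool"),
                _conv(cfg, rng, in_ch, w(96), (1, 1), name=f"{name}.pool_conv")]),
        Branch([_conv(cfg, rng, in_ch, w(96), (1, 1), name=f"{name}.b1")]),
        Branch([_conv(cfg, rng, in_ch, w(64), (1, 1)),
                _conv(cfg, rng, w(64), w(96), (3, 3))]),
        Branch([_conv(cfg, rng, in_ch, w(64), (1, 1)),
                _conv(cfg, rng, w(64), w(96), (3, 3)),
                _conv(cfg, rng, w(96), w(96), (3, 3))]),
    ]
    out_ch = w(96) * 3 + w(96)
    return InceptionBlock(branches, name), out_ch


def _reduction_a(cfg, rng, in_ch, name):
    w = cfg.width
    branches = [
        Branch([MaxPool2d((3, 3), (2, 2), "valid", name=f"{name}.pool")]),
        Branch([_conv(cfg, rng, in_ch, w(384), (3, 3), (2, 2), "valid")]),
        Branch([_conv(cfg, rng, in_ch, w(192), (1, 1)),
                _conv(cfg, rng, w(192), w(224), (3, 3)),
                _conv(cfg, rng, w(224), w(256), (3, 3), (2, 2), "valid")]),
    ]
    return InceptionBlock(branches, name), in_ch + w(384) + w(256)


def _inception_b(cfg, rng, in_ch, name):
    w = cfg.width
    branches = [
        Branch([AvgPool2d((3, 3), (1, 1), "same", name=f"{name}.pool"),
                _conv(cfg, rng, in_ch, w(128), (1, 1))]),
        Branch([_conv(cfg, rng, in_ch, w(384), (1, 1))]),
        Branch([_conv(cfg, rng, in_ch, w(192), (1, 1)),
                _conv(cfg, rng, w(192), w(224), (1, 7)),
                _conv(cfg, rng, w(224), w(256), (7, 1))]),
        Branch([_conv(cfg, rng, in_ch, w(192), (1, 1)),
                _conv(cfg, rng, w(192), w(192), (1, 7)),
                _conv(cfg, rng, w(192), w(224), (7, 1)),
                _conv(cfg, rng, w(224), w(224), (1, 7)),
                _conv(cfg, rng, w(224), w(256), (7, 1))]),
    ]
    return InceptionBlock(branches, name), w(128) + w(384) + w(256) + w(256)


def _reduction_b(cfg, rng, in_ch, name):
    w = cfg.width
    branches = [
        Branch([MaxPool2d((3, 3), (2, 2), "valid", name=f"{name}.pool")]),
        Branch([_conv(cfg, rng, in_ch, w(192), (1, 1)),
                _conv(cfg, rng, w(192), w(192), (3, 3), (2, 2), "valid")]),
        Branch([_conv(cfg, rng, in_ch, w(256), (1, 1)),
                _conv(cfg, rng, w(256), w(256), (1, 7)),
                _conv(cfg, rng, w(256), w(320), (7, 1)),
                _conv(cfg, rng, w(320), w(320), (3, 3), (2, 2), "valid")]),
    ]
    return InceptionBlock(branches, name), in_ch + w(192) + w(320)


def _inception_c(cfg, rng, in_ch, name):
    w = cfg.width
    branches = [
        Branch([AvgPool2d((3, 3), (1, 1), "same", name=f"{name}.pool"),
                _conv(cfg, rng, in_ch, w(256), (1, 1))]),
        Branch([_conv(cfg, rng, in_ch, w(256), (1, 1))]),
        SplitBranch(
            [_conv(cfg, rng, in_ch, w(384), (1, 1))],
            [_conv(cfg, rng, w(384), w(256), (1, 3)),
             _conv(cfg, rng, w(384), w(256), (3, 1))],
        ),
        SplitBranch(
            [_conv(cfg, rng, in_ch, w(384), (1, 1)),
             _conv(cfg, rng, w(384), w(448), (1, 3)),
             _conv(cfg, rng, w(448), w(512), (3, 1))],
            [_conv(cfg, rng, w(512), w(256), (1, 3)),
             _conv(cfg, rng, w(512), w(256), (3, 1))],
        ),
    ]
    return InceptionBlock(branches, name), w(256) * 2 + w(256) * 2 + w(256) * 2


# --------------------------------------------------------------------- model

class Model:
    """The instantiated network: stem, Inception stack, classifier head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.width
        self.stem = [
            _conv(config, rng, config.in_channels, w(32), (3, 3), (1, 1), "valid", "stem.conv1"),
            _conv(config, rng, w(32), w(64), (3, 3), (1, 1), "valid", "stem.conv2"),
            MaxPool2d((2, 2), (2, 2), "valid", name="stem.pool"),
            _conv(config, rng, w(64), w(80), (3, 3), (2, 2), "valid", "stem.conv3"),
        ]
        self.blocks = []
        ch = w(80)
        for i in range(config.n_inception_a):
            blk, ch = _inception_a(config, rng, ch, f"inception_a{i}")
            self.blocks.append(blk)
        blk, ch = _reduction_a(config, rng, ch, "reduction_a")
        self.blocks.append(blk)
        for i in range(config.n_inception_b):
            blk, ch = _inception_b(config, rng, ch, f"inception_b{i}")
            self.blocks.append(blk)
        blk, ch = _reduction_b(config, rng, ch, "reduction_b")
        self.blocks.append(blk)
        for i in range(config.n_inception_c):
            blk, ch = _inception_c(config, rng, ch, f"inception_c{i}")
            self.blocks.append(blk)
        self.gap = GlobalAvgPool()
        self.head = Dense(ch, config.n_classes, rng)
        self.feature_channels = ch
        self._dropout_rng = np.random.default_rng(seed + 1)
        self.stem_trace = self._check_geometry()

    # -- introspection ------------------------------------------------------

    def walk(self):
        """Depth-first iteration over every leaf layer, in execution order."""
        for layer in self.stem:
            yield layer
        for blk in self.blocks:
            for b in blk.branches:
                yield from b.layers
        yield self.gap
        yield self.head

    def parameters(self):
        return [p for layer in self.walk() for p in layer.params() if hasattr(layer, "params")]

    def _check_geometry(self):
        """Analytic spatial-shape trace; raises a sizing error naming the
        first layer the input cannot pass."""
        h = w = self.config.patch_size
        trace = [h]
        for layer in self.stem:
            h, w = layer.spatial(h, w)
            trace.append(h)
        for blk in self.blocks:
            sizes = set()
            for b in blk.branches:
                bh, bw = h, w
                for layer in b.layers if not isinstance(b, SplitBranch) else b._stem:
                    bh, bw = layer.spatial(bh, bw)
                sizes.add((bh, bw))
            if len(sizes) != 1:
                raise ValueError(f"block {blk.name}: branch output sizes differ: {sizes}")
            (h, w), = sizes
            trace.append(h)
        self.gap.spatial(h, w)
        return trace

    # -- forward ------------------------------------------------------------

    def _features(self, x: Tensor, stop_after_stem=False):
        for layer in self.stem:
            x = layer(x)
        if stop_after_stem:
            return x
        for blk in self.blocks:
            x = blk(x)
        return x

    def logits(self, batch: np.ndarray, train: bool = False) -> Tensor:
        """Logit pairs for a batch of HSV patches, shape (N, ps, ps, 3)."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        ps = self.config.patch_size
        if batch.shape[1:] != (ps, ps, self.config.in_channels):
            raise ValueError(
                f"expected batch of {ps}x{ps}x{self.config.in_channels} patches, "
                f"got shape {batch.shape}"
            )
        x = self._features(Tensor(batch))
        x = self.gap(x)
        if train and self.config.dropout > 0.0:
            x = ad.dropout(x, self.config.dropout, self._dropout_rng)
        return self.head(x)

    def forward(self, batch: np.ndarray) -> list[Prediction]:
        """Deterministic (eval-mode) predictions for a batch of HSV patches."""
        with ad.no_grad():
            logits = self.logits(batch, train=False).data
        probs = ad.softmax(logits)
        return [
            Prediction(p=float(pr[1]), logits=(float(lg[0]), float(lg[1])))
            for pr, lg in zip(probs, logits)
        ]

    def predict_proba(self, batch: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Cancer probabilities for any number of HSV patches."""
        batch = np.asarray(batch, dtype=np.float32)
        out = np.empty(len(batch), dtype=np.float64)
        for i in range(0, len(batch), batch_size):
            with ad.no_grad():
                lg = self.logits(batch[i : i + batch_size]).data
            out[i : i + len(lg)] = ad.softmax(lg)[:, 1]
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: npz of parameters plus a JSON architecture manifest."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, **arrays)
        n_conv, n_pool = count_layers_walk(self)
        manifest = {"config": asdict(self.config), "n_conv": n_conv, "n_pool": n_pool}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**manifest["config"]))
        npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        if not npz_path.exists():
            npz_path = path
        with np.load(npz_path) as data:
            for i, p in enumerate(model.parameters()):
                arr = data[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint parameter p{i} shape {arr.shape} != {p.data.shape}")
                p.data = arr.astype(np.float32)
        return model


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate the network for a configuration (seeded weight init)."""
    return Model(config, seed=seed)


# ------------------------------------------------------------- layer counts

def count_layers(config: ModelConfig) -> tuple[int, int]:
    """Exact (n_conv, n_pool) for a configuration, in closed form.

    Per block: Inception-A 7 convs, Reduction-A 4, Inception-B 10,
    Reduction-B 6, Inception-C 10; the stem has 3 convs.  Pooling layers:
    stem max-pool, one pooling branch per Inception block, one per Reduction
    block, and the final average pool.
    """
    na, nb, nc = config.n_inception_a, config.n_inception_b, config.n_inception_c
    n_conv = 3 + 7 * na + 4 + 10 * nb + 6 + 10 * nc
    n_pool = 4 + na + nb + nc
    return n_conv, n_pool


def count_layers_walk(model: Model) -> tuple[int, int]:
    """(n_conv, n_pool) counted by walking the instantiated network."""
    n_conv = sum(1 for layer in model.walk() if isinstance(layer, Conv2d))
    n_pool = sum(
        1 for layer in model.walk() if isinstance(layer, (MaxPool2d, GlobalAvgPool))
    )
    return n_conv, n_pool
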