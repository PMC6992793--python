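"""Tile-classifier backbones.

Two families behind one interface:

``inception_v3_slim``
    The standard inception-v3 graph with every convolutional layer's
    channel count scaled by a *depth multiplier* (integer truncation,
    floored at ``min_depth``), the device the original slide-classification
    work used to slim the network. With multiplier 0.35 the pooled feature
    vector that remains after dropping the classification layer is
    715-dimensional (2048 at multiplier 1). Implemented forward-only with
    random weights: it exists for architecture-shape verification and
    feature-dimension bookkeeping at full scale, not for CPU training.

``tiny_cnn``
    A small trainable CNN for desk-scale experiments: the 512x512 input is
    average-pooled 8x to a 64x64 field, passed through four 3x3 conv
    blocks with 2x2 max pooling between them, and each block contributes a
    global-max-pooled 16-channel slice to a 64-dim feature vector. The
    multi-scale global max pooling matters: a structure much smaller than
    a tile (a speck, ~100 px) still spans several cells of the working
    grid and drives the fine-scale features at near-full strength, while
    the coarse-scale features see it diluted — so a single false-positive
    speck yields a confidently wrong tile, which is what lets
    sliding-window max-pool aggregation inflate slide scores.

Both map normalised pixels in [-1, 1] to (feature vector, 3-class
probability simplex).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .labels import LABELS


@dataclass(frozen=True)
class BackboneConfig:
    family: str = "tiny_cnn"
    depth_multiplier: float = 0.35
    min_depth: int = 16
    input_size: int = 512
    n_classes: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("inception_v3_slim", "tiny_cnn"):
            raise ValueError(f"unknown backbone family {self.family!r}")
        if not 0.0 < self.depth_multiplier <= 1.0:
            raise ValueError("depth_multiplier must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def scale_depth(channels: int, depth_multiplier: float, min_depth: int = 16) -> int:
    """Scaled channel count: max(trunc(channels * multiplier), min_depth)."""
    if depth_multiplier <= 0:
        raise ValueError("depth_multiplier must be positive")
    if channels < 1:
        raise ValueError("channels must be >= 1")
    return max(int(channels * depth_multiplier), min_depth)


def normalize_pixels(tile: np.ndarray) -> np.ndarray:
    """Map 8-bit RGB to [-1, 1]: x -> x/127.5 - 1 (0 -> -1, 255 -> +1)."""
    return np.asarray(tile, dtype=np.float32) / np.float32(127.5) - np.float32(1.0)


class TinyCNN:
    """Four conv blocks, multi-scale global max pooling, 64-dim features."""

    BLOCK_CHANNELS = (16, 16, 16, 16)

    def __init__(self, cfg: BackboneConfig):
        cfg.validate()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.pool_factor = max(1, cfg.input_size // 64)
        chans = self.BLOCK_CHANNELS
        self.convs = [nn.Conv2d(3, chans[0], rng)]
        for c_in, c_out in zip(chans, chans[1:]):
            self.convs.append(nn.Conv2d(c_in, c_out, rng))
        self.relus = [nn.ReLU() for _ in chans]
        self.pools = [nn.MaxPool2x2() for _ in chans[:-1]]
        self.gmaxes = [nn.GlobalMaxPool() for _ in chans]
        self.feature_dim = int(sum(chans))
        # zero-initialised classifier head: the untrained model is exactly
        # the uniform predictor (initial cross-entropy ln 3)
        self.head = nn.Dense(self.feature_dim, cfg.n_classes, rng)
        self.head.W.value[...] = 0.0
        self.class_order = LABELS[: cfg.n_classes]

    # -- forward / backward -------------------------------------------------

    def pool_input(self, x: np.ndarray) -> np.ndarray:
        """Average-pool the normalised input to the 64x64 working grid."""
        f = self.pool_factor
        if f == 1:
            return np.asarray(x, dtype=np.float32)
        n, h, w, c = x.shape
        return (
            np.asarray(x, dtype=np.float32)
            .reshape(n, h // f, f, w // f, f, c)
            .mean(axis=(2, 4))
        )

    def forward_pooled(self, xp: np.ndarray, train: bool = False):
        """(N, 64, 64, 3) pooled input -> (features, probs, logits)."""
        feats = []
        a = xp
        for i, (conv, relu, gmax) in enumerate(zip(self.convs, self.relus, self.gmaxes)):
            a = relu.forward(conv.forward(a, train), train)
            feats.append(gmax.forward(a, train))
            if i < len(self.pools):
                a = self.pools[i].forward(a, train)
        features = np.concatenate(feats, axis=1)
        logits = self.head.forward(features, train)
        return features, nn.softmax(logits), logits

    def forward(self, x: np.ndarray, train: bool = False):
        """Normalised [-1, 1] input at full tile size -> (features, probs)."""
        features, probs, _ = self.forward_pooled(self.pool_input(x), train)
        return features, probs

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        splits = np.cumsum(self.BLOCK_CHANNELS)[:-1]
        dfs = np.split(dfeat, splits, axis=1)
        da = None
        for i in range(len(self.convs) - 1, -1, -1):
            d = self.gmaxes[i].backward(np.ascontiguousarray(dfs[i]))
            if da is not None:
                d = d + self.pools[i].backward(da)
            da = self.convs[i].backward(self.relus[i].backward(d))

    @property
    def params(self):
        out = []
        for conv in self.convs:
            out.extend(conv.params)
        out.extend(self.head.params)
        return out

    # -- inference convenience ---------------------------------------------

    def predict_tiles(self, tiles_uint8: np.ndarray):
        """uint8 tiles -> (features, probs); handles normalisation."""
        features, probs = self.forward(normalize_pixels(tiles_uint8), train=False)
        return features, probs


def _conv_infer(x, w, b, stride=1, pad="same"):
    kh, kw = w.shape[:2]
    if pad == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        x = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    y = np.tensordot(win, w, axes=([4, 5, 3], [0, 1, 2])) + b
    return np.maximum(y, 0.0, dtype=np.float32)


def _pool_infer(x, kind, k=3, stride=1, pad="same"):
    if pad == "same":
        p = (k - 1) // 2
        fill = -np.inf if kind == "max" else 0.0
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=fill)
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(4, 5)) if kind == "max" else win.mean(axis=(4, 5))


class InceptionV3Slim:
    """Depth-multiplier-slimmed inception-v3, forward-only.

    Channel counts follow the published graph, each scaled through
    :func:`scale_depth`. ``feature_dim`` is the width of the global-
    average-pooled vector left when the classification layer is removed:
    the concatenation of the last mixed block's branch widths.
    """

    def __init__(self, cfg: BackboneConfig):
        cfg.validate()
        self.config = cfg
        self._rng = np.random.default_rng(cfg.seed)
        self._d = lambda c: scale_depth(c, cfg.depth_multiplier, cfg.min_depth)
        d = self._d
        # final mixed block branch widths -> pooled feature dimension
        self.feature_dim = d(320) + 2 * d(384) + 2 * d(384) + d(192)
        self.class_order = LABELS[: cfg.n_classes]
        self._weights: dict[str, tuple] = {}
        self._built = False

    def _w(self, name, c_in, c_out, kh, kw):
        key = f"{name}:{kh}x{kw}:{c_in}->{c_out}"
        if key not in self._weights:
            fan_in = kh * kw * c_in
            w = self._rng.normal(0.0, np.sqrt(2.0 / fan_in), (kh, kw, c_in, c_out))
            self._weights[key] = (w.astype(np.float32), np.zeros(c_out, np.float32))
        return self._weights[key]

    def _conv(self, x, name, c_out, k, stride=1, pad="same"):
        kh, kw = (k, k) if np.isscalar(k) else k
        w, b = self._w(name, x.shape[-1], c_out, kh, kw)
        return _conv_infer(x, w, b, stride=stride, pad=pad)

    def forward(self, x: np.ndarray, train: bool = False):
        """Normalised [-1, 1] RGB (N, S, S, 3) -> (features, probs)."""
        if train:
            raise NotImplementedError(
                "inception_v3_slim is a forward-only architecture model; "
                "use the tiny_cnn family for CPU training"
            )
        d = self._d
        x = np.asarray(x, dtype=np.float32)
        # stem
        x = self._conv(x, "stem1", d(32), 3, stride=2, pad="valid")
        x = self._conv(x, "stem2", d(32), 3, pad="valid")
        x = self._conv(x, "stem3", d(64), 3)
        x = _pool_infer(x, "max", 3, 2, pad="valid")
        x = self._conv(x, "stem4", d(80), 1)
        x = self._conv(x, "stem5", d(192), 3, pad="valid")
        x = _pool_infer(x, "max", 3, 2, pad="valid")
        for i, pf in enumerate((32, 64, 64)):  # Mixed_5b..5d
            x = self._block_a(x, f"a{i}", pf)
        x = self._block_b(x, "b0")  # Mixed_6a
        for i, c7 in enumerate((128, 160, 160, 192)):  # Mixed_6b..6e
            x = self._block_c(x, f"c{i}", c7)
        x = self._block_d(x, "d0")  # Mixed_7a
        for i in range(2):  # Mixed_7b, Mixed_7c
            x = self._block_e(x, f"e{i}")
        features = x.mean(axis=(1, 2))
        if features.shape[1] != self.feature_dim:
            raise AssertionError(
                f"pooled feature width {features.shape[1]} != derived {self.feature_dim}"
            )
        if "head" not in self._weights:
            fan_in = self.feature_dim
            w = self._rng.normal(0.0, np.sqrt(1.0 / fan_in), (fan_in, self.config.n_classes))
            self._weights["head"] = (w.astype(np.float32), np.zeros(self.config.n_classes, np.float32))
        w, b = self._weights["head"]
        probs = nn.softmax(features @ w + b)
        return features, probs

    def predict_tiles(self, tiles_uint8: np.ndarray):
        return self.forward(normalize_pixels(tiles_uint8))

    def _block_a(self, x, tag, pool_features):
        d = self._d
        b1 = self._conv(x, f"{tag}.1", d(64), 1)
        b2 = self._conv(x, f"{tag}.2a", d(48), 1)
        b2 = self._conv(b2, f"{tag}.2b", d(64), 5)
        b3 = self._conv(x, f"{tag}.3a", d(64), 1)
        b3 = self._conv(b3, f"{tag}.3b", d(96), 3)
        b3 = self._conv(b3, f"{tag}.3c", d(96), 3)
        b4 = self._conv(_pool_infer(x, "avg"), f"{tag}.4", d(pool_features), 1)
        return np.concatenate([b1, b2, b3, b4], axis=-1)

    def _block_b(self, x, tag):
        d = self._d
        b1 = self._conv(x, f"{tag}.1", d(384), 3, stride=2, pad="valid")
        b2 = self._conv(x, f"{tag}.2a", d(64), 1)
        b2 = self._conv(b2, f"{tag}.2b", d(96), 3)
        b2 = self._conv(b2, f"{tag}.2c", d(96), 3, stride=2, pad="valid")
        b3 = _pool_infer(x, "max", 3, 2, pad="valid")
        return np.concatenate([b1, b2, b3], axis=-1)

    def _block_c(self, x, tag, c7):
        d = self._d
        b1 = self._conv(x, f"{tag}.1", d(192), 1)
        b2 = self._conv(x, f"{tag}.2a", d(c7), 1)
        b2 = self._conv(b2, f"{tag}.2b", d(c7), (1, 7))
        b2 = self._conv(b2, f"{tag}.2c", d(192), (7, 1))
        b3 = self._conv(x, f"{tag}.3a", d(c7), 1)
        b3 = self._conv(b3, f"{tag}.3b", d(c7), (7, 1))
        b3 = self._conv(b3, f"{tag}.3c", d(c7), (1, 7))
        b3 = self._conv(b3, f"{tag}.3d", d(c7), (7, 1))
        b3 = self._conv(b3, f"{tag}.3e", d(192), (1, 7))
        b4 = self._conv(_pool_infer(x, "avg"), f"{tag}.4", d(192), 1)
        return np.concatenate([b1, b2, b3, b4], axis=-1)

    def _block_d(self, x, tag):
        d = self._d
        b1 = self._conv(x, f"{tag}.1a", d(192), 1)
        b1 = self._conv(b1, f"{tag}.1b", d(320), 3, stride=2, pad="valid")
        b2 = self._conv(x, f"{tag}.2a", d(192), 1)
        b2 = self._conv(b2, f"{tag}.2b", d(192), (1, 7))
        b2 = self._conv(b2, f"{tag}.2c", d(192), (7, 1))
        b2 = self._conv(b2, f"{tag}.2d", d(192), 3, stride=2, pad="valid")
        b3 = _pool_infer(x, "max", 3, 2, pad="valid")
        return np.concatenate([b1, b2, b3], axis=-1)

    def _block_e(self, x, tag):
        d = self._d
        b1 = self._conv(x, f"{tag}.1", d(320), 1)
        b2 = self._conv(x, f"{tag}.2a", d(384), 1)
        b2 = np.concatenate(
            [
                self._conv(b2, f"{tag}.2b", d(384), (1, 3)),
                self._conv(b2, f"{tag}.2c", d(384), (3, 1)),
            ],
            axis=-1,
        )
        b3 = self._conv(x, f"{tag}.3a", d(448), 1)
        b3 = self._conv(b3, f"{tag}.3b", d(384), 3)
        b3 = np.concatenate(
            [
                self._conv(b3, f"{tag}.3c", d(384), (1, 3)),
                self._conv(b3, f"{tag}.3d", d(384), (3, 1)),
            ],
            axis=-1,
        )
        b4 = self._conv(_pool_infer(x, "avg"), f"{tag}.4", d(192), 1)
        return np.concatenate([b1, b2, b3, b4], axis=-1)


def build_backbone(cfg: BackboneConfig):
    """Model handle for the configured family; exposes ``feature_dim``."""
    cfg.validate()
    if cfg.family == "tiny_cnn":
        return TinyCNN(cfg)
    return InceptionV3Slim(cfg)


def save_model(model: TinyCNN, path: Path) -> None:
    """Weights as .npz plus a JSON sidecar with config and conventions."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "backbone": asdict(model.config),
        "feature_dim": model.feature_dim,
        "class_order": list(model.class_order),
        "normalization": "x / 127.5 - 1",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: Path) -> TinyCNN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = BackboneConfig(**sidecar["backbone"])
    model = build_backbone(cfg)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
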