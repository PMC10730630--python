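"""NumPy forward pass of the ResNet-18 architecture, classification head removed.

The encoder maps a batch of 3×224×224 images to 512-dimensional embeddings
(the output of the global average pool, i.e. the penultimate layer of
ResNet-18).  Convolutions are evaluated via im2col matrix multiplication and
batch-norm runs in inference mode, so the forward pass is deterministic for
fixed weights.

Weights default to He-initialized values drawn from a fixed seed, which is
sufficient for shape/contract checks and for exercising the full pipeline
offline; trained weights can be supplied as an ``.npz`` whose keys follow the
standard ResNet-18 state-dict naming (``conv1.weight``, ``layer1.0.conv1.weight``,
``bn1.running_mean`` ...).
"""

from __future__ import annotations

import numpy as np

# Channel-wise normalization constants of the natural-image training corpus.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

EMBEDDING_DIM = 512

# (blocks per stage, channels per stage) of ResNet-18.
_STAGES = [(2, 64), (2, 128), (2, 256), (2, 512)]
_BN_EPS = 1e-5


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) → (N, out_h*out_w, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w, c * kh * kw)
    return cols, out_h, out_w


def _conv2d(x: np.ndarray, weight: np.ndarray, stride: int, pad: int) -> np.ndarray:
    out_c, in_c, kh, kw = weight.shape
    cols, out_h, out_w = _im2col(x, kh, kw, stride, pad)
    out = cols @ weight.reshape(out_c, in_c * kh * kw).T
    return out.transpose(0, 2, 1).reshape(x.shape[0], out_c, out_h, out_w)


def _maxpool(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    return windows.max(axis=(4, 5))


class ResNet18Encoder:
    """ResNet-18 feature extractor: 3×224×224 batch → (N, 512) embeddings."""

    def __init__(self, weights: dict[str, np.ndarray] | None = None, seed: int = 0):
        self.weights = weights if weights is not None else self._init_weights(seed)

    @classmethod
    def from_npz(cls, path) -> "ResNet18Encoder":
        with np.load(path) as data:
            return cls(weights={k: np.asarray(data[k], dtype=np.float32) for k in data.files})

    # -- weight construction -------------------------------------------------

    @staticmethod
    def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        fan_in = int(np.prod(shape[1:]))
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

    @classmethod
    def _init_weights(cls, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        w: dict[str, np.ndarray] = {"conv1.weight": cls._he(rng, (64, 3, 7, 7))}
        cls._init_bn(w, "bn1", 64)
        in_c = 64
        for i, (blocks, out_c) in enumerate(_STAGES, start=1):
            for b in range(blocks):
                prefix = f"layer{i}.{b}"
                stride = 2 if (i > 1 and b == 0) else 1
                w[f"{prefix}.conv1.weight"] = cls._he(rng, (out_c, in_c, 3, 3))
                cls._init_bn(w, f"{prefix}.bn1", out_c)
                w[f"{prefix}.conv2.weight"] = cls._he(rng, (out_c, out_c, 3, 3))
                cls._init_bn(w, f"{prefix}.bn2", out_c)
                if stride != 1 or in_c != out_c:
                    w[f"{prefix}.downsample.0.weight"] = cls._he(rng, (out_c, in_c, 1, 1))
                    cls._init_bn(w, f"{prefix}.downsample.1", out_c)
                in_c = out_c
        return w

    @staticmethod
    def _init_bn(w: dict[str, np.ndarray], prefix: str, c: int) -> None:
        w[f"{prefix}.weight"] = np.ones(c, dtype=np.float32)
        w[f"{prefix}.bias"] = np.zeros(c, dtype=np.float32)
        w[f"{prefix}.running_mean"] = np.zeros(c, dtype=np.float32)
        w[f"{prefix}.running_var"] = np.ones(c, dtype=np.float32)

    # -- forward -------------------------------------------------------------

    def _bn(self, x: np.ndarray, prefix: str) -> np.ndarray:
        w = self.weights
        scale = w[f"{prefix}.weight"] / np.sqrt(w[f"{prefix}.running_var"] + _BN_EPS)
        shift = w[f"{prefix}.bias"] - w[f"{prefix}.running_mean"] * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def _block(self, x: np.ndarray, prefix: str, stride: int) -> np.ndarray:
        w = self.weights
        out = _conv2d(x, w[f"{prefix}.conv1.weight"], stride, 1)
        out = np.maximum(self._bn(out, f"{prefix}.bn1"), 0.0)
        out = _conv2d(out, w[f"{prefix}.conv2.weight"], 1, 1)
        out = self._bn(out, f"{prefix}.bn2")
        if f"{prefix}.downsample.0.weight" in w:
            identity = _conv2d(x, w[f"{prefix}.downsample.0.weight"], stride, 0)
            identity = self._bn(identity, f"{prefix}.downsample.1")
        else:
            identity = x
        return np.maximum(out + identity, 0.0)

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        """Encode a (N, 3, 224, 224) float batch into (N, 512) embeddings."""
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) batch, got shape {x.shape}")
        x = _conv2d(x, self.weights["conv1.weight"], stride=2, pad=3)
        x = np.maximum(self._bn(x, "bn1"), 0.0)
        x = _maxpool(x, k=3, stride=2, pad=1)
        for i, (blocks, _) in enumerate(_STAGES, start=1):
            for b in range(blocks):
                stride = 2 if (i > 1 and b == 0) else 1
                x = self._block(x, f"layer{i}.{b}", stride)
        return x.mean(axis=(2, 3)).astype(np.float64)
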