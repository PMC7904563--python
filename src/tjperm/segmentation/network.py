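"""Multi-resolution residual segmentation network, implemented in NumPy.

The model follows the refinement-network pattern used for semantic
segmentation of microscopy images: stacks of 3x3 convolutions with ReLU
activations and residual connections extract features at several
resolutions (strides 1/2/4/...), and a decoder fuses the coarse features
back up to a full-resolution per-pixel junction probability via a sigmoid
head. Forward and backward passes are written directly against NumPy
(im2col convolutions), which keeps training deterministic, dependency-free
and fast enough for CPU-scale schedules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["SegmenterConfig", "RefineNet"]


@dataclass(frozen=True)
class SegmenterConfig:
    """Training hyperparameters.

    Defaults are the full-scale recipe (input 256, batch 32, lr 1e-5,
    3x3 filters, stride 1, 128 channels, Adam with weight decay 0);
    :meth:`desk_scale` gives a reduced schedule that trains in minutes on
    one CPU.
    """

    input_size_px: int = 256
    batch_size: int = 32
    learning_rate: float = 1e-5
    conv_filter_size: int = 3
    stride: int = 1
    n_channels: int = 128
    n_epochs: int = 320
    weight_decay: float = 0.0
    optimiser: str = "adam"
    rng_seed: int = 0
    n_levels: int = 4
    eval_interval: int = 25
    max_updates: Optional[int] = None
    dice_smoothing: float = 1.0

    def __post_init__(self) -> None:
        if self.optimiser != "adam":
            raise ValueError("only the Adam optimiser is implemented")
        if self.stride != 1:
            raise ValueError("only stride-1 convolutions are supported")
        if self.input_size_px % 2 ** (self.n_levels - 1):
            raise ValueError("input_size_px must be divisible by 2**(n_levels-1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "SegmenterConfig":
        """Reduced schedule for CPU runs: 64-px crops, 8 channels, 3 levels."""
        base = dict(
            input_size_px=64, batch_size=8, learning_rate=1e-3, n_channels=8,
            n_epochs=20, n_levels=3, eval_interval=25,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) with same zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


class _Conv:
    """Same-padded stride-1 convolution with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if cache:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.dW += (dflat.T @ self._cols).reshape(self.W.shape)
        self.db += dflat.sum(axis=0)
        # input gradient = convolution of dout with transposed, 180-rotated kernels
        w_t = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_d = _im2col(dout, self.k)
        dx = cols_d @ w_t.reshape(w_t.shape[0], -1).T
        self._cols = None
        return dx.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    @property
    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _ResBlock:
    """y = relu(x + conv2(relu(conv1(x))))."""

    def __init__(self, c: int, k: int, rng: np.random.Generator):
        self.conv1 = _Conv(c, c, k, rng)
        self.conv2 = _Conv(c, c, k, rng)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        h1 = self.conv1.forward(x, cache)
        a1 = _relu(h1)
        h2 = self.conv2.forward(a1, cache)
        y = _relu(x + h2)
        if cache:
            self._m1 = h1 > 0
            self._my = (x + h2) > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy * self._my
        da1 = self.conv2.backward(d)
        dh1 = da1 * self._m1
        dx = self.conv1.backward(dh1)
        return dx + d

    @property
    def convs(self) -> List[_Conv]:
        return [self.conv1, self.conv2]


class RefineNet:
    """Encoder at strides 1/2/4/... with residual blocks, fused top-down.

    ``forward`` maps a batch ``(B, 1, H, W)`` in [0, 1] to per-pixel
    probabilities ``(B, H, W)``; H and W must be divisible by
    ``2**(n_levels-1)``.
    """

    def __init__(self, config: SegmenterConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        c, k = config.n_channels, config.conv_filter_size
        self.stem = _Conv(1, c, k, rng)
        self.enc = [_ResBlock(c, k, rng) for _ in range(config.n_levels)]
        self.fuse = [_Conv(c, c, k, rng) for _ in range(config.n_levels - 1)]
        self.head = _Conv(c, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    @property
    def _convs(self) -> List[_Conv]:
        convs = [self.stem]
        for blk in self.enc:
            convs.extend(blk.convs)
        convs.extend(self.fuse)
        convs.append(self.head)
        return convs

    def parameters(self) -> List[np.ndarray]:
        return [p for conv in self._convs for p in conv.params]

    def gradients(self) -> List[np.ndarray]:
        return [g for conv in self._convs for g in conv.grads]

    def zero_grad(self) -> None:
        for conv in self._convs:
            conv.dW[...] = 0.0
            conv.db[...] = 0.0

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: List[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        stride_total = 2 ** (self.config.n_levels - 1)
        if x.shape[2] % stride_total or x.shape[3] % stride_total:
            raise ValueError(
                f"input extent {x.shape[2:]} not divisible by {stride_total}"
            )
        h0 = self.stem.forward(x, cache)
        a0 = _relu(h0)
        feats = []
        cur = a0
        for lvl, blk in enumerate(self.enc):
            if lvl > 0:
                cur = _avgpool2(cur)
            cur = blk.forward(cur, cache)
            feats.append(cur)
        top = feats[-1]
        fused_pre: List[np.ndarray] = []
        for lvl in range(self.config.n_levels - 2, -1, -1):
            s = _upsample2(top) + feats[lvl]
            h = self.fuse[lvl].forward(s, cache)
            top = _relu(h)
            fused_pre.append(h)
        z = self.head.forward(top, cache)[:, 0]
        p = 1.0 / (1.0 + np.exp(-z))
        if cache:
            self._stem_mask = h0 > 0
            self._fuse_masks = [h > 0 for h in fused_pre]
            self._p = p
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate gradient w.r.t. the probability output."""
        dz = dp * self._p * (1.0 - self._p)
        dtop = self.head.backward(dz[:, None])
        dfeats: Dict[int, np.ndarray] = {}
        for i, lvl in enumerate(range(0, self.config.n_levels - 1)):
            # reverse of decoder: decoder ran lvl = L-2 .. 0, cached masks in
            # that order; we unwind from lvl 0 upward
            mask = self._fuse_masks[len(self._fuse_masks) - 1 - i]
            dh = dtop * mask
            ds = self.fuse[lvl].backward(dh)
            dfeats[lvl] = ds
            dtop = _upsample2_backward(ds)
        dfeats[self.config.n_levels - 1] = dtop
        dcur = None
        for lvl in range(self.config.n_levels - 1, -1, -1):
            d = dfeats[lvl] if dcur is None else dfeats[lvl] + dcur
            d = self.enc[lvl].backward(d)
            dcur = _avgpool2_backward(d) if lvl > 0 else d
        da0 = dcur
        dh0 = da0 * self._stem_mask
        self.stem.backward(dh0)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file archive with the config embedded."""
        arrays = {f"param_{i}": p for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "RefineNet":
        with np.load(path, allow_pickle=False) as data:
            config = SegmenterConfig(**json.loads(str(data["config"])))
            model = cls(config)
            state = [data[f"param_{i}"] for i in range(len(model.parameters()))]
        model.set_state(state)
        return model


class Adam:
    """Adam optimiser over a parameter list, with optional weight decay."""

    def __init__(self, params: List[np.ndarray], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.wd:
                g = g + self.wd * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
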