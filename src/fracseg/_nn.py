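"""Minimal 3D convolutional network core: numpy + numba kernels.

Implements exactly what the segmentation networks need — 3x3x3 and 1x1x1
convolutions, instance normalization, leaky ReLU, 2x max-pooling,
nearest-neighbour upsampling, channel concatenation, softmax — each with
an explicit backward pass, plus Adam.  The 3^3 convolutions run as
numba-compiled direct loops in (N, C, D, H, W) layout with a contiguous
spatial inner loop, which SIMD-vectorizes well; the input gradient is the
transposed convolution, computed as a forward convolution with the
channel-swapped, spatially flipped kernel.

Layers cache their last forward activations, so the usage contract is
strictly ``forward`` then ``backward`` on the same input, single-threaded.
Arrays are float32 of shape (N, C, D, H, W).
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

__all__ = ["UNet3D", "Adam", "softmax", "softmax_backward"]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, fastmath=True)
def _conv3_fwd(xp, W, b, y):
    # xp (N, Ci, D+2, H+2, W+2), W (Co, Ci, 3, 3, 3), b (Co,), y (N, Co, D, H, W)
    N, Co, D, H, Wd = y.shape
    Ci = xp.shape[1]
    for n in range(N):
        for co in range(Co):
            acc = y[n, co]
            bv = b[co]
            for d in range(D):
                for h in range(H):
                    for w in range(Wd):
                        acc[d, h, w] = bv
            for ci in range(Ci):
                xpc = xp[n, ci]
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            wv = W[co, ci, i, j, k]
                            for d in range(D):
                                for h in range(H):
                                    xr = xpc[d + i, h + j]
                                    accr = acc[d, h]
                                    for w in range(Wd):
                                        accr[w] += wv * xr[w + k]


@njit(cache=True, fastmath=True)
def _conv3_bwd_dw(xp, dy, gW, gb):
    # gW (Co, Ci, 3, 3, 3), gb (Co,) accumulated in place; single spatial pass
    N, Co, D, H, Wd = dy.shape
    Ci = xp.shape[1]
    for n in range(N):
        for co in range(Co):
            dyc = dy[n, co]
            s = 0.0
            for d in range(D):
                for h in range(H):
                    dyr = dyc[d, h]
                    for w in range(Wd):
                        s += dyr[w]
            gb[co] += s
            for ci in range(Ci):
                xpc = xp[n, ci]
                gw = np.zeros((3, 3, 3), dtype=np.float32)
                for d in range(D):
                    for h in range(H):
                        dyr = dyc[d, h]
                        for i in range(3):
                            for j in range(3):
                                xr = xpc[d + i, h + j]
                                for k in range(3):
                                    acc = 0.0
                                    for w in range(Wd):
                                        acc += dyr[w] * xr[w + k]
                                    gw[i, j, k] += acc
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            gW[co, ci, i, j, k] += gw[i, j, k]


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)


def _pad1(x: np.ndarray) -> np.ndarray:
    N, C, D, H, W = x.shape
    xp = np.zeros((N, C, D + 2, H + 2, W + 2), dtype=np.float32)
    xp[:, :, 1:-1, 1:-1, 1:-1] = x
    return xp


class Conv3d3:
    """Same-padded 3^3 convolution via numba direct loops."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 need_dx: bool = True):
        fan_in = cin * 27
        self.cin, self.cout = cin, cout
        self.need_dx = need_dx
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(cout, cin, 3, 3, 3)))
        self.b = Param(np.zeros(cout))
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = _pad1(np.ascontiguousarray(x, dtype=np.float32))
        N = x.shape[0]
        y = np.empty((N, self.cout) + x.shape[2:], dtype=np.float32)
        _conv3_fwd(xp, self.W.v, self.b.v, y)
        self._xp = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        _conv3_bwd_dw(self._xp, dy, self.W.g, self.b.g)
        if not self.need_dx:
            return None
        # input gradient = conv of dy with the channel-swapped flipped kernel
        Wt = np.ascontiguousarray(
            self.W.v.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        dyp = _pad1(dy)
        dx = np.empty((dy.shape[0], self.cin) + dy.shape[2:], dtype=np.float32)
        _conv3_fwd(dyp, Wt, np.zeros(self.cin, dtype=np.float32), dx)
        return dx


class Conv1x1:
    """Pointwise convolution: a matmul over the channel axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(self.W.v, x, axes=([1], [1]))  # (Co, N, D, H, W)
        y = y.transpose(1, 0, 2, 3, 4) + self.b.v[None, :, None, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        N = x.shape[0]
        x2 = x.transpose(1, 0, 2, 3, 4).reshape(self.cin, -1)
        dy2 = dy.transpose(1, 0, 2, 3, 4).reshape(self.cout, -1)
        self.W.g += dy2 @ x2.T
        self.b.g += dy2.sum(axis=1)
        dx = (self.W.v.T @ dy2).reshape((self.cin, N) + x.shape[2:])
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3, 4))


class InstanceNorm:
    """Per-(sample, channel) normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.gamma.v[None, :, None, None, None]
        b = self.beta.v[None, :, None, None, None]
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        ax = (2, 3, 4)
        self.gamma.g += (dy * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.g += dy.sum(axis=(0, 2, 3, 4))
        dxhat = dy * self.gamma.v[None, :, None, None, None]
        m1 = dxhat.mean(axis=ax, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU:
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, D, H, W = x.shape
        xr = x.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._cache
        ym = y[:, :, :, None, :, None, :, None]
        mask = xr == ym
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        dxr = mask * (dy[:, :, :, None, :, None, :, None] / counts)
        N, C, D2, _, H2, _, W2, _ = xr.shape
        return dxr.reshape(N, C, D2 * 2, H2 * 2, W2 * 2)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, D, H, W = dy.shape
        return dy.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2).sum(axis=(3, 5, 7))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(P: np.ndarray, dP: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient w.r.t. logits given gradient w.r.t. softmax output."""
    s = (dP * P).sum(axis=axis, keepdims=True)
    return P * (dP - s)


class ConvBlock:
    """Two (conv3 -> instance norm -> leaky ReLU) stages, as in standard UNets."""

    def __init__(self, cin: int, cout: int, rng, n_convs: int = 2,
                 need_dx: bool = True):
        self.stages = []
        for i in range(n_convs):
            self.stages.append((Conv3d3(cin if i == 0 else cout, cout, rng,
                                        need_dx=(need_dx or i > 0)),
                                InstanceNorm(cout), LeakyReLU()))

    def params(self):
        out = []
        for conv, norm, _ in self.stages:
            out.extend(conv.params() + norm.params())
        return out

    def forward(self, x):
        for conv, norm, act in self.stages:
            x = act.forward(norm.forward(conv.forward(x)))
        return x

    def backward(self, dy):
        for conv, norm, act in reversed(self.stages):
            dy = conv.backward(norm.backward(act.backward(dy)))
        return dy


class UNet3D:
    """Compact 3D UNet with optional multi-resolution supervision heads.

    ``forward`` maps a (N, C, D, H, W) patch to softmax probability grids,
    full resolution first; with deep supervision there are ``n_levels - 1``
    heads (the bottleneck carries no head), each at half the resolution of
    the previous.  ``backward`` takes the per-level loss gradients w.r.t.
    the probabilities.
    """

    MAX_CHANNELS = 128

    def __init__(self, in_channels: int, n_classes: int, n_levels: int = 4,
                 base_channels: int = 8, deep_supervision: bool = True,
                 seed: int = 0):
        if n_levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.n_levels = n_levels
        self.base_channels = base_channels
        self.deep_supervision = deep_supervision
        ch = [min(base_channels * 2 ** l, self.MAX_CHANNELS) for l in range(n_levels)]
        self._ch = ch
        self.enc = [ConvBlock(in_channels if l == 0 else ch[l - 1], ch[l], rng,
                              need_dx=(l > 0))
                    for l in range(n_levels)]
        self.pools = [MaxPool2() for _ in range(n_levels - 1)]
        self.ups = [Upsample2() for _ in range(n_levels - 1)]
        self.dec = [ConvBlock(ch[l + 1] + ch[l], ch[l], rng)
                    for l in range(n_levels - 1)]
        self.n_heads = (n_levels - 1) if deep_supervision else 1
        self.heads = [Conv1x1(ch[l], n_classes, rng) for l in range(self.n_heads)]
        self._probs: Optional[List[np.ndarray]] = None

    # -- parameter plumbing -------------------------------------------------

    def modules(self):
        return self.enc + self.dec + self.heads

    def params(self) -> List[Param]:
        out = []
        for m in self.modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.g[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.v for i, p in enumerate(self.params())}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        for i, p in enumerate(self.params()):
            p.v[...] = state[f"p{i}"]

    def config(self) -> Dict:
        return {
            "in_channels": self.in_channels, "n_classes": self.n_classes,
            "n_levels": self.n_levels, "base_channels": self.base_channels,
            "deep_supervision": self.deep_supervision,
        }

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, D, H, W) input, got {x.shape}")
        f = 2 ** (self.n_levels - 1)
        if any(s % f for s in x.shape[2:]):
            raise ValueError(f"spatial shape {x.shape[2:]} not divisible by {f}")

    def forward(self, x: np.ndarray) -> List[np.ndarray]:
        self._check_input(x)
        h = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for l in range(self.n_levels - 1):
            h = self.enc[l].forward(h)
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.enc[-1].forward(h)
        dec_feats = {}
        for l in reversed(range(self.n_levels - 1)):
            h = self.ups[l].forward(h)
            h = np.concatenate([h, skips[l]], axis=1)
            h = self.dec[l].forward(h)
            dec_feats[l] = h
        probs = [softmax(self.heads[l].forward(dec_feats[l]))
                 for l in range(self.n_heads)]
        self._probs = probs
        return probs

    def backward(self, dprobs: List[np.ndarray]):
        if self._probs is None:
            raise RuntimeError("backward called before forward")
        if len(dprobs) != self.n_heads:
            raise ValueError(f"expected {self.n_heads} gradient grids, got {len(dprobs)}")
        dskips = [None] * (self.n_levels - 1)
        dh = None  # gradient flowing into dec_feats[l]
        for l in range(self.n_levels - 1):
            dhead = None
            if l < self.n_heads:
                dlogits = softmax_backward(self._probs[l],
                                           np.asarray(dprobs[l], dtype=np.float32))
                dhead = self.heads[l].backward(dlogits)
            if dh is None:
                dh = dhead
            elif dhead is not None:
                dh = dh + dhead
            dcat = self.dec[l].backward(dh)
            c_up = dcat.shape[1] - self._ch[l]
            dup, dskips[l] = dcat[:, :c_up], dcat[:, c_up:]
            dh = self.ups[l].backward(dup)
        dh = self.enc[-1].backward(dh)
        for l in reversed(range(self.n_levels - 1)):
            dh = self.pools[l].backward(dh)
            dh = dh + dskips[l]
            dh = self.enc[l].backward(dh)
        return dh

    # -- persistence ---------------------------------------------------------

    def save(self, path: str):
        np.savez_compressed(path, __config__=json.dumps(self.config()),
                            **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "UNet3D":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            model = cls(**cfg)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


class Adam:
    def __init__(self, params: List[Param], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def state(self) -> Dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state(self, st: Dict):
        self.t = int(st["t"])
        self.m = [np.asarray(a) for a in st["m"]]
        self.v = [np.asarray(a) for a in st["v"]]
        self.lr = float(st["lr"])
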