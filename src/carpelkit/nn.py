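"""Minimal convolutional-network engine used by the segmentation module.

Implements exactly the pieces a small U-Net-style encoder--decoder needs:
3x3 same-padding convolutions (nine shifted GEMMs), ReLU, 2x2 max pooling,
nearest-neighbour x2 upsampling, channel concatenation, a 1x1 output
convolution, sigmoid, a soft-Dice loss and the Adam optimizer -- all in
float32 numpy with hand-written backward passes.  Everything is a pure
function of its inputs plus the explicit RNG, so training is bit
reproducible on a given machine.

Arrays are NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

F32 = np.float32


# ---------------------------------------------------------------------------
# layers (3x3 conv: stride 1, same padding)
# ---------------------------------------------------------------------------

class Conv3x3:
    """3x3 convolution + instance norm + ReLU (each part optional).

    The convolution is evaluated as nine shifted GEMMs (one per kernel tap)
    rather than im2col: same arithmetic, far less memory traffic, which is
    what binds a CPU-only float32 implementation at these sizes.  Per-sample,
    per-channel normalization keeps activation magnitudes bounded -- without
    it an unnormalized deep ReLU stack trained with Adam can blow up its
    activations within a few dozen steps.
    """

    NORM_EPS = 1e-5

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 relu: bool = True, norm: bool = True):
        fan_in = c_in * 9
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)       # conv bias (gamma/beta when norm)
        self.relu = relu
        self.norm = norm
        if norm:
            self.gamma = np.ones(c_out, dtype=F32)
        self.c_in, self.c_out = c_in, c_out
        self._xp = None
        self._mask = None

    def params(self):
        return [self.w, self.b, self.gamma] if self.norm else [self.w, self.b]

    def grads(self):
        return ([self.dw, self.db, self.dgamma] if self.norm
                else [self.dw, self.db])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        xp = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (N,H+2,W+2,C)
        y = np.zeros((n, h, w, self.c_out), dtype=F32)
        for ki in range(3):
            for kj in range(3):
                xs = xp[:, ki:ki + h, kj:kj + w, :].reshape(-1, c)
                y += (xs @ self.w[:, :, ki, kj].T).reshape(n, h, w, self.c_out)
        if self.norm:
            mu = y.mean(axis=(1, 2), keepdims=True)
            var = y.var(axis=(1, 2), keepdims=True)
            ivstd = 1.0 / np.sqrt(var + self.NORM_EPS)
            xhat = (y - mu) * ivstd
            y = self.gamma * xhat + self.b
            if train:
                self._xhat = xhat.astype(F32)
                self._ivstd = ivstd.astype(F32)
        else:
            y += self.b
        if self.relu:
            mask = y > 0
            y = np.where(mask, y, F32(0.0)).astype(F32)
            if train:
                self._mask = mask
        if train:
            self._xp = xp
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray):
        n, co, h, w = dy.shape
        c = self.c_in
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).astype(F32)
        if self.relu:
            np.multiply(dyf, self._mask, out=dyf)
        if self.norm:
            self.dgamma = (dyf * self._xhat).sum(axis=(0, 1, 2))
            self.db = dyf.sum(axis=(0, 1, 2))
            m = h * w
            dxhat = dyf * self.gamma
            # d(pre-norm): ivstd * (dxhat - mean(dxhat) - xhat * mean(dxhat*xhat))
            mean_d = dxhat.mean(axis=(1, 2), keepdims=True)
            mean_dx = (dxhat * self._xhat).mean(axis=(1, 2), keepdims=True)
            dyf = self._ivstd * (dxhat - mean_d - self._xhat * mean_dx)
            dyf = dyf.astype(F32)
            self._xhat = None
            self._ivstd = None
        else:
            self.db = dyf.sum(axis=(0, 1, 2))
        dyflat = dyf.reshape(-1, co)
        self.dw = np.empty_like(self.w)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for ki in range(3):
            for kj in range(3):
                xs = self._xp[:, ki:ki + h, kj:kj + w, :].reshape(-1, c)
                self.dw[:, :, ki, kj] = dyflat.T @ xs
                dxp[:, ki:ki + h, kj:kj + w, :] += (
                    dyflat @ self.w[:, :, ki, kj]).reshape(n, h, w, c)
        self._xp = None
        self._mask = None
        dx = dxp[:, 1:1 + h, 1:1 + w, :]
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Conv1x1:
    """1x1 convolution (per-pixel linear head), no activation."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        y = np.einsum('nchw,oc->nohw', x, self.w, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray):
        self.dw = np.einsum('nohw,nchw->oc', dy, self._x, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3))
        dx = np.einsum('nohw,oc->nchw', dy, self.w, optimize=True)
        self._x = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return y

    def backward(self, dy: np.ndarray):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling."""
    return np.ascontiguousarray(x.repeat(2, axis=2).repeat(2, axis=3))


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# U-Net style encoder--decoder
# ---------------------------------------------------------------------------

class UNet:
    """Encoder--decoder with skip connections.

    `depth` encoder levels with channel widths base * 2**level, a bottleneck,
    nearest-upsample decoder levels with skip concatenation, and a 1x1
    sigmoid head with `n_out` channels.  Two 3x3+ReLU convolutions per block.
    """

    def __init__(self, depth: int, base: int, n_out: int, seed: int,
                 in_channels: int = 3):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.n_out = n_out
        widths = [base * (2 ** d) for d in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for d in range(depth):
            self.enc.append((Conv3x3(c_prev, widths[d], rng),
                             Conv3x3(widths[d], widths[d], rng)))
            c_prev = widths[d]
        self.mid = (Conv3x3(c_prev, widths[depth], rng),
                    Conv3x3(widths[depth], widths[depth], rng))
        self.dec = []
        c_prev = widths[depth]
        for d in reversed(range(depth)):
            c_cat = c_prev + widths[d]
            self.dec.append((Conv3x3(c_cat, widths[d], rng),
                             Conv3x3(widths[d], widths[d], rng)))
            c_prev = widths[d]
        self.head = Conv1x1(c_prev, n_out, rng)
        self.pools = [MaxPool2() for _ in range(depth)]

    # -- parameter plumbing -------------------------------------------------
    def _convs(self):
        for blk in self.enc:
            yield from blk
        yield from self.mid
        for blk in self.dec:
            yield from blk
        yield self.head

    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params())
        return out

    def grads(self):
        out = []
        for conv in self._convs():
            out.extend(conv.grads())
        return out

    def state_dict(self) -> dict:
        return {f"p{i}": p for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            q = np.asarray(state[f"p{i}"], dtype=F32)
            if q.shape != p.shape:
                raise ValueError(f"checkpoint shape mismatch at p{i}: "
                                 f"{q.shape} vs {p.shape}")
            p[...] = q

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Returns sigmoid probabilities, shape (N, n_out, H, W)."""
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for d in range(self.depth):
            a, b = self.enc[d]
            x = b.forward(a.forward(x, train), train)
            skips.append(x)
            x = self.pools[d].forward(x, train)
        a, b = self.mid
        x = b.forward(a.forward(x, train), train)
        self._skip_ch = []
        for i, d in enumerate(reversed(range(self.depth))):
            x = upsample2(x)
            skip = skips[d]
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            a, b = self.dec[i]
            x = b.forward(a.forward(x, train), train)
        logits = self.head.forward(x, train)
        # clamp keeps sigmoid gradients non-zero in float arithmetic, so a
        # transiently saturated network can still recover during training
        probs = expit(np.clip(logits.astype(np.float64), -25.0, 25.0))
        if train:
            self._probs = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        p = self._probs
        dlogits = (dprobs * p * (1.0 - p)).astype(F32)
        dx = self.head.backward(dlogits)
        dskips = [None] * self.depth
        for i in reversed(range(len(self.dec))):
            a, b = self.dec[i]
            dx = a.backward(b.backward(dx))
            n_skip = self._skip_ch[i]
            dskip, dx = dx[:, :n_skip], dx[:, n_skip:]
            d_level = self.depth - 1 - i
            dskips[d_level] = dskip
            dx = upsample2_backward(dx)
        a, b = self.mid
        dx = a.backward(b.backward(dx))
        for d in reversed(range(self.depth)):
            dx = self.pools[d].backward(dx)
            dx = dx + dskips[d]
            a, b = self.enc[d]
            dx = a.backward(b.backward(dx))
        self._probs = None


# ---------------------------------------------------------------------------
# Soft-Dice loss and Adam
# ---------------------------------------------------------------------------

def soft_dice_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """1 - soft Dice, averaged over channels and batch items.

    Returns (loss, dprobs).  probs/targets: (N, C, H, W), targets in {0,1}.
    """
    p = probs.astype(np.float64)
    t = targets.astype(np.float64)
    inter = (p * t).sum(axis=(2, 3))
    tot = p.sum(axis=(2, 3)) + t.sum(axis=(2, 3))
    dice = (2.0 * inter + eps) / (tot + eps)
    loss = float(1.0 - dice.mean())
    # d(dice)/dp = 2t/(tot+eps) - (2 inter + eps)/(tot+eps)^2
    denom = tot + eps
    ddice_dp = (2.0 * t / denom[:, :, None, None]
                - ((2.0 * inter + eps) / denom ** 2)[:, :, None, None])
    dprobs = -ddice_dp / (dice.size)
    return loss, dprobs


class Adam:
    """Adam with global gradient-norm clipping (default max norm 5)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        if self.clip_norm is not None:
            gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads))
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
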