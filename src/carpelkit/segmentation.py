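"""Trainable stigma / ovary segmentation.

Two independently trained encoder--decoder networks annotate carpel images:
the *stigma network* predicts a single stigma-envelope mask; the *ovary
network* predicts two masks (ovary and stigma) from the same RGB input.
Training minimises 1 - soft Dice with Adam.  Images are resized to the
network input size for training and inference; predicted probability maps
are resized back and thresholded at the image's native resolution, so all
downstream geometry is measured on native-resolution masks using each
image's own mm-per-pixel scale.

`CarpelSegmenter` follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``); `train_segmenter` and `predict_masks` are
thin functional wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .nn import Adam, UNet, soft_dice_loss
from .synthetic import CarpelImage

__all__ = [
    "SegmentationConfig",
    "CarpelSegmenter",
    "train_segmenter",
    "predict_masks",
    "postprocess_mask",
    "save_segmenter",
    "load_segmenter",
]


@dataclass
class SegmentationConfig:
    """Hyperparameters of one segmentation network."""

    input_size: int = 256
    depth: int = 4
    base_channels: int = 16
    n_output_channels: int = 1     # 1 = stigma net, 2 = ovary net (ovary, stigma)
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 2
    val_fraction: float = 0.2
    seed: int = 0
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^depth = {2 ** self.depth}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.n_output_channels not in (1, 2):
            raise ValueError("n_output_channels must be 1 (stigma) or 2 (ovary)")


def _as_pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, CarpelImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    if px.size == 0:
        raise ValueError("empty image")
    return px


def _dihedral(x: np.ndarray, k: int) -> np.ndarray:
    """Apply one of the 8 axis-aligned flips/rotations to (C, H, W)."""
    if k >= 4:
        x = x[:, :, ::-1]
    return np.rot90(x, k % 4, axes=(1, 2))


class CarpelSegmenter(BaseEstimator):
    """Encoder--decoder semantic segmenter for carpel tissues.

    Parameters mirror :class:`SegmentationConfig`.  After ``fit``:

    Attributes
    ----------
    net_ : the trained network
    training_log_ : DataFrame with per-epoch train/validation soft-Dice loss
    config_ : the validated SegmentationConfig echo
    """

    def __init__(self, input_size: int = 256, depth: int = 4,
                 base_channels: int = 16, n_output_channels: int = 1,
                 learning_rate: float = 1e-3, epochs: int = 15,
                 batch_size: int = 2, val_fraction: float = 0.2,
                 seed: int = 0, binarize_threshold: float = 0.5):
        self.input_size = input_size
        self.depth = depth
        self.base_channels = base_channels
        self.n_output_channels = n_output_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.seed = seed
        self.binarize_threshold = binarize_threshold

    # -- helpers --------------------------------------------------------------
    def _config(self) -> SegmentationConfig:
        return SegmentationConfig(**{k: getattr(self, k)
                                     for k in SegmentationConfig.__dataclass_fields__})

    def _prepare(self, images, truths):
        size = self.input_size
        xs, ys = [], []
        for i, (img, truth) in enumerate(zip(images, truths)):
            px = _as_pixels(img)
            if isinstance(truth, np.ndarray):
                truth = (truth,)
            if len(truth) != self.n_output_channels:
                raise ValueError(
                    f"image {i}: {len(truth)} truth masks for a "
                    f"{self.n_output_channels}-channel network")
            for m in truth:
                if m.shape != px.shape[:2]:
                    raise ValueError(f"image {i}: truth shape {m.shape} does not "
                                     f"match image {px.shape[:2]}")
            x = resize(px.astype(np.float32) / 255.0, (size, size),
                       order=1, anti_aliasing=True, preserve_range=True)
            y = np.stack([
                resize(m.astype(np.float32), (size, size), order=0,
                       anti_aliasing=False, preserve_range=True)
                for m in truth])
            xs.append(np.ascontiguousarray(x.transpose(2, 0, 1), dtype=np.float32))
            ys.append(y.astype(np.float32))
        return np.stack(xs), np.stack(ys)

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y):
        """Train on images ``X`` and per-image truth-mask tuples ``y``."""
        config = self._config()
        if len(X) < 10:
            raise ValueError("need at least 10 annotated images to train")
        if len(X) != len(y):
            raise ValueError("images and truths differ in length")
        xs, ys = self._prepare(X, y)
        rng = np.random.default_rng(config.seed)
        n = len(xs)
        order = rng.permutation(n)
        n_val = max(1, int(round(config.val_fraction * n)))
        val_idx, train_idx = order[:n_val], order[n_val:]

        net = UNet(depth=config.depth, base=config.base_channels,
                   n_out=config.n_output_channels, seed=config.seed)
        opt = Adam(net.params(), lr=config.learning_rate)
        log = []
        for epoch in range(config.epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(perm), config.batch_size):
                idx = perm[start:start + config.batch_size]
                ks = rng.integers(0, 8, size=len(idx))
                xb = np.stack([_dihedral(xs[i], k) for i, k in zip(idx, ks)])
                yb = np.stack([_dihedral(ys[i], k) for i, k in zip(idx, ks)])
                probs = net.forward(xb, train=True)
                loss, dprobs = soft_dice_loss(probs, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                net.backward(dprobs)
                opt.step(net.grads())
                losses.append(loss)
            val_losses = []
            for start in range(0, len(val_idx), config.batch_size):
                idx = val_idx[start:start + config.batch_size]
                probs = net.forward(xs[idx], train=False)
                vloss, _ = soft_dice_loss(probs, ys[idx])
                val_losses.append((vloss, len(idx)))
            vl = float(np.average([v for v, _ in val_losses],
                                  weights=[w for _, w in val_losses]))
            log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": vl})
        self.net_ = net
        self.config_ = config
        self.training_log_ = pd.DataFrame(log)
        return self

    def predict_proba_map(self, image) -> np.ndarray:
        """Per-channel probability maps at the image's native resolution."""
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not trained; call fit first")
        px = _as_pixels(image)
        size = self.config_.input_size
        x = resize(px.astype(np.float32) / 255.0, (size, size),
                   order=1, anti_aliasing=True, preserve_range=True)
        x = np.ascontiguousarray(x.transpose(2, 0, 1), dtype=np.float32)[None]
        probs = self.net_.forward(x, train=False)[0]
        native = np.stack([
            resize(p, px.shape[:2], order=1, preserve_range=True)
            for p in probs])
        return native

    def predict(self, image):
        """Binary mask(s) at native resolution.

        Returns a single boolean mask for a 1-channel network and an
        ``(ovary, stigma)`` tuple for a 2-channel network.
        """
        probs = self.predict_proba_map(image)
        masks = probs > self.config_.binarize_threshold
        if self.config_.n_output_channels == 1:
            return masks[0]
        return masks[0], masks[1]


def train_segmenter(images, truths, config: SegmentationConfig) -> CarpelSegmenter:
    """Functional wrapper: train a :class:`CarpelSegmenter` from a config."""
    est = CarpelSegmenter(**asdict(config))
    return est.fit(images, truths)


def predict_masks(segmenter: CarpelSegmenter, image):
    """Predict mask(s) for one image; see :meth:`CarpelSegmenter.predict`."""
    out = segmenter.predict(image)
    return (out, None) if isinstance(out, np.ndarray) else out


_STRUCT8 = np.ones((3, 3), dtype=bool)


def postprocess_mask(mask: np.ndarray):
    """Keep the largest 8-connected component and fill interior holes.

    Returns ``(cleaned_mask, empty)`` where ``empty`` is True when the input
    had no foreground pixels (the cleaned mask is then all-False).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask), True
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask), False


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_segmenter(segmenter: CarpelSegmenter, path) -> None:
    """Single-file checkpoint: config echo + weights (npz with a JSON header)."""
    if not hasattr(segmenter, "net_"):
        raise RuntimeError("cannot save an untrained segmenter")
    state = segmenter.net_.state_dict()
    header = json.dumps({"format": "carpelkit-segmenter-v1",
                         "config": asdict(segmenter.config_)})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_segmenter(path) -> CarpelSegmenter:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != "carpelkit-segmenter-v1":
            raise ValueError(f"unrecognised checkpoint format in {path}")
        config = SegmentationConfig(**header["config"])
        est = CarpelSegmenter(**asdict(config))
        net = UNet(depth=config.depth, base=config.base_channels,
                   n_out=config.n_output_channels, seed=config.seed)
        net.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    est.net_ = net
    est.config_ = config
    est.training_log_ = pd.DataFrame(columns=["epoch", "train_loss", "val_loss"])
    return est
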