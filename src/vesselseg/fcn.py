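"""Fully convolutional segmenter with crop layer, skip connection and multi-loss.

Unlike the patch CNN, the FCN maps an image of any size to a dense per-pixel
probability field of the same size.  The backbone reuses the convolution and
pooling layers of :mod:`vesselseg.cnn`:

    input ─ conv(8, same) ─┬─ pool(2) ─ conv(16, same) ─┬─ aux head (half res)
                           │                            └─ ×2 bilinear upsample
                           │                                   │ crop to input
                           └────────── concat (skip) ──────────┘
                                          │
                                    1×1 conv head → per-pixel softmax

The crop layer trims the upsampled maps back to the exact input shape (pooling
pads odd sizes, so upsampling can overshoot by one pixel), keeping the skip
concatenation aligned.  Training minimizes a weighted sum of per-pixel softmax
losses at full resolution and at the auxiliary half resolution (labels
downsampled by majority), which feeds gradient to the deep layers directly and
counters vanishing gradients.

Foreground pixels are rare, so the pixel losses support a foreground class
weight (default 3) to keep the net from predicting all-background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d

from vesselseg.cnn import (
    ConvLayer,
    LayerError,
    PoolLayer,
    TrainConfig,
    TrainingError,
    softmax_probabilities,
)

_BILINEAR_KERNEL = np.array([0.5, 1.0, 0.5])


class UpsampleLayer:
    """Fixed ×2 bilinear upsampling (zero-stuffing + tent-kernel smoothing).

    The tent kernel is symmetric, so the backward pass is the same filtering
    followed by decimation — an exact adjoint.
    """

    kind = "upsample"

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        z = np.zeros((N, C, 2 * H, 2 * W))
        z[:, :, ::2, ::2] = x
        y = correlate1d(z, _BILINEAR_KERNEL, axis=2, mode="constant")
        y = correlate1d(y, _BILINEAR_KERNEL, axis=3, mode="constant")
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = correlate1d(gy, _BILINEAR_KERNEL, axis=2, mode="constant")
        g = correlate1d(g, _BILINEAR_KERNEL, axis=3, mode="constant")
        return g[:, :, ::2, ::2]

    def params(self):
        return iter(())

    def descriptor(self) -> dict:
        return {"kind": self.kind, "factor": 2}


def crop_align(
    feature_map: np.ndarray,
    reference_shape: tuple[int, int],
    crop_spec: tuple[int, int] | None = None,
) -> np.ndarray:
    """Crop trailing spatial axes of ``feature_map`` to ``reference_shape``.

    ``crop_spec`` gives explicit (top, left) offsets; default is a centered
    crop (extra pixels split evenly, the odd one trimmed from the far side).
    """
    H, W = feature_map.shape[-2:]
    h, w = reference_shape
    if h > H or w > W:
        raise LayerError(f"reference shape {reference_shape} exceeds feature shape {(H, W)}")
    if crop_spec is None:
        top, left = (H - h) // 2, (W - w) // 2
    else:
        top, left = crop_spec
        if top + h > H or left + w > W:
            raise LayerError(f"crop offsets {crop_spec} overflow feature shape {(H, W)}")
    return feature_map[..., top : top + h, left : left + w]


class _CropLayer:
    def __init__(self):
        self._pad = None

    def forward(self, x: np.ndarray, reference_shape: tuple[int, int]) -> np.ndarray:
        H, W = x.shape[-2:]
        h, w = reference_shape
        top, left = (H - h) // 2, (W - w) // 2
        self._pad = (top, H - h - top, left, W - w - left)
        return crop_align(x, reference_shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        t, b, l, r = self._pad
        return np.pad(gy, ((0, 0), (0, 0), (t, b), (l, r)))


def softmax_map(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the class axis of (..., P, H, W) logit maps."""
    z = logits - logits.max(axis=-3, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-3, keepdims=True)


def majority_downsample(labels: np.ndarray, factor: int) -> np.ndarray:
    """Downsample an integer label map by per-block majority vote.

    Odd sizes are edge-padded to fit (consistent with pooling); ties resolve
    to the smaller label.
    """
    if factor == 1:
        return labels
    H, W = labels.shape
    ph, pw = (-H) % factor, (-W) % factor
    lp = np.pad(labels, ((0, ph), (0, pw)), mode="edge")
    blocks = lp.reshape(lp.shape[0] // factor, factor, lp.shape[1] // factor, factor)
    K = int(labels.max()) + 1
    votes = np.stack([(blocks == k).sum(axis=(1, 3)) for k in range(K)])
    return votes.argmax(axis=0).astype(labels.dtype)  # argmax takes smaller label on ties


def _pixel_softmax_loss_grad(
    logits: np.ndarray, labels: np.ndarray, fg_weight: float
) -> tuple[float, np.ndarray]:
    """Weighted mean per-pixel softmax loss on (N, P, H, W) logits and its gradient."""
    probs = softmax_map(logits)
    N, P, H, W = probs.shape
    lab = np.broadcast_to(labels, (N, H, W))
    weights = np.where(lab == 1, fg_weight, 1.0)
    wsum = weights.sum()
    p_true = np.take_along_axis(probs, lab[:, None], axis=1)[:, 0]
    loss = float(-(weights * np.log(np.clip(p_true, 1e-300, None))).sum() / wsum)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, lab[:, None], 1.0, axis=1)
    grad = (probs - onehot) * (weights[:, None] / wsum)
    return loss, grad


def fcn_multi_loss(
    aux_outputs: Sequence[np.ndarray],
    labels: np.ndarray,
    weights: Sequence[float] | None = None,
    fg_weight: float = 1.0,
) -> float:
    """Weighted sum of per-scale softmax losses.

    ``aux_outputs`` are probability maps ``(P, h, w)`` at full or reduced
    resolution; ``labels`` is the full-resolution label map, downsampled by
    majority vote to each scale.  Default weights are uniform 1.
    """
    if len(aux_outputs) == 0:
        raise LayerError("need at least one output")
    weights = list(weights) if weights is not None else [1.0] * len(aux_outputs)
    if len(weights) != len(aux_outputs):
        raise LayerError("one weight per output required")
    H = labels.shape[0]
    total = 0.0
    for w, probs in zip(weights, aux_outputs):
        h = probs.shape[-2]
        if H % h and h != labels.shape[0]:
            pass  # majority_downsample pads; factor check below
        factor = int(round(H / h))
        if factor < 1 or (H + (-H) % factor) // factor != h:
            raise LayerError(f"output of height {h} is not an integer downscale of labels height {H}")
        lab = majority_downsample(labels, factor)
        p_true = np.take_along_axis(probs, lab[None], axis=0)[0]
        total += w * float(-np.mean(np.log(np.clip(p_true, 1e-300, None))))
    return total


class FCNModel:
    """Two-scale fully convolutional network with one skip connection."""

    kind = "fcn"
    #: smallest image the receptive-field chain supports
    min_size = 8

    def __init__(self, seed: int = 0, loss_weights: tuple[float, float] = (0.7, 0.3)):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.loss_weights = loss_weights
        self.conv1 = ConvLayer(1, 8, 3, padding="same", activation="relu", rng=rng)
        self.pool = PoolLayer(8, 2, down="mean")
        self.conv2 = ConvLayer(8, 16, 3, padding="same", activation="relu", rng=rng)
        self.aux_head = ConvLayer(16, 2, 1, padding="same", activation="identity", rng=rng)
        self.upsample = UpsampleLayer()
        self.crop = _CropLayer()
        self.head = ConvLayer(8 + 16, 2, 1, padding="same", activation="identity", rng=rng)

    def forward_logits(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full-resolution and auxiliary half-resolution logit maps."""
        if x.ndim != 4:
            raise LayerError(f"expected (N, 1, H, W) input, got {x.shape}")
        if min(x.shape[2:]) < self.min_size:
            raise LayerError(f"image {x.shape[2:]} below minimum size {self.min_size}")
        a = self.conv1.forward(x)
        p = self.pool.forward(a)
        b = self.conv2.forward(p)
        aux = self.aux_head.forward(b)
        u = self.upsample.forward(b)
        uc = self.crop.forward(u, a.shape[-2:])
        self._split = a.shape[1]
        cat = np.concatenate([a, uc], axis=1)
        return self.head.forward(cat), aux

    def backward(self, glogits: np.ndarray, gaux: np.ndarray) -> np.ndarray:
        gcat = self.head.backward(glogits)
        ga1, guc = gcat[:, : self._split], gcat[:, self._split :]
        gb = self.upsample.backward(self.crop.backward(guc))
        gb = gb + self.aux_head.backward(gaux)
        gp = self.conv2.backward(gb)
        ga2 = self.pool.backward(gp)
        return self.conv1.backward(ga1 + ga2)

    def parameters(self):
        for lname, layer in (
            ("conv1", self.conv1),
            ("pool", self.pool),
            ("conv2", self.conv2),
            ("aux_head", self.aux_head),
            ("head", self.head),
        ):
            for name, p, g in layer.params():
                yield f"{lname}.{name}", p, g

    def sgd_step(self, lr: float) -> None:
        for _, p, g in self.parameters():
            p -= lr * g

    def descriptor(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "loss_weights": list(self.loss_weights)}


def build_default_fcn(seed: int = 0) -> FCNModel:
    return FCNModel(seed=seed)


def fcn_forward(image: np.ndarray, model: FCNModel) -> np.ndarray:
    """Dense (2, H, W) class-probability map for an image of any size ≥ min_size."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise LayerError(f"expected 2-D image, got shape {image.shape}")
    logits, _ = model.forward_logits(image[None, None])
    return softmax_map(logits)[0]


def train_fcn(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: TrainConfig,
    model: FCNModel | None = None,
    fg_weight: float = 3.0,
) -> tuple[FCNModel, list[float]]:
    """SGD on the two-scale multi-loss over full images.

    Per-epoch mean loss is recorded; NaN loss raises :class:`TrainingError`.
    """
    config.validate()
    if len(images) == 0:
        raise LayerError("empty training set")
    model = model or build_default_fcn(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    w_final, w_aux = model.loss_weights
    history: list[float] = []
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in order:
            x = np.asarray(images[i], dtype=float)[None, None]
            lab = np.asarray(masks[i], dtype=int)
            logits, aux_logits = model.forward_logits(x)
            factor = int(round(lab.shape[0] / aux_logits.shape[-2]))
            lab_aux = majority_downsample(lab, factor)
            loss_f, grad_f = _pixel_softmax_loss_grad(logits, lab, fg_weight)
            loss_a, grad_a = _pixel_softmax_loss_grad(aux_logits, lab_aux, fg_weight)
            loss = w_final * loss_f + w_aux * loss_a
            if not np.isfinite(loss):
                raise TrainingError(f"FCN training diverged at epoch {epoch}")
            model.backward(w_final * grad_f, w_aux * grad_a)
            model.sgd_step(config.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history
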