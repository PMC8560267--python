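"""Patch-based CNN segmenter built from first principles in numpy.

The network is assembled from four layer types, each with a hand-written
forward and backward pass:

* convolution      h_j = f( Σ_{i∈M_j} h_i ⋆ p_ij + c_j )   (cross-correlation
  convention; M_j is an optional receptive set restricting which input maps
  feed output map j);
* pooling          h_j = f( u_j · down(h_j) + c_j )  with ``down`` a mean or
  max reduction over non-overlapping windows; the multiplicative deviation u
  and additive deviation c default to 1 and 0 and are held fixed unless
  explicitly flagged trainable;
* fully connected  h = f( t·h + c );
* softmax head     class probabilities by exp-normalization, trained with the
  mean negative log-probability of the true class over the batch.

Training is plain mini-batch SGD with a fixed learning rate, bit-reproducible
under a fixed seed.  Inference segments an image by sliding-window patch
classification with overlap-averaged assembly of the per-pixel foreground
probability.

Arrays are channels-first: batches are ``(N, C, H, W)`` float64.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class LayerError(ValueError):
    """Shape or parameter violation inside a layer."""


class TrainingError(RuntimeError):
    """Raised when training diverges (NaN loss)."""


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _relu(z):
    return np.maximum(z, 0.0)


def _drelu(z):
    return (z > 0).astype(z.dtype)


def _identity(z):
    return z


def _didentity(z):
    return np.ones_like(z)


ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "identity": (_identity, _didentity),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def _get_activation(name: str):
    if name not in ACTIVATIONS:
        raise LayerError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")
    return ACTIVATIONS[name]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class ConvLayer:
    """2-D convolution layer (cross-correlation) over multi-map inputs.

    Parameters
    ----------
    in_maps, out_maps
        Input / output feature-map counts.
    ksize
        Odd spatial kernel size.
    padding
        ``"valid"`` (no padding) or ``"same"`` (zero padding preserving shape).
    receptive
        Optional boolean ``(out_maps, in_maps)`` table; output map j sees only
        input maps i with ``receptive[j, i]``.  Default: fully connected maps.
    """

    kind = "conv"

    def __init__(
        self,
        in_maps: int,
        out_maps: int,
        ksize: int = 3,
        *,
        padding: str = "valid",
        activation: str = "relu",
        receptive: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        if ksize % 2 != 1:
            raise LayerError(f"kernel size must be odd, got {ksize}")
        if padding not in ("valid", "same"):
            raise LayerError(f"padding must be 'valid' or 'same', got {padding!r}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_maps * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_maps, in_maps, ksize, ksize))
        self.b = np.zeros(out_maps)
        self.padding = padding
        self.activation = activation
        self._f, self._df = _get_activation(activation)
        if receptive is not None:
            receptive = np.asarray(receptive, dtype=bool)
            if receptive.shape != (out_maps, in_maps):
                raise LayerError(
                    f"receptive table must be ({out_maps}, {in_maps}), got {receptive.shape}"
                )
        self.receptive = receptive
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def ksize(self) -> int:
        return self.W.shape[-1]

    def _effective_W(self) -> np.ndarray:
        if self.receptive is None:
            return self.W
        return self.W * self.receptive[:, :, None, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.W.shape[1]:
            raise LayerError(
                f"expected input (N, {self.W.shape[1]}, H, W), got {x.shape}"
            )
        k = self.ksize
        pad = k // 2 if self.padding == "same" else 0
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        if xp.shape[2] < k or xp.shape[3] < k:
            raise LayerError(f"input spatial size {x.shape[2:]} smaller than kernel {k}")
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H',W',k,k)
        pre = np.einsum("nchwij,ocij->nohw", win, self._effective_W(), optimize=True)
        pre += self.b[None, :, None, None]
        self._cache = (win, pre, x.shape, pad)
        return self._f(pre)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        win, pre, x_shape, pad = self._cache
        gpre = gy * self._df(pre)
        self.gW = np.einsum("nchwij,nohw->ocij", win, gpre, optimize=True)
        if self.receptive is not None:
            self.gW *= self.receptive[:, :, None, None]
        self.gb = gpre.sum(axis=(0, 2, 3))
        k = self.ksize
        gp = np.pad(gpre, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        gwin = sliding_window_view(gp, (k, k), axis=(2, 3))
        Wrot = self._effective_W()[:, :, ::-1, ::-1]
        gxp = np.einsum("nohwij,ocij->nchw", gwin, Wrot, optimize=True)
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        assert gxp.shape == x_shape
        return gxp

    def params(self):
        yield "W", self.W, self.gW
        yield "b", self.b, self.gb

    def descriptor(self) -> dict:
        return {
            "kind": self.kind,
            "in_maps": int(self.W.shape[1]),
            "out_maps": int(self.W.shape[0]),
            "ksize": int(self.ksize),
            "padding": self.padding,
            "activation": self.activation,
            "has_receptive": self.receptive is not None,
        }


class PoolLayer:
    """Pooling with multiplicative/additive deviations u and c.

    ``down`` reduces non-overlapping ``window × window`` blocks by mean or
    max; inputs whose spatial size is not divisible by the window are
    edge-padded to fit.  u and c are per-map and by default fixed at 1 and 0;
    set ``trainable=True`` to learn them.
    """

    kind = "pool"

    def __init__(
        self,
        n_maps: int,
        window: int = 2,
        *,
        down: str = "mean",
        activation: str = "identity",
        trainable: bool = False,
    ) -> None:
        if window < 2:
            raise LayerError(f"pooling window must be >= 2, got {window}")
        if down not in ("mean", "max"):
            raise LayerError(f"down must be 'mean' or 'max', got {down!r}")
        self.window = window
        self.down = down
        self.u = np.ones(n_maps)
        self.c = np.zeros(n_maps)
        self.trainable = trainable
        self.activation = activation
        self._f, self._df = _get_activation(activation)
        self.gu = np.zeros_like(self.u)
        self.gc = np.zeros_like(self.c)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.size == 0:
            raise LayerError(f"expected non-empty (N, C, H, W) input, got {x.shape}")
        if abs(self.u).min() == 0 or not np.all(np.isfinite(self.u)):
            raise LayerError("multiplicative deviation u must be finite and nonzero")
        w = self.window
        N, C, H, W = x.shape
        ph, pw = (-H) % w, (-W) % w
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge") if ph or pw else x
        Hb, Wb = xp.shape[2] // w, xp.shape[3] // w
        blocks = xp.reshape(N, C, Hb, w, Wb, w)
        if self.down == "mean":
            down = blocks.mean(axis=(3, 5))
            argmask = None
        else:
            down = blocks.max(axis=(3, 5))
            argmask = blocks == down[:, :, :, None, :, None]
            # break ties deterministically: keep only the first max per block
            flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Hb, Wb, w * w)
            first = flat.cumsum(axis=-1) == 1
            argmask = (flat & first).reshape(N, C, Hb, Wb, w, w).transpose(0, 1, 2, 4, 3, 5)
        pre = self.u[None, :, None, None] * down + self.c[None, :, None, None]
        self._cache = (down, argmask, pre, (H, W), (ph, pw))
        return self._f(pre)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        down, argmask, pre, (H, W), (ph, pw) = self._cache
        gpre = gy * self._df(pre)
        if self.trainable:
            self.gu = (gpre * down).sum(axis=(0, 2, 3))
            self.gc = gpre.sum(axis=(0, 2, 3))
        gdown = gpre * self.u[None, :, None, None]
        w = self.window
        N, C, Hb, Wb = gdown.shape
        if self.down == "mean":
            gblocks = np.broadcast_to(
                gdown[:, :, :, None, :, None] / (w * w), (N, C, Hb, w, Wb, w)
            )
        else:
            gblocks = gdown[:, :, :, None, :, None] * argmask
        gxp = gblocks.reshape(N, C, Hb * w, Wb * w)
        # fold gradients of edge-padded rows/cols back onto the true edge
        gx = np.array(gxp[:, :, : H + ph, : W + pw])
        if ph:
            gx[:, :, H - 1, :] += gx[:, :, H:, :].sum(axis=2)
            gx = gx[:, :, :H, :]
        if pw:
            gx[:, :, :, W - 1] += gx[:, :, :, W:].sum(axis=3)
            gx = gx[:, :, :, :W]
        return gx

    def params(self):
        if self.trainable:
            yield "u", self.u, self.gu
            yield "c", self.c, self.gc

    def descriptor(self) -> dict:
        return {
            "kind": self.kind,
            "n_maps": int(self.u.shape[0]),
            "window": self.window,
            "down": self.down,
            "activation": self.activation,
            "trainable": self.trainable,
        }


class FlattenLayer:
    """Reshape (N, C, H, W) feature maps to (N, C·H·W) vectors."""

    kind = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)

    def params(self):
        return iter(())

    def descriptor(self) -> dict:
        return {"kind": self.kind}


class FCLayer:
    """Fully connected layer h = f(t·h_prev + c)."""

    kind = "fc"

    def __init__(
        self,
        in_features: int,
        out_features: int,
        *,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.activation = activation
        self._f, self._df = _get_activation(activation)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.W.shape[1]:
            raise LayerError(f"expected input (N, {self.W.shape[1]}), got {x.shape}")
        pre = x @ self.W.T + self.b
        self._cache = (x, pre)
        return self._f(pre)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, pre = self._cache
        gpre = gy * self._df(pre)
        self.gW = gpre.T @ x
        self.gb = gpre.sum(axis=0)
        return gpre @ self.W

    def params(self):
        yield "W", self.W, self.gW
        yield "b", self.b, self.gb

    def descriptor(self) -> dict:
        return {
            "kind": self.kind,
            "in_features": int(self.W.shape[1]),
            "out_features": int(self.W.shape[0]),
            "activation": self.activation,
        }


# ---------------------------------------------------------------------------
# softmax head
# ---------------------------------------------------------------------------

def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Exp-normalized class probabilities, stabilized by max-subtraction.

    Accepts ``(P,)`` or ``(N, P)``; per-sample probabilities sum to 1.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise LayerError("logits must be finite")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class over the batch.

    ``labels`` are 1-based class indices in {1, …, P}, matching the sample
    labels z^i of the classification objective.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    P = probs.shape[1]
    if labels.shape[0] != probs.shape[0]:
        raise LayerError(f"batch size mismatch: {probs.shape[0]} probs vs {labels.shape[0]} labels")
    if labels.min() < 1 or labels.max() > P:
        raise LayerError(f"labels must lie in 1..{P}, found range [{labels.min()}, {labels.max()}]")
    true_p = probs[np.arange(probs.shape[0]), labels.astype(int) - 1]
    return float(-np.mean(np.log(np.clip(true_p, 1e-300, None))))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Mini-batch SGD settings for patch training."""

    learning_rate: float = 0.05
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0
    patches_per_image: int = 300
    class_balance_ratio: float = 1.0  # foreground : background

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise LayerError("learning_rate must be >= 0")
        for name in ("batch_size", "epochs", "patches_per_image"):
            if getattr(self, name) < 1:
                raise LayerError(f"{name} must be >= 1")
        if self.class_balance_ratio <= 0:
            raise LayerError("class_balance_ratio must be > 0")


class CNNModel:
    """Ordered layer stack ending in a softmax head over ``n_classes``."""

    kind = "cnn"

    def __init__(self, layers: Sequence, n_classes: int = 2, patch_size: int = 17, seed: int = 0):
        self.layers = list(layers)
        self.n_classes = n_classes
        self.patch_size = patch_size
        self.seed = seed

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        if x.ndim != 2 or x.shape[1] != self.n_classes:
            raise LayerError(f"model must emit (N, {self.n_classes}) logits, got {x.shape}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of patches (N, C, p, p) -> (N, P)."""
        return softmax_probabilities(self.forward_logits(x))

    def backward_from_logits(self, glogits: np.ndarray) -> np.ndarray:
        g = glogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                yield f"layer{li}.{name}", p, g

    def sgd_step(self, lr: float) -> None:
        for _, p, g in self.parameters():
            p -= lr * g

    def descriptor(self) -> dict:
        return {
            "kind": self.kind,
            "n_classes": self.n_classes,
            "patch_size": self.patch_size,
            "seed": self.seed,
            "layers": [layer.descriptor() for layer in self.layers],
        }


def build_default_cnn(patch_size: int = 17, n_classes: int = 2, seed: int = 0) -> CNNModel:
    """Default architecture: conv(8)–pool–conv(16)–fc(32)–fc(P), ReLU hidden.

    The smallest stack that exercises all four layer equations and segments
    64 px phantoms on a CPU in minutes.
    """
    rng = np.random.default_rng(seed)
    c1 = ConvLayer(1, 8, 3, padding="valid", activation="relu", rng=rng)
    p1 = PoolLayer(8, 2, down="mean")
    c2 = ConvLayer(8, 16, 3, padding="valid", activation="relu", rng=rng)
    side = (patch_size - 2 + 1) // 2  # conv valid, then pool pad-to-fit
    side = side - 2  # second conv valid
    n_flat = 16 * side * side
    f1 = FCLayer(n_flat, 32, activation="relu", rng=rng)
    f2 = FCLayer(32, n_classes, activation="identity", rng=rng)
    return CNNModel([c1, p1, c2, FlattenLayer(), f1, f2], n_classes=n_classes, patch_size=patch_size, seed=seed)


# ---------------------------------------------------------------------------
# patch sampling and training
# ---------------------------------------------------------------------------

def sample_patches(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    patch_size: int,
    patches_per_image: int,
    class_balance_ratio: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced patch sampling; patch label = mask value at its center.

    Vessel pixels are rare, so patches are drawn at ``ratio : 1``
    foreground : background to keep the classifier from collapsing to
    all-background.  Images are mirror-padded so border pixels can be centers.
    """
    pad = patch_size // 2
    X, y = [], []
    for img, mask in zip(images, masks):
        padded = np.pad(img, pad, mode="reflect")
        win = sliding_window_view(padded, (patch_size, patch_size))
        fg = np.argwhere(mask == 1)
        bg = np.argwhere(mask == 0)
        n_fg = int(round(patches_per_image * class_balance_ratio / (1 + class_balance_ratio)))
        n_bg = patches_per_image - n_fg
        if len(fg) == 0:
            n_bg, n_fg = patches_per_image, 0
        for coords, n in ((fg, n_fg), (bg, n_bg)):
            if n == 0 or len(coords) == 0:
                continue
            idx = rng.choice(len(coords), size=n, replace=len(coords) < n)
            for r, c in coords[idx]:
                X.append(win[r, c])
                y.append(mask[r, c])
    X = np.asarray(X, dtype=float)[:, None, :, :]
    return X, np.asarray(y, dtype=int)


def train_cnn(
    patches: np.ndarray,
    labels: np.ndarray,
    model: CNNModel,
    config: TrainConfig,
) -> tuple[CNNModel, list[float]]:
    """Mini-batch SGD on the softmax loss; returns the model and loss history.

    ``labels`` are 0-based class indices of the patch centers.  Deterministic
    under ``config.seed``; divergence (NaN loss) raises :class:`TrainingError`
    naming the epoch.
    """
    config.validate()
    if len(patches) == 0:
        raise LayerError("empty training set")
    rng = np.random.default_rng(config.seed)
    n = len(patches)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = patches[idx], labels[idx]
            probs = model.forward(xb)
            loss = softmax_loss(probs, yb + 1)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
            onehot = np.eye(model.n_classes)[yb]
            glogits = (probs - onehot) / len(idx)
            model.backward_from_logits(glogits)
            model.sgd_step(config.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_cnn_on_phantoms(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: TrainConfig,
    patch_size: int = 17,
) -> tuple[CNNModel, list[float]]:
    """Convenience: sample balanced patches from phantoms and train a default CNN."""
    rng = np.random.default_rng(config.seed)
    X, y = sample_patches(
        images, masks, patch_size, config.patches_per_image, config.class_balance_ratio, rng
    )
    model = build_default_cnn(patch_size=patch_size, seed=config.seed)
    return train_cnn(X, y, model, config)


# ---------------------------------------------------------------------------
# sliding-window inference
# ---------------------------------------------------------------------------

def segment_cnn(
    image: np.ndarray,
    model: CNNModel,
    stride: int = 1,
    assembly_window: int = 1,
    batch_size: int = 1024,
) -> np.ndarray:
    """Dense foreground probability map by sliding-window classification.

    Patches centered on a stride grid (always including the last row/column)
    are classified in batches.  With the default ``stride=1`` every pixel is
    classified by the patch centered on it; with a coarser stride each
    center's foreground probability is spread over a centered
    ``assembly_window`` square and overlaps are averaged (which trades edge
    sharpness for speed).  Returns a ``(2, H, W)`` probability map
    (background, foreground) summing to 1 at every pixel.
    """
    image = np.asarray(image, dtype=float)
    p = model.patch_size
    if image.ndim != 2 or min(image.shape) < p:
        raise LayerError(f"image {image.shape} smaller than patch size {p}")
    if assembly_window < stride:
        raise LayerError("assembly_window must be >= stride to guarantee coverage")
    H, W = image.shape
    pad = p // 2
    padded = np.pad(image, pad, mode="reflect")
    win = sliding_window_view(padded, (p, p))  # (H, W, p, p)

    def grid(n):
        g = list(range(0, n, stride))
        if g[-1] != n - 1:
            g.append(n - 1)
        return np.asarray(g)

    rows, cols = grid(H), grid(W)
    patches = win[np.ix_(rows, cols)].reshape(-1, 1, p, p)
    fg = np.empty(len(patches))
    for start in range(0, len(patches), batch_size):
        probs = model.forward(patches[start : start + batch_size])
        fg[start : start + batch_size] = probs[:, 1]

    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    a = assembly_window // 2
    k = 0
    for r in rows:
        r0, r1 = max(0, r - a), min(H, r + a + 1)
        for c in cols:
            c0, c1 = max(0, c - a), min(W, c + a + 1)
            acc[r0:r1, c0:c1] += fg[k]
            cnt[r0:r1, c0:c1] += 1.0
            k += 1
    assert cnt.min() > 0
    fg_map = acc / cnt
    return np.stack([1.0 - fg_map, fg_map])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_FORMAT = "vesselseg-ckpt-v1"


def save_checkpoint(model, path: str | Path) -> None:
    """Single-file zip archive: JSON architecture descriptor + parameter tensors."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = {"format": CHECKPOINT_FORMAT, "model": model.descriptor()}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("architecture.json", json.dumps(desc, indent=2))
        for name, p, _ in model.parameters():
            buf = io.BytesIO()
            np.save(buf, p)
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path: str | Path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    from vesselseg.fcn import FCNModel, build_default_fcn  # cycle: fcn reuses these layers

    with zipfile.ZipFile(path) as zf:
        desc = json.loads(zf.read("architecture.json"))
        if desc.get("format") != CHECKPOINT_FORMAT:
            raise LayerError(f"unrecognized checkpoint format in {path}")
        mdesc = desc["model"]
        if mdesc["kind"] == "cnn":
            model = build_default_cnn(
                patch_size=mdesc["patch_size"], n_classes=mdesc["n_classes"], seed=mdesc["seed"]
            )
        elif mdesc["kind"] == "fcn":
            model = build_default_fcn(seed=mdesc["seed"])
        else:
            raise LayerError(f"unknown model kind {mdesc['kind']!r}")
        for name, p, _ in model.parameters():
            buf = io.BytesIO(zf.read(f"params/{name}.npy"))
            p[...] = np.load(buf)
    return model
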