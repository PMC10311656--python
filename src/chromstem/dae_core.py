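"""Fully convolutional denoising autoencoder for STEM image stacks.

Architecture (all convolutions 3x3, stride 1, same padding, ReLU):

* encoder — three conv + 2x2 max-pool blocks with 256, 128, and 64 filters,
  compressing a grayscale image into a 64-channel latent embedding that acts
  as an information bottleneck;
* decoder — the mirror image: three conv + 2x nearest-neighbour upsampling
  blocks (64, 128, 256 filters) followed by a single-filter conv with a
  sigmoid that maps back to one grayscale channel in (0, 1).

There are no fully connected layers, so a trained model applies to images
of any size: inputs are reflect-padded to the next multiple of 8 (three 2x
poolings) and the output is cropped back.

Training minimizes per-pixel binary cross-entropy between the reconstruction
of a noise-corrupted image and its noise-free original, with Adam (lr 1e-3),
batch size 32, a 20% random validation hold-out and early stopping that
restores the best-validation weights.

The network, backpropagation, and Adam are implemented directly on NumPy
(im2col convolutions running on BLAS matmul), keeping the package free of a
deep-learning framework dependency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .voxel_imaging import VoxelStack, extract_slices, restack

__all__ = [
    "DAEConfig",
    "DAE",
    "TrainedDAE",
    "build_model",
    "bce_loss",
    "train",
    "denoise",
    "denoise_image",
    "save_dae",
    "load_dae",
]

EPS = 1e-7  # BCE clipping


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DAEConfig:
    encoder_filters: tuple = (256, 128, 64)
    kernel: tuple = (3, 3)
    pool: tuple = (2, 2)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    #: minimum validation-loss drop counted as progress by early stopping
    min_delta: float = 1e-4
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_filters) == 0:
            raise ValueError("encoder_filters must be non-empty")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        object.__setattr__(self, "encoder_filters", tuple(int(f) for f in self.encoder_filters))
        object.__setattr__(self, "kernel", tuple(self.kernel))
        object.__setattr__(self, "pool", tuple(self.pool))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv:
    """3x3 same-padding convolution on channels-last (B, H, W, C) tensors.

    Implemented as one GEMM per kernel offset, which keeps buffers small and
    BLAS-friendly; weights are stored (k, k, C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self._xp = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        k, p = self.k, self.k // 2
        f = self.w.shape[-1]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        if c * k * k <= 128:
            # few input channels: one GEMM on explicit patches is cheaper
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
            patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * c)
            out = patches @ self._patch_weight() + self.b
        else:
            out = np.empty((b * h * w, f), dtype=np.float32)
            out[:] = self.b
            for di in range(k):
                for dj in range(k):
                    xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, c)
                    out += xs @ self.w[di, dj]
        if train:
            self._xp = xp
        return out.reshape(b, h, w, f)

    def _patch_weight(self) -> np.ndarray:
        """Weights reshaped to match patch layout (k, k, C) flattened."""
        return self.w.reshape(-1, self.w.shape[-1])

    def backward(self, dout: np.ndarray):
        b, h, w, f = dout.shape
        k, p = self.k, self.k // 2
        xp = self._xp
        dflat = dout.reshape(-1, f)
        dw = np.empty_like(self.w)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.c_in)
                dw[di, dj] = xs.T @ dflat
                dxp[:, di : di + h, dj : dj + w, :] += (dflat @ self.w[di, dj].T).reshape(
                    b, h, w, self.c_in
                )
        db = dflat.sum(axis=0)
        dx = dxp[:, p : p + h, p : p + w, :]
        self._xp = None
        return dx, [dw, db]


class _ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dout *= self._mask  # dout is layer-local; safe to reuse in place
        self._mask = None
        return dout, []


class _MaxPool2:
    """2x2 max pooling on channels-last tensors; the argmax quadrant is
    remembered so the gradient routes to the maximal pixel only."""

    params: list = []

    def __init__(self):
        self._idx = None

    def forward(self, x, train=False):
        quads = np.stack(
            [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]]
        )
        idx = quads.argmax(axis=0)
        out = np.take_along_axis(quads, idx[None], axis=0)[0]
        if train:
            self._idx = idx.astype(np.uint8)
        return out

    def backward(self, dout):
        b, h2, w2, c = dout.shape
        dx = np.zeros((b, h2 * 2, w2 * 2, c), dtype=dout.dtype)
        idx = self._idx
        dx[:, 0::2, 0::2, :] = np.where(idx == 0, dout, 0)
        dx[:, 0::2, 1::2, :] = np.where(idx == 1, dout, 0)
        dx[:, 1::2, 0::2, :] = np.where(idx == 2, dout, 0)
        dx[:, 1::2, 1::2, :] = np.where(idx == 3, dout, 0)
        self._idx = None
        return dx, []


class _Upsample2:
    """Nearest-neighbour 2x upsampling (channels-last)."""

    params: list = []

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout):
        b, h, w, c = dout.shape
        dx = dout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        return dx, []


class _Sigmoid:
    params: list = []

    def __init__(self):
        self._out = None

    def forward(self, x, train=False):
        from scipy.special import expit

        out = expit(x)
        if train:
            self._out = out
        return out

    def backward(self, dout):
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx, []


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DAE:
    """The untrained/trainable network; built by :func:`build_model`."""

    def __init__(self, config: DAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel[0]
        filters = list(config.encoder_filters)
        layers: list = []
        c_in = 1
        for f in filters:
            layers += [_Conv(c_in, f, rng, k), _ReLU(), _MaxPool2()]
            c_in = f
        for f in reversed(filters):
            layers += [_Conv(c_in, f, rng, k), _ReLU(), _Upsample2()]
            c_in = f
        layers += [_Conv(c_in, 1, rng, k), _Sigmoid()]
        self.layers = layers
        self.depth = len(filters)  # number of 2x poolings

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    # -- forward / backward --------------------------------------------------
    def _pad_batch(self, x: np.ndarray):
        """Reflect-pad (B, H, W, 1) so H and W divide 2**depth."""
        m = 2 ** self.depth
        b, h, w, c = x.shape
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        return x, (h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> list:
        grads: list = []
        for layer in reversed(self.layers):
            dout, g = layer.backward(dout)
            grads = g + grads
        return grads

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Denoise a batch of 2D images (B, H, W) of arbitrary size."""
        images = np.asarray(images, dtype=np.float32)
        squeeze = images.ndim == 2
        if squeeze:
            images = images[None]
        x, (h, w) = self._pad_batch(images[..., None])
        out = self.forward(x, train=False)[:, :h, :w, 0]
        return out[0] if squeeze else out


def build_model(config: DAEConfig | None = None) -> DAE:
    """Instantiate the network with seeded He-normal initialization."""
    return DAE(config or DAEConfig())


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy; predictions clipped to
    [EPS, 1-EPS] for finiteness."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, EPS, 1.0 - EPS)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def _bce_grad(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    p = np.clip(y_pred, EPS, 1.0 - EPS)
    return ((p - y_true) / (p * (1.0 - p)) / y_true.size).astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedDAE:
    """Trained network plus its config and per-epoch loss history."""

    model: DAE
    config: DAEConfig
    history: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.history) == 0:
            raise ValueError("training history must be non-empty")

    @property
    def weights(self) -> list:
        return self.model.get_weights()


def _stack_pairs(pairs, model: DAE):
    noisy = np.stack([np.asarray(p.noisy, dtype=np.float32) for p in pairs])[..., None]
    clean = np.stack([np.asarray(p.clean, dtype=np.float32) for p in pairs])[..., None]
    noisy, _ = model._pad_batch(noisy)
    clean, _ = model._pad_batch(clean)
    return noisy, clean


def train(
    model: DAE,
    pairs: list,
    config: DAEConfig | None = None,
    verbose: bool = False,
) -> TrainedDAE:
    """Train on (clean, noisy) pairs with Adam, BCE, and early stopping.

    Pairs are split into train/validation by a seeded permutation
    (``val_fraction`` held out); training stops once validation loss has not
    improved for ``patience`` epochs and the best-validation weights are
    restored.  Both images of each pair are reflect-padded identically to
    the pooling-compatible size, so the loss is computed on padded images.
    """
    config = config or model.config
    if len(pairs) < 10:
        raise ValueError("need at least 10 training pairs")
    rng = np.random.default_rng(config.seed)
    noisy, clean = _stack_pairs(pairs, model)
    n = len(pairs)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    bs = min(config.batch_size, len(tr_idx))
    if bs < config.batch_size:
        warnings.warn(
            f"only {len(tr_idx)} training pairs: reducing batch size "
            f"{config.batch_size} -> {bs}",
            stacklevel=2,
        )

    opt = _Adam(model.params, config.learning_rate)
    history = []
    best_val = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr_idx)
        tr_losses = []
        for start in range(0, len(order), bs):
            bidx = order[start : start + bs]
            pred = model.forward(noisy[bidx], train=True)
            tr_losses.append(bce_loss(clean[bidx], pred))
            grads = model.backward(_bce_grad(clean[bidx], pred))
            opt.step(grads)
        val_losses = []
        for start in range(0, len(val_idx), bs):
            bidx = val_idx[start : start + bs]
            pred = model.forward(noisy[bidx], train=False)
            val_losses.append(bce_loss(clean[bidx], pred) * len(bidx))
        val_loss = float(np.sum(val_losses) / len(val_idx))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(tr_losses)), "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {history[-1]['train_loss']:.5f}  val {val_loss:.5f}")
        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.set_weights(best_weights)
    return TrainedDAE(model=model, config=config, history=pd.DataFrame(history))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def denoise_image(trained: TrainedDAE | DAE, image: np.ndarray) -> np.ndarray:
    """Denoise a single 2D image in [0, 1] of arbitrary size."""
    model = trained.model if isinstance(trained, TrainedDAE) else trained
    image = np.asarray(image, dtype=np.float32)
    if image.size and (image.min() < 0 or image.max() > 1):
        raise ValueError("denoise expects a normalized image in [0, 1]")
    return model.predict(image).astype(np.float64)


def denoise(trained: TrainedDAE | DAE, stack: VoxelStack) -> VoxelStack:
    """Apply the 2D model independently to every planar slice of a stack."""
    if not stack.normalized:
        raise ValueError("denoise expects a normalized stack")
    model = trained.model if isinstance(trained, TrainedDAE) else trained
    slices = np.stack(extract_slices(stack)).astype(np.float32)  # (Z, M, N)
    out = model.predict(slices).astype(np.float64)
    return restack([out[z] for z in range(len(out))], stack.grid, normalized=True)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_dae(trained: TrainedDAE, path: str | Path) -> None:
    """Write weights (npz) plus a JSON config sidecar and a history CSV."""
    path = Path(path)
    arrays = {f"param_{i}": w for i, w in enumerate(trained.model.get_weights())}
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(asdict(trained.config), indent=2))
    trained.history.to_csv(path.with_suffix(".history.csv"), index=False)


def load_dae(path: str | Path) -> TrainedDAE:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    for key in ("encoder_filters", "kernel", "pool"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = DAEConfig(**cfg_raw)
    model = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights([data[f"param_{i}"] for i in range(len(data.files))])
    history = pd.read_csv(path.with_suffix(".history.csv"))
    return TrainedDAE(model=model, config=config, history=history)
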