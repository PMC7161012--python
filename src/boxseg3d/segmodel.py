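"""A small configurable 3D UNet for binary segmentation, in pure numpy.

The encoder-decoder with skip connections follows the standard UNet plan:
each resolution level applies two 3x3x3 same-convolutions with ReLU; levels
are linked by 2x max-pooling on the way down and nearest-neighbor upsampling
plus channel concatenation on the way up; a final 1x1x1 convolution maps to
per-voxel class scores. Forward and backward passes are written directly
against numpy (im2col convolutions), with Adam updates and an exponentially
decayed learning rate

    lr(step) = lr_init * decay_rate ** (global_step / decay_steps).

The network is deliberately small (default depth 3, 8 base channels) so the
full three-stage pipeline trains in minutes on one CPU core at phantom
scale; depth, channels and input shape are configurable for larger settings.
Everything is deterministic under the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import ClassWeights
from .preprocessing import VolumeImage

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "LossSpec",
    "SegmentationModel",
    "build_network",
    "lr_at_step",
    "train_model",
    "predict_mask",
]

_DTYPE = np.float32
_LEAKY = 0.1  # leaky-ReLU slope: keeps gradients alive in the small unnormalized net


@dataclass
class NetworkConfig:
    depth: int = 3
    base_channels: int = 8
    in_shape: tuple[int, int, int] = (48, 48, 48)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        f = 2 ** (self.depth - 1)
        if any(s % f for s in self.in_shape):
            raise ValueError(
                f"in_shape {self.in_shape} must be divisible by 2^(depth-1) = {f} on all axes"
            )
        if self.n_classes != 2:
            raise ValueError("binary segmentation only (n_classes = 2)")


@dataclass
class TrainConfig:
    lr_init: float = 1e-3
    decay_rate: float = 0.95
    decay_steps: int | None = None  # None: one decay step per epoch
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be > 0")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is wired, got {self.optimizer!r}")


@dataclass
class LossSpec:
    """Which training loss to use and its weights.

    kind: 'ce' | 'wce' | 'vwce'. For 'vwce', ``weight_maps`` aligns 1:1 with
    the training samples.
    """

    kind: str = "wce"
    class_weights: ClassWeights = field(default_factory=ClassWeights)
    weight_maps: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ce", "wce", "vwce"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind == "vwce" and self.weight_maps is None:
            raise ValueError("vwce loss requires weight_maps")


# ---------------------------------------------------------------------------
# layer primitives (channel-first (C, X, Y, Z) activations)


def _conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3x3 (or 1x1x1) same-convolution as a sum of shifted channel matmuls."""
    k = W.shape[2]
    C = x.shape[0]
    K = W.shape[0]
    if k == 1:
        flat = x.reshape(C, -1)
        out = W[:, :, 0, 0, 0] @ flat
        return (out + b[:, None]).reshape(K, *x.shape[1:])
    _, X, Y, Z = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((K, X * Y * Z), dtype=_DTYPE)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sl = np.ascontiguousarray(xp[:, i : i + X, j : j + Y, l : l + Z]).reshape(C, -1)
                out += W[:, :, i, j, l] @ sl
    return (out + b[:, None]).reshape(K, X, Y, Z)


def _conv3d_backward(
    x: np.ndarray, W: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of the same-convolution."""
    k = W.shape[2]
    K = W.shape[0]
    C = x.shape[0]
    db = dout.sum(axis=(1, 2, 3))
    if k == 1:
        xf = x.reshape(C, -1)
        df = dout.reshape(K, -1)
        dW = (df @ xf.T).reshape(K, C, 1, 1, 1)
        dx = (W[:, :, 0, 0, 0].T @ df).reshape(C, *x.shape[1:])
        return dx, dW.astype(_DTYPE), db
    _, X, Y, Z = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    df = dout.reshape(K, -1)
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sl = np.ascontiguousarray(xp[:, i : i + X, j : j + Y, l : l + Z]).reshape(C, -1)
                dW[:, :, i, j, l] = df @ sl.T
                dxp[:, i : i + X, j : j + Y, l : l + Z] += (
                    W[:, :, i, j, l].T @ df
                ).reshape(C, X, Y, Z)
    return dxp[:, 1:-1, 1:-1, 1:-1], dW.astype(_DTYPE), db


def _maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C, X, Y, Z = x.shape
    r = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
    r = np.ascontiguousarray(r).reshape(C, X // 2, Y // 2, Z // 2, 8)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    C, X, Y, Z = in_shape
    dr = np.zeros((C, X // 2, Y // 2, Z // 2, 8), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(C, X // 2, Y // 2, Z // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    return np.ascontiguousarray(dr).reshape(C, X, Y, Z)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    C, X, Y, Z = dout.shape
    return (
        dout.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))
    )


# ---------------------------------------------------------------------------


class SegmentationModel:
    """UNet parameters + forward/backward machinery."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        ch_in = 1
        for lvl in range(cfg.depth):
            ch = cfg.base_channels * 2**lvl
            self._init_conv(rng, f"enc{lvl}a", ch_in, ch)
            self._init_conv(rng, f"enc{lvl}b", ch, ch)
            ch_in = ch
        for lvl in range(cfg.depth - 2, -1, -1):
            ch = cfg.base_channels * 2**lvl
            up_ch = cfg.base_channels * 2 ** (lvl + 1)
            self._init_conv(rng, f"dec{lvl}a", up_ch + ch, ch)
            self._init_conv(rng, f"dec{lvl}b", ch, ch)
        self._init_conv(rng, "out", cfg.base_channels, cfg.n_classes, k=1)

    def _init_conv(self, rng, name: str, c_in: int, c_out: int, k: int = 3) -> None:
        fan_in = c_in * k**3
        self.params[f"{name}_W"] = (
            rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)
        ).astype(_DTYPE)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=_DTYPE)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits (n_classes, X, Y, Z) from a (X, Y, Z) or (1, X, Y, Z) input."""
        if x.ndim == 3:
            x = x[None]
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        f = 2 ** (self.cfg.depth - 1)
        if any(s % f for s in x.shape[1:]):
            raise ValueError(f"input shape {x.shape[1:]} not divisible by {f}")
        P = self.params
        cache: dict = {"x": x}
        h = x
        skips = []
        for lvl in range(self.cfg.depth):
            for sub in "ab":
                name = f"enc{lvl}{sub}"
                cache[f"{name}_in"] = h
                h = _conv3d_forward(h, P[f"{name}_W"], P[f"{name}_b"])
                cache[f"{name}_pre"] = h
                h = np.where(h > 0, h, _LEAKY * h)
            if lvl < self.cfg.depth - 1:
                skips.append(h)
                cache[f"pool{lvl}_in_shape"] = h.shape
                h, idx = _maxpool2_forward(h)
                cache[f"pool{lvl}_idx"] = idx
        for lvl in range(self.cfg.depth - 2, -1, -1):
            up = _upsample2(h)
            skip = skips[lvl]
            h = np.concatenate([up, skip], axis=0)
            cache[f"cat{lvl}_split"] = up.shape[0]
            for sub in "ab":
                name = f"dec{lvl}{sub}"
                cache[f"{name}_in"] = h
                h = _conv3d_forward(h, P[f"{name}_W"], P[f"{name}_b"])
                cache[f"{name}_pre"] = h
                h = np.where(h > 0, h, _LEAKY * h)
        cache["out_in"] = h
        logits = _conv3d_forward(h, P["out_W"], P["out_b"])
        if want_cache:
            return logits, cache
        return logits

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        P = self.params
        grads: dict[str, np.ndarray] = {}
        dlogits = np.ascontiguousarray(dlogits, dtype=_DTYPE)
        dh, grads["out_W"], grads["out_b"] = _conv3d_backward(cache["out_in"], P["out_W"], dlogits)
        dskips: dict[int, np.ndarray] = {}
        for lvl in range(0, self.cfg.depth - 1):
            for sub in "ba":
                name = f"dec{lvl}{sub}"
                dh = dh * np.where(cache[f"{name}_pre"] > 0, 1.0, _LEAKY).astype(_DTYPE)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3d_backward(
                    cache[f"{name}_in"], P[f"{name}_W"], dh
                )
            split = cache[f"cat{lvl}_split"]
            dup, dskip = dh[:split], dh[split:]
            dskips[lvl] = dskip
            dh = _upsample2_backward(dup)
        for lvl in range(self.cfg.depth - 1, -1, -1):
            if lvl < self.cfg.depth - 1:
                dh = _maxpool2_backward(dh, cache[f"pool{lvl}_idx"], cache[f"pool{lvl}_in_shape"])
                dh = dh + dskips[lvl]
            for sub in "ba":
                name = f"enc{lvl}{sub}"
                dh = dh * np.where(cache[f"{name}_pre"] > 0, 1.0, _LEAKY).astype(_DTYPE)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3d_backward(
                    cache[f"{name}_in"], P[f"{name}_W"], dh
                )
        return grads

    # -- inference helpers ---------------------------------------------------

    def predict_probs(self, image: VolumeImage | np.ndarray) -> np.ndarray:
        data = image.data if isinstance(image, VolumeImage) else np.asarray(image)
        logits = self.forward(data).astype(np.float64)
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def checksum(self) -> float:
        return float(sum(np.abs(p.astype(np.float64)).sum() for p in self.params.values()))


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Construct a seeded UNet for the given configuration."""
    return SegmentationModel(cfg, seed=seed)


def lr_at_step(cfg: TrainConfig, global_step: int, default_decay_steps: int = 1) -> float:
    """Exponentially decayed learning rate at a global step."""
    if global_step < 0:
        raise ValueError("global_step must be >= 0")
    ds = cfg.decay_steps if cfg.decay_steps is not None else max(1, default_decay_steps)
    return cfg.lr_init * cfg.decay_rate ** (global_step / ds)


def _loss_and_dlogits(
    logits: np.ndarray, target: np.ndarray, spec: LossSpec, vmap: np.ndarray | None
) -> tuple[float, np.ndarray]:
    """Per-sample loss (voxel terms summed) and gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    t = (np.asarray(target) > 0).astype(np.float64)
    y = np.stack([1.0 - t, t])
    if spec.kind == "ce":
        wvox = np.ones_like(t)
    else:
        cw = spec.class_weights
        wvox = np.where(t > 0, cw.w_tumor, cw.w_background)
    if spec.kind == "vwce":
        assert vmap is not None
        wvox = wvox * vmap
    logp = np.log(np.clip(p, 1e-8, None))
    loss = float(-(wvox[None] * y * logp).sum())
    dlogits = wvox[None] * (p - y)
    return loss, dlogits


def train_model(
    samples: list[tuple[VolumeImage, np.ndarray]],
    loss_spec: LossSpec,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    model: SegmentationModel | None = None,
    log_every: int = 0,
) -> tuple[SegmentationModel, list[float]]:
    """Train a UNet on (image, mask) pairs; returns (model, per-step loss series).

    Each step draws a mini-batch (without replacement within an epoch),
    accumulates the mean per-sample gradient and applies one Adam update with
    the decayed learning rate. Fully deterministic under ``train_cfg.seed``.
    """
    if not samples:
        raise ValueError("train_model requires at least one sample")
    if loss_spec.kind == "vwce" and (
        loss_spec.weight_maps is None or len(loss_spec.weight_maps) != len(samples)
    ):
        raise ValueError("vwce training requires one weight map per sample")
    model = model if model is not None else build_network(net_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    n = len(samples)
    bs = min(train_cfg.batch_size, n)
    steps_per_epoch = (n + bs - 1) // bs

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_adam = 0

    images = [np.ascontiguousarray(img.data, dtype=_DTYPE) for img, _ in samples]
    masks = [np.asarray(msk) for _, msk in samples]

    history: list[float] = []
    global_step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for s in range(steps_per_epoch):
            batch = order[s * bs : (s + 1) * bs]
            grads_acc: dict[str, np.ndarray] = {}
            loss_acc = 0.0
            for i in batch:
                logits, cache = model.forward(images[i], want_cache=True)
                vmap = loss_spec.weight_maps[i] if loss_spec.kind == "vwce" else None
                loss, dlogits = _loss_and_dlogits(logits, masks[i], loss_spec, vmap)
                g = model.backward(cache, dlogits / len(batch))
                loss_acc += loss / len(batch)
                for k, gv in g.items():
                    grads_acc[k] = grads_acc.get(k, 0) + gv
            lr = lr_at_step(train_cfg, global_step, default_decay_steps=steps_per_epoch)
            t_adam += 1
            for k in model.params:
                g64 = grads_acc[k].astype(np.float64)
                m[k] = beta1 * m[k] + (1 - beta1) * g64
                v[k] = beta2 * v[k] + (1 - beta2) * g64**2
                mhat = m[k] / (1 - beta1**t_adam)
                vhat = v[k] / (1 - beta2**t_adam)
                model.params[k] = (
                    model.params[k].astype(np.float64) - lr * mhat / (np.sqrt(vhat) + eps)
                ).astype(_DTYPE)
            history.append(loss_acc)
            global_step += 1
        if log_every and (epoch + 1) % log_every == 0:
            import logging

            logging.getLogger(__name__).info(
                "epoch %d/%d loss %.4f", epoch + 1, train_cfg.epochs, history[-1]
            )
    return model, history


def predict_mask(
    model: SegmentationModel, image: VolumeImage, threshold: float = 0.5
) -> np.ndarray:
    """Binary prediction: softmax foreground probability > threshold."""
    probs = model.predict_probs(image)
    return (probs[1] > threshold).astype(np.uint8)
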