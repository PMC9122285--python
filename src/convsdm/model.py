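"""Multi-species convolutional SDM: feature extractor φ, linear head ψ, training.

The model follows the classic convolutional species-classifier decomposition:
a stack of non-linear transformations maps an environmental tensor x to a
feature vector z = φ(x), and a linear classifier ψ gives per-species logits,
turned into relative probabilities by the softmax

    P(Y = k | X = x) = exp(ψ_k(z)) / Σ_j exp(ψ_j(z)).

Training minimizes the multinomial cross-entropy (negative log likelihood of
the true species). The backbone here is a small strided conv stack ending in
global average pooling — the same φ/ψ structure as a full-size image backbone
(e.g. Inception V3 with a 2,048-d feature space), scaled to desk-size inputs;
the architecture is configurable through :class:`ModelConfig`.

Everything is plain numpy with explicit forward/backward passes and an Adam
optimizer, seeded and fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .rasters import CATEGORICAL, EnvironmentalTensor

__all__ = [
    "ModelConfig",
    "ConvSDM",
    "TrainingLog",
    "LayoutError",
    "softmax_probabilities",
    "cross_entropy",
    "train",
    "forward",
    "predict",
    "stack_tensors",
]


class LayoutError(ValueError):
    """Input tensor channel layout does not match the model configuration."""


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis (max-shifted); order-preserving."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log likelihood of the true species under the softmax."""
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return float(np.mean(lse - z[np.arange(len(labels)), labels]))


# ---------------------------------------------------------------------------
# im2col convolution primitives

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    sn, sc, sh, sw = xp.strides
    win = as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
    )
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dwin[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class _Conv:
    """3x3 (configurable) convolution, stride s, zero padding, with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        n = x.shape[0]
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if keep:
            self._cache = (x.shape, cols, ho, wo)
        return out

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        xshape, cols, ho, wo = self._cache
        n = dout.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)
        self.dw = (dflat.T @ cols).reshape(self.w.shape)
        self.db = dflat.sum(axis=0)
        if not need_dx:
            return None
        dcols = dflat @ self.w.reshape(self.w.shape[0], -1)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, ho, wo)

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x, keep=True):
        out = np.maximum(x, 0.0)
        if keep:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng):
        self.w = rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)

    def forward(self, z, keep=True):
        if keep:
            self._z = z
        return z @ self.w.T + self.b

    def backward(self, dout):
        self.dw = dout.T @ self._z
        self.db = dout.sum(axis=0)
        return dout @ self.w


@dataclass
class ModelConfig:
    """Architecture and training specification (JSON round-trippable).

    ``conv_widths`` are the output widths of the strided conv blocks; the last
    one is the feature dimension d. ``land_cover_classes`` is the one-hot
    width used to expand the categorical land-cover channel at model input.
    """

    n_species: int
    patch_px: int = 32
    channel_names: list[str] = field(
        default_factory=lambda: ["red", "green", "blue", "near_ir", "land_cover", "elevation"]
    )
    categorical_channels: list[str] = field(default_factory=lambda: ["land_cover"])
    land_cover_classes: int = 5
    conv_widths: list[int] = field(default_factory=lambda: [24, 48, 64])
    kernel: int = 3
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 2e-3
    val_fraction: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("a multinomial species classifier needs >= 2 species")
        if not self.conv_widths:
            raise ValueError("at least one conv block is required")

    @property
    def feature_dim(self) -> int:
        return self.conv_widths[-1]

    @property
    def input_channels(self) -> int:
        n_cont = len(self.channel_names) - len(self.categorical_channels)
        return n_cont + self.land_cover_classes * len(self.categorical_channels)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclass
class TrainingLog:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0


class ConvSDM:
    """The trained model: preprocessing stats + conv stack φ + linear head ψ."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        c_in = config.input_channels
        for c_out in config.conv_widths:
            self.blocks.append(_Conv(c_in, c_out, config.kernel, 2, config.kernel // 2, rng))
            self.blocks.append(_ReLU())
            c_in = c_out
        self.head = _Linear(config.feature_dim, config.n_species, rng)
        # per-channel standardization stats (expanded layout), set at training time
        self.channel_mean = np.zeros(config.input_channels)
        self.channel_std = np.ones(config.input_channels)
        self._cont_mask = None  # which expanded channels get standardized

    # -- preprocessing ------------------------------------------------------

    def expand_channels(self, raw: np.ndarray) -> np.ndarray:
        """One-hot expand categorical channels of a raw (N, C, H, W) batch.

        Stored tensors keep the integer land-cover code; the model input uses a
        one-hot encoding to avoid imposing a fake ordering on classes.
        """
        cfg = self.config
        if raw.ndim != 4 or raw.shape[1] != len(cfg.channel_names):
            raise LayoutError(
                f"expected (N, {len(cfg.channel_names)}, P, P) raw batch, got {raw.shape}"
            )
        if raw.shape[2] != cfg.patch_px or raw.shape[3] != cfg.patch_px:
            raise LayoutError(
                f"expected {cfg.patch_px}x{cfg.patch_px} patches, got {raw.shape[2:]}"
            )
        out, cont_mask = [], []
        for i, name in enumerate(cfg.channel_names):
            if name in cfg.categorical_channels:
                codes = raw[:, i].astype(int)
                if codes.min() < 0 or codes.max() >= cfg.land_cover_classes:
                    raise LayoutError(
                        f"land-cover codes outside 0..{cfg.land_cover_classes - 1}"
                    )
                onehot = np.eye(cfg.land_cover_classes, dtype=np.float32)[codes]  # N,H,W,K
                out.append(onehot.transpose(0, 3, 1, 2))
                cont_mask.extend([False] * cfg.land_cover_classes)
            else:
                out.append(raw[:, i : i + 1].astype(np.float32))
                cont_mask.append(True)
        self._cont_mask = np.array(cont_mask)
        return np.concatenate(out, axis=1)

    def fit_channel_stats(self, expanded: np.ndarray) -> None:
        """Per-channel mean/std from the *training* batch only (leakage hygiene)."""
        mean = expanded.mean(axis=(0, 2, 3), dtype=np.float64)
        std = expanded.astype(np.float64).std(axis=(0, 2, 3))
        mask = self._cont_mask
        self.channel_mean = np.where(mask, mean, 0.0)
        self.channel_std = np.where(mask & (std > 1e-6), std, 1.0)

    def standardize(self, expanded: np.ndarray) -> np.ndarray:
        return (expanded - self.channel_mean[:, None, None]) / self.channel_std[:, None, None]

    def preprocess(self, raw: np.ndarray) -> np.ndarray:
        return self.standardize(self.expand_channels(raw))

    # -- forward / backward -------------------------------------------------

    def features(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        """z = φ(x): conv blocks then global average pooling."""
        h = x
        for layer in self.blocks:
            h = layer.forward(h, keep=keep)
        if keep:
            self._pool_shape = h.shape
        return h.mean(axis=(2, 3))

    def logits(self, z: np.ndarray, keep: bool = False) -> np.ndarray:
        return self.head.forward(z, keep=keep)

    def forward_batch(self, raw: np.ndarray):
        """(features, logits, probabilities) for a raw (N, C, H, W) batch."""
        x = self.preprocess(raw)
        z = self.features(x)
        lg = self.logits(z)
        return z, lg, softmax_probabilities(lg)

    def _backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        n, c, hh, ww = self._pool_shape
        dh = np.broadcast_to(dz[:, :, None, None], (n, c, hh, ww)) / (hh * ww)
        dh = np.ascontiguousarray(dh)
        for i, layer in enumerate(reversed(self.blocks)):
            if isinstance(layer, _Conv):
                need_dx = i < len(self.blocks) - 1  # skip input grads of 1st conv
                dh = layer.backward(dh, need_dx=need_dx)
            else:
                dh = layer.backward(dh)

    def parameters(self):
        out = []
        for layer in self.blocks + [self.head]:
            if hasattr(layer, "w"):
                out.append(layer)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint = weights container (npz) + JSON config + channel stats."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.parameters()):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
        np.savez(d / "weights.npz", **arrays)
        (d / "config.json").write_text(self.config.to_json())
        stats = {
            "mean": self.channel_mean.tolist(),
            "std": self.channel_std.tolist(),
            "cont_mask": [bool(v) for v in self._cont_mask]
            if self._cont_mask is not None
            else None,
        }
        (d / "channel_stats.json").write_text(json.dumps(stats))

    @classmethod
    def load(cls, directory) -> "ConvSDM":
        from pathlib import Path

        d = Path(directory)
        config = ModelConfig.from_json((d / "config.json").read_text())
        model = cls(config)
        with np.load(d / "weights.npz") as npz:
            for i, layer in enumerate(model.parameters()):
                layer.w = npz[f"w{i}"]
                layer.b = npz[f"b{i}"]
        stats = json.loads((d / "channel_stats.json").read_text())
        model.channel_mean = np.array(stats["mean"])
        model.channel_std = np.array(stats["std"])
        if stats["cont_mask"] is not None:
            model._cont_mask = np.array(stats["cont_mask"])
        return model


class _Adam:
    def __init__(self, layers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [(np.zeros_like(l.w), np.zeros_like(l.b)) for l in layers]
        self.v = [(np.zeros_like(l.w), np.zeros_like(l.b)) for l in layers]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, layer in enumerate(self.layers):
            for j, (p, g) in enumerate([(layer.w, layer.dw), (layer.b, layer.db)]):
                m, v = self.m[i][j], self.v[i][j]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def stack_tensors(tensors: list[EnvironmentalTensor]) -> np.ndarray:
    """Stack a list of environmental tensors into a raw (N, C, H, W) batch."""
    return np.stack([t.channels for t in tensors])


def train(
    raw_patches: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
) -> tuple[ConvSDM, TrainingLog]:
    """Train a :class:`ConvSDM` by cross-entropy on (tensor, species) pairs.

    A validation split of ``config.val_fraction`` of the occurrences is held
    out at random for monitoring; channel statistics come from the training
    part only. Returns the model and a per-epoch log of the mean training
    loss and top-1 accuracy. Deterministic given ``config.seed``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 species (softmax is degenerate)")
    if raw_patches.shape[0] != labels.shape[0]:
        raise ValueError("patches and labels must align")

    model = ConvSDM(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(labels)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    x_all = model.expand_channels(raw_patches)
    model.fit_channel_stats(x_all[tr_idx])
    x_all = model.standardize(x_all)
    x_tr, y_tr = x_all[tr_idx], labels[tr_idx]
    x_val, y_val = x_all[val_idx], labels[val_idx]

    opt = _Adam(model.parameters(), config.learning_rate)
    log = TrainingLog(n_train=len(tr_idx), n_val=len(val_idx))
    bs = config.batch_size
    for _ in range(config.epochs):
        order = rng.permutation(len(y_tr))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            xb, yb = x_tr[idx], y_tr[idx]
            z = model.features(xb, keep=True)
            lg = model.logits(z, keep=True)
            p = softmax_probabilities(lg)
            losses.append(cross_entropy(lg, yb) * len(yb))
            hits += int((lg.argmax(axis=1) == yb).sum())
            seen += len(yb)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model._backward(dlogits)
            opt.step()
        log.epoch_loss.append(float(np.sum(losses) / seen))
        log.epoch_accuracy.append(hits / seen)
        if len(y_val):
            lgv = model.logits(model.features(x_val))
            log.val_loss.append(cross_entropy(lgv, y_val))
            log.val_accuracy.append(float((lgv.argmax(axis=1) == y_val).mean()))
    return model, log


def predict(
    model: ConvSDM, raw_patches: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched inference: (features, logits, probabilities) for raw patches."""
    zs, lgs = [], []
    for start in range(0, len(raw_patches), batch_size):
        z, lg, _ = model.forward_batch(raw_patches[start : start + batch_size])
        zs.append(z)
        lgs.append(lg)
    z = np.concatenate(zs)
    lg = np.concatenate(lgs)
    return z, lg, softmax_probabilities(lg)


def forward(tensor: EnvironmentalTensor, model: ConvSDM):
    """Forward a single tensor: returns (feature vector z, logits, probabilities).

    Deterministic for a frozen model; the probabilities are the softmax of the
    logits and sum to 1 within numerical precision.
    """
    names = [n for n, _ in tensor.channel_meta]
    if names != model.config.channel_names:
        raise LayoutError(
            f"tensor channels {names} do not match model layout {model.config.channel_names}"
        )
    z, lg, p = model.forward_batch(tensor.channels[None])
    return z[0], lg[0], p[0]
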