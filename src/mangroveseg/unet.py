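"""Configurable encoder-decoder U-Net and its training loop.

The network is the classic U shape: each contracting stage applies two
3x3 convolutions with ReLU and then 2x2 max-pooling; the expanding path
upsamples, halves the channel count with a 3x3 convolution, concatenates
the same-resolution encoder features (the skip connection) and applies
another double convolution; a final 1x1 convolution projects to per-class
scores and a softmax yields per-pixel class probabilities. Depth and base
width are configuration, so heterogeneous ensemble members are just
different presets rather than different code.

Training minimizes a loss from :mod:`mangroveseg.losses` with Adam.
Forward/backward are hand-written numpy (see :mod:`mangroveseg.nn`);
with a fixed seed and one BLAS thread the trajectory is reproducible.
Inputs are 8-bit tiles scaled by 1/255 before the first convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import LossParams, get_loss
from .tiling import TileSet


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 3
    num_classes: int = 6
    encoder_depth: int = 4
    base_width: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth < 1:
            raise ValueError("encoder_depth must be >= 1")
        if self.base_width < 1 or self.in_channels < 1 or self.num_classes < 2:
            raise ValueError("invalid channel configuration")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss: str = "focal+dice"
    loss_params: LossParams = field(default_factory=LossParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,train_loss,train_acc,val_loss,val_acc"]
        for i in range(len(self)):
            vl = self.val_loss[i] if i < len(self.val_loss) else ""
            va = self.val_acc[i] if i < len(self.val_acc) else ""
            lines.append(f"{i + 1},{self.train_loss[i]},{self.train_acc[i]},{vl},{va}")
        Path(path).write_text("\n".join(lines) + "\n")


class UNet:
    """U-Net with parameters in a flat name -> array dict."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        p: dict[str, np.ndarray] = {}
        d, w0 = config.encoder_depth, config.base_width

        def double(prefix: str, cin: int, cout: int) -> int:
            p[f"{prefix}a_w"] = nn.he_init(rng, cout, cin, 3, 3)
            p[f"{prefix}a_b"] = np.zeros(cout, dtype=nn.DTYPE)
            p[f"{prefix}b_w"] = nn.he_init(rng, cout, cout, 3, 3)
            p[f"{prefix}b_b"] = np.zeros(cout, dtype=nn.DTYPE)
            return cout

        cin = config.in_channels
        for i in range(d):
            cin = double(f"enc{i}", cin, w0 * 2**i)
        cin = double("bot", cin, w0 * 2**d)
        for i in reversed(range(d)):
            wi = w0 * 2**i
            p[f"up{i}_w"] = nn.he_init(rng, wi, cin, 3, 3)
            p[f"up{i}_b"] = np.zeros(wi, dtype=nn.DTYPE)
            cin = double(f"dec{i}", 2 * wi, wi)
        p["head_w"] = nn.he_init(rng, config.num_classes, cin, 1, 1)
        p["head_b"] = np.zeros(config.num_classes, dtype=nn.DTYPE)
        self.params = p

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W), got {x.shape}"
            )
        step = 2**self.config.encoder_depth
        if x.shape[2] % step or x.shape[3] % step:
            raise ValueError(
                f"tile size {x.shape[2:]} not divisible by 2^depth = {step}"
            )

    def _double_fwd(self, x, prefix, caches):
        p = self.params
        x, c = nn.conv_forward(x, p[f"{prefix}a_w"], p[f"{prefix}a_b"])
        caches[f"{prefix}a"] = c
        x, m = nn.relu_forward(x)
        caches[f"{prefix}a_relu"] = m
        x, c = nn.conv_forward(x, p[f"{prefix}b_w"], p[f"{prefix}b_b"])
        caches[f"{prefix}b"] = c
        x, m = nn.relu_forward(x)
        caches[f"{prefix}b_relu"] = m
        return x

    def _double_bwd(self, dx, prefix, caches, grads):
        dx = nn.relu_backward(dx, caches[f"{prefix}b_relu"])
        dx, dw, db = nn.conv_backward(dx, caches[f"{prefix}b"])
        grads[f"{prefix}b_w"], grads[f"{prefix}b_b"] = dw, db
        dx = nn.relu_backward(dx, caches[f"{prefix}a_relu"])
        dx, dw, db = nn.conv_backward(dx, caches[f"{prefix}a"])
        grads[f"{prefix}a_w"], grads[f"{prefix}a_b"] = dw, db
        return dx

    def forward(self, x: np.ndarray):
        """Map (N, 3, H, W) float input to (N, C, H, W) softmax probabilities."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        caches: dict = {}
        d = self.config.encoder_depth
        for i in range(d):
            x = self._double_fwd(x, f"enc{i}", caches)
            caches[f"skip{i}"] = x
            x, c = nn.maxpool2_forward(x)
            caches[f"pool{i}"] = c
        x = self._double_fwd(x, "bot", caches)
        for i in reversed(range(d)):
            x, shape = nn.upsample2_forward(x)
            caches[f"upshape{i}"] = shape
            x, c = nn.conv_forward(x, self.params[f"up{i}_w"], self.params[f"up{i}_b"])
            caches[f"up{i}"] = c
            x, m = nn.relu_forward(x)
            caches[f"up{i}_relu"] = m
            x = np.concatenate([caches[f"skip{i}"], x], axis=1)
            x = self._double_fwd(x, f"dec{i}", caches)
        logits, c = nn.conv_forward(x, self.params["head_w"], self.params["head_b"])
        caches["head"] = c
        probs = nn.softmax_channels(logits.astype(np.float64)).astype(nn.DTYPE)
        caches["probs"] = probs
        return probs, caches

    def backward(self, dprobs: np.ndarray, caches: dict) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, from d loss/d probs."""
        grads: dict[str, np.ndarray] = {}
        dx = nn.softmax_backward(dprobs.astype(nn.DTYPE), caches["probs"])
        dx, dw, db = nn.conv_backward(dx, caches["head"])
        grads["head_w"], grads["head_b"] = dw, db
        d = self.config.encoder_depth
        dskips: dict[int, np.ndarray] = {}
        for i in range(d):
            dx = self._double_bwd(dx, f"dec{i}", caches, grads)
            wi = self.config.base_width * 2**i
            dskips[i] = dx[:, :wi]
            dx = dx[:, wi:]
            dx = nn.relu_backward(dx, caches[f"up{i}_relu"])
            dx, dw, db = nn.conv_backward(dx, caches[f"up{i}"])
            grads[f"up{i}_w"], grads[f"up{i}_b"] = dw, db
            dx = nn.upsample2_backward(dx, caches[f"upshape{i}"])
        dx = self._double_bwd(dx, "bot", caches, grads)
        for i in reversed(range(d)):
            dx = nn.maxpool2_backward(dx, caches[f"pool{i}"])
            dx = dx + dskips[i]
            dx = self._double_bwd(dx, f"enc{i}", caches, grads)
        return grads

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(Path(path)) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k] = data[k]
        return model


def build_unet(config: ModelConfig) -> UNet:
    """Construct a U-Net with seed-deterministic initial parameters."""
    return UNet(config)


#: Depth/width presets standing in for heterogeneous ensemble member roles.
MEMBER_PRESETS: dict[str, dict] = {
    "M3": {"encoder_depth": 3, "base_width": 12},
    "M10": {"encoder_depth": 2, "base_width": 8},
    "M12": {"encoder_depth": 3, "base_width": 16},
}


def preset_config(name: str, num_classes: int = 6, seed: int = 0) -> ModelConfig:
    if name not in MEMBER_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(MEMBER_PRESETS)}")
    return ModelConfig(num_classes=num_classes, seed=seed, **MEMBER_PRESETS[name])


# ---------------------------------------------------------------------------
# training / inference


def _to_arrays(tiles: TileSet, num_classes: int):
    x = np.stack(tiles.images).astype(nn.DTYPE) / 255.0
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    y = np.stack(tiles.masks).astype(np.int64)
    if y.max(initial=0) >= num_classes:
        raise ValueError("mask labels exceed the model's class count")
    return x, y


def _one_hot(y: np.ndarray, c: int) -> np.ndarray:
    return np.eye(c, dtype=np.float64)[y]


def _eval_batches(model: UNet, x: np.ndarray, y: np.ndarray, loss_fn,
                  params: LossParams, batch_size: int):
    losses, correct = [], 0
    c = model.config.num_classes
    for s in range(0, len(x), batch_size):
        probs, _ = model.forward(x[s : s + batch_size])
        pr = probs.transpose(0, 2, 3, 1).astype(np.float64)
        gt = _one_hot(y[s : s + batch_size], c)
        losses.append(loss_fn(gt, pr, params) * len(pr))
        correct += int((probs.argmax(axis=1) == y[s : s + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / y.size


def train_model(model: UNet, train_tiles: TileSet, val_tiles: TileSet | None,
                tcfg: TrainConfig, log=None) -> tuple[UNet, TrainingHistory]:
    """Minimize the configured loss with Adam; one history row per epoch."""
    if len(train_tiles) == 0:
        raise ValueError("training set is empty")
    c = model.config.num_classes
    loss_fn, grad_fn = get_loss(tcfg.loss)
    x_tr, y_tr = _to_arrays(train_tiles, c)
    has_val = val_tiles is not None and len(val_tiles) > 0
    if has_val:
        x_va, y_va = _to_arrays(val_tiles, c)
    rng = np.random.default_rng(tcfg.seed)
    adam = nn.Adam(model.params.keys(), lr=tcfg.learning_rate)
    history = TrainingHistory()
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, len(order), tcfg.batch_size):
            idx = order[s : s + tcfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs, caches = model.forward(xb)
            pr = probs.transpose(0, 2, 3, 1).astype(np.float64)
            gt = _one_hot(yb, c)
            value, dpr = grad_fn(gt, pr, tcfg.loss_params)
            grads = model.backward(dpr.transpose(0, 3, 1, 2), caches)
            adam.step(model.params, grads)
            ep_loss += value * len(idx)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        history.train_loss.append(ep_loss / len(x_tr))
        history.train_acc.append(ep_correct / y_tr.size)
        if has_val:
            vl, va = _eval_batches(model, x_va, y_va, loss_fn, tcfg.loss_params,
                                   tcfg.batch_size)
            history.val_loss.append(vl)
            history.val_acc.append(va)
        if log is not None:
            msg = (f"epoch {epoch + 1}/{tcfg.epochs} "
                   f"loss={history.train_loss[-1]:.4f} acc={history.train_acc[-1]:.4f}")
            if has_val:
                msg += f" val_loss={history.val_loss[-1]:.4f} val_acc={history.val_acc[-1]:.4f}"
            log(msg)
    return model, history


def predict_probabilities(model: UNet, tiles: TileSet | list[np.ndarray],
                          batch_size: int = 8) -> list[np.ndarray]:
    """Per-tile (H, W, C) class-probability stacks; deterministic."""
    images = tiles.images if isinstance(tiles, TileSet) else list(tiles)
    if not images:
        return []
    x = np.stack(images).astype(nn.DTYPE) / 255.0
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    out: list[np.ndarray] = []
    for s in range(0, len(x), batch_size):
        probs, _ = model.forward(x[s : s + batch_size])
        out.extend(np.ascontiguousarray(p.transpose(1, 2, 0)) for p in probs)
    return out
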