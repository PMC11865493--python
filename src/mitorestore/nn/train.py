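"""Seeded training loop (Adam) and whole-image inference."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..sampling import NormalizationParams, PatchPair, percentile_normalize
from .loss import SCoPParams, scop_loss_and_grad, scop_loss
from .unet import ResidualUNet

__all__ = ["TrainingConfig", "TrainingRecord", "train", "predict_image"]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size >= 1 and learning_rate > 0 required")


@dataclass
class TrainingRecord:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (array, grad) pairs, updated in place
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _stack(patches: list[PatchPair]):
    x = np.stack([p.lr_patch for p in patches]).astype(np.float32)[:, None]
    y = np.stack([p.hr_patch for p in patches]).astype(np.float32)[:, None]
    g = np.stack([p.gamma_map for p in patches]).astype(np.float32)
    return x, y, g


def _epoch_loss(model: ResidualUNet, x, y, g, sparams: SCoPParams, batch: int) -> float:
    losses, weights = [], []
    for i in range(0, len(x), batch):
        out = model.forward(x[i:i + batch], keep=False)
        loss = scop_loss(y[i:i + batch, 0], out[:, 0], g[i:i + batch], sparams)
        losses.append(loss)
        weights.append(len(x[i:i + batch]))
    return float(np.average(losses, weights=weights))


def train(
    model: ResidualUNet,
    train_patches: list[PatchPair],
    val_patches: list[PatchPair],
    tconf: TrainingConfig | None = None,
    sparams: SCoPParams | None = None,
) -> tuple[ResidualUNet, TrainingRecord]:
    """Minimize the SCoP loss with Adam; returns the best-validation model.

    Fully deterministic for fixed seeds: batch order comes from a dedicated
    generator and all computation is NumPy.  Raises on empty patch sets or a
    non-finite loss (with epoch context).
    """
    tconf = tconf or TrainingConfig()
    sparams = sparams or SCoPParams()
    if not train_patches or not val_patches:
        raise ValueError("training and validation patch sets must be non-empty")

    x_tr, y_tr, g_tr = _stack(train_patches)
    x_va, y_va, g_va = _stack(val_patches)
    rng = np.random.default_rng(tconf.seed)
    opt = _Adam(model.parameters(), tconf.learning_rate)
    record = TrainingRecord()
    best_weights = model.get_weights()
    since_best = 0

    for epoch in range(tconf.epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        for i in range(0, len(order), tconf.batch_size):
            sel = order[i:i + tconf.batch_size]
            xb, yb, gb = x_tr[sel], y_tr[sel], g_tr[sel]
            out = model.forward(xb, keep=True)
            loss, dyhat = scop_loss_and_grad(yb[:, 0], out[:, 0], gb, sparams)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
            model.zero_grad()
            model.backward(dyhat[:, None].astype(np.float32))
            opt.step()
            epoch_losses.append(loss)
        record.train_losses.append(float(np.mean(epoch_losses)))
        val_loss = _epoch_loss(model, x_va, y_va, g_va, sparams, tconf.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch + 1}")
        record.val_losses.append(val_loss)
        if val_loss < record.best_val_loss:
            record.best_val_loss = val_loss
            record.best_epoch = epoch
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= tconf.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, record


def predict_image(
    model: ResidualUNet,
    image: np.ndarray,
    norm: NormalizationParams | None = None,
) -> np.ndarray:
    """Restore an image (or a stack, plane by plane) of any size.

    Each plane is percentile-normalized, reflect-padded to a multiple of
    ``2**depth``, passed through the network and cropped back.  A plane with
    degenerate normalization is returned unrestored with a warning.
    """
    norm = norm or NormalizationParams()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        return np.stack([predict_image(model, plane, norm) for plane in image])
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image or a 3D plane stack, got shape {image.shape}")
    try:
        x = percentile_normalize(image, norm)
    except ValueError as exc:
        warnings.warn(f"frame skipped: {exc}", stacklevel=2)
        return image.copy()
    m = 2**model.config.depth
    h, w = x.shape
    ph = (-h) % m
    pw = (-w) % m
    xp = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    out = model(xp[None, None].astype(np.float32))[0, 0]
    return np.asarray(out[:h, :w], dtype=np.float64)
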