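"""Mini-batch training of the correction network, ablation, and fine-tuning.

The network is trained to predict the wavelet-domain artifact of each sample
(label = corrupted coefficients minus clean coefficients) by Adam on the
composite objective ``L = L_M + lambda * L_W``.

Two coefficient modes implement the ablation of interest:

* ``complete`` — all four sub-bands (WA, WH, WV, WD) feed the network;
* ``related`` — only WA and WH carry data, the other input channels are
  zeroed.  A single 4-channel architecture is kept in both modes so
  checkpoints stay interchangeable.

Transfer learning is plain fine-tuning: initialize from a checkpoint trained
on the large synthetic set, then continue training (typically at a reduced
learning rate) on a small target dataset whose artifact statistics differ.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._nn import Adam
from .losses import LossConfig, total_loss_and_grad
from .network import (CorrectionModel, CorrectionModelSpec, build_model,
                      load_checkpoint, save_checkpoint)

__all__ = ["TrainConfig", "TrainHistory", "DivergenceError", "train", "fine_tune"]


class DataError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """Loss became non-finite; ``.model`` holds the last finite checkpoint."""

    def __init__(self, message: str, model: CorrectionModel):
        super().__init__(message)
        self.model = model


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    deterministic_mode: bool = True
    coefficient_mode: str = "complete"
    lambda_reg: float = 0.1
    smoothness_norm: str = "l2"
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    patch_size: int | None = None
    log: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")
        if self.coefficient_mode not in ("complete", "related"):
            raise ValueError(f"unknown coefficient_mode {self.coefficient_mode!r}")

    def loss_config(self) -> LossConfig:
        return LossConfig(lambda_reg=self.lambda_reg,
                          smoothness_norm=self.smoothness_norm)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text) or {}
        if "betas" in d:
            d["betas"] = tuple(d["betas"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch losses plus the provenance needed to reproduce the run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_time_s: list[float] = field(default_factory=list)
    seed: int = 0
    metadata: dict = field(default_factory=dict)


def _prepare(split, model: CorrectionModel, related: bool, dtype):
    """Stack a split's coefficient planes into (N, 4, H, W) input/label tensors."""
    if not split:
        raise DataError("empty split")
    xs, ys = [], []
    for rec in split:
        x = rec.corrupted_coeffs.stack()
        y = rec.artifact_coeffs.stack()
        scale = model._sample_scale(x)
        xs.append(x / scale)
        ys.append(y / scale)
    x = np.stack(xs).astype(dtype)
    y = np.stack(ys).astype(dtype)
    if related:
        x[:, 2:, :, :] = 0.0  # only WA and WH carry data
    return x, y


def _epoch_loss(model: CorrectionModel, x: np.ndarray, y: np.ndarray,
                cfg: LossConfig, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        xb, yb = x[i:i + batch], y[i:i + batch]
        pred = model.net.forward(xb, keep=False)
        loss, _ = total_loss_and_grad(pred, yb, cfg)
        total += loss * len(xb)
        n += len(xb)
    return total / n


def _crop_patches(x, y, patch: int, rng) -> tuple[np.ndarray, np.ndarray]:
    _, _, h, w = x.shape
    if h <= patch and w <= patch:
        return x, y
    r0 = int(rng.integers(0, max(1, h - patch + 1)))
    c0 = int(rng.integers(0, max(1, w - patch + 1)))
    return (x[:, :, r0:r0 + patch, c0:c0 + patch],
            y[:, :, r0:r0 + patch, c0:c0 + patch])


def train(model: CorrectionModel, train_split, val_split,
          cfg: TrainConfig) -> tuple[CorrectionModel, TrainHistory]:
    """Optimize ``model`` on a split; returns the best-validation checkpoint.

    Labels are each sample's ``artifact_coeffs``.  ``epochs=0`` returns the
    model untouched.  A non-finite loss aborts with :class:`DivergenceError`
    carrying the last finite parameters.
    """
    loss_cfg = cfg.loss_config()
    history = TrainHistory(seed=cfg.seed, metadata={
        "coefficient_mode": cfg.coefficient_mode,
        "lambda_reg": cfg.lambda_reg,
        "n_train": len(train_split),
        "n_val": len(val_split),
    })
    if cfg.epochs == 0:
        return model, history

    dtype = model.net.head.w.dtype
    related = cfg.coefficient_mode == "related"
    x_tr, y_tr = _prepare(train_split, model, related, dtype)
    x_va, y_va = _prepare(val_split, model, related, dtype)

    seed = cfg.seed if cfg.deterministic_mode else None
    rng = np.random.default_rng(seed)
    opt = Adam(model.net, lr=cfg.learning_rate, betas=cfg.betas)

    best_val = np.inf
    best_state = model.net.get_state()
    last_finite = model.net.get_state()
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(x_tr))
        total, n = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            if cfg.patch_size:
                xb, yb = _crop_patches(xb, yb, cfg.patch_size, rng)
            pred = model.net.forward(xb, keep=True)
            loss, dpred = total_loss_and_grad(pred, yb, loss_cfg)
            if not np.isfinite(loss):
                model.net.set_state(last_finite)
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}", model)
            model.net.zero_grad()
            model.net.backward(dpred.astype(dtype))
            opt.step()
            total += loss * len(xb)
            n += len(xb)
        last_finite = model.net.get_state()
        val = _epoch_loss(model, x_va, y_va, loss_cfg, cfg.batch_size)
        history.train_loss.append(total / n)
        history.val_loss.append(val)
        history.epoch_time_s.append(time.time() - t0)
        if cfg.log:
            print(f"epoch {epoch:4d}  train {total / n:.6f}  val {val:.6f}")
        if val < best_val:
            best_val = val
            best_state = model.net.get_state()
        if cfg.checkpoint_every and cfg.checkpoint_dir and \
                (epoch + 1) % cfg.checkpoint_every == 0:
            model.provenance.update(epoch=epoch, val_loss=val)
            save_checkpoint(f"{cfg.checkpoint_dir}/epoch_{epoch + 1:05d}.npz", model)

    model.net.set_state(best_state)
    model.coefficient_mode = cfg.coefficient_mode
    model.provenance.update(
        trained=True, seed=cfg.seed, epochs=cfg.epochs,
        coefficient_mode=cfg.coefficient_mode, best_val_loss=float(best_val))
    return model, history


def fine_tune(pretrained, small_split, cfg: TrainConfig,
              val_split=None) -> tuple[CorrectionModel, TrainHistory]:
    """Continue training from a pretrained checkpoint on a small dataset.

    ``pretrained`` is a checkpoint path or a :class:`CorrectionModel`.  If no
    validation split is given, the last quarter of ``small_split`` is held
    out.  ``epochs=0`` returns the pretrained parameters bit-for-bit.
    """
    if isinstance(pretrained, CorrectionModel):
        model = pretrained.copy()
        source = "<in-memory model>"
    else:
        model = load_checkpoint(pretrained)
        source = str(pretrained)
    if val_split is None:
        n_val = max(1, len(small_split) // 4)
        if len(small_split) <= n_val:
            raise DataError("small_split too small to hold out validation samples")
        small_split, val_split = small_split[:-n_val], small_split[-n_val:]
    model, history = train(model, small_split, val_split, cfg)
    history.metadata["source_checkpoint"] = source
    history.metadata["fine_tuned"] = True
    model.provenance["source_checkpoint"] = source
    return model, history
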