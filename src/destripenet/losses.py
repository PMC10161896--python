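"""Composite training objective ``L = L_M + lambda * L_W``.

``L_M`` (wavelet loss) is the unweighted sum of per-band mean squared errors
between the predicted artifact sub-bands and the ground-truth artifact
sub-bands.  ``L_W`` (regular/smoothness loss) exploits the geometry of stripe
artifacts: a stripe's gray value varies little along the stripe direction, so
the finite difference of the predicted stripe components along that axis
should be small.  By the printed definition only the WA and WH stripe
components enter ``L_W``; the band selection is overridable because which
sub-bands carry stripe energy depends on the sinogram orientation convention
(under this package's row=angle convention a detector stripe lands in WA and
WV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haar_wavelet import WaveletCoefficients

__all__ = ["LossConfig", "mse", "wavelet_loss", "regular_loss", "total_loss",
           "total_loss_and_grad", "calibrate_lambda"]

_BAND_INDEX = {"wa": 0, "wh": 1, "wv": 2, "wd": 3}


@dataclass
class LossConfig:
    """Parameters of the composite loss.

    Parameters
    ----------
    lambda_reg:
        Non-negative regularization weight balancing ``L_M`` and ``L_W``.
    smoothness_norm:
        ``"l2"`` (mean of squared finite differences) or ``"l1"``
        (mean of absolute finite differences).
    stripe_axis:
        Sub-band axis along which stripes run. 0 = the angle axis (default:
        a detector defect is constant over angles, i.e. down a column).
    smooth_bands:
        Which predicted stripe components enter ``L_W``.
    """

    lambda_reg: float = 0.1
    smoothness_norm: str = "l2"
    stripe_axis: int = 0
    smooth_bands: tuple[str, ...] = ("wa", "wh")

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.smoothness_norm not in ("l2", "l1"):
            raise ValueError(f"unknown smoothness_norm {self.smoothness_norm!r}")
        if self.stripe_axis not in (0, 1):
            raise ValueError("stripe_axis must be 0 or 1")
        bad = [b for b in self.smooth_bands if b not in _BAND_INDEX]
        if bad:
            raise ValueError(f"unknown band names {bad}")


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error (1/N) * sum((a_i - b_i)^2) over all N pixels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def wavelet_loss(pred: WaveletCoefficients, label: WaveletCoefficients) -> float:
    """``L_M`` — sum of the four per-band MSEs (WA + WH + WV + WD)."""
    return float(sum(mse(p, l) for p, l in zip(pred.bands(), label.bands())))


def regular_loss(pred: WaveletCoefficients, cfg: LossConfig | None = None) -> float:
    """``L_W`` — smoothness of the predicted stripe components along the stripe axis.

    For each selected band the forward finite difference along
    ``cfg.stripe_axis`` is taken and reduced by the mean of the chosen norm
    over all difference elements; the per-band values are summed.
    """
    cfg = cfg or LossConfig()
    total = 0.0
    bands = pred.bands()
    for name in cfg.smooth_bands:
        d = np.diff(bands[_BAND_INDEX[name]], axis=cfg.stripe_axis)
        if d.size == 0:
            continue
        total += float(np.mean(d ** 2 if cfg.smoothness_norm == "l2" else np.abs(d)))
    return total


def total_loss(pred: WaveletCoefficients, label: WaveletCoefficients,
               cfg: LossConfig | None = None) -> float:
    """``L = L_M + lambda * L_W``."""
    cfg = cfg or LossConfig()
    return wavelet_loss(pred, label) + cfg.lambda_reg * regular_loss(pred, cfg)


def total_loss_and_grad(pred: np.ndarray, label: np.ndarray,
                        cfg: LossConfig | None = None) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the prediction, on channel-first stacks.

    ``pred`` and ``label`` are (..., 4, H, W) arrays in band order
    WA, WH, WV, WD; leading batch axes are allowed and the loss is the mean
    over the batch of the per-sample ``L``.  Used by the training loop.
    """
    cfg = cfg or LossConfig()
    pred = np.asarray(pred, dtype=pred.dtype if hasattr(pred, "dtype") else float)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    n_batch = int(np.prod(pred.shape[:-3])) if pred.ndim > 3 else 1
    h, w = pred.shape[-2:]
    n_pix = h * w

    diff = pred - label
    # L_M: per band, MSE over that band's pixels; summed over bands, averaged
    # over the batch.
    loss_m = float(np.sum(diff ** 2)) / (n_pix * n_batch)
    grad = (2.0 / (n_pix * n_batch)) * diff

    # L_W on the selected predicted bands.
    n_diff = (h - 1) * w if cfg.stripe_axis == 0 else h * (w - 1)
    loss_w = 0.0
    if n_diff > 0 and cfg.lambda_reg > 0:
        for name in cfg.smooth_bands:
            band = pred[..., _BAND_INDEX[name], :, :]
            d = np.diff(band, axis=cfg.stripe_axis + band.ndim - 2)
            if cfg.smoothness_norm == "l2":
                loss_w += float(np.sum(d ** 2)) / (n_diff * n_batch)
                dd = (2.0 / (n_diff * n_batch)) * d
            else:
                loss_w += float(np.sum(np.abs(d))) / (n_diff * n_batch)
                dd = np.sign(d) / (n_diff * n_batch)
            g = np.zeros_like(band)
            sl_hi = [slice(None)] * band.ndim
            sl_lo = [slice(None)] * band.ndim
            ax = cfg.stripe_axis + band.ndim - 2
            sl_hi[ax] = slice(1, None)
            sl_lo[ax] = slice(None, -1)
            g[tuple(sl_hi)] += dd
            g[tuple(sl_lo)] -= dd
            grad[..., _BAND_INDEX[name], :, :] += cfg.lambda_reg * g

    return loss_m + cfg.lambda_reg * loss_w, grad


def calibrate_lambda(preds: list[WaveletCoefficients],
                     labels: list[WaveletCoefficients],
                     cfg: LossConfig | None = None) -> float:
    """Lambda that balances the two loss terms on a pilot batch.

    Returns ``mean(L_M) / mean(L_W)`` so that at this lambda the two terms
    contribute equally; falls back to the configured default when ``L_W`` is
    (numerically) zero.
    """
    cfg = cfg or LossConfig()
    lm = np.mean([wavelet_loss(p, l) for p, l in zip(preds, labels)])
    lw = np.mean([regular_loss(p, cfg) for p in preds])
    if lw <= 1e-300:
        return cfg.lambda_reg
    return float(lm / lw)
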