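"""Scaled, seeded study protocols: end-to-end efficacy, ablation, transfer.

These functions package the three headline experiments at a size a single
CPU handles in minutes (the methods note documents the sizes):

* :func:`run_end_to_end` — simulate a paired dataset, train the complete
  correction model, and measure mean PSNR/SSIM of uncorrected vs corrected
  test sinograms (optionally also the Fourier-wavelet baseline).
* :func:`run_ablation` — complete vs related coefficient mode under
  identical budgets and seeds, compared by held-out wavelet loss.
* :func:`run_transfer` — fine-tuning a pretrained checkpoint on a small
  distribution-shifted stripe set vs equal-budget training from random
  initialization, compared by best validation loss.

All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baseline_fw import fw_destripe, params_for_shape
from .losses import wavelet_loss
from .network import CorrectionModelSpec, build_model, correct_sinogram, forward
from .recon_metrics import psnr, ssim
from .simulate import PhantomConfig, SampleRecord, StripeSpec, build_dataset, default_angles
from .train import TrainConfig, fine_tune, train

__all__ = ["EndToEndConfig", "run_end_to_end", "run_ablation", "run_transfer",
           "SHIFTED_STRIPES"]

#: Distribution-shifted stripe statistics standing in for experimental data:
#: wider and stronger stripes than the training default.
SHIFTED_STRIPES = StripeSpec(width_range_px=(4, 8), amplitude_range=(0.05, 0.25))


@dataclass(frozen=True)
class EndToEndConfig:
    """The scaled end-to-end study conditions.

    200 phantom sinograms (64x64 images, 90 projection angles) with the
    default stripe model, 80/20 split; a reduced-width network (32 hidden
    channels, 3 residual blocks) trained for 40 epochs.
    """

    n_total: int = 200
    train_fraction: float = 0.8
    size_px: int = 64
    n_angles: int = 90
    hidden_channels: int = 32
    n_res_blocks: int = 3
    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3


def _mean_metrics(model, test_split: list[SampleRecord],
                  include_fw: bool = False) -> dict:
    cols: dict[str, list[float]] = {k: [] for k in
                                    ("psnr_uncorrected", "psnr_corrected",
                                     "ssim_uncorrected", "ssim_corrected",
                                     "psnr_fw", "ssim_fw")}
    for rec in test_split:
        rng = float(rec.clean.data.max() - rec.clean.data.min()) or 1.0
        corr = correct_sinogram(model, rec.corrupted)
        cols["psnr_uncorrected"].append(psnr(rec.clean.data, rec.corrupted.data, rng))
        cols["psnr_corrected"].append(psnr(rec.clean.data, corr.data, rng))
        cols["ssim_uncorrected"].append(ssim(rec.clean.data, rec.corrupted.data, rng))
        cols["ssim_corrected"].append(ssim(rec.clean.data, corr.data, rng))
        if include_fw:
            fw = fw_destripe(rec.corrupted,
                             params_for_shape(rec.corrupted.data.shape))
            cols["psnr_fw"].append(psnr(rec.clean.data, fw.data, rng))
            cols["ssim_fw"].append(ssim(rec.clean.data, fw.data, rng))
    out = {k: float(np.mean(v)) for k, v in cols.items() if v}
    out["psnr_gain_db"] = out["psnr_corrected"] - out["psnr_uncorrected"]
    return out


def run_end_to_end(seed: int, cfg: EndToEndConfig | None = None,
                   include_fw: bool = False) -> dict:
    """Train the complete model on fresh synthetic data; mean test metrics."""
    cfg = cfg or EndToEndConfig()
    train_split, test_split = build_dataset(
        cfg.n_total, cfg.train_fraction, PhantomConfig(size_px=cfg.size_px),
        StripeSpec(seed=seed), default_angles(cfg.n_angles))
    model = build_model(CorrectionModelSpec(
        hidden_channels=cfg.hidden_channels, n_res_blocks=cfg.n_res_blocks),
        init_seed=seed)
    tcfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                       learning_rate=cfg.learning_rate, seed=seed)
    model, history = train(model, train_split, test_split, tcfg)
    out = _mean_metrics(model, test_split, include_fw=include_fw)
    out["final_val_loss"] = history.val_loss[-1]
    out["n_test"] = len(test_split)
    return out


#: Reduced conditions for the multi-seed comparisons.
_SMALL = EndToEndConfig(n_total=120, size_px=48, n_angles=64,
                        hidden_channels=16, n_res_blocks=2, epochs=30)


def _small_dataset(seed: int, stripes: StripeSpec, n_total: int | None = None,
                   train_fraction: float | None = None):
    c = _SMALL
    return build_dataset(n_total or c.n_total, train_fraction or c.train_fraction,
                         PhantomConfig(size_px=c.size_px),
                         replace(stripes, seed=seed), default_angles(c.n_angles))


def _held_out_wavelet_loss(model, test_split) -> float:
    return float(np.mean([
        wavelet_loss(forward(model, rec.corrupted_coeffs), rec.artifact_coeffs)
        for rec in test_split]))


def run_ablation(seeds=(0, 1, 2)) -> dict:
    """Complete vs related coefficient mode, identical budgets and seeds.

    Returns per-seed and median held-out wavelet losses.  The complete model
    sees all four sub-bands; the related model has WV/WD zeroed on input and
    so cannot exploit the cross-band complementarity.
    """
    c = _SMALL
    losses = {"complete": [], "related": []}
    for seed in seeds:
        tr, te = _small_dataset(seed, StripeSpec())
        for mode in ("complete", "related"):
            model = build_model(CorrectionModelSpec(
                hidden_channels=c.hidden_channels, n_res_blocks=c.n_res_blocks),
                init_seed=seed)
            tcfg = TrainConfig(epochs=c.epochs, batch_size=c.batch_size,
                               learning_rate=c.learning_rate, seed=seed,
                               coefficient_mode=mode)
            model, _ = train(model, tr, te, tcfg)
            losses[mode].append(_held_out_wavelet_loss(model, te))
    return {
        "complete": losses["complete"],
        "related": losses["related"],
        "median_complete": float(np.median(losses["complete"])),
        "median_related": float(np.median(losses["related"])),
    }


def run_transfer(seeds=(0, 1, 2), n_small: int = 25,
                 budget_epochs: int = 12) -> dict:
    """Fine-tune from a synthetic-data checkpoint vs train from scratch.

    Per seed: pretrain on the default stripe distribution, then adapt to the
    distribution-shifted stripe set (:data:`SHIFTED_STRIPES`, 20 training
    samples) either by fine-tuning the pretrained parameters (reduced
    learning rate) or by training from random initialization with the same
    epoch budget.  Compared on best validation loss.
    """
    c = _SMALL
    spec = CorrectionModelSpec(hidden_channels=c.hidden_channels,
                               n_res_blocks=c.n_res_blocks)
    out = {"fine_tuned": [], "from_scratch": []}
    for seed in seeds:
        pre_tr, pre_te = _small_dataset(seed, StripeSpec())
        pre_model = build_model(spec, init_seed=seed)
        pre_model, _ = train(pre_model, pre_tr, pre_te, TrainConfig(
            epochs=c.epochs, batch_size=c.batch_size, seed=seed))

        small_tr, small_te = _small_dataset(seed + 1000, SHIFTED_STRIPES,
                                            n_total=n_small, train_fraction=20 / n_small)
        ft_cfg = TrainConfig(epochs=budget_epochs, batch_size=c.batch_size,
                             learning_rate=1e-4, seed=seed)
        ft_model, ft_hist = fine_tune(pre_model, small_tr, ft_cfg, val_split=small_te)

        scratch = build_model(spec, init_seed=seed + 7)
        sc_cfg = TrainConfig(epochs=budget_epochs, batch_size=c.batch_size,
                             learning_rate=c.learning_rate, seed=seed)
        scratch, sc_hist = train(scratch, small_tr, small_te, sc_cfg)

        out["fine_tuned"].append(float(min(ft_hist.val_loss)))
        out["from_scratch"].append(float(min(sc_hist.val_loss)))
    out["median_fine_tuned"] = float(np.median(out["fine_tuned"]))
    out["median_from_scratch"] = float(np.median(out["from_scratch"]))
    return out
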