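"""The artifact-correction residual network and its sinogram-level wrapper.

The network maps the four Haar sub-bands of a (possibly striped) sinogram to
the four predicted stripe components.  At default width it comprises 14
convolution layers: a 4->64 head conv, six residual blocks of two 64->64
convs each, and a linear 64->4 tail conv.  Stride is 1 everywhere and padding
preserves the spatial size — down-sampling would lose the one- and
few-pixel-wide stripes the network is meant to find.

Correction of a sinogram is: pad to even size, Haar transform, predict the
artifact per band, subtract it from each band, inverse transform, crop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import CorrectionNet
from .haar_wavelet import (ArtifactEstimate, Sinogram, WaveletCoefficients,
                           crop, hdwt, ihdwt, pad_to_even)

__all__ = ["CorrectionModelSpec", "CorrectionModel", "build_model", "forward",
           "correct_sinogram", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1


class CheckpointError(ValueError):
    """A checkpoint is unreadable or does not match the requested model spec."""


@dataclass(frozen=True)
class CorrectionModelSpec:
    """Architecture hyper-parameters.

    The defaults give the full-size network: 2 + 2 * n_res_blocks = 14
    convolution layers, hidden width 64.  ``input_scale`` selects an optional
    per-sample standardization of the coefficient stack before the network
    (``"std"``: divide by the stack's standard deviation, multiply the
    predicted artifact back; ``"none"``: feed raw coefficients).
    """

    in_channels: int = 4
    out_channels: int = 4
    hidden_channels: int = 64
    n_res_blocks: int = 6
    input_scale: str = "std"

    def __post_init__(self) -> None:
        if self.in_channels != 4 or self.out_channels != 4:
            raise ValueError("the correction network is four-band in, four-band out")
        if self.hidden_channels < 1 or self.n_res_blocks < 0:
            raise ValueError("invalid width/depth")
        if self.input_scale not in ("none", "std"):
            raise ValueError(f"unknown input_scale {self.input_scale!r}")

    @property
    def n_conv_layers(self) -> int:
        return 2 + 2 * self.n_res_blocks


class CorrectionModel:
    """A :class:`CorrectionNet` plus its spec and training provenance."""

    def __init__(self, spec: CorrectionModelSpec, net: CorrectionNet,
                 init_seed: int, provenance: dict | None = None,
                 coefficient_mode: str = "complete"):
        self.spec = spec
        self.net = net
        self.init_seed = init_seed
        self.provenance = dict(provenance or {})
        #: "complete" feeds all four sub-bands; "related" zeroes WV/WD on
        #: input (the ablation variant trained on WA+WH only).
        self.coefficient_mode = coefficient_mode

    @property
    def n_conv_layers(self) -> int:
        return len(self.net.conv_layers())

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def copy(self) -> "CorrectionModel":
        other = build_model(self.spec, self.init_seed)
        other.net.set_state(self.net.get_state())
        other.provenance = dict(self.provenance)
        other.coefficient_mode = self.coefficient_mode
        return other

    def _sample_scale(self, stack: np.ndarray) -> float:
        if self.spec.input_scale == "none":
            return 1.0
        s = float(np.std(stack))
        return s if s > 1e-12 else 1.0

    def predict_stack(self, stack: np.ndarray) -> np.ndarray:
        """(4, H, W) coefficient stack -> (4, H, W) predicted artifact stack."""
        scale = self._sample_scale(stack)
        x = (stack / scale).astype(self.net.head.w.dtype)[None]
        if self.coefficient_mode == "related":
            x[:, 2:, :, :] = 0.0
        y = self.net.forward(x, keep=False)[0]
        return y.astype(float) * scale


def build_model(spec: CorrectionModelSpec | None = None,
                init_seed: int = 0) -> CorrectionModel:
    """Deterministically initialized correction model (He fan-in init)."""
    spec = spec or CorrectionModelSpec()
    rng = np.random.default_rng(init_seed)
    net = CorrectionNet(spec.in_channels, spec.hidden_channels,
                        spec.out_channels, spec.n_res_blocks, rng)
    return CorrectionModel(spec, net, init_seed)


def forward(model: CorrectionModel, c: WaveletCoefficients) -> ArtifactEstimate:
    """Predicted per-band stripe components; spatial shape is preserved."""
    h, w = c.band_shape
    if h < 3 or w < 3:
        raise ValueError(f"sub-band {h}x{w} smaller than the 3x3 kernel")
    return ArtifactEstimate.from_stack(model.predict_stack(c.stack()))


def correct_sinogram(model: CorrectionModel, s: Sinogram) -> Sinogram:
    """Remove the predicted stripe artifact from a sinogram.

    Angle metadata is preserved; odd dimensions are handled by replicate
    padding before the transform and exact cropping after the inverse.
    """
    padded, rec = pad_to_even(s.data)
    coeffs = hdwt(padded)
    est = forward(model, coeffs)
    cleaned = ihdwt(coeffs - est)
    return s.with_data(crop(cleaned, rec))


def save_checkpoint(path, model: CorrectionModel) -> None:
    """Single-file checkpoint: parameters + spec + provenance, versioned."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "spec": asdict(model.spec),
        "init_seed": model.init_seed,
        "coefficient_mode": model.coefficient_mode,
        "provenance": model.provenance,
    }
    arrays = {f"param_{i}": arr for i, arr in enumerate(model.net.get_state())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_spec: CorrectionModelSpec | None = None) -> CorrectionModel:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = [data[f"param_{i}"]
                     for i in range(sum(1 for k in data.files if k.startswith("param_")))]
    except Exception as exc:  # noqa: BLE001 - surfaced as a checkpoint error
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version {meta.get('format_version')}")
    spec = CorrectionModelSpec(**meta["spec"])
    if expect_spec is not None and spec != expect_spec:
        raise CheckpointError(f"checkpoint spec {spec} does not match expected {expect_spec}")
    model = build_model(spec, meta["init_seed"])
    model.net.set_state(state)
    model.provenance = meta.get("provenance", {})
    model.coefficient_mode = meta.get("coefficient_mode", "complete")
    return model
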