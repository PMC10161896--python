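"""FBP reconstruction and the PSNR/SSIM evaluation harness.

The evaluation protocol scores correction methods on both the sinogram and
the reconstructed slice: for every test sample and method, the corrupted
sinogram is corrected, PSNR/SSIM against the clean sinogram are computed,
both sinograms are reconstructed by filtered back projection, and slice
PSNR/SSIM are computed inside the reconstruction support circle.  Results
are aggregated per degradation bin (the corrupted-vs-clean sinogram PSNR
serving as the artifact-severity axis), always including an identity
"no correction" method as the floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skimage.transform
from skimage.metrics import structural_similarity

from .haar_wavelet import Sinogram

__all__ = ["EvaluationReport", "fbp", "psnr", "ssim", "evaluate",
           "support_mask", "PSNR_IDENTICAL"]

#: Sentinel reported when reference and test are identical (zero MSE).
PSNR_IDENTICAL = math.inf


class ParameterError(ValueError):
    pass


def fbp(s: Sinogram, filter_name: str = "ramp") -> np.ndarray:
    """Filtered back projection; square output with side = detector count."""
    if s.n_angles < 2:
        raise ParameterError("need at least 2 projection angles")
    if np.any(s.angles_deg < 0) or np.any(s.angles_deg >= 180):
        raise ParameterError("angles must lie in [0, 180)")
    valid = {"ramp", "shepp-logan", "cosine", "hamming", "hann"}
    if filter_name is not None and filter_name not in valid:
        raise ParameterError(f"unknown filter {filter_name!r}; choose from {sorted(valid)}")
    return skimage.transform.iradon(
        s.data.T, theta=s.angles_deg, filter_name=filter_name,
        circle=True, output_size=s.n_detectors)


def support_mask(side: int, margin: int = 2) -> np.ndarray:
    """Boolean inscribed-circle mask; outside it FBP output is geometry artifact."""
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    r = np.hypot(yy - c, xx - c)
    return r <= (side / 2.0 - margin)


def psnr(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    ``data_range`` defaults to the reference image's max - min; identical
    images return the +inf sentinel.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = float(np.mean((reference - test) ** 2))
    if err == 0.0:
        return PSNR_IDENTICAL
    return 10.0 * math.log10(data_range ** 2 / err)


def ssim(reference: np.ndarray, test: np.ndarray,
         data_range: float | None = None) -> float:
    """Mean structural similarity (Gaussian window, standard constants), in [0, 1]."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if min(reference.shape) < 7:
        raise ValueError(f"image {reference.shape} smaller than the 7x7 SSIM window")
    if data_range is None:
        data_range = float(reference.max() - reference.min())
        if data_range <= 0:
            data_range = 1.0
    val = structural_similarity(
        reference, test, data_range=data_range, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False)
    return float(np.clip(val, 0.0, 1.0))


@dataclass
class EvaluationReport:
    """Per-method, per-sample metric table plus per-degradation-bin aggregates."""

    table: pd.DataFrame
    aggregates: dict
    metadata: dict = field(default_factory=dict)

    def to_files(self, csv_path, json_path) -> None:
        self.table.to_csv(csv_path, index=False)
        with open(json_path, "w") as f:
            json.dump({"aggregates": self.aggregates, "metadata": self.metadata},
                      f, indent=2, default=float)

    @classmethod
    def from_files(cls, csv_path, json_path) -> "EvaluationReport":
        table = pd.read_csv(csv_path)
        with open(json_path) as f:
            d = json.load(f)
        return cls(table=table, aggregates=d["aggregates"], metadata=d["metadata"])


_METRIC_COLS = ["sino_psnr", "sino_ssim", "slice_psnr", "slice_ssim"]


def evaluate(methods: dict, test_split, bins: int | list = 3,
             filter_name: str = "ramp", metadata: dict | None = None) -> EvaluationReport:
    """Score correction methods on a test split.

    ``methods`` maps a name to a callable ``Sinogram -> Sinogram``.  An
    ``identity`` (no correction) entry is always included as the floor.
    ``bins`` follows pandas ``cut``: an int bins the degradation PSNR axis
    into equal-width intervals.
    """
    methods = {"identity": lambda s: s, **methods}
    rows = []
    for i, rec in enumerate(test_split):
        deg = psnr(rec.clean.data, rec.corrupted.data)
        clean_slice = fbp(rec.clean, filter_name)
        mask = support_mask(clean_slice.shape[0])
        srange = float(rec.clean.data.max() - rec.clean.data.min()) or 1.0
        crange = float(clean_slice.max() - clean_slice.min()) or 1.0
        for name, fn in methods.items():
            row = {"sample": i, "method": name, "degradation_psnr": deg}
            try:
                corrected = fn(rec.corrupted)
                row["sino_psnr"] = psnr(rec.clean.data, corrected.data, srange)
                row["sino_ssim"] = ssim(rec.clean.data, corrected.data, srange)
                corr_slice = fbp(corrected, filter_name)
                row["slice_psnr"] = psnr(clean_slice[mask], corr_slice[mask], crange)
                row["slice_ssim"] = ssim(clean_slice * mask, corr_slice * mask, crange)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - per-sample failures recorded
                row.update({c: np.nan for c in _METRIC_COLS})
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)

    table = pd.DataFrame(rows)
    finite_deg = table["degradation_psnr"].replace(math.inf, np.nan)
    if finite_deg.notna().any():
        table["degradation_bin"] = pd.cut(finite_deg, bins=bins).astype(str)
    else:
        table["degradation_bin"] = "all"

    aggregates: dict = {}
    grouped = table.groupby(["method", "degradation_bin"], observed=True)
    for (method, dbin), sub in grouped:
        finite = sub[_METRIC_COLS].replace(math.inf, np.nan)
        aggregates.setdefault(method, {})[str(dbin)] = {
            "n": int(len(sub)),
            **{c: {"mean": float(finite[c].mean()), "sd": float(finite[c].std())}
               for c in _METRIC_COLS},
        }
    return EvaluationReport(table=table, aggregates=aggregates,
                            metadata=dict(metadata or {}))
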