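"""Single-level 2-D Haar wavelet transform and its exact inverse.

The correction workflow operates in the wavelet domain: a sinogram is split
into four half-resolution sub-bands (approximation WA, horizontal detail WH,
vertical detail WV, diagonal detail WD), the network predicts the stripe
component of each band, and the inverse transform maps the cleaned bands back
to a sinogram.

The transform uses the *orthonormal* Haar normalization: for each disjoint
2x2 block ``[[p00, p01], [p10, p11]]``

    WA = (p00 + p01 + p10 + p11) / 2
    WH = (p00 + p01 - p10 - p11) / 2
    WV = (p00 - p01 + p10 - p11) / 2
    WD = (p00 - p01 - p10 + p11) / 2

so that the sum of squares over the four bands equals the sum of squares of
the source (energy preservation), which keeps wavelet-domain MSE commensurate
with image-domain MSE.

Axis convention (package-wide): sinogram row index = projection angle,
column index = detector pixel.  A defective detector pixel therefore shows up
as a constant *column* stripe; under the formulas above such a stripe affects
only the WA and WV bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sinogram",
    "WaveletCoefficients",
    "PadRecord",
    "hdwt",
    "ihdwt",
    "pad_to_even",
    "crop",
]


class DimensionError(ValueError):
    """An array axis has an incompatible length (e.g. odd where even is required)."""


@dataclass
class Sinogram:
    """Parallel-beam projection data.

    Parameters
    ----------
    data:
        2-D float array; rows are projection angles, columns detector pixels.
    angles_deg:
        Ascending projection angles in degrees, one per row of ``data``.
    """

    data: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(f"sinogram data must be 2-D, got {self.data.ndim}-D")
        if self.angles_deg.ndim != 1 or len(self.angles_deg) != self.data.shape[0]:
            raise DimensionError(
                f"angles_deg length {self.angles_deg.size} does not match "
                f"row count {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles_deg must be strictly ascending")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Sinogram":
        """New sinogram sharing this one's angle metadata."""
        return Sinogram(data=np.asarray(data, dtype=float), angles_deg=self.angles_deg.copy())


@dataclass
class WaveletCoefficients:
    """The four half-resolution Haar sub-bands of one image.

    Also used for the network's *predicted artifact* per band (the stripe
    components S_WA, S_WH, S_WV, S_WD), which shares the same structure.
    """

    wa: np.ndarray
    wh: np.ndarray
    wv: np.ndarray
    wd: np.ndarray

    BAND_NAMES = ("wa", "wh", "wv", "wd")

    def __post_init__(self) -> None:
        self.wa = np.asarray(self.wa, dtype=float)
        self.wh = np.asarray(self.wh, dtype=float)
        self.wv = np.asarray(self.wv, dtype=float)
        self.wd = np.asarray(self.wd, dtype=float)
        shapes = {b.shape for b in self.bands()}
        if len(shapes) != 1:
            raise DimensionError(f"sub-band shapes differ: {sorted(shapes)}")

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.wa, self.wh, self.wv, self.wd)

    @property
    def band_shape(self) -> tuple[int, int]:
        return self.wa.shape

    def stack(self) -> np.ndarray:
        """Channel-first array of shape (4, H', W') in band order WA, WH, WV, WD."""
        return np.stack(self.bands(), axis=0)

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "WaveletCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != 4:
            raise DimensionError(f"expected (4, H, W) stack, got {arr.shape}")
        return cls(wa=arr[0], wh=arr[1], wv=arr[2], wd=arr[3])

    def __sub__(self, other: "WaveletCoefficients") -> "WaveletCoefficients":
        return WaveletCoefficients.from_stack(self.stack() - other.stack())

    def __add__(self, other: "WaveletCoefficients") -> "WaveletCoefficients":
        return WaveletCoefficients.from_stack(self.stack() + other.stack())


#: Alias: the network's per-band predicted stripe components have the same
#: structure as a coefficient set.
ArtifactEstimate = WaveletCoefficients


@dataclass
class PadRecord:
    """How many replicate rows/columns :func:`pad_to_even` appended."""

    rows_added: int = 0
    cols_added: int = 0

    @property
    def empty(self) -> bool:
        return self.rows_added == 0 and self.cols_added == 0


def _as_image(s) -> np.ndarray:
    if isinstance(s, Sinogram):
        return s.data
    return np.asarray(s, dtype=float)


def hdwt(s) -> WaveletCoefficients:
    """Single-level Haar discrete wavelet transform of a sinogram or 2-D image.

    Both dimensions must be even (see :func:`pad_to_even`).  Returns the four
    sub-bands at half resolution, each of shape (H/2, W/2).
    """
    x = _as_image(s)
    if x.ndim != 2:
        raise DimensionError(f"expected 2-D input, got {x.ndim}-D")
    h, w = x.shape
    if h % 2:
        raise DimensionError(f"height {h} is odd; pad_to_even first (axis 0)")
    if w % 2:
        raise DimensionError(f"width {w} is odd; pad_to_even first (axis 1)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    p00 = x[0::2, 0::2]
    p01 = x[0::2, 1::2]
    p10 = x[1::2, 0::2]
    p11 = x[1::2, 1::2]
    return WaveletCoefficients(
        wa=(p00 + p01 + p10 + p11) / 2.0,
        wh=(p00 + p01 - p10 - p11) / 2.0,
        wv=(p00 - p01 + p10 - p11) / 2.0,
        wd=(p00 - p01 - p10 + p11) / 2.0,
    )


def ihdwt(c: WaveletCoefficients) -> np.ndarray:
    """Exact algebraic inverse of :func:`hdwt`; output shape (2H', 2W')."""
    wa, wh, wv, wd = c.bands()
    hh, ww = wa.shape
    out = np.empty((2 * hh, 2 * ww), dtype=float)
    out[0::2, 0::2] = (wa + wh + wv + wd) / 2.0
    out[0::2, 1::2] = (wa + wh - wv - wd) / 2.0
    out[1::2, 0::2] = (wa - wh + wv - wd) / 2.0
    out[1::2, 1::2] = (wa - wh - wv + wd) / 2.0
    return out


def pad_to_even(image: np.ndarray) -> tuple[np.ndarray, PadRecord]:
    """Replicate-pad at most one row and one column so both dimensions are even.

    Returns the (possibly) padded image and a :class:`PadRecord` that
    :func:`crop` uses to recover the original extent exactly.
    """
    x = _as_image(image)
    if x.ndim != 2:
        raise DimensionError(f"expected 2-D input, got {x.ndim}-D")
    rec = PadRecord(rows_added=x.shape[0] % 2, cols_added=x.shape[1] % 2)
    if rec.empty:
        return x, rec
    return np.pad(x, ((0, rec.rows_added), (0, rec.cols_added)), mode="edge"), rec


def crop(image: np.ndarray, rec: PadRecord) -> np.ndarray:
    """Undo :func:`pad_to_even`."""
    x = np.asarray(image)
    h = x.shape[0] - rec.rows_added
    w = x.shape[1] - rec.cols_added
    return x[:h, :w]
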