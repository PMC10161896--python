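"""Synthetic paired training data: phantoms -> sinograms -> stripe injection.

Real training corpora for ring-artifact correction are scarce, so training
pairs are manufactured: a grayscale image is Radon-transformed into a clean
sinogram S1, and random stripe artifacts (the sinogram-domain signature of
detector-pixel defects) are added to obtain the corrupted sinogram S2.  The
difference S2 - S1 is the ground-truth artifact field, and its Haar
transform is the wavelet-domain label the network trains against.

Phantom images of random overlapping ellipses/rectangles stand in for a
natural-image corpus so the package needs no download; a folder loader
(grayscale conversion + center crop) accepts user-supplied images.

Everything is seeded: the same master seed reproduces a bit-identical
dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import skimage.transform

from .haar_wavelet import Sinogram, WaveletCoefficients, hdwt, pad_to_even

__all__ = [
    "StripeSpec", "PhantomConfig", "SampleRecord",
    "make_phantom", "radon", "default_angles", "add_stripes",
    "build_dataset", "degradation_psnr", "save_dataset", "load_dataset",
    "load_image_folder",
]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class StripeSpec:
    """Random stripe-artifact model.

    Stripes are contiguous runs of detector columns carrying a constant
    offset (additive mode) or constant gain (multiplicative mode), spanning
    either all projection angles (full ring) or, with probability
    ``partial_fraction``, a random contiguous angular interval (semi-ring).
    Amplitudes are fractions of the clean sinogram's dynamic range, drawn
    with random sign.

    Defaults emulate the common beamline situation: 5-30 mostly one- to
    few-pixel stripes of modest amplitude, with a ~30% share of semi-rings.
    """

    n_stripes_range: tuple[int, int] = (5, 30)
    width_range_px: tuple[int, int] = (1, 3)
    amplitude_range: tuple[float, float] = (0.02, 0.15)
    partial_fraction: float = 0.3
    mode: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stripes_range", "width_range_px", "amplitude_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ParameterError(f"{name} is empty: {(lo, hi)}")
        if self.width_range_px[0] < 1:
            raise ParameterError("stripe widths must be >= 1 px")
        if not 0.0 <= self.partial_fraction <= 1.0:
            raise ParameterError("partial_fraction must be in [0, 1]")
        if self.mode not in ("additive", "multiplicative"):
            raise ParameterError(f"unknown stripe mode {self.mode!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StripeSpec":
        d = json.loads(text)
        for name in ("n_stripes_range", "width_range_px", "amplitude_range"):
            d[name] = tuple(d[name])
        return cls(**d)


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom generator settings: image side and shape-count range."""

    size_px: int = 64
    n_shapes_range: tuple[int, int] = (3, 8)


@dataclass
class SampleRecord:
    """One paired training sample.

    ``artifact_field`` is exactly ``corrupted - clean``; ``artifact_coeffs``
    (= corrupted_coeffs - clean_coeffs) is the training label, and by
    linearity of the Haar transform equals ``hdwt(artifact_field)``.
    """

    clean: Sinogram
    corrupted: Sinogram
    artifact_field: np.ndarray
    clean_coeffs: WaveletCoefficients
    corrupted_coeffs: WaveletCoefficients
    artifact_coeffs: WaveletCoefficients

    @classmethod
    def from_pair(cls, clean: Sinogram, corrupted: Sinogram) -> "SampleRecord":
        cc = hdwt(pad_to_even(clean.data)[0])
        kc = hdwt(pad_to_even(corrupted.data)[0])
        return cls(
            clean=clean,
            corrupted=corrupted,
            artifact_field=corrupted.data - clean.data,
            clean_coeffs=cc,
            corrupted_coeffs=kc,
            artifact_coeffs=kc - cc,
        )


def make_phantom(size_px: int, n_shapes: int, seed: int) -> np.ndarray:
    """Random grayscale phantom in [0, 1] on a circular support.

    Overlapping ellipses and rectangles with smooth linear intensity ramps,
    zero outside the inscribed circle; deterministic for fixed arguments.
    """
    if size_px < 16:
        raise ParameterError(f"size_px must be >= 16, got {size_px}")
    if n_shapes < 0:
        raise ParameterError("n_shapes must be >= 0")
    rng = np.random.default_rng(seed)
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px].astype(float)
    yn, xn = (yy - c) / c, (xx - c) / c
    support = (xn ** 2 + yn ** 2) <= (1.0 - 2.0 / size_px) ** 2

    img = np.zeros((size_px, size_px), dtype=float)
    for _ in range(n_shapes):
        kind = rng.choice(["ellipse", "rect"])
        cx, cy = rng.uniform(-0.55, 0.55, size=2)
        a, b = rng.uniform(0.08, 0.45, size=2)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0], p=[0.3, 0.7])
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xn - cx) * ct + (yn - cy) * st
        yr = -(xn - cx) * st + (yn - cy) * ct
        if kind == "ellipse":
            mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        else:
            mask = (np.abs(xr) <= a) & (np.abs(yr) <= b)
        # smooth intensity ramp along a random direction
        phi = rng.uniform(0, 2 * np.pi)
        ramp = 0.75 + 0.25 * (np.cos(phi) * xn + np.sin(phi) * yn)
        img += amp * ramp * mask

    img *= support
    lo, hi = img[support].min() if support.any() else 0.0, img.max()
    if hi > lo:
        img = (img - min(lo, 0.0)) / (hi - min(lo, 0.0))
        img *= support
    img = np.clip(img, 0.0, 1.0)
    return img


def default_angles(n: int = 360, start: float = 0.0, stop: float = 179.5) -> np.ndarray:
    """``n`` equally spaced projection angles from ``start`` to ``stop`` inclusive."""
    if n < 2:
        raise ParameterError(f"need at least 2 angles, got {n}")
    return np.linspace(start, stop, n)


def radon(image: np.ndarray, angles_deg) -> Sinogram:
    """Parallel-beam Radon transform over the inscribed-circle support.

    Returns one projection row per angle (row = angle, column = detector).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2-D, got {image.shape}")
    angles_deg = np.asarray(angles_deg, dtype=float)
    if np.any(angles_deg < 0) or np.any(angles_deg >= 180):
        raise ParameterError("angles must lie in [0, 180)")
    sino = skimage.transform.radon(image, theta=angles_deg, circle=True)
    return Sinogram(data=sino.T, angles_deg=angles_deg)


def add_stripes(s: Sinogram, spec: StripeSpec) -> SampleRecord:
    """Inject random stripe artifacts according to ``spec``; fully seeded."""
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = s.data.shape
    if spec.width_range_px[1] >= n_cols:
        raise ParameterError(
            f"max stripe width {spec.width_range_px[1]} >= detector count {n_cols}")
    dyn = float(s.data.max() - s.data.min())
    n_stripes = int(rng.integers(spec.n_stripes_range[0], spec.n_stripes_range[1] + 1))

    add_field = np.zeros_like(s.data)
    gain_field = np.ones_like(s.data)
    for _ in range(n_stripes):
        width = int(rng.integers(spec.width_range_px[0], spec.width_range_px[1] + 1))
        col0 = int(rng.integers(0, n_cols - width + 1))
        amp = float(rng.uniform(*spec.amplitude_range)) * float(rng.choice([-1.0, 1.0]))
        rows = slice(None)
        if rng.uniform() < spec.partial_fraction:
            min_len = max(1, n_rows // 10)
            lo = int(rng.integers(0, n_rows - min_len + 1))
            hi = int(rng.integers(lo + min_len, n_rows + 1))
            rows = slice(lo, hi)
        if spec.mode == "additive":
            add_field[rows, col0:col0 + width] += amp * dyn
        else:
            gain_field[rows, col0:col0 + width] *= (1.0 + amp)

    if spec.mode == "additive":
        corrupted = s.data + add_field
    else:
        corrupted = s.data * gain_field
    return SampleRecord.from_pair(s, s.with_data(corrupted))


def build_dataset(n_total: int, train_fraction: float,
                  phantom_cfg: PhantomConfig | None = None,
                  stripe_spec: StripeSpec | None = None,
                  angles=None) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Seeded train/test split of freshly simulated samples.

    ``stripe_spec.seed`` is the master seed for phantoms, stripe draws and
    the split; per the reference protocol scale, ``n_total=824`` with
    ``train_fraction=712/824`` yields the 712/112 split.
    """
    phantom_cfg = phantom_cfg or PhantomConfig()
    stripe_spec = stripe_spec or StripeSpec()
    if angles is None:
        angles = default_angles()
    if n_total < 2:
        raise ParameterError("n_total must be >= 2")
    n_train = int(round(n_total * train_fraction))
    if not 0 < n_train < n_total:
        raise ParameterError(
            f"train_fraction {train_fraction} leaves an empty split for n_total {n_total}")

    master = np.random.default_rng(stripe_spec.seed)
    records: list[SampleRecord] = []
    for _ in range(n_total):
        seed_phantom = int(master.integers(0, 2 ** 31))
        seed_stripe = int(master.integers(0, 2 ** 31))
        n_shapes = int(master.integers(phantom_cfg.n_shapes_range[0],
                                       phantom_cfg.n_shapes_range[1] + 1))
        img = make_phantom(phantom_cfg.size_px, n_shapes, seed_phantom)
        sino = radon(img, angles)
        records.append(add_stripes(sino, replace(stripe_spec, seed=seed_stripe)))

    order = master.permutation(n_total)
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def degradation_psnr(record: SampleRecord) -> float:
    """PSNR (dB) of the corrupted vs clean sinogram — the artifact-severity axis."""
    from .recon_metrics import psnr
    return psnr(record.clean.data, record.corrupted.data)


# ---------------------------------------------------------------------------
# persistence

def save_dataset(path, train: list[SampleRecord], test: list[SampleRecord],
                 stripe_spec: StripeSpec, angles=None) -> None:
    """Write a paired dataset to one HDF5 file (groups /train and /test)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["stripe_spec"] = stripe_spec.to_json()
        f.attrs["format_version"] = 1
        if angles is None and train:
            angles = train[0].clean.angles_deg
        if angles is not None:
            f.attrs["angles_deg"] = np.asarray(angles, dtype=float)
        for name, split in (("train", train), ("test", test)):
            g = f.create_group(name)
            for i, rec in enumerate(split):
                sg = g.create_group(f"sample_{i:05d}")
                sg.create_dataset("clean", data=rec.clean.data.astype(np.float32))
                sg.create_dataset("corrupted", data=rec.corrupted.data.astype(np.float32))
                sg.create_dataset("artifact", data=rec.artifact_field.astype(np.float32))
                sg.attrs["angles_deg"] = rec.clean.angles_deg


def load_dataset(path) -> tuple[list[SampleRecord], list[SampleRecord], StripeSpec]:
    """Read a dataset written by :func:`save_dataset`; coefficients are recomputed."""
    import h5py

    out: dict[str, list[SampleRecord]] = {"train": [], "test": []}
    with h5py.File(path, "r") as f:
        spec = StripeSpec.from_json(f.attrs["stripe_spec"])
        for name in ("train", "test"):
            for key in sorted(f[name].keys()):
                sg = f[name][key]
                angles = np.asarray(sg.attrs["angles_deg"], dtype=float)
                clean = Sinogram(np.asarray(sg["clean"], dtype=float), angles)
                corrupted = Sinogram(np.asarray(sg["corrupted"], dtype=float), angles)
                out[name].append(SampleRecord.from_pair(clean, corrupted))
    return out["train"], out["test"], spec


def load_image_folder(path, size_px: int) -> list[np.ndarray]:
    """Load user-supplied images as [0, 1] grayscale, center-cropped squares.

    Mirrors the pre-processing applied to a natural-image corpus: grayscale
    conversion, center crop to ``size_px`` x ``size_px``, rescale to [0, 1].
    """
    from pathlib import Path

    import imageio.v3 as iio
    import skimage.transform as sktr

    images = []
    for p in sorted(Path(path).iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"):
            continue
        arr = np.asarray(iio.imread(p), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=-1)
        side = min(arr.shape)
        r0 = (arr.shape[0] - side) // 2
        c0 = (arr.shape[1] - side) // 2
        arr = arr[r0:r0 + side, c0:c0 + side]
        if side != size_px:
            arr = sktr.resize(arr, (size_px, size_px), anti_aliasing=True)
        lo, hi = arr.min(), arr.max()
        images.append((arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr))
    return images
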