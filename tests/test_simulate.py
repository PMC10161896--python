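"""Synthetic-data factory: phantoms, Radon geometry, stripe injection, splits."""

import dataclasses

import numpy as np
import pytest

from destripenet.haar_wavelet import hdwt
from destripenet.simulate import (ParameterError, PhantomConfig, SampleRecord,
                                  StripeSpec, add_stripes, build_dataset,
                                  default_angles, degradation_psnr,
                                  load_dataset, make_phantom, radon,
                                  save_dataset)


class TestPhantom:
    def test_seeded_determinism(self):
        a = make_phantom(32, 5, seed=7)
        b = make_phantom(32, 5, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make_phantom(32, 5, seed=8))

    def test_no_shapes_gives_background_only(self):
        assert np.array_equal(make_phantom(32, 0, seed=0), np.zeros((32, 32)))

    def test_values_in_unit_interval_across_seeds(self):
        for seed in range(100):
            img = make_phantom(24, 4, seed=seed)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_zero_outside_circular_support(self):
        img = make_phantom(32, 6, seed=1)
        assert img[0, 0] == 0.0 and img[0, -1] == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            make_phantom(8, 3, seed=0)


class TestRadon:
    def test_zero_image_zero_sinogram(self):
        s = radon(np.zeros((32, 32)), default_angles(8))
        assert np.allclose(s.data, 0.0)

    def test_projection_mass_conserved(self):
        img = make_phantom(64, 5, seed=3)
        s = radon(img, default_angles(45))
        mass = img.sum()
        assert np.max(np.abs(s.data.sum(axis=1) - mass)) / mass < 0.01

    def test_center_pixel_projects_to_central_column(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        s = radon(img, default_angles(20))
        assert set(np.argmax(s.data, axis=1)) == {16}

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            radon(np.zeros((16, 20)), default_angles(4))


class TestDefaultAngles:
    def test_reference_protocol(self):
        a = default_angles()
        assert len(a) == 360 and a[0] == 0.0 and a[-1] == 179.5
        assert np.allclose(np.diff(a), 0.5)

    def test_two_point_case(self):
        assert np.array_equal(default_angles(2, 0, 90), [0.0, 90.0])

    @pytest.mark.parametrize("n,start,stop", [(5, 0, 100), (7, 10, 20)])
    def test_spacing_by_construction(self, n, start, stop):
        assert np.allclose(np.diff(default_angles(n, start, stop)),
                           (stop - start) / (n - 1))

    def test_too_few_rejected(self):
        with pytest.raises(ParameterError):
            default_angles(1)


def _sino(seed=3, size=32, n_angles=32):
    return radon(make_phantom(size, 5, seed=seed), default_angles(n_angles))


class TestAddStripes:
    def test_zero_amplitude_leaves_sinogram_unchanged(self):
        rec = add_stripes(_sino(), StripeSpec(amplitude_range=(0.0, 0.0), seed=0))
        assert np.array_equal(rec.corrupted.data, rec.clean.data)

    def test_single_full_stripe_is_column_constant(self):
        spec = StripeSpec(n_stripes_range=(1, 1), width_range_px=(1, 1),
                          amplitude_range=(0.1, 0.1), partial_fraction=0.0, seed=5)
        rec = add_stripes(_sino(), spec)
        diff = rec.corrupted.data - rec.clean.data
        cols = np.flatnonzero(np.abs(diff).max(axis=0) > 0)
        assert len(cols) == 1
        dyn = rec.clean.data.max() - rec.clean.data.min()
        col = diff[:, cols[0]]
        assert np.allclose(np.abs(col), 0.1 * dyn)
        assert np.allclose(col, col[0])

    def test_seeded_determinism(self):
        spec = StripeSpec(seed=9)
        a = add_stripes(_sino(), spec)
        b = add_stripes(_sino(), spec)
        assert np.array_equal(a.corrupted.data, b.corrupted.data)

    def test_multiplicative_mode_scales_clean(self):
        spec = StripeSpec(mode="multiplicative", partial_fraction=0.0, seed=2)
        rec = add_stripes(_sino(), spec)
        # gains are column-constant wherever the clean sinogram is nonzero
        for j in range(rec.clean.data.shape[1]):
            rows = np.abs(rec.clean.data[:, j]) > 1e-9
            if rows.any():
                gains = rec.corrupted.data[rows, j] / rec.clean.data[rows, j]
                assert gains.max() - gains.min() < 1e-9

    def test_too_wide_stripe_rejected(self):
        with pytest.raises(ParameterError):
            add_stripes(_sino(), StripeSpec(width_range_px=(1, 64), seed=0))

    def test_record_invariants(self):
        rec = add_stripes(_sino(), StripeSpec(seed=11))
        assert np.array_equal(rec.clean.data + rec.artifact_field, rec.corrupted.data)
        label = rec.artifact_coeffs.stack()
        direct = hdwt(rec.artifact_field).stack()
        assert np.max(np.abs(label - direct)) < 1e-10  # hdwt linearity


class TestBuildDataset:
    def test_reference_scale_split_is_712_112(self):
        angles = default_angles(2, 0.0, 90.0)
        train, test = build_dataset(
            824, 712 / 824, PhantomConfig(size_px=16, n_shapes_range=(0, 1)),
            StripeSpec(width_range_px=(1, 2), seed=0), angles)
        assert len(train) == 712 and len(test) == 112

    def test_small_split_partition(self):
        train, test = build_dataset(10, 0.8, PhantomConfig(size_px=16),
                                    StripeSpec(seed=1), default_angles(4))
        assert len(train) == 8 and len(test) == 2
        ids = [id(r) for r in train + test]
        assert len(set(ids)) == 10  # disjoint and exhaustive

    def test_master_seed_reproduces_dataset(self):
        args = (6, 0.5, PhantomConfig(size_px=16), StripeSpec(seed=42),
                default_angles(8))
        t1, s1 = build_dataset(*args)
        t2, s2 = build_dataset(*args)
        for a, b in zip(t1 + s1, t2 + s2):
            assert np.array_equal(a.corrupted.data, b.corrupted.data)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ParameterError):
            build_dataset(4, 0.01, PhantomConfig(size_px=16),
                          StripeSpec(seed=0), default_angles(4))


class TestDegradationPsnr:
    def test_infinite_for_zero_amplitude(self):
        rec = add_stripes(_sino(), StripeSpec(amplitude_range=(0.0, 0.0), seed=0))
        assert degradation_psnr(rec) == np.inf

    def test_monotone_in_stripe_amplitude(self):
        values = []
        for a in (0.02, 0.04, 0.08, 0.16, 0.32):
            spec = StripeSpec(n_stripes_range=(8, 8), width_range_px=(1, 2),
                              amplitude_range=(a, a), partial_fraction=0.0, seed=4)
            values.append(degradation_psnr(add_stripes(_sino(), spec)))
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_delegates_to_psnr(self):
        from destripenet.recon_metrics import psnr
        rec = add_stripes(_sino(), StripeSpec(seed=6))
        assert degradation_psnr(rec) == psnr(rec.clean.data, rec.corrupted.data)


def test_hdf5_round_trip(tmp_path, small_dataset):
    train, test = small_dataset
    spec = StripeSpec(seed=3)
    path = tmp_path / "ds.h5"
    save_dataset(path, train, test, spec)
    t2, s2, spec2 = load_dataset(path)
    assert spec2 == spec
    assert len(t2) == len(train) and len(s2) == len(test)
    for a, b in zip(train + test, t2 + s2):
        np.testing.assert_allclose(a.corrupted.data, b.corrupted.data, atol=1e-6)
        np.testing.assert_allclose(a.clean.angles_deg, b.clean.angles_deg)
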