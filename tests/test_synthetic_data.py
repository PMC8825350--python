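"""Phantom rendering, Poisson dose model statistics, dataset manifests."""

import numpy as np
import pandas as pd
import pytest

from dwtpet.io_formats import ImageGrid
from dwtpet.synthetic_data import (
    DoseLevel,
    Ellipse,
    PhantomSpec,
    build_dataset,
    generate_phantom_pair,
    phantom_masks,
    sample_phantom_spec,
    simulate_dose,
)


def one_ellipse_spec():
    return PhantomSpec(
        shape=(32, 32),
        ellipses=[Ellipse(center=(15.5, 15.5), semi_axes=(8, 8), rotation_deg=0,
                          pet_activity=10.0, prior_intensity=1.0)],
        background_activity=1.0,
    )


class TestPhantomRendering:
    def test_center_and_corner_values(self):
        pet, _ = generate_phantom_pair(one_ellipse_spec(), seed=0)
        assert pet.pixels[15, 15] == 10.0
        assert pet.pixels[0, 0] == 1.0

    def test_deterministic_given_seed(self):
        spec = one_ellipse_spec()
        p1, m1 = generate_phantom_pair(spec, seed=4)
        p2, m2 = generate_phantom_pair(spec, seed=4)
        np.testing.assert_array_equal(p1.pixels, p2.pixels)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_later_ellipses_overwrite_earlier(self):
        spec = one_ellipse_spec()
        spec.ellipses.append(
            Ellipse(center=(15.5, 15.5), semi_axes=(3, 3), rotation_deg=0,
                    pet_activity=20.0, prior_intensity=0.2)
        )
        pet, _ = generate_phantom_pair(spec, seed=0)
        assert pet.pixels[15, 15] == 20.0

    def test_out_of_bounds_ellipse_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PhantomSpec(
                shape=(16, 16),
                ellipses=[Ellipse((8, 8), (12, 12), 0, 5.0, 1.0)],
                background_activity=1.0,
            )

    def test_contrast_required(self):
        with pytest.raises(ValueError, match="contrast"):
            PhantomSpec(
                shape=(32, 32),
                ellipses=[Ellipse((15, 15), (5, 5), 0, 1.0, 1.0)],
                background_activity=2.0,
            )

    def test_prior_correlates_without_duplicating_pet(self):
        """Over 20 random specs: 0 < corr(PET, prior) < 1."""
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            spec = sample_phantom_spec((64, 64), rng)
            pet, prior = generate_phantom_pair(spec, seed=s)
            r = np.corrcoef(pet.pixels.ravel(), prior.pixels.ravel())[0, 1]
            assert 0.0 < r < 1.0
            assert not np.allclose(pet.pixels, prior.pixels)


class TestSimulateDose:
    def test_high_count_limit_recovers_truth(self):
        truth = ImageGrid(np.full((64, 64), 100.0))
        out = simulate_dose(truth, DoseLevel(1.0), counts_per_unit=1e7, psf_sigma_px=0.0, seed=1)
        np.testing.assert_allclose(out.pixels, 100.0, rtol=1e-3)

    def test_poisson_mean_and_variance_scaling(self):
        truth = ImageGrid(np.full((64, 64), 100.0))
        out = simulate_dose(truth, DoseLevel(0.25), counts_per_unit=1.0, psf_sigma_px=0.0, seed=2)
        n = out.pixels.size
        se = np.sqrt(400.0 / n)
        assert abs(out.pixels.mean() - 100.0) < 3 * se
        assert abs(out.pixels.var() - 400.0) / 400.0 < 0.15
        assert out.dose_fraction == 0.25

    def test_variance_ratio_between_fractions(self):
        truth = ImageGrid(np.full((96, 96), 50.0))
        v = {}
        for i, f in enumerate((1.0, 0.25)):
            out = simulate_dose(truth, DoseLevel(f), counts_per_unit=2.0, psf_sigma_px=0.0, seed=5 + i)
            v[f] = out.pixels.var()
        assert v[0.25] / v[1.0] == pytest.approx(4.0, rel=0.15)

    def test_unbiased_over_seeds(self):
        """Mean over many realizations converges to the blurred truth (3 sigma)."""
        truth = ImageGrid(np.full((16, 16), 30.0))
        acc = np.zeros((16, 16))
        n_rep = 200
        for s in range(n_rep):
            acc += simulate_dose(truth, DoseLevel(0.5), counts_per_unit=1.0, psf_sigma_px=1.5, seed=s).pixels
        mean_img = acc / n_rep
        se = np.sqrt(30.0 / 0.5 / n_rep)  # per-pixel standard error
        inner = mean_img[4:-4, 4:-4]
        assert np.abs(inner - 30.0).max() < 4 * se
        assert abs(inner.mean() - 30.0) < 3 * se / np.sqrt(inner.size / 4)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            DoseLevel(1.2)
        with pytest.raises(ValueError):
            DoseLevel(0.0)

    def test_negative_truth_rejected(self):
        img = ImageGrid(np.zeros((8, 8)))
        img.pixels[0, 0] = -1.0  # bypass constructor validation
        with pytest.raises(ValueError, match="negative"):
            simulate_dose(img, DoseLevel(0.5), seed=0)

    def test_deterministic_given_seed(self):
        truth = ImageGrid(np.full((32, 32), 10.0))
        a = simulate_dose(truth, DoseLevel(0.5), seed=9)
        b = simulate_dose(truth, DoseLevel(0.5), seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestPhantomMasks:
    def test_masks_disjoint_and_nonempty(self):
        rng = np.random.default_rng(3)
        spec = sample_phantom_spec((64, 64), rng)
        roi, bg = phantom_masks(spec)
        assert roi.any() and bg.any()
        assert not (roi & bg).any()


class TestBuildDataset:
    def test_manifest_row_counting(self, tmp_path):
        manifest = build_dataset(
            tmp_path, n_subjects=5, dose_levels=[DoseLevel(0.25), DoseLevel(1.0)],
            shape=(32, 32), seed=1,
        )
        # per subject: truth + prior + one low-dose (fraction 1.0 is the truth)
        assert len(manifest) == 15
        counts = manifest["role"].value_counts()
        assert counts["truth"] == 5 and counts["prior"] == 5 and counts["lowdose"] == 5

    def test_same_seed_identical_manifest(self, tmp_path):
        m1 = build_dataset(tmp_path / "a", n_subjects=2, shape=(32, 32), seed=3)
        m2 = build_dataset(tmp_path / "b", n_subjects=2, shape=(32, 32), seed=3)
        c1 = m1.drop(columns=[c for c in m1.columns if "path" in c])
        c2 = m2.drop(columns=[c for c in m2.columns if "path" in c])
        pd.testing.assert_frame_equal(c1, c2)
        # and the image payloads are identical too
        t1 = np.load(tmp_path / "a" / "S000" / "roi_mask.npz")["pixels"]
        t2 = np.load(tmp_path / "b" / "S000" / "roi_mask.npz")["pixels"]
        np.testing.assert_array_equal(t1, t2)

    def test_single_subject_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_dataset(tmp_path, n_subjects=1, shape=(32, 32), seed=0)

    def test_truth_is_mean_of_lowdose(self, tiny_dataset):
        """E[low dose] = stored truth: check the spatial mean is close."""
        out, manifest = tiny_dataset
        from dwtpet.io_formats import read_image

        row = manifest[manifest["role"] == "lowdose"].iloc[0]
        low = read_image(row["path"])
        truth = read_image(row["truth_path"])
        assert low.pixels.mean() == pytest.approx(truth.pixels.mean(), rel=0.05)
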