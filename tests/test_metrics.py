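"""Metric formulas vs brute-force oracles; batch report consistency."""

import math

import numpy as np
import pytest

from dwtpet.io_formats import ImageGrid
from dwtpet.metrics import (
    MetricConfig,
    MetricsReport,
    ROISpec,
    batch_report,
    cnr,
    fraction_outside,
    nmse,
    psnr,
    rcnr,
    relative_difference_map,
    ssim_global,
)


def oracle_psnr(x, y, n):
    mse = np.mean((np.asarray(x) - np.asarray(y)) ** 2)
    return 10.0 * math.log10((2.0**n - 1.0) ** 2 / mse)


def oracle_ssim(x, y, c1=0.01, c2=0.03):
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return (2 * mx * my + c1) * (2 * cov + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def oracle_nmse(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return ((x - y) ** 2).sum() / (y**2).sum()


class TestPSNR:
    def test_identical_hits_sentinel(self, rng):
        x = rng.normal(size=(8, 8))
        assert psnr(x, x) == math.inf

    def test_peak_equals_error_is_zero_db(self):
        y = np.zeros((8, 8))
        x = np.full((8, 8), 255.0)
        assert psnr(x, y, MetricConfig(bit_depth=8)) == pytest.approx(0.0, abs=1e-12)

    def test_tenth_of_peak_is_twenty_db(self):
        y = np.zeros((8, 8))
        x = np.full((8, 8), 25.5)
        assert psnr(x, y, MetricConfig(bit_depth=8)) == pytest.approx(20.0, abs=1e-12)

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            y = rng.random((6, 6)) * 255
            x = y + rng.normal(size=(6, 6))
            assert psnr(x, y, MetricConfig(bit_depth=8)) == pytest.approx(
                oracle_psnr(x, y, 8), abs=1e-9
            )

    def test_decreases_with_noise_amplitude(self, rng):
        y = rng.random((32, 32))
        noise = rng.normal(size=(32, 32))
        vals = [psnr(y + a * noise, y) for a in (0.01, 0.05, 0.2)]
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSSIM:
    def test_self_similarity_exactly_one(self, rng):
        x = rng.normal(size=(16, 16))
        assert ssim_global(x, x) == 1.0

    def test_constant_pair_hand_value(self):
        x = np.ones((8, 8))
        y = np.zeros((8, 8))
        expected = (0.01 * 0.03) / (1.01 * 0.03)
        assert ssim_global(x, y) == pytest.approx(expected, abs=1e-12)
        assert ssim_global(x, y) == pytest.approx(0.009901, abs=1e-6)

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            x, y = rng.random((7, 9)), rng.random((7, 9))
            assert ssim_global(x, y) == pytest.approx(oracle_ssim(x, y), abs=1e-9)

    def test_symmetric(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        assert ssim_global(x, y) == pytest.approx(ssim_global(y, x), abs=1e-12)

    def test_windowed_variant_runs(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        v = ssim_global(x, y, windowed=True)
        assert -1.0 <= v <= 1.0


class TestNMSE:
    def test_identical_is_zero(self, rng):
        x = rng.random((8, 8))
        assert nmse(x, x) == 0.0

    def test_doubling_gives_one(self, rng):
        y = rng.random((8, 8)) + 0.5
        assert nmse(2 * y, y) == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(50):
            x, y = rng.random((6, 6)), rng.random((6, 6)) + 0.1
            assert nmse(x, y) == pytest.approx(oracle_nmse(x, y), abs=1e-12)

    def test_asymmetric(self, rng):
        x, y = rng.random((8, 8)) + 0.1, rng.random((8, 8)) + 0.1
        assert nmse(x, y) != pytest.approx(nmse(y, x), abs=1e-12)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.ones((4, 4)), np.zeros((4, 4)))


class TestCNR:
    def _roi(self):
        roi = np.zeros((8, 8), bool)
        bg = np.zeros((8, 8), bool)
        roi[:4] = True
        bg[4:] = True
        return ROISpec(roi, bg)

    def test_hand_value(self):
        img = np.where(self._roi().roi_mask, 2.0, 1.0)
        assert cnr(img, self._roi()) == pytest.approx(0.5, abs=1e-12)

    def test_no_contrast_is_zero(self):
        assert cnr(np.ones((8, 8)), self._roi()) == 0.0

    def test_rcnr_identity(self, rng):
        img = rng.random((8, 8)) + 1.0
        assert rcnr(img, img, self._roi()) == 1.0

    def test_zero_roi_mean_rejected(self):
        with pytest.raises(ValueError, match="ROI mean"):
            cnr(np.zeros((8, 8)), self._roi())

    def test_masks_must_be_disjoint(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            ROISpec(m, m)


class TestRelativeDifferenceMap:
    def test_identical_is_zero(self, rng):
        y = ImageGrid(rng.random((8, 8)) + 0.5)
        np.testing.assert_array_equal(relative_difference_map(y, y).pixels, 0.0)

    def test_offset_scaled_by_peak(self):
        y = ImageGrid(np.full((4, 4), 5.0))
        y.pixels[0, 0] = 10.0
        x = ImageGrid(y.pixels + 1.0)
        np.testing.assert_allclose(relative_difference_map(x, y).pixels, 0.1)

    def test_fraction_outside_threshold(self):
        y = np.full((10, 10), 10.0)
        x = y.copy()
        x[:2, :] += 2.0  # 20% of pixels at +0.2 relative
        frac = fraction_outside(relative_difference_map(x, y), 0.10)
        assert frac == pytest.approx(0.2)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            relative_difference_map(np.zeros((4, 4)), np.zeros((4, 4)))


def test_flip_invariance(rng):
    x, y = rng.random((8, 8)), rng.random((8, 8)) + 0.1
    roi = np.zeros((8, 8), bool)
    bg = np.zeros((8, 8), bool)
    roi[:3], bg[5:] = True, True
    spec = ROISpec(roi, bg)
    spec_f = ROISpec(roi[::-1], bg[::-1])
    assert psnr(x, y) == pytest.approx(psnr(x[::-1], y[::-1]), abs=1e-12)
    assert ssim_global(x, y) == pytest.approx(ssim_global(x[::-1], y[::-1]), abs=1e-12)
    assert nmse(x, y) == pytest.approx(nmse(x[::-1], y[::-1]), abs=1e-12)
    assert rcnr(x, y, spec) == pytest.approx(rcnr(x[::-1], y[::-1], spec_f), abs=1e-12)


class TestBatchReport:
    def test_truth_vs_truth_is_perfect(self, tiny_dataset):
        out, manifest = tiny_dataset
        m = manifest.copy()
        # point every low-dose row at the truth image
        m.loc[m["role"] == "lowdose", "path"] = m.loc[m["role"] == "lowdose", "truth_path"]
        report = batch_report(m)
        rows = report.rows
        assert (rows["SSIM"] == 1.0).all()
        assert (rows["NMSE"] == 0.0).all()
        assert (rows["RCNR"] == 1.0).all()
        assert np.isinf(rows["PSNR"]).all()

    def test_summary_matches_rows(self, tiny_dataset):
        out, manifest = tiny_dataset
        report = batch_report(manifest)
        ok = report.rows[report.rows["error"].isna()]
        grp = ok[ok["dose_label"] == "25%"]
        mean_psnr = grp["PSNR"].mean()
        srow = report.summary[
            (report.summary["dose_label"] == "25%") & (report.summary["variant"] == "input")
        ]
        assert srow["PSNR_mean"].iloc[0] == pytest.approx(mean_psnr, abs=1e-9)

    def test_missing_file_recorded_not_fatal(self, tiny_dataset, tmp_path):
        out, manifest = tiny_dataset
        m = manifest.copy()
        idx = m[m["role"] == "lowdose"].index[0]
        m.loc[idx, "path"] = str(tmp_path / "missing.nii")
        report = batch_report(m)
        errs = report.rows["error"].notna()
        assert errs.sum() == 1
        assert len(report.rows) == (m["role"] == "lowdose").sum()

    def test_csv_round_trip(self, tiny_dataset, tmp_path):
        import pandas as pd

        out, manifest = tiny_dataset
        report = batch_report(manifest)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        text = path.read_text()
        head = text.split("# summary")[0]
        from io import StringIO

        rows = pd.read_csv(StringIO(head))
        assert len(rows) == len(report.rows)
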