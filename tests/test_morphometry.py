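"""Speed estimators and fibre-density quantification."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vitellometrics import (
    AxisLandmarkSeries,
    FibreImage,
    InsufficientDataError,
    convergence_speed,
    elongation_speed,
    fibre_density,
    gen_fibre_image,
    gen_landmark_series,
    segmentation_speed,
)


def series_from_arrays(t, length, width, somites):
    n = t.size
    return AxisLandmarkSeries(
        time_h=t,
        somite_ref=np.zeros((n, 2)),
        post_end=np.column_stack([np.zeros(n), length]),
        pnt_left_x=-width / 2.0,
        pnt_right_x=width / 2.0,
        somite_pairs=somites,
    )


class TestSpeeds:
    def test_static_landmarks_zero_speeds(self):
        t = np.arange(0.0, 6.0, 0.5)
        s = series_from_arrays(
            t, np.full_like(t, 2000.0), np.full_like(t, 400.0), np.full_like(t, 5.0)
        )
        assert elongation_speed(s) == pytest.approx(0.0, abs=1e-12)
        assert convergence_speed(s) == pytest.approx(0.0, abs=1e-12)
        assert segmentation_speed(s) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_series(self):
        t = np.arange(0.0, 6.0, 0.5)
        s = series_from_arrays(
            t,
            2000.0 + 100.0 * t,  # elongating 100 um/h
            400.0 - 30.0 * t,  # converging 30 um/h
            4.0 + t / 1.5,  # one somite pair per 1.5 h
        )
        assert elongation_speed(s) == pytest.approx(100.0, rel=1e-12)
        assert convergence_speed(s) == pytest.approx(30.0, rel=1e-12)
        assert segmentation_speed(s) == pytest.approx(1.0 / 1.5, rel=1e-12)

    def test_widening_gives_negative_convergence(self):
        t = np.arange(0.0, 6.0, 0.5)
        s = series_from_arrays(
            t, np.full_like(t, 2000.0), 400.0 + 20.0 * t, np.full_like(t, 5.0)
        )
        assert convergence_speed(s) == pytest.approx(-20.0, rel=1e-12)

    def test_zero_noise_generator_recovery(self):
        s, truth = gen_landmark_series(
            elongation_um_h=80.0, convergence_um_h=30.0, seg_rate_per_h=0.667,
            noise_sd_um=0.0, seed=0,
        )
        assert elongation_speed(s) == pytest.approx(80.0, rel=1e-9)
        assert convergence_speed(s) == pytest.approx(30.0, rel=1e-9)
        assert segmentation_speed(s) == pytest.approx(0.667, rel=1e-9)

    def test_noisy_estimates_unbiased(self):
        """Monte-Carlo mean of each speed lands within 2 SE of truth."""
        n_rep = 60
        ests = np.array(
            [
                [elongation_speed(s), convergence_speed(s), segmentation_speed(s)]
                for s, _ in (
                    gen_landmark_series(noise_sd_um=5.0, seed=k) for k in range(n_rep)
                )
            ]
        )
        truth = np.array([80.0, 30.0, 0.667])
        se = ests.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(ests.mean(axis=0) - truth) <= 2.0 * np.maximum(se, 1e-12))

    def test_single_frame_rejected(self):
        t = np.array([0.0])
        s = series_from_arrays(t, np.array([2000.0]), np.array([400.0]), np.array([4.0]))
        with pytest.raises(InsufficientDataError):
            elongation_speed(s)

    def test_series_validation(self):
        t = np.arange(0.0, 3.0, 0.5)
        with pytest.raises(ValueError):
            series_from_arrays(
                t, np.full_like(t, 1.0), np.full_like(t, -5.0), np.full_like(t, 4.0)
            )  # negative pNT width
        with pytest.raises(ValueError):
            series_from_arrays(
                t, np.full_like(t, 1.0), np.full_like(t, 5.0),
                np.array([4, 5, 4, 5, 6, 6], dtype=float),
            )  # somite count decreasing


class TestFibreDensity:
    def test_half_white_whole_image(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        res = fibre_density(FibreImage(img), n_rois=5, roi_size=64, seed=0)
        assert res.density == pytest.approx(0.5)

    def test_near_full_coverage(self):
        img = np.ones((64, 64))
        img[0, 0] = 0.0
        res = fibre_density(FibreImage(img), n_rois=1, roi_size=64, seed=0)
        assert res.density == pytest.approx(1.0, abs=1e-3)

    def test_blank_image_degenerate(self):
        res = fibre_density(FibreImage(np.zeros((64, 64))), n_rois=3, roi_size=32)
        assert res.density == 0.0
        assert res.degenerate

    def test_zero_coverage_noiseless(self):
        image, truth = gen_fibre_image(coverage=0.0, noise_sd=0.0, size_px=128, seed=3)
        res = fibre_density(image, n_rois=4, roi_size=64, seed=0)
        assert truth["coverage_true"] == 0.0
        assert res.density == 0.0 and res.degenerate

    def test_intensity_rescaling_invariance(self):
        image, _ = gen_fibre_image(coverage=0.2, size_px=128, seed=4)
        a = fibre_density(image, n_rois=6, roi_size=64, seed=7)
        b = fibre_density(FibreImage(image.intensity * 0.4), n_rois=6, roi_size=64, seed=7)
        assert b.density == pytest.approx(a.density, abs=1e-3)

    def test_whole_image_roi_seed_invariant(self):
        image, _ = gen_fibre_image(coverage=0.15, size_px=128, seed=5)
        a = fibre_density(image, n_rois=3, roi_size=128, seed=0)
        b = fibre_density(image, n_rois=3, roi_size=128, seed=999)
        assert a.density == b.density

    def test_density_monotone_in_coverage(self):
        coverages = np.arange(0.05, 0.41, 0.05)
        densities = []
        for i, cov in enumerate(coverages):
            image, _ = gen_fibre_image(coverage=cov, size_px=256, seed=60 + i)
            res = fibre_density(image, n_rois=16, roi_size=192, seed=1)
            densities.append(res.density)
        rho, _ = spearmanr(coverages, densities)
        assert rho == 1.0

    def test_fibres_dark_polarity(self):
        image, _ = gen_fibre_image(coverage=0.2, size_px=128, seed=6)
        inverted = FibreImage(1.0 - image.intensity)
        a = fibre_density(image, n_rois=1, roi_size=128, seed=0)
        b = fibre_density(inverted, n_rois=1, roi_size=128, seed=0, fibres_dark=True)
        assert b.density == pytest.approx(a.density, abs=1e-3)

    def test_roi_larger_than_image_rejected(self):
        image, _ = gen_fibre_image(coverage=0.1, size_px=64, seed=7)
        with pytest.raises(ValueError):
            fibre_density(image, roi_size=128)
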