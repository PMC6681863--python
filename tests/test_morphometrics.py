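"""Dropout area, moment-ellipse metrics, radial profiles, and the
irregularity score."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import rotate

from meibokit.errors import (DegenerateObjectError, InsufficientReferenceError,
                             InvalidCountsError, NonStarShapedWarning,
                             OutsideROIError)
from meibokit.morphometrics import (DOAResult, IrregularityEnvelope, RadialProfile,
                                    build_envelope, compute_doa, detect_reflections,
                                    estimate_gland_region, eyelid_summary,
                                    gland_ellipse_metrics, irregularity_score,
                                    radial_profile, relative_length)
from meibokit.roi import BoundaryCurve, ROIResult
from meibokit.segmentation import label_glands
from meibokit.synthetic import generate_gland_shape


def _full_roi(shape):
    return ROIResult(mask=np.ones(shape, bool))


# ---------------------------------------------------------------------------
# dropout area


class TestGlandRegion:
    def test_empty_mask(self):
        region, n = estimate_gland_region(np.zeros((50, 50), bool), _full_roi((50, 50)))
        assert n == 0 and not region.any()

    @pytest.mark.parametrize("gap,filled", [(10, True), (100, False)])
    def test_gap_filling_matches_brute_force_closing(self, gap, filled):
        h = 200
        mask = np.zeros((h, 160 + gap), bool)
        mask[10:190, 10:30] = True
        mask[10:190, 30 + gap:50 + gap] = True
        roi = _full_roi(mask.shape)
        region, _ = estimate_gland_region(mask, roi, disk_radius=20)
        gap_center = (30 + 30 + gap) // 2
        assert region[100, gap_center] == filled
        # brute-force oracle: pad, dilate with an explicit disk, erode back
        yy, xx = np.mgrid[-20:21, -20:21]
        disk = yy**2 + xx**2 <= 20**2
        padded = np.pad(mask, 25)
        oracle = ndi.binary_erosion(ndi.binary_dilation(padded, structure=disk),
                                    structure=disk)[25:-25, 25:-25]
        np.testing.assert_array_equal(region, oracle)

    def test_closing_is_extensive_and_idempotent(self):
        rng = np.random.default_rng(21)
        mask = np.zeros((150, 150), bool)
        for _ in range(6):
            r, c = rng.integers(20, 120, 2)
            mask[r:r + rng.integers(10, 40), c:c + rng.integers(5, 15)] = True
        roi = _full_roi(mask.shape)
        region, n1 = estimate_gland_region(mask, roi)
        assert (mask & ~region).sum() == 0          # extensive
        region2, n2 = estimate_gland_region(region, roi)
        np.testing.assert_array_equal(region, region2)  # idempotent

    def test_meanfilter_alternative_is_extensive(self):
        mask = np.zeros((120, 120), bool)
        mask[20:100, 40:60] = True
        region, _ = estimate_gland_region(mask, _full_roi(mask.shape),
                                          method="meanfilter")
        assert (mask & ~region).sum() == 0


class TestReflections:
    def test_no_bright_pixels(self):
        _, n = detect_reflections(np.full((40, 40), 100), _full_roi((40, 40)))
        assert n == 0

    def test_saturated_roi(self):
        roi = _full_roi((40, 40))
        _, n = detect_reflections(np.full((40, 40), 255), roi)
        assert n == roi.area_px

    def test_threshold_is_strict(self):
        gray = np.full((10, 10), 0)
        gray[3, 3] = 200                       # exactly 200: not a reflection
        gray[5, 5] = 201
        mask, n = detect_reflections(gray, _full_roi((10, 10)))
        assert n == 1 and mask[5, 5] and not mask[3, 3]


class TestComputeDOA:
    @pytest.mark.parametrize("counts,expected", [
        ((100000, 100000, 0), 0.0),
        ((100000, 0, 0), 100.0),
        ((200000, 150000, 10000), 20.0),
    ])
    def test_formula(self, counts, expected):
        assert compute_doa(*counts).doa_percent == pytest.approx(expected)

    def test_invalid_counts(self):
        with pytest.raises(InvalidCountsError):
            compute_doa(0, 0, 0)
        with pytest.raises(InvalidCountsError):
            compute_doa(100, 90, 20)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            n_roi = int(rng.integers(1, 10**6))
            n_gl = int(rng.integers(0, n_roi + 1))
            n_r = int(rng.integers(0, n_roi - n_gl + 1))
            doa = compute_doa(n_roi, n_gl, n_r).doa_percent
            assert 0.0 <= doa <= 100.0
            if n_gl > 0:
                # removing gland pixels never decreases the DOA
                assert compute_doa(n_roi, n_gl - 1, n_r).doa_percent >= doa


# ---------------------------------------------------------------------------
# moment-ellipse metrics


class TestEllipseMetrics:
    def test_ellipse_recovers_itself(self):
        mask = np.zeros((140, 60), bool)
        rr, cc = draw_ellipse(70, 30, 50, 10)
        mask[rr, cc] = True
        g = gland_ellipse_metrics(mask, mm_per_px=0.02)
        assert g.length_px == pytest.approx(100, rel=0.02)
        assert g.width_px == pytest.approx(20, rel=0.05)
        assert g.orientation_deg == pytest.approx(90, abs=1)
        assert g.length_mm == pytest.approx(2.0, rel=0.02)

    def test_rotation_invariance_of_axes(self):
        base = np.zeros((160, 160), float)
        rr, cc = draw_ellipse(80, 80, 50, 10)
        base[rr, cc] = 1.0
        g0 = gland_ellipse_metrics(base > 0.5)
        g30 = gland_ellipse_metrics(rotate(base, 30, order=0) > 0.5)
        assert g30.length_px == pytest.approx(g0.length_px, rel=0.02)
        assert g30.width_px == pytest.approx(g0.width_px, rel=0.02)
        diff = abs(g30.orientation_deg - ((g0.orientation_deg - 30) % 180))
        assert min(diff, 180 - diff) <= 2

    def test_rectangle_moment_length(self):
        # uniform bar of length L: moment-ellipse length = 2L/sqrt(3)
        mask = np.zeros((120, 40), bool)
        mask[10:110, 10:30] = True
        g = gland_ellipse_metrics(mask)
        assert g.length_px == pytest.approx(2 * 100 / np.sqrt(3), rel=0.01)
        assert g.width_px == pytest.approx(2 * 20 / np.sqrt(3), rel=0.01)

    def test_length_ge_width_and_translation_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            h, w = rng.integers(10, 60, 2)
            mask = np.zeros((140, 140), bool)
            mask[20:20 + h, 20:20 + w] = True
            g = gland_ellipse_metrics(mask)
            assert g.length_px >= g.width_px > 0
            shifted = np.roll(np.roll(mask, 30, axis=0), 40, axis=1)
            g2 = gland_ellipse_metrics(shifted)
            assert g2.length_px == pytest.approx(g.length_px, abs=1e-9)

    def test_degenerate(self):
        with pytest.raises(DegenerateObjectError):
            gland_ellipse_metrics(np.zeros((10, 10), bool))


class TestRelativeLength:
    def _roi(self):
        upper = BoundaryCurve("quadratic", (100.0, 0.0, 1e-9), (0.0, 499.0))
        lower = BoundaryCurve("chebyshev4", (200.0, 0, 0, 0, 0), (0.0, 499.0))
        mask = np.zeros((400, 500), bool)
        mask[100:200, :] = True
        return ROIResult(mask=mask, upper=upper, lower=lower)

    def test_full_height_gland(self):
        roi = self._roi()
        from meibokit.morphometrics import GlandMetrics
        g = GlandMetrics(length_px=100.0, width_px=10, length_mm=2, width_mm=0.2,
                         orientation_deg=90, area_px=1000, centroid_xy=(250.0, 150.0))
        assert relative_length(g, roi) == pytest.approx(100.0, abs=0.01)
        g.length_px = 50.0
        assert relative_length(g, roi) == pytest.approx(50.0, abs=0.01)

    def test_outside_roi(self):
        roi = ROIResult(mask=np.zeros((50, 50), bool))
        from meibokit.morphometrics import GlandMetrics
        g = GlandMetrics(length_px=10, width_px=5, length_mm=0.2, width_mm=0.1,
                         orientation_deg=90, area_px=50, centroid_xy=(25.0, 25.0))
        with pytest.raises(OutsideROIError):
            relative_length(g, roi)


# ---------------------------------------------------------------------------
# radial profiles and irregularity


class TestRadialProfile:
    def test_circle_is_unity(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = draw_ellipse(60, 60, 45, 45)
        mask[rr, cc] = True
        prof = radial_profile(mask)
        assert prof.radii_norm.max() == pytest.approx(1.0)
        assert prof.radii_norm.min() >= 0.97

    def test_two_to_one_ellipse(self):
        mask = np.zeros((220, 120), bool)
        rr, cc = draw_ellipse(110, 60, 90, 45)
        mask[rr, cc] = True
        prof = radial_profile(mask)
        assert prof.radii_norm.min() == pytest.approx(0.5, abs=0.02)
        assert prof.radii_norm.max() == pytest.approx(1.0)

    def test_six_lobes_detected(self):
        shape = generate_gland_shape(180, 120, wave_amplitude=0.25, n_lobes=6,
                                     seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonStarShapedWarning)
            prof = radial_profile(shape)
        from scipy.signal import find_peaks
        r = prof.radii_norm
        wrapped = np.r_[r[-30:], r, r[:30]]
        peaks, _ = find_peaks(wrapped, prominence=0.05)
        peaks = peaks[(peaks >= 30) & (peaks < 390)]
        assert len(peaks) == 6

    def test_polygon_input(self):
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        poly = np.c_[50 + 20 * np.cos(theta), 50 + 20 * np.sin(theta)]
        prof = radial_profile(poly)
        assert np.allclose(prof.radii_norm, 1.0, atol=0.01)
        assert prof.mass_center[0] == pytest.approx(50, abs=0.1)

    def test_non_star_shape_warns(self):
        # a crescent: rays through the concavity cross the boundary twice
        mask = np.zeros((140, 140), bool)
        rr, cc = draw_ellipse(70, 70, 60, 60)
        mask[rr, cc] = True
        rr, cc = draw_ellipse(70, 40, 40, 40)
        mask[rr, cc] = False
        with pytest.warns(NonStarShapedWarning):
            radial_profile(mask)


class TestEnvelope:
    def _profiles(self, arrays):
        return [RadialProfile(radii_norm=a, mass_center=(0.0, 0.0)) for a in arrays]

    def test_identical_profiles_collapse(self):
        r = np.full(360, 0.9)
        env = build_envelope(self._profiles([r, r, r]))
        assert np.all(env.sd_profile == 0)
        np.testing.assert_allclose(env.mean_profile, 0.9)

    def test_sample_sd_closed_form(self):
        a = np.full(360, 0.8)
        b = a.copy()
        b[45] += 0.1
        env = build_envelope(self._profiles([a, b]))
        assert env.sd_profile[45] == pytest.approx(0.1 / np.sqrt(2))
        assert env.sd_profile[44] == 0

    def test_insufficient_reference(self):
        with pytest.raises(InsufficientReferenceError):
            build_envelope(self._profiles([np.full(360, 0.9)]))

    def test_csv_round_trip(self, tmp_path):
        env = build_envelope(self._profiles([np.full(360, 0.8),
                                             np.full(360, 0.9)]))
        path = tmp_path / "env.csv"
        env.to_csv(path)
        back = IrregularityEnvelope.from_csv(path, n_reference=2)
        np.testing.assert_allclose(back.mean_profile, env.mean_profile, atol=1e-6)
        np.testing.assert_allclose(back.sd_profile, env.sd_profile, atol=1e-6)


class TestIrregularityScore:
    def _flat_env(self, mean=0.8, sd=0.05):
        return IrregularityEnvelope(mean_profile=np.full(360, mean),
                                    sd_profile=np.full(360, sd), n_reference=10)

    def test_inside_envelope_scores_zero(self):
        env = self._flat_env()
        assert irregularity_score(np.full(360, 0.8), env) == 0.0

    def test_rectangular_protrusion(self):
        env = self._flat_env()
        prof = np.full(360, 0.8)
        prof[100:190] = 0.85 + 0.1               # 0.1 above the upper limit
        assert irregularity_score(prof, env) == pytest.approx(9.0, abs=0.1)

    def test_mixed_protrusions_match_fine_grid_oracle(self):
        env = self._flat_env()
        prof = 0.8 + 0.12 * np.sin(np.arange(360) / 17.0)
        score = irregularity_score(prof, env)
        # oracle: dense resampling + rectangle sum
        fine = np.interp(np.linspace(0, 359, 359 * 50 + 1), np.arange(360), prof)
        up = 0.85
        lo = 0.75
        excess = np.clip(fine - up, 0, None) + np.clip(lo - fine, 0, None)
        oracle = excess.sum() * (359 / (359 * 50))
        assert score == pytest.approx(oracle, rel=0.01)

    def test_monotone_in_amplitude(self):
        env = self._flat_env()
        scores = []
        for amp in (0.05, 0.1, 0.2, 0.3):
            prof = 0.8 + amp * np.sin(np.deg2rad(np.arange(360)) * 4)
            scores.append(irregularity_score(prof, env))
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_scale_and_translation_invariance_via_shapes(self, envelope):
        # same aspect ratio as the reference population, two sizes
        base = generate_gland_shape(400, 22, 0.0, seed=9)
        small = generate_gland_shape(200, 11, 0.0, seed=9)
        s_base = irregularity_score(radial_profile(base), envelope)
        s_small = irregularity_score(radial_profile(small), envelope)
        assert s_small == pytest.approx(s_base, abs=0.5)
        padded = np.pad(base, ((40, 7), (13, 29)))
        assert irregularity_score(radial_profile(padded), envelope) \
            == pytest.approx(s_base, abs=1e-9)


# ---------------------------------------------------------------------------
# eyelid summary


class TestEyelidSummary:
    def test_zero_glands_still_reports_doa(self, envelope):
        roi = _full_roi((120, 120))
        report = eyelid_summary(label_glands(np.zeros((120, 120), bool)), roi,
                                np.full((120, 120), 90), envelope)
        assert report.n_glands == 0
        assert report.doa.doa_percent == pytest.approx(100.0)
        assert report.mean_length_mm is None
        assert report.eyelid_irregularity is None

    def test_single_gland_means_equal_gland(self, envelope):
        mask = np.zeros((300, 200), bool)
        mask[20:280, 90:110] = True
        roi = _full_roi(mask.shape)
        report = eyelid_summary(label_glands(mask), roi,
                                np.where(mask, 160, 90), envelope)
        assert report.n_glands == 1
        g = report.per_gland[0]
        assert report.mean_length_mm == g.length_mm
        assert report.mean_width_mm == g.width_mm
        assert report.eyelid_irregularity is not None

    def test_reflections_not_double_counted(self, envelope):
        # a reflection inside the gland region must not inflate N_pxGL
        mask = np.zeros((300, 200), bool)
        mask[20:280, 90:110] = True
        gray = np.where(mask, 160, 90)
        gray[100:110, 95:105] = 250
        roi = _full_roi(mask.shape)
        report = eyelid_summary(label_glands(mask), roi, gray, envelope)
        assert report.doa.n_px_gl + report.doa.n_px_r <= report.doa.n_px_roi
        assert report.doa.n_px_r == 100
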