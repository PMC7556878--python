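"""Vessel geometry: FWHM widths, TiRS areas, trace conditioning."""

import math

import numpy as np
import pytest

from vasopipe import synth
from vasopipe.diameter import (
    DiameterTrace,
    despike_trace,
    equivalent_diameter,
    fwhm_diameter_trace,
    fwhm_profile_width,
    median_filter_trace,
    tirs_area,
)
from vasopipe.errors import (
    EdgeTruncationError,
    InvalidParameterError,
    NoVesselError,
)


def box_profile(width_px: int, n: int = 64, amplitude: float = 100.0) -> np.ndarray:
    p = np.zeros(n)
    start = (n - width_px) // 2
    p[start : start + width_px] = amplitude
    return p


def dense_fwhm(f, lo: float, hi: float, n: int = 200001) -> float:
    """Brute-force FWHM of a callable profile on a dense grid."""
    x = np.linspace(lo, hi, n)
    y = f(x)
    level = 0.5 * y.max()
    above = np.where(y >= level)[0]
    return x[above[-1]] - x[above[0]]


class TestFwhmProfileWidth:
    def test_box_profile_exact(self):
        assert fwhm_profile_width(box_profile(10), pixel_size=0.5) == pytest.approx(5.0)

    @pytest.mark.parametrize("sigma", [2.0, 4.0, 8.0])
    def test_gaussian_profile_analytic(self, sigma):
        n = int(16 * sigma)
        x = np.arange(n)
        mu = float(n // 2)  # grid-centered: no peak-sampling offset
        profile = 100.0 * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma
        brute = dense_fwhm(
            lambda u: np.exp(-0.5 * ((u - mu) / sigma) ** 2), x[0], x[-1]
        )
        assert brute == pytest.approx(expected, abs=1e-2)
        assert fwhm_profile_width(profile, 1.0) == pytest.approx(expected, abs=0.1)

    def test_all_zero_profile_raises(self):
        with pytest.raises(NoVesselError):
            fwhm_profile_width(np.zeros(64), 1.0)

    def test_edge_truncated_profile_raises(self):
        # vessel flush against the profile edge: left crossing missing
        p = np.zeros(64)
        p[:5] = 100.0
        with pytest.raises(EdgeTruncationError):
            fwhm_profile_width(p, 1.0)

    def test_side_lobe_ignored(self):
        # a dimmer neighboring vessel must not widen the measurement
        p = box_profile(10) + 0.6 * np.roll(box_profile(8), 24)
        assert fwhm_profile_width(p, 1.0) == pytest.approx(10.0, abs=0.5)

    def test_monotone_in_width(self):
        widths = [4, 8, 12, 20, 30]
        measured = [fwhm_profile_width(box_profile(w, n=128), 1.0) for w in widths]
        assert np.all(np.diff(measured) > 0)


class TestFwhmDiameterTrace:
    def test_ground_truth_recovery(self, pial_movie):
        trace = fwhm_diameter_trace(pial_movie)
        assert np.nanmean(trace.values) == pytest.approx(20.0, rel=0.02)

    def test_blank_frame_flagged_missing(self):
        movie = synth.make_pial_movie(np.full(4, 20.0), snr=float("inf"), seed=0)
        movie.frames[2] = 0.0
        trace = fwhm_diameter_trace(movie)
        assert np.isnan(trace.values[2])
        assert np.all(np.isfinite(np.delete(trace.values, 2)))

    def test_segment_length_clamped_with_warning(self, pial_movie, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="vasopipe.diameter"):
            trace = fwhm_diameter_trace(pial_movie, segment_length=10.0)
        assert "clamping" in caplog.text
        assert np.nanmean(trace.values) == pytest.approx(20.0, rel=0.02)


class TestTirsArea:
    def test_binary_disk(self):
        n, r = 64, 10
        yy, xx = np.mgrid[0:n, 0:n]
        disk = (((xx - n // 2) ** 2 + (yy - n // 2) ** 2) <= r * r) * 100.0
        m = tirs_area(disk)
        assert m.area == pytest.approx(math.pi * r * r, rel=0.05)
        assert m.method == "tirs"
        assert m.diameter == pytest.approx(equivalent_diameter(m.area))

    @pytest.mark.parametrize("phi", [0.0, 45.0, 120.0])
    def test_ellipse_any_rotation(self, phi):
        movie = synth.make_penetrating_movie(
            np.array([[10.0, 5.0, phi]]), snr=float("inf"), psf_sigma_px=0.0,
        )
        m = tirs_area(movie.frames[0], roi=movie.roi, pixel_size=1.0)
        assert m.area == pytest.approx(50.0 * math.pi, rel=0.05)

    def test_rotation_spread_small(self):
        areas = []
        for phi in np.linspace(0, 150, 6):
            movie = synth.make_penetrating_movie(
                np.array([[10.0, 5.0, phi]]), snr=float("inf"), psf_sigma_px=0.0,
            )
            areas.append(tirs_area(movie.frames[0], pixel_size=1.0).area)
        spread = (max(areas) - min(areas)) / (50.0 * math.pi)
        assert spread < 0.03

    def test_zero_roi_raises(self):
        with pytest.raises(NoVesselError):
            tirs_area(np.zeros((64, 64)))

    def test_circle_consistency_fwhm_vs_tirs(self):
        # for a circular lumen the two measurement families must agree
        movie = synth.make_penetrating_movie(
            np.array([[10.0, 10.0, 0.0]]), pixel_size=1.0, snr=float("inf"),
        )
        frame = movie.frames[0]
        tirs_d = tirs_area(frame, pixel_size=1.0).diameter
        profile = frame[32, :]
        fwhm_d = fwhm_profile_width(profile, pixel_size=1.0)
        assert tirs_d == pytest.approx(fwhm_d, rel=0.05)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("area,expected", [
        (math.pi, 2.0),
        (100.0 * math.pi, 20.0),
        (0.0, 0.0),
    ])
    def test_values(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            equivalent_diameter(-1.0)


class TestDespike:
    def test_hand_computed_example(self):
        # a 3 um jump in one 8 Hz frame is 24 um/s > 16 um/s
        trace = DiameterTrace(values=[20.0, 20.0, 23.0, 20.0], frame_rate=8.0)
        out = despike_trace(trace)
        assert out.values[2] == pytest.approx(20.0)
        assert out.despiked_mask[2]

    def test_smooth_sinusoid_unchanged(self):
        t = np.arange(200) / 8.0
        values = 20.0 + 2.0 * np.sin(2 * math.pi * 0.1 * t)
        out = despike_trace(DiameterTrace(values=values, frame_rate=8.0))
        np.testing.assert_allclose(out.values, values)
        assert not out.despiked_mask.any()

    def test_two_consecutive_spikes_share_gap(self):
        values = np.array([20.0, 26.0, 26.5, 20.0, 20.0])
        out = despike_trace(DiameterTrace(values=values, frame_rate=8.0))
        # both spike frames interpolate between the surrounding good frames
        assert out.values[1] == pytest.approx(20.0)
        assert out.values[2] == pytest.approx(20.0)
        assert list(out.despiked_mask) == [False, True, True, False, False]

    def test_end_spike_nearest_value(self):
        values = np.array([20.0, 20.0, 20.0, 28.0])
        out = despike_trace(DiameterTrace(values=values, frame_rate=8.0))
        assert out.values[-1] == pytest.approx(20.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        values = 20.0 + 0.2 * rng.normal(size=100)
        values[30] += 5.0
        once = despike_trace(DiameterTrace(values=values, frame_rate=8.0))
        twice = despike_trace(once)
        np.testing.assert_allclose(twice.values, once.values)


class TestMedianFilter:
    @pytest.mark.parametrize("values,expected", [
        ([5.0] * 7, [5.0] * 7),
        ([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0]),
    ])
    def test_reference_cases(self, values, expected):
        out = median_filter_trace(DiameterTrace(values=values, frame_rate=8.0))
        np.testing.assert_allclose(out.values, expected)

    def test_impulse_removed(self):
        values = np.full(21, 10.0)
        values[10] = 50.0
        out = median_filter_trace(DiameterTrace(values=values, frame_rate=8.0))
        np.testing.assert_allclose(out.values, 10.0)

    def test_idempotent_on_piecewise_constant(self):
        values = np.repeat([10.0, 14.0, 12.0], 10)
        once = median_filter_trace(DiameterTrace(values=values, frame_rate=8.0))
        twice = median_filter_trace(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_even_order_rejected(self):
        with pytest.raises(InvalidParameterError):
            median_filter_trace(DiameterTrace(values=np.ones(10), frame_rate=8.0), order=4)
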