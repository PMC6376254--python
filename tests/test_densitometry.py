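"""Profiles, baselines, peak detection, area integration, MW calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kospec.densitometry import (
    DensitometryError,
    LaneProfile,
    calibrate_ladder,
    detect_peaks,
    estimate_baseline,
    extract_lane_profile,
    integrate_peak,
)
from kospec.pipeline import quantify_lane
from kospec.simulate import blot_spec_from_fractions, render_blot

from conftest import gaussian

GAUSS_AREA = 100.0 * 4.0 * math.sqrt(2.0 * math.pi)  # amp 100, sigma 4


# --- lane profiles ---------------------------------------------------------


def test_profile_of_constant_image_is_constant():
    image = np.full((50, 60), 7.5)
    prof = extract_lane_profile(image, x_center=30)
    assert np.allclose(prof.values, 7.5)
    assert len(prof) == 50


def test_profile_is_mean_over_sampling_width():
    # one column at 20, nineteen at 0 -> mean 1.0 at every row
    image = np.zeros((30, 20))
    image[:, 5] = 20.0
    prof = extract_lane_profile(image, x_center=10, width_px=20)
    assert np.allclose(prof.values, 1.0)


def test_profile_out_of_bounds_names_lane():
    image = np.zeros((30, 25))
    with pytest.raises(DensitometryError, match="laneX"):
        extract_lane_profile(image, x_center=20, width_px=20, lane_id="laneX")


def test_profile_invert_makes_dark_bands_maxima():
    image = np.full((100, 30), 200.0)
    image[40:45, :] = 50.0  # dark band
    prof = extract_lane_profile(image, x_center=15, invert=True)
    assert prof.values.argmax() in range(40, 45)


def test_rendered_band_profile_matches_generator(gaussian_lane):
    spec = blot_spec_from_fractions(1.0, 0.0, snr=None, seed=0,
                                    background=((0.0,),))
    image, truth = render_blot(spec)
    row = truth.iloc[0]
    prof = extract_lane_profile(image, spec.lane_centers[0])
    assert abs(prof.values.max() - row.amplitude) / row.amplitude < 0.005
    assert abs(prof.values.argmax() - row.row) <= 1


# --- baseline --------------------------------------------------------------


def test_baseline_without_peaks_equals_profile():
    ramp = LaneProfile(values=0.5 * np.arange(200.0))
    base = estimate_baseline(ramp, [])
    assert np.allclose(base.values, ramp.values)


def test_baseline_under_gaussian_on_zero_background_is_near_zero(gaussian_lane):
    base = estimate_baseline(gaussian_lane, [(130, 170)])
    assert np.all(np.abs(base.values[130:170]) < 1.0)  # < 1% of amplitude


def test_baseline_never_exceeds_profile_at_anchors(gaussian_lane):
    base = estimate_baseline(gaussian_lane, [(130, 170)])
    assert np.all(base.anchor_values <= gaussian_lane.values[base.anchor_rows] + 1e-12)


def test_baseline_full_span_region_falls_back_with_warning():
    prof = LaneProfile(values=gaussian(100, 50.0, 50.0, 20.0) + 5.0)
    with pytest.warns(UserWarning, match="entire profile"):
        base = estimate_baseline(prof, [(0, 100)])
    assert np.allclose(base.values, prof.values.min())


def test_corrected_area_of_gaussian_on_ramp_within_2pct():
    n = 300
    values = gaussian(n, 100.0, 150.0, 4.0) + 0.1 * np.arange(n)
    prof = LaneProfile(values=values)
    region = (135, 166)
    base = estimate_baseline(prof, [region])
    area = integrate_peak(prof, base, region)
    assert abs(area - GAUSS_AREA) / GAUSS_AREA < 0.02


# --- peak detection --------------------------------------------------------


def test_detect_on_flat_profile_returns_empty():
    assert detect_peaks(LaneProfile(values=np.full(100, 3.0))) == []


def test_detect_two_gaussians_and_prominence_threshold():
    values = gaussian(400, 100.0, 120.0, 4.0) + gaussian(400, 50.0, 280.0, 4.0)
    prof = LaneProfile(values=values)
    peaks = detect_peaks(prof, min_prominence=0.1)
    assert len(peaks) == 2
    assert abs(peaks[0].apex - 120) <= 1 and abs(peaks[1].apex - 280) <= 1
    # at 60% of max only the large band clears the threshold
    peaks_hi = detect_peaks(prof, min_prominence=0.6)
    assert len(peaks_hi) == 1 and abs(peaks_hi[0].apex - 120) <= 1


def test_detected_regions_are_sorted_and_disjoint():
    values = gaussian(400, 80.0, 100.0, 6.0) + gaussian(400, 60.0, 150.0, 6.0)
    peaks = detect_peaks(LaneProfile(values=values), min_prominence=0.05)
    assert len(peaks) == 2
    assert peaks[0].end <= peaks[1].start


# --- integration -----------------------------------------------------------


def test_integral_is_zero_when_profile_equals_baseline():
    prof = LaneProfile(values=np.linspace(0, 10, 50))
    base = estimate_baseline(prof, [])
    assert integrate_peak(prof, base, (10, 40)) == 0.0


def test_rectangle_integrates_to_height_times_width():
    values = np.zeros(60)
    values[20:30] = 7.0  # height 7 over 10 rows
    prof = LaneProfile(values=values)
    assert integrate_peak(prof, None, (20, 30)) == pytest.approx(70.0)


def test_integral_matches_riemann_sum_oracle(gaussian_lane):
    base = estimate_baseline(gaussian_lane, [(130, 170)])
    region = (130, 170)
    oracle = float(
        np.clip(gaussian_lane.values - base.values, 0, None)[region[0]:region[1]].sum()
    )
    area = integrate_peak(gaussian_lane, base, region)
    assert abs(area - oracle) <= 1e-9 * max(oracle, 1.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(offset=st.floats(min_value=0.0, max_value=80.0))
def test_corrected_area_invariant_under_constant_offset(offset):
    """Adding a constant to the whole profile leaves corrected areas alone."""
    values = gaussian(300, 100.0, 150.0, 4.0)
    region = (130, 170)

    def corrected_area(vals):
        prof = LaneProfile(values=vals)
        base = estimate_baseline(prof, [region])
        return integrate_peak(prof, base, region)

    a0 = corrected_area(values)
    a1 = corrected_area(values + offset)
    assert abs(a1 - a0) / a0 < 0.01


# --- ladder calibration ----------------------------------------------------


def test_log_linear_interpolation_closed_form(two_anchor_calibration):
    # halfway in rows is the geometric mean of the anchor MWs: 50/sqrt(2)
    assert two_anchor_calibration.mw_of(150) == pytest.approx(50.0 / math.sqrt(2.0))


def test_calibration_round_trips_exactly_on_log_linear_anchors(two_anchor_calibration):
    assert two_anchor_calibration.mw_of(two_anchor_calibration.row_of(25.0)) == pytest.approx(25.0)


def test_calibration_rejects_single_anchor_and_non_monotonic():
    with pytest.raises(DensitometryError):
        calibrate_ladder([(100, 50.0)])
    with pytest.raises(DensitometryError, match="monotonic"):
        calibrate_ladder([(100, 25.0), (200, 50.0)])


def test_quantified_lane_recovers_true_areas_noiseless():
    spec = blot_spec_from_fractions(0.7, 0.0, snr=None, seed=0)
    image, truth = render_blot(spec)
    lane = quantify_lane(image, spec.lane_centers[0], spec.calibration())
    got = sorted(p.area for p in lane.quantification.peaks)
    want = sorted(truth[truth.lane_id == "control"].true_area)
    assert np.allclose(got, want, rtol=0.01)
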