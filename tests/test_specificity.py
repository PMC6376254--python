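"""Band-of-interest identification, the specificity index, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kospec.densitometry import Peak
from kospec.pipeline import WBThresholds, analyze_antibody_blot
from kospec.simulate import TARGET_MW_KDA, blot_spec_from_fractions
from kospec.specificity import (
    FLAG_EMPTY_KO_LANE,
    FLAG_NO_BAND,
    FLAG_NO_DISAPPEARING_BAND,
    AmbiguousBandError,
    LaneQuantification,
    SpecificityError,
    SpecificityResult,
    identify_band_of_interest,
    rank_antibodies,
    specificity_index,
    undefined_result,
)


def peak(mw, area, start=0):
    width = 10
    return Peak(start=start, end=start + width, apex=start + width // 2,
                area=float(area), mw_kda=float(mw))


def lane(condition, peaks, lane_id="L"):
    return LaneQuantification(lane_id=lane_id, condition=condition, peaks=tuple(peaks))


class TestIdentifyBandOfInterest:
    def test_band_that_disappears_in_ko_is_selected(self):
        control = lane("control", [peak(25, 80, 0), peak(50, 20, 50)])
        ko = lane("ko", [peak(50, 20, 50)])
        c, k = identify_band_of_interest(control, ko, 25.0)
        assert c.peak_of_interest is not None
        assert c.peak_of_interest.mw_kda == 25
        assert k.peak_of_interest is None

    def test_identical_lanes_are_flagged_not_matched(self):
        peaks = [peak(25, 80, 0), peak(50, 20, 50)]
        c, k = identify_band_of_interest(lane("control", peaks), lane("ko", peaks), 25.0)
        assert c.peak_of_interest is None
        assert FLAG_NO_DISAPPEARING_BAND in c.flags

    def test_diminished_band_qualifies_at_60pct_reduction(self):
        control = lane("control", [peak(25, 100, 0)])
        ko = lane("ko", [peak(25, 40, 0)])
        c, k = identify_band_of_interest(control, ko, 25.0, min_reduction=0.5)
        assert c.peak_of_interest is not None
        assert k.peak_of_interest is not None and k.peak_of_interest.area == 40

    def test_no_band_at_target_size_is_flagged(self):
        control = lane("control", [peak(50, 100, 0)])
        c, _ = identify_band_of_interest(control, lane("ko", []), 25.0)
        assert c.peak_of_interest is None
        assert FLAG_NO_BAND in c.flags

    def test_equally_close_candidates_raise(self):
        control = lane("control", [peak(24, 50, 0), peak(26, 50, 50)])
        with pytest.raises(AmbiguousBandError):
            identify_band_of_interest(control, lane("ko", []), 25.0)

    def test_mw_window_none_disables_loss_gate(self):
        peaks = [peak(25, 80, 0), peak(50, 20, 50)]
        c, k = identify_band_of_interest(
            lane("control", peaks), lane("ko", peaks), 25.0, min_reduction=None
        )
        assert c.peak_of_interest is not None and k.peak_of_interest is not None


class TestSpecificityIndex:
    def test_fraction_arithmetic(self):
        control = lane("control", [peak(25, 80, 0), peak(50, 20, 50)])
        ko = lane("ko", [peak(50, 20, 50)])
        c, k = identify_band_of_interest(control, ko, 25.0)
        r = specificity_index(c, k, "ab")
        assert r.fraction_control == pytest.approx(0.8)
        assert r.fraction_ko == 0.0
        assert r.index == pytest.approx(0.8)

    def test_single_fully_specific_band_scores_one(self):
        control = lane("control", [peak(25, 100, 0)])
        c, k = identify_band_of_interest(control, lane("ko", []), 25.0)
        r = specificity_index(c, k)
        assert r.index == 1.0
        assert FLAG_EMPTY_KO_LANE in r.flags

    def test_identical_lanes_with_forced_match_score_zero(self):
        peaks = [peak(25, 80, 0), peak(50, 20, 50)]
        c, k = identify_band_of_interest(
            lane("control", peaks), lane("ko", peaks), 25.0, min_reduction=None
        )
        assert specificity_index(c, k).index == 0.0

    def test_empty_control_lane_and_unset_poi_raise(self):
        with pytest.raises(SpecificityError, match="peak_of_interest"):
            specificity_index(lane("control", [peak(25, 10, 0)]), lane("ko", []))
        zero = lane("control", [peak(25, 0, 0)])
        c, k = identify_band_of_interest(zero, lane("ko", []), 25.0)
        with pytest.raises(SpecificityError, match="empty control"):
            specificity_index(c, k)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a_poi=st.floats(min_value=0.0, max_value=1e3),
        a_ns=st.floats(min_value=1e-3, max_value=1e3),
        k_poi=st.floats(min_value=0.0, max_value=1e3),
        k_ns=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_index_always_within_bounds(self, a_poi, a_ns, k_poi, k_ns):
        control = lane("control", [peak(25, a_poi, 0), peak(50, a_ns, 50)])
        ko = lane("ko", [peak(25, k_poi, 0), peak(50, k_ns, 50)])
        c, k = identify_band_of_interest(control, ko, 25.0, min_reduction=None)
        r = specificity_index(c, k)
        assert -1.0 <= r.index <= 1.0

    @pytest.mark.parametrize("scale", [0.5, 3.0, 10.0])
    def test_index_invariant_under_intensity_rescaling(self, scale):
        """Multiplying both lanes' intensities by k > 0 leaves the index alone."""
        from kospec.simulate.blot import render_blot
        from kospec.pipeline import analyze_antibody_image

        spec = blot_spec_from_fractions(0.7, 0.1, snr=None, seed=2)
        image, _ = render_blot(spec)
        kwargs = dict(
            control_x=spec.lane_centers[0], ko_x=spec.lane_centers[1],
            calibration=spec.calibration(), target_mw=TARGET_MW_KDA,
        )
        r1 = analyze_antibody_image(image, **kwargs).result
        r2 = analyze_antibody_image(image * scale, **kwargs).result
        assert r2.index == pytest.approx(r1.index, abs=1e-6)

    def test_more_nonspecific_signal_strictly_lowers_index(self):
        indices = []
        for f_c in (0.8, 0.6, 0.4):  # growing non-specific share in control
            spec = blot_spec_from_fractions(f_c, 0.0, snr=None, seed=4)
            r = analyze_antibody_blot(spec, TARGET_MW_KDA,
                                      thresholds=WBThresholds(min_reduction=None)).result
            indices.append(r.index)
        assert indices[0] > indices[1] > indices[2]


class TestRanking:
    def r(self, ab, idx):
        return SpecificityResult(ab, 0.5, 0.0, idx) if idx is not None else \
            undefined_result(ab, (FLAG_NO_BAND,))

    def test_sorted_descending_by_index(self):
        entries = rank_antibodies([self.r("A", 0.8), self.r("B", 0.3), self.r("C", 0.5)])
        assert [e.result.antibody_id for e in entries] == ["A", "C", "B"]
        assert [e.rank for e in entries] == [1, 2, 3]

    def test_single_result_ranks_first(self):
        entries = rank_antibodies([self.r("only", 0.4)])
        assert len(entries) == 1 and entries[0].rank == 1

    def test_undefined_index_listed_last_with_flags(self):
        entries = rank_antibodies([self.r("A", None), self.r("B", 0.2)])
        assert entries[-1].result.antibody_id == "A"
        assert FLAG_NO_BAND in entries[-1].result.flags

    def test_ties_preserve_input_order_and_are_marked(self):
        entries = rank_antibodies([self.r("A", 0.5), self.r("B", 0.5), self.r("C", 0.1)])
        assert [e.result.antibody_id for e in entries] == ["A", "B", "C"]
        assert entries[0].tied and entries[1].tied and not entries[2].tied

    def test_empty_input_raises(self):
        with pytest.raises(SpecificityError):
            rank_antibodies([])
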