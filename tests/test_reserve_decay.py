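"""Two-phase follicle-decline model: calibration, closed form, RK4."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ovreserve import (
    CalibrationError,
    DomainError,
    ParameterError,
    age_at_count,
    calibrate_decay,
    decline_rate,
    integrate_rk4,
    oocyte_count,
    time_to_threshold,
)

# independently computed (40-digit arithmetic) from the published anchors
K1_EXPECTED = 0.09010587373456429
K2_EXPECTED = 0.22991970177630005
N27_EXPECTED = 61555.21409569593


class TestCalibration:
    def test_rates_from_published_anchors(self, decay):
        assert decay.k1 == pytest.approx(K1_EXPECTED, rel=1e-12)
        assert decay.k2 == pytest.approx(K2_EXPECTED, rel=1e-12)

    def test_passes_through_all_three_anchors(self, decay):
        assert oocyte_count(0.0, decay) == pytest.approx(701_200, rel=1e-12)
        assert oocyte_count(37.0, decay) == pytest.approx(25_000, rel=1e-12)
        assert oocyte_count(51.0, decay) == pytest.approx(1_000, rel=1e-9)

    @pytest.mark.parametrize(
        "anchors",
        [
            (25_000, 701_200, 37, 1_000, 51),  # n_break > n0
            (701_200, 25_000, 37, 30_000, 51),  # n_menopause > n_break
            (701_200, 25_000, 51, 1_000, 37),  # ages out of order
            (701_200, -5, 37, 1_000, 51),  # non-positive count
        ],
    )
    def test_bad_anchors_raise(self, anchors):
        with pytest.raises(CalibrationError):
            calibrate_decay(*anchors)


class TestDeclineRate:
    def test_first_phase_rate(self, decay):
        assert decline_rate(701_200, decay) == pytest.approx(
            -K1_EXPECTED * 701_200, rel=1e-12
        )

    def test_second_phase_rate(self, decay):
        assert decline_rate(1_000, decay) == pytest.approx(
            -K2_EXPECTED * 1_000, rel=1e-12
        )

    def test_boundary_count_uses_accelerated_phase(self, decay):
        assert decline_rate(25_000, decay) == pytest.approx(
            -K2_EXPECTED * 25_000, rel=1e-12
        )

    def test_nonpositive_count_raises(self, decay):
        with pytest.raises(DomainError):
            decline_rate(0.0, decay)


class TestClosedForm:
    def test_count_at_27(self, decay):
        assert oocyte_count(27.0, decay) == pytest.approx(N27_EXPECTED, rel=1e-12)

    def test_negative_age_raises(self, decay):
        with pytest.raises(DomainError):
            oocyte_count(-1.0, decay)

    def test_continuous_at_phase_break(self, decay):
        eps = 1e-9
        below = oocyte_count(decay.age_break - eps, decay)
        above = oocyte_count(decay.age_break + eps, decay)
        assert below == pytest.approx(above, rel=1e-6)

    @given(
        st.tuples(
            st.floats(min_value=0.0, max_value=60.0),
            st.floats(min_value=1e-6, max_value=60.0),
        )
    )
    def test_strictly_decreasing(self, decay, pair):
        a, delta = pair
        assert oocyte_count(a + delta, decay) < oocyte_count(a, decay)

    @pytest.mark.parametrize(
        "count, expected_age",
        [(1_000, 51.0), (701_200, 0.0), (25_000, 37.0)],
    )
    def test_inverse_at_anchors(self, decay, count, expected_age):
        assert age_at_count(count, decay) == pytest.approx(expected_age, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=51.0))
    def test_inverse_round_trip(self, decay, age):
        assert age_at_count(oocyte_count(age, decay), decay) == pytest.approx(
            age, abs=1e-9
        )

    @pytest.mark.parametrize("count", [0.0, -10.0, 800_000.0])
    def test_inverse_domain(self, decay, count):
        with pytest.raises(DomainError):
            age_at_count(count, decay)

    def test_time_to_threshold_matches_age_arithmetic(self, decay):
        # a pool of N behaves like an unirradiated pool at age_at_count(N)
        assert time_to_threshold(25_000, decay) == pytest.approx(14.0, abs=1e-9)
        assert time_to_threshold(500.0, decay) == 0.0


class TestRK4:
    def test_zero_length_integration(self, decay):
        tr = integrate_rk4(701_200, 0.0, 0.0, 0.5, decay)
        assert len(tr) == 1
        assert tr.final_count() == 701_200

    def test_reaches_menopause_threshold(self, decay):
        tr = integrate_rk4(701_200, 0.0, 51.0, 0.01, decay)
        assert tr.final_count() == pytest.approx(1_000, rel=1e-6)

    def test_matches_closed_form_everywhere(self, decay):
        tr = integrate_rk4(701_200, 0.0, 51.0, 0.01, decay)
        exact = oocyte_count(tr.ages, decay)
        assert np.max(np.abs(tr.counts - exact) / exact) < 1e-6

    def test_fourth_order_convergence(self, decay):
        # halving the step should shrink the max error ~16x (before roundoff)
        errs = []
        for h in (0.5, 0.25, 0.125):
            tr = integrate_rk4(701_200, 0.0, 51.0, h, decay)
            errs.append(np.max(np.abs(tr.counts - oocyte_count(tr.ages, decay))))
        for coarse, fine in zip(errs, errs[1:]):
            assert 10.0 < coarse / fine < 24.0

    def test_start_below_phase_break(self, decay):
        # an irradiated pool below 25,000 decays at k2 from the start
        tr = integrate_rk4(10_000, 30.0, 35.0, 0.01, decay)
        expected = 10_000 * np.exp(-decay.k2 * 5.0)
        assert tr.final_count() == pytest.approx(expected, rel=1e-9)

    def test_count_at_27_by_integration(self, decay):
        tr = integrate_rk4(701_200, 0.0, 27.0, 0.01, decay)
        assert tr.final_count() == pytest.approx(N27_EXPECTED, rel=1e-6)

    @pytest.mark.parametrize("step", [0.0, -0.1])
    def test_bad_step_raises(self, decay, step):
        with pytest.raises(ParameterError):
            integrate_rk4(701_200, 0.0, 51.0, step, decay)

    def test_trajectory_monotone(self, decay):
        tr = integrate_rk4(701_200, 0.0, 51.0, 0.25, decay)
        assert np.all(np.diff(tr.ages) > 0)
        assert np.all(np.diff(tr.counts) < 0)
        assert np.all(tr.counts > 0)
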