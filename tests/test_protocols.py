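"""Protocol construction, recruitment splitting, fatigue."""

import numpy as np
import pytest

from musclesim.protocols import (ExhaustionError, FatigueModel, FiberLoad,
                                 RecruitmentModel, apply_fatigue,
                                 continuous_protocol, exhaustion_time,
                                 interval_protocol, ramp_protocol, recruit,
                                 type2_onset_time)

REC = RecruitmentModel()


class TestRecruitment:
    def test_zero_power_recruits_nothing(self):
        assert recruit(0.0, REC) == (0.0, 0.0)

    def test_type_ii_onset_at_24_percent_of_wmax(self):
        W_on = 0.24 * 250.0
        w1, w2 = recruit(W_on, REC)
        assert (w1, w2) == (pytest.approx(60.0), 0.0)
        assert recruit(W_on + 1e-6, REC)[1] > 0.0

    def test_full_recruitment_splits_at_caps(self):
        assert recruit(250.0, REC) == (pytest.approx(125.0),
                                       pytest.approx(125.0))

    @pytest.mark.parametrize("W", np.linspace(0, 250, 11).tolist())
    def test_split_sums_to_total_and_is_monotone(self, W):
        w1, w2 = recruit(W, REC)
        assert w1 + w2 == pytest.approx(W)
        if W > 0:
            p1, p2 = recruit(W - 1e-6, REC)
            assert w1 >= p1 - 1e-9
            assert w2 >= p2 - 1e-9

    def test_supramaximal_power_raises_without_flag(self):
        with pytest.raises(ExhaustionError):
            recruit(500.0, REC)

    def test_supramaximal_split_caps_type_i(self):
        assert REC.split(500.0, supramaximal=True) == (125.0, 375.0)


class TestRampProtocol:
    def test_power_is_zero_before_onset(self):
        p = ramp_protocol(10.0, t_start=5.0, recruitment=REC)
        assert p(4.9) == 0.0

    def test_default_slope_reaches_type_ii_onset_at_minute_six(self):
        p = ramp_protocol(10.0, t_start=0.0, recruitment=REC)
        assert type2_onset_time(p, REC) == pytest.approx(6.0, abs=1e-6)

    def test_exhaustion_fires_at_full_recruitment(self):
        p = ramp_protocol(10.0, t_start=0.0, recruitment=REC)
        t_exh = exhaustion_time(p, REC)
        assert t_exh == pytest.approx(25.0, abs=2e-3)
        assert p(t_exh) == pytest.approx(250.0, abs=0.05)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            ramp_protocol(0.0)


class TestIntervalProtocol:
    def test_16_32_pattern_has_period_48s_and_duty_one_third(self):
        p = interval_protocol(16, 32, 6, 250.0)
        period = 48.0 / 60.0
        ts = np.linspace(0, p.t_end, 2000)
        on = np.array([p(t) > 0 for t in ts])
        assert p.t_end == pytest.approx(6 * period - 32.0 / 60.0)
        assert on.mean() == pytest.approx(6 * (16 / 60) / p.t_end, abs=0.02)

    def test_single_bout_is_one_pulse(self):
        p = interval_protocol(30, 20, 1, 500.0)
        assert p(0.25) == 500.0
        assert p.t_end == pytest.approx(0.5)
        assert p(0.6) == 0.0

    def test_high_intensity_30_20_pattern_with_supramaximal_split(self):
        # 30 s work / 20 s recovery bouts at a constant 500 W per bout
        p = interval_protocol(30, 20, 4, 500.0)
        load = FiberLoad(p, REC, FatigueModel(), supramaximal=True)
        assert load.W_I(0.25) == pytest.approx(125.0)
        assert load.W_II(0.25) == pytest.approx(375.0)

    def test_every_edge_appears_in_the_event_list(self):
        p = interval_protocol(16, 32, 3, 250.0, t_start=2.0)
        edges = p.event_times()
        for k in range(3):
            start = 2.0 + k * 48 / 60
            assert any(abs(e - start) < 1e-9 for e in edges)
            assert any(abs(e - (start + 16 / 60)) < 1e-9 for e in edges)


class TestContinuousProtocol:
    @pytest.mark.parametrize("frac, expected", [(0.5, 125.0), (0.7, 175.0),
                                                (1.0, 250.0)])
    def test_power_is_fraction_of_wmax(self, frac, expected):
        p = continuous_protocol(frac, 30.0, recruitment=REC)
        assert p(10.0) == pytest.approx(expected)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            continuous_protocol(0.0, 30.0)


class TestFatigue:
    def test_zero_decline_leaves_powers_unchanged(self):
        p = interval_protocol(30, 20, 4, 500.0)
        plain = FiberLoad(p, REC, FatigueModel(), supramaximal=True)
        fat = apply_fatigue(p, FatigueModel(enabled=True, decline=0.0), REC,
                            supramaximal=True)
        for t in np.linspace(0, p.t_end, 40):
            assert fat.W_II(t) == pytest.approx(plain.W_II(t))

    def test_total_power_declines_within_a_bout(self):
        p = interval_protocol(30, 20, 4, 500.0)
        fat = apply_fatigue(p, FatigueModel(enabled=True, decline=0.3), REC,
                            supramaximal=True)
        assert fat.W_total(0.4) < fat.W_total(0.1)

    def test_successive_bouts_start_with_less_type_ii_power(self):
        p = interval_protocol(30, 20, 4, 500.0)
        fat = apply_fatigue(p, FatigueModel(enabled=True, decline=0.2), REC,
                            supramaximal=True)
        starts = [fat.W_II(k * 50 / 60 + 0.01) for k in range(4)]
        assert all(b < a for a, b in zip(starts, starts[1:]))
        assert starts[0] == pytest.approx(375.0, rel=0.01)

    def test_type_i_power_is_unaffected_by_fatigue(self):
        p = interval_protocol(30, 20, 4, 500.0)
        fat = apply_fatigue(p, FatigueModel(enabled=True, decline=0.3), REC,
                            supramaximal=True)
        for t in (0.1, 0.9, 1.7):
            assert fat.W_I(t) == pytest.approx(125.0)

    def test_negative_decline_rejected(self):
        with pytest.raises(ValueError):
            FatigueModel(enabled=True, decline=-0.1)
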