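"""Per-cycle sleep-measure predictions and the sleep-cycle invariant."""

import math

import numpy as np
import pytest

from sleepwave import (
    MorseWell,
    RelaxationComplete,
    SleepModelParams,
    lorentz_delay,
    nrem_duration,
    nrem_intensity_rel,
    predict_cycles,
    relaxation_level,
    rem_duration,
    rem_intensity_rel,
    resonance_level,
    scenario_shift,
    sci_theoretical,
)


def _random_ladders(n, rng):
    for _ in range(n):
        sigma = rng.uniform(1.5, 40.0)
        jmax = MorseWell(sigma).j_max
        j_in = int(rng.integers(1, jmax + 1))
        yield sigma, j_in


class TestRelaxationLadder:
    def test_levels(self, params):
        assert relaxation_level(params, 1) == 16
        assert relaxation_level(params, 5) == 12

    def test_ladder_exhaustion_is_distinct_signal(self):
        p = SleepModelParams(sigma=2.0, j_in=3, eps_res=-0.5, gamma=0.1)
        with pytest.raises(RelaxationComplete):
            relaxation_level(p, 5)
        with pytest.raises(ValueError):
            relaxation_level(p, 0)


class TestNremDuration:
    def test_cycle_ratio_is_parameter_free(self, params):
        # (2 sigma - j_in) / (2 sigma - j_in + 1) = 4/5 for sigma=10, j_in=16
        assert nrem_duration(params, 2) / nrem_duration(params, 1) == (
            pytest.approx(0.8, abs=1e-12))

    def test_first_cycle_correction_factor(self, params):
        corrected = nrem_duration(params, 1, first_cycle_correction=True)
        assert corrected / nrem_duration(params, 1) == pytest.approx(0.75)

    def test_linear_in_time_scale(self, params):
        doubled = params.with_(a_nr=2 * params.a_nr)
        for n in (1, 3, 5):
            assert nrem_duration(doubled, n) == pytest.approx(
                2 * nrem_duration(params, n))


class TestLorentzDelay:
    def test_peak_value(self):
        p = SleepModelParams(10.0, 16, eps_res=-0.1, gamma=0.1)
        assert lorentz_delay(p, -0.1) == pytest.approx(2 / (0.1 * math.pi))

    def test_half_width_at_half_maximum(self):
        p = SleepModelParams(10.0, 16, eps_res=-0.1, gamma=0.1)
        peak = lorentz_delay(p, p.eps_res)
        for sign in (-1, 1):
            assert lorentz_delay(p, p.eps_res + sign * 0.05) == (
                pytest.approx(peak / 2))

    def test_off_resonance_closed_form(self):
        p = SleepModelParams(10.0, 16, eps_res=-0.4, gamma=0.2)
        assert lorentz_delay(p, -0.1) == pytest.approx(1 / math.pi, rel=1e-12)


class TestRemDuration:
    def test_peak_minutes_at_resonant_level(self):
        sigma = 10.0
        eps14 = -((1 - 14.5 / 20) ** 2)
        p = SleepModelParams(sigma, 16, eps_res=eps14, gamma=0.1, a_rem=1.0)
        assert rem_duration(p, 3) == pytest.approx(2 / (0.1 * math.pi))

    def test_monotone_increase_when_threshold_not_reached(self):
        # resonance below every level the night visits: durations only grow
        sigma = 10.0
        p = SleepModelParams(sigma, 18, eps_res=-0.5, gamma=0.05)
        durs = [rem_duration(p, n) for n in range(1, 6)]
        assert np.all(np.diff(durs) > 0)

    def test_wider_resonance_flattens_profile(self, params):
        narrow = [rem_duration(params, n) for n in range(1, 6)]
        wide = [rem_duration(params.with_(gamma=0.5), n) for n in range(1, 6)]
        assert max(wide) / min(wide) < max(narrow) / min(narrow)

    def test_bell_shape_when_ladder_crosses_resonance(self, params):
        durs = [rem_duration(params, n) for n in range(1, 6)]
        k = int(np.argmax(durs))
        assert 0 < k < len(durs) - 1  # interior maximum at the nearest level


class TestIntensities:
    def test_normalisation_at_first_cycle(self, params):
        assert nrem_intensity_rel(params, 1) == 1.0
        assert rem_intensity_rel(params, 1) == 1.0

    def test_nrem_intensity_worked_example(self):
        p = SleepModelParams(2.0, 3, eps_res=-0.5, gamma=0.1)
        assert nrem_intensity_rel(p, 2) == pytest.approx(0.03884, abs=2e-5)

    def test_nrem_intensity_decreasing_everywhere(self, rng):
        for sigma, j_in in _random_ladders(25, rng):
            if j_in < 2:
                continue
            p = SleepModelParams(sigma, j_in, eps_res=-0.5, gamma=0.1)
            vals = [nrem_intensity_rel(p, n) for n in range(1, j_in + 1)]
            assert np.all(np.diff(vals) < 0)

    def test_rem_intensity_exact_line(self, params):
        slope = 1 / (2 * params.sigma - params.j_in)
        for n in range(1, 6):
            assert rem_intensity_rel(params, n) == pytest.approx(
                1 + (n - 1) * slope, abs=1e-15)
        assert rem_intensity_rel(params, 3) == pytest.approx(1.5)

    def test_rem_slope_steepens_toward_jmax(self):
        sigma = 10.0
        slopes = [
            rem_intensity_rel(SleepModelParams(sigma, j, -0.5, 0.1), 2) - 1
            for j in (12, 16, 19)
        ]
        assert np.all(np.diff(slopes) > 0)


class TestSleepCycleInvariant:
    def test_value_is_two_pi(self, params):
        assert sci_theoretical(params, 1) == pytest.approx(2 * math.pi, abs=1e-12)

    def test_constant_across_cycles_random_ladders(self, rng):
        for sigma, j_in in _random_ladders(100, rng):
            p = SleepModelParams(sigma, j_in, eps_res=-0.5, gamma=0.1)
            vals = [sci_theoretical(p, n) for n in range(1, j_in + 1)]
            assert np.ptp(vals) < 1e-12 * abs(vals[0])

    def test_invariance_under_scale_changes(self, params):
        rescaled = params.with_(a_nr=7.3, i_r1=99.0)
        df = predict_cycles(rescaled, 5)
        assert np.allclose(df["sci_rel"], 1.0, atol=1e-12)


class TestResonanceLevel:
    def test_closed_form_example(self):
        p = SleepModelParams(10.0, 16, eps_res=-0.25, gamma=0.1)
        assert resonance_level(p) == pytest.approx(9.5, abs=1e-12)

    def test_integer_round_trip(self):
        well = MorseWell(10.0)
        from sleepwave import energy_level

        for j in (3, 9, 14):
            p = SleepModelParams(10.0, 16, eps_res=energy_level(well, j),
                                 gamma=0.1)
            assert resonance_level(p) == pytest.approx(j, abs=1e-12)

    def test_continuous_round_trip(self, rng):
        for _ in range(20):
            eps = -float(rng.uniform(0.01, 0.98))
            p = SleepModelParams(10.0, 16, eps_res=eps, gamma=0.1)
            jc = resonance_level(p)
            back = -((1 - (jc + 0.5) / 20.0) ** 2)
            assert back == pytest.approx(eps, abs=1e-12)


class TestPredictCycles:
    def test_table_shapes_and_monotonicities(self, params):
        df = predict_cycles(params, 5)
        assert list(df["j"]) == [16, 15, 14, 13, 12]
        assert np.all(np.diff(df["t_nrem_min"]) < 0)
        assert np.all(np.diff(df["i_nrem_rel"]) < 0)
        assert np.all(np.diff(df["i_rem_rel"]) > 0)
        assert not df.attrs["relaxation_complete"]

    def test_ladder_exhaustion_truncates(self):
        p = SleepModelParams(2.0, 3, eps_res=-0.5, gamma=0.1)
        df = predict_cycles(p, 6)
        assert len(df) == 3
        assert df.attrs["relaxation_complete"]


class TestScenarioShift:
    def test_noop(self, params):
        base, shifted = scenario_shift(params, 0)
        assert base == shifted

    def test_deprivation_orderings(self, params):
        base, dep = scenario_shift(params, +2)
        assert dep.rem_duration_1 < base.rem_duration_1
        assert dep.rem_intensity_abs_1 < base.rem_intensity_abs_1
        assert dep.nrem_intensity_proxy_1 > base.nrem_intensity_proxy_1

    def test_abundance_orderings(self, params):
        base, abn = scenario_shift(params, -2)
        assert abn.rem_duration_1 > base.rem_duration_1
        assert abn.rem_intensity_abs_1 > base.rem_intensity_abs_1

    def test_out_of_range_shift(self, params):
        with pytest.raises(ValueError):
            scenario_shift(params, +10)
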