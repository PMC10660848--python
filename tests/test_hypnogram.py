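"""Hypnogram IO, cycle segmentation rules and per-cycle measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepwave import (
    Hypnogram,
    per_cycle_measures,
    read_hypnogram,
    read_hypnograms,
    segment_cycles,
    sleep_efficiency,
    write_hypnograms,
)
from sleepwave.hypnogram import EFFICIENCY_HIGH, EFFICIENCY_STANDARD


def make_hypnogram(spec, em=None, **kwargs):
    """Build a stage array from (stage, count) pairs."""
    stages = [s for stage, n in spec for s in [stage] * n]
    return Hypnogram(stages=np.array(stages), em_counts=em, **kwargs)


class TestIO:
    def test_round_trip_with_counts(self, tmp_path, rng):
        stages = ["N2"] * 30 + ["REM"] * 10 + ["W"] * 4
        em = np.where(np.array(stages) == "REM", rng.poisson(3, len(stages)), 0)
        h = Hypnogram(stages=np.array(stages), em_counts=em, night_id="n1")
        path = tmp_path / "stages.csv"
        write_hypnograms(h, path)
        back = read_hypnogram(path)
        assert back.night_id == "n1"
        assert np.array_equal(back.stages, h.stages)
        assert np.array_equal(back.em_counts, h.em_counts)

    def test_multiple_nights(self, tmp_path):
        a = Hypnogram(stages=np.array(["N2"] * 4), night_id="a")
        b = Hypnogram(stages=np.array(["W"] * 3), night_id="b")
        path = tmp_path / "two.csv"
        write_hypnograms([a, b], path)
        assert [h.night_id for h in read_hypnograms(path)] == ["a", "b"]
        assert read_hypnogram(path, night_id="b").n_epochs == 3
        with pytest.raises(ValueError, match="2 nights"):
            read_hypnogram(path)

    def test_unknown_stage_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "night_id,epoch_index,stage\nn1,0,N2\nn1,1,N4\n")
        with pytest.raises(ValueError, match="row 3"):
            read_hypnograms(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("night_id,stage\nn1,N2\n")
        with pytest.raises(ValueError, match="epoch_index"):
            read_hypnograms(path)

    def test_non_contiguous_epochs(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "night_id,epoch_index,stage\nn1,0,N2\nn1,2,N2\n")
        with pytest.raises(ValueError, match="contiguous"):
            read_hypnograms(path)

    def test_invalid_constructor_inputs(self):
        with pytest.raises(ValueError, match="unknown stage"):
            Hypnogram(stages=np.array(["N2", "XX"]))
        with pytest.raises(ValueError, match="non-negative"):
            Hypnogram(stages=np.array(["REM"]), em_counts=np.array([-1]))


class TestSegmentation:
    def test_two_clean_cycles(self):
        # 20 min NREM, 5 min REM, 15 min NREM, 4 min terminal REM
        h = make_hypnogram([("N2", 40), ("REM", 10), ("N2", 30), ("REM", 8)])
        seg = segment_cycles(h)
        assert len(seg) == 2
        df = per_cycle_measures(seg, h)
        assert list(df["nrem_min"]) == [20.0, 15.0]
        assert list(df["rem_min"]) == [5.0, 4.0]

    def test_short_midnight_rem_merges_into_nrem(self):
        # 2-min REM after 20-min NREM does not close the cycle; the NREM
        # episode continues through it to the next qualifying REM
        h = make_hypnogram([
            ("N2", 40), ("REM", 4), ("N2", 30), ("REM", 10), ("N2", 24),
            ("REM", 8),
        ])
        seg = segment_cycles(h)
        assert len(seg) == 2
        df = per_cycle_measures(seg, h)
        assert df.loc[0, "nrem_min"] == pytest.approx(37.0)  # 40+4+30 epochs
        assert df.loc[0, "rem_min"] == pytest.approx(5.0)
        assert any("merged" in w for w in seg.warnings)

    def test_terminal_rem_exempt_from_minimum(self):
        h = make_hypnogram([("N2", 40), ("REM", 10), ("N2", 30), ("REM", 4),
                            ("W", 10)])
        seg = segment_cycles(h)
        assert len(seg) == 2
        assert seg.cycles[-1].rem_end == 84  # ends at final awakening
        df = per_cycle_measures(seg, h)
        assert df.loc[1, "rem_min"] == pytest.approx(2.0)

    def test_terminal_nrem_without_rem_is_incomplete(self):
        h = make_hypnogram([("N2", 40), ("REM", 10), ("N2", 30), ("W", 6)])
        seg = segment_cycles(h)
        assert len(seg) == 2
        assert not seg.cycles[-1].complete

    def test_no_stage2_onset_warns(self):
        h = make_hypnogram([("W", 5), ("N1", 5), ("W", 5)])
        seg = segment_cycles(h)
        assert len(seg) == 0
        assert seg.warnings

    def test_nrem_onset_needs_two_consecutive_n2(self):
        h = make_hypnogram([("N1", 2), ("N2", 1), ("N1", 1), ("N2", 40),
                            ("REM", 10)])
        seg = segment_cycles(h)
        assert seg.cycles[0].nrem_start == 4

    def test_idempotence(self):
        h = make_hypnogram([("N2", 40), ("REM", 10), ("N2", 30), ("REM", 8)])
        a, b = segment_cycles(h), segment_cycles(h)
        assert a.cycles == b.cycles

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(blocks=st.lists(
        st.tuples(st.sampled_from(["W", "N1", "N2", "SWS", "REM"]),
                  st.integers(min_value=1, max_value=30)),
        min_size=1, max_size=12))
    def test_fuzzed_inputs_respect_minima(self, blocks):
        """Complete non-terminal cycles always satisfy the duration minima."""
        h = make_hypnogram(blocks)
        seg = segment_cycles(h)
        total = 0.0
        for k, c in enumerate(seg.cycles):
            assert c.nrem_start < c.nrem_end
            if c.complete:
                assert c.rem_start == c.nrem_end and c.rem_start < c.rem_end
                total += h.minutes(c.rem_end - c.nrem_start)
            else:
                assert k == len(seg.cycles) - 1
                total += h.minutes(c.nrem_end - c.nrem_start)
            if k < len(seg.cycles) - 1:
                assert h.minutes(c.nrem_end - c.nrem_start) >= 10.0
                assert h.minutes(c.rem_end - c.rem_start) >= 3.0
                assert c.rem_end <= seg.cycles[k + 1].nrem_start
            elif c.complete:
                # last cycle: NREM minimum still applies, REM is exempt
                assert h.minutes(c.nrem_end - c.nrem_start) >= 10.0
        assert total <= h.minutes(h.n_epochs)


class TestPerCycleMeasures:
    def _night(self):
        em = np.zeros(88, dtype=int)
        em[70:80] = 6  # 60 eye movements across the 5-min REM episode
        return make_hypnogram(
            [("N2", 20), ("SWS", 10), ("N2", 40), ("REM", 10), ("W", 8)],
            em=em)

    def test_sws_minutes_and_rem_density(self):
        h = self._night()
        df = per_cycle_measures(segment_cycles(h), h)
        assert df.loc[0, "sws_min"] == pytest.approx(5.0)
        assert df.loc[0, "rem_min"] == pytest.approx(5.0)
        assert df.loc[0, "rem_density"] == pytest.approx(12.0)

    def test_density_absent_without_counts(self):
        h = make_hypnogram([("N2", 40), ("REM", 10)])
        df = per_cycle_measures(segment_cycles(h), h)
        assert np.isnan(df.loc[0, "rem_density"])

    def test_pure_stage_minutes_exclude_wake(self):
        h = make_hypnogram([("N2", 30), ("W", 4), ("N2", 6), ("REM", 10)])
        df = per_cycle_measures(segment_cycles(h), h, pure_stage=True)
        assert df.loc[0, "nrem_min"] == pytest.approx(20.0)
        assert df.loc[0, "nrem_pure_min"] == pytest.approx(18.0)


class TestSleepEfficiency:
    def test_limits_and_filters(self):
        assert sleep_efficiency(Hypnogram(stages=np.array(["W"] * 10))) == 0.0
        assert sleep_efficiency(Hypnogram(stages=np.array(["N2"] * 10))) == 100.0
        h = Hypnogram(stages=np.array(["N2"] * 90 + ["W"] * 10))
        eff = sleep_efficiency(h)
        assert eff == 90.0
        assert eff >= EFFICIENCY_STANDARD
        assert eff < EFFICIENCY_HIGH

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sleep_efficiency(Hypnogram(stages=np.array([], dtype="U3")))
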