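"""Stage partitioning, vessel classification and direction tabulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lymphwave import (DiameterTrace, IndexSet, classify_flow_responsive,
                       classify_initial_direction, partition_stages,
                       standard_protocol, summarize_stages,
                       tabulate_directions)
from lymphwave.waves import WaveEvent


def protocol_trace(protocol, dt=0.05, drop_last_stage=False):
    stages = protocol.windows()
    if drop_last_stage:
        stages = stages[:-1]
    rows = []
    for s in stages:
        t = np.arange(s.t_start, s.t_end, dt)
        rows.append(pd.DataFrame({
            "time_s": t, "p_in_cmh2o": s.p_in, "p_out_cmh2o": s.p_out,
            "diameter_um": 160.0}))
    return DiameterTrace(data=pd.concat(rows, ignore_index=True))


def idx(amp, freq, n=None):
    n = n if n is not None else (0 if freq == 0 else max(int(freq * 2), 1))
    ef = 0.5 if n else math.nan
    return IndexSet(amp_um=amp if n else math.nan,
                    norm_amp_pct=100 * amp / 200 if n else math.nan,
                    freq_per_min=freq, ef=ef,
                    fpf_per_min=ef * freq if n else math.nan,
                    d_max_um=200.0, window_s=120.0, n_events=n)


def wave(score, extent=1.0, t=0.0, flags=()):
    return WaveEvent(label=1, t_onset_s=t, onset_x_um=np.arange(5.0),
                     onset_t_s=np.arange(5.0), slope_s_per_um=1e-4,
                     velocity_mm_s=10.0 * score if score else None,
                     origin_um=0.0, score=score, extent_fraction=extent,
                     fit_r2=1.0, flags=list(flags))


class TestPartitionStages:
    def test_protocol1_gives_four_two_minute_slices(self):
        prot = standard_protocol(1)
        w = partition_stages(protocol_trace(prot), prot)
        assert [s.name for s in w] == ["control", "step1", "step2",
                                       "recovery"]
        for s in w:
            assert s.duration == pytest.approx(120.0, abs=0.1)
        assert [(s.p_in, s.p_out) for s in w] == [(3, 3), (4, 2), (5, 1),
                                                  (3, 3)]

    def test_protocol2_pressures(self):
        prot = standard_protocol(2, stage_duration_s=20.0)
        w = partition_stages(protocol_trace(prot), prot)
        assert [(s.p_in, s.p_out) for s in w] == [(1, 1), (1, 3), (1, 5),
                                                  (1, 1)]

    def test_missing_recovery_tolerated(self):
        prot = standard_protocol(1, stage_duration_s=20.0)
        w = partition_stages(protocol_trace(prot, drop_last_stage=True),
                             prot)
        assert [s.name for s in w] == ["control", "step1", "step2"]

    def test_schedule_mismatch_reports_detected_vs_expected(self):
        p1 = standard_protocol(1, stage_duration_s=20.0)
        p2 = standard_protocol(2, stage_duration_s=20.0)
        with pytest.raises(ValueError, match="detected.*expected"):
            partition_stages(protocol_trace(p1), p2)


class TestClassification:
    @pytest.mark.parametrize("scores,expected", [
        ([-1.0] * 23 + [1.0] * 2, "retrograde"),       # mean −0.84
        ([1.0, -1.0, 1.0, -1.0], "mixed"),
        ([1.0] * 5, "antegrade"),
    ])
    def test_initial_direction(self, scores, expected):
        assert classify_initial_direction(scores) == expected

    def test_no_control_waves_unclassifiable(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            classify_initial_direction([])

    def test_cessation_is_flow_responsive(self):
        assert classify_flow_responsive(idx(40, 8), [idx(0, 0, n=0)])

    def test_unchanged_indices_not_responsive(self):
        assert not classify_flow_responsive(idx(40, 8),
                                            [idx(40, 8), idx(39, 7.8)])

    def test_frequency_drop_to_54pct_is_responsive(self):
        assert classify_flow_responsive(idx(40, 8), [idx(40, 8 * 0.54)],
                                        drop_fraction=0.2)


class TestTabulate:
    @pytest.mark.parametrize("retro,ante,mixed,pct", [
        (38, 17, 5, 63),     # protocol 1: 38/60 imposed-flow tests
        (27, 8, 0, 77),      # protocol 2: 27/35 tests
        (27, 13, 0, 68),     # protocol 3: 27/40 tests
    ])
    def test_printed_tabulations(self, retro, ante, mixed, pct):
        classes = (["retrograde"] * retro + ["antegrade"] * ante
                   + ["mixed"] * mixed)
        out = tabulate_directions(classes)
        assert out["pct_retrograde"] == pct
        assert out["n_total"] == retro + ante + mixed

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tabulate_directions([])

    @given(st.lists(st.sampled_from(["antegrade", "retrograde", "mixed"]),
                    min_size=1, max_size=120))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_count_conservation(self, classes):
        out = tabulate_directions(classes)
        assert (out["n_antegrade"] + out["n_retrograde"] + out["n_mixed"]
                == out["n_total"] == len(classes))
        assert 0 <= out["pct_retrograde"] <= 100


class TestSummarize:
    def stage_data(self, recovery_amp=38.0):
        events = {
            "control": [wave(-1.0, 1.0), wave(-1.0, 0.9), wave(1.0, 1.0)],
            "step1": [wave(1.0, 0.6)],
            "step2": [wave(1.0, 0.5, flags=["censored"])],
            "recovery": [wave(-1.0, 0.95)],
        }
        indices = {"control": idx(40, 8), "step1": idx(30, 5),
                   "step2": idx(20, 3), "recovery": idx(recovery_amp, 7)}
        return events, indices

    def test_control_normalized_extent_is_one(self):
        events, indices = self.stage_data()
        rec = summarize_stages(events, indices)
        ctrl = rec.stage_named("control")
        assert ctrl.extent_norm_to_control == pytest.approx(1.0)
        assert rec.stage_named("step1").extent_norm_to_control < 1.0

    def test_censored_waves_excluded_from_direction(self):
        events, indices = self.stage_data()
        rec = summarize_stages(events, indices)
        s2 = rec.stage_named("step2")
        assert s2.n_waves == 0
        assert s2.mean_score is None

    def test_recovery_validity_threshold(self):
        events, indices = self.stage_data(recovery_amp=31.0)
        assert summarize_stages(events, indices).recovery_valid   # 77.5%
        events, indices = self.stage_data(recovery_amp=29.0)
        assert not summarize_stages(events, indices).recovery_valid

    def test_flow_responsiveness_from_step_indices(self):
        events, indices = self.stage_data()
        rec = summarize_stages(events, indices)      # freq 8 -> 5: drop
        assert rec.flow_responsive
        indices2 = dict(indices, step1=idx(40, 8), step2=idx(39, 7.5))
        rec2 = summarize_stages(events, indices2)
        assert not rec2.flow_responsive

    def test_initial_direction_classification(self):
        events, indices = self.stage_data()
        rec = summarize_stages(events, indices)
        assert rec.initial_direction == "retrograde"     # mean −1/3


class TestPressureSweep:
    def test_chronotropy_and_amplitude_fall_across_pressures(self):
        from lymphwave import ProtocolSpec, pressure_sweep_table
        from lymphwave.synthetic import simulate_trace
        from conftest import make_field

        prot = ProtocolSpec(stages=(("p1", 40.0, 1.0, 1.0),
                                    ("p3", 40.0, 3.0, 3.0),
                                    ("p5", 40.0, 5.0, 5.0)))
        f = make_field(frequency_per_min=8.0, protocol=prot)
        tr = simulate_trace(f, 1500.0)
        curve = (np.array([0.1, 1, 3, 5, 15]),
                 np.array([146, 176, 200, 209, 222.0]))
        tab = pressure_sweep_table(tr, prot, curve)
        assert list(tab.stage) == ["p1", "p3", "p5"]
        freq = tab.freq_per_min.to_numpy()
        assert freq[0] < freq[1] < freq[2]       # pressure chronotropy
        amp = tab.amp_um.to_numpy()
        assert amp[2] < amp[0]                   # amplitude falls above 2
        assert (tab.n_events > 0).all()
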