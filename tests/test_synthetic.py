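"""Generator correctness: kinematics, amplitudes, protocols, determinism."""

import math

import numpy as np
import pytest

from lymphwave import (ModulationRules, OpticsSpec, PacemakerSpec,
                       ProtocolSpec, VesselSpec, render_video,
                       simulate_diameter_field, simulate_trace,
                       stage_pacemaker, standard_protocol)
from conftest import FLAT_VESSEL, ONE_STAGE, make_field


def onset_times_by_crossing(field, level_um):
    """Oracle onset per axial row: linearly interpolated first crossing
    of the constriction through ``level_um`` (exact for a linear
    systolic rise)."""
    edd = field.diam.max(axis=1)
    c = edd[:, None] - field.diam
    t = field.t_s
    out = np.full(field.n_x, np.nan)
    for i in range(field.n_x):
        above = np.nonzero(c[i] >= level_um)[0]
        if above.size == 0:
            continue
        j = above[0]
        if j == 0:
            out[i] = t[0]
        else:
            f = (level_um - c[i, j - 1]) / (c[i, j] - c[i, j - 1])
            out[i] = t[j - 1] + f * field.dt_s
    return out


class TestSimulateField:
    def test_zero_frequency_gives_static_vessel(self):
        f = make_field(frequency_per_min=0.0)
        profile = FLAT_VESSEL.edd_profile(f.x_um)
        assert np.allclose(f.diam, profile[:, None])
        assert f.ground_truth == []

    def test_onset_difference_between_ends_matches_velocity(self):
        # +10 mm/s from the inflow end of a 3 mm vessel: the far end
        # activates (3 - dx) mm / 10 mm/s later
        f = make_field(velocity_mm_s=10.0)
        onsets = onset_times_by_crossing(f, 20.0)
        expected = (f.x_um[-1] - f.x_um[0]) / 10_000.0
        assert onsets[-1] - onsets[0] == pytest.approx(expected, abs=1e-9)

    def test_supra_threshold_extent_closed_form(self):
        # A(x) = 40·exp(−x/1 mm) µm from an end origin crosses a 10 µm
        # threshold at 1 mm·ln(4) ≈ 1.386 mm; cross-checked against a
        # dense numerical scan of the amplitude profile
        lam, a0, thr = 1000.0, 40.0, 10.0
        xs = np.arange(0, 3000.0, 0.1)
        scan_extent = 0.1 * np.count_nonzero(a0 * np.exp(-xs / lam) >= thr)
        closed = lam * math.log(a0 / thr)
        assert scan_extent == pytest.approx(closed, rel=1e-3)

        vessel = VesselSpec(length_um=3000.0, n_valves=0,
                            baseline_edd_um=100.0, sinus_bump_um=0.0)
        f = simulate_diameter_field(
            vessel,
            PacemakerSpec(origin_um=0.0, frequency_per_min=10.0,
                          conduction_velocity_mm_s=10.0, amplitude_um=a0,
                          attenuation_um=lam),
            ONE_STAGE, dt=0.04, dx=10.0, seed=0,
            amp_threshold_frac=thr / 100.0)
        assert f.ground_truth[0].extent_um == pytest.approx(closed, rel=1e-6)

    def test_per_wave_onset_regression_recovers_velocity(self):
        # noise-free kinematic consistency: regression of interpolated
        # onset times over x recovers 1/v within 1%
        for v in (2.0, -5.0, 10.0, -20.0):
            f = make_field(velocity_mm_s=v,
                           origin_um=0.0 if v > 0 else 3000.0)
            onsets = onset_times_by_crossing(f, 20.0)
            slope = np.polyfit(f.x_um, onsets, 1)[0]    # s/µm
            assert 1.0 / slope / 1000.0 == pytest.approx(v, rel=0.01)

    def test_amplitude_bookkeeping(self):
        f = make_field(amplitude_um=40.0, attenuation_um=1000.0,
                       origin_um=1500.0)
        edd = FLAT_VESSEL.edd_profile(f.x_um)
        measured = (edd[:, None] - f.diam).max(axis=1)
        expected = 40.0 * np.exp(-np.abs(f.x_um - 1500.0) / 1000.0)
        # the sampled waveform peak sits within one dt of the true peak
        tol = expected * (1 - math.exp(-f.dt_s / 1.0)) + 1e-9
        assert np.all(measured <= expected + 1e-9)
        assert np.all(expected - measured <= tol)

    def test_direction_sign_of_ground_truth(self):
        ante = make_field(velocity_mm_s=10.0, origin_um=0.0)
        retro = make_field(velocity_mm_s=-10.0, origin_um=3000.0)
        assert all(w.antegrade for w in ante.ground_truth)
        assert all(not w.antegrade for w in retro.ground_truth)

    def test_determinism_under_fixed_seed(self):
        a = make_field(jitter_sd_s=0.5, seed=42)
        b = make_field(jitter_sd_s=0.5, seed=42)
        assert np.array_equal(a.diam, b.diam)
        c = make_field(jitter_sd_s=0.5, seed=43)
        assert not np.array_equal(a.diam, c.diam)

    def test_lumen_closure_rejected(self):
        with pytest.raises(ValueError, match="close the lumen"):
            make_field(amplitude_um=160.0)

    @pytest.mark.parametrize("dt,dx", [(0.06, 10.0), (0.04, 25.0),
                                       (-0.01, 10.0), (0.04, 0.0)])
    def test_bad_resolution_rejected(self, dt, dx):
        with pytest.raises(ValueError):
            make_field(dt=dt, dx=dx)

    def test_stage_shorter_than_cycle_rejected(self):
        prot = ProtocolSpec(stages=(("control", 4.0, 3.0, 3.0),))
        with pytest.raises(ValueError, match="shorter than one"):
            make_field(frequency_per_min=10.0, protocol=prot)


class TestProtocols:
    def test_standard_pressure_schedules(self):
        p1 = standard_protocol(1)
        assert [(s[2], s[3]) for s in p1.stages] == [(3, 3), (4, 2),
                                                     (5, 1), (3, 3)]
        p2 = standard_protocol(2)
        assert [(s[2], s[3]) for s in p2.stages] == [(1, 1), (1, 3),
                                                     (1, 5), (1, 1)]
        p3 = standard_protocol(3)
        assert [(s[2], s[3]) for s in p3.stages] == [(1, 1), (3, 1),
                                                     (5, 1), (1, 1)]
        assert all(s[1] == 120.0 for s in p1.stages)

    def test_pout_step_moves_pacemaker_to_outflow(self):
        p2 = standard_protocol(2, stage_duration_s=30.0)
        w = p2.windows()
        pm = PacemakerSpec(origin_um=0.0, conduction_velocity_mm_s=10.0)
        eff = stage_pacemaker(pm, w[2], w[0], p2.rules, 4000.0)
        assert eff.origin_um == 4000.0
        assert eff.conduction_velocity_mm_s == -10.0
        back = stage_pacemaker(pm, w[3], w[0], p2.rules, 4000.0)
        assert back.origin_um == 0.0

    def test_imposed_flow_inhibits_frequency_and_amplitude(self):
        p1 = standard_protocol(1, stage_duration_s=30.0)
        w = p1.windows()
        pm = PacemakerSpec()
        eff = stage_pacemaker(pm, w[2], w[0], p1.rules, 4000.0)
        assert eff.frequency_per_min < pm.frequency_per_min
        assert eff.amplitude_um < pm.amplitude_um
        unresponsive = ModulationRules(flow_responsive=False)
        eff2 = stage_pacemaker(pm, w[2], w[0], unresponsive, 4000.0)
        assert eff2.frequency_per_min == pytest.approx(
            pm.frequency_per_min)
        assert eff2.amplitude_um == pytest.approx(pm.amplitude_um)


class TestTrace:
    def test_midpoint_trace_equals_column(self, small_field):
        tr = simulate_trace(small_field, small_field.length_um / 2)
        assert np.array_equal(tr.diameter,
                              small_field.column_at(1500.0))

    def test_pressure_columns_follow_protocol(self):
        prot = standard_protocol(2, stage_duration_s=10.0)
        f = make_field(frequency_per_min=8.0, protocol=prot)
        tr = simulate_trace(f, 1500.0, prot)
        # during protocol 2 step 2 the outflow pressure is 5 cmH2O and
        # the inflow pressure stays at 1 cmH2O
        step2 = tr.data[(tr.data.time_s >= 20.0) & (tr.data.time_s < 30.0)]
        assert (step2.p_out_cmh2o == 5.0).all()
        assert (step2.p_in_cmh2o == 1.0).all()

    def test_stage_boundaries_match_protocol(self):
        prot = standard_protocol(3, stage_duration_s=10.0)
        f = make_field(protocol=prot)
        tr = simulate_trace(f, 1000.0, prot)
        assert [(s.name, s.t_start, s.t_end) for s in tr.stages] == [
            ("control", 0.0, 10.0), ("step1", 10.0, 20.0),
            ("step2", 20.0, 30.0), ("recovery", 30.0, 40.0)]

    def test_outside_vessel_rejected(self, small_field):
        with pytest.raises(ValueError):
            simulate_trace(small_field, 5000.0)


class TestRenderVideo:
    def test_constant_diameter_gives_constant_gap(self):
        f = make_field(frequency_per_min=0.0)
        optics = OpticsSpec(pixel_scale=1.0, frame_rate=25.0, noise_sd=0.0)
        frames, meta = render_video(f, optics)
        img = frames[0].astype(float)
        # per column, count lumen-level pixels: inner gap = 160 px
        lumen = (img < (optics.lumen_intensity
                        + optics.wall_intensity) / 2).sum(axis=0)
        assert np.all(np.abs(lumen - 160) <= 1)

    def test_seed_reproducibility(self, small_field):
        optics = OpticsSpec(pixel_scale=0.4, noise_sd=5.0, seed=7)
        a, _ = render_video(small_field, optics)
        b, _ = render_video(small_field, optics)
        assert np.array_equal(a, b)

    def test_vessel_wider_than_frame_rejected(self, small_field):
        optics = OpticsSpec(pixel_scale=1.0, image_height=40)
        with pytest.raises(ValueError, match="wider than frame"):
            render_video(small_field, optics)
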