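"""Shared fixtures: small synthetic vessels reused across test modules."""

from __future__ import annotations

import math

import pytest

from lymphwave import (ModulationRules, PacemakerSpec, ProtocolSpec,
                       VesselSpec, simulate_diameter_field)

# a single-stage, straight (no sinus) vessel keeps closed forms simple
FLAT_VESSEL = VesselSpec(length_um=3000.0, n_valves=0, baseline_edd_um=160.0,
                         sinus_bump_um=0.0)
ONE_STAGE = ProtocolSpec(stages=(("control", 12.0, 3.0, 3.0),),
                         rules=ModulationRules())


def make_field(velocity_mm_s=10.0, origin_um=0.0, amplitude_um=40.0,
               attenuation_um=math.inf, frequency_per_min=10.0,
               vessel=FLAT_VESSEL, protocol=ONE_STAGE, dt=0.04, dx=10.0,
               seed=0, jitter_sd_s=0.0):
    pm = PacemakerSpec(origin_um=origin_um,
                       frequency_per_min=frequency_per_min,
                       conduction_velocity_mm_s=velocity_mm_s,
                       amplitude_um=amplitude_um,
                       attenuation_um=attenuation_um,
                       systole_s=0.3, diastole_tau_s=1.0,
                       jitter_sd_s=jitter_sd_s)
    return simulate_diameter_field(vessel, pm, protocol, dt=dt, dx=dx,
                                   seed=seed)


@pytest.fixture(scope="session")
def small_field():
    """3 mm vessel, two antegrade +10 mm/s full-length waves in 12 s."""
    return make_field()


@pytest.fixture(scope="session")
def attenuated_field():
    """4 mm vessel, mid-vessel pacemaker, amplitude 40 µm decaying with
    a 1 mm attenuation length: the closed-form band-extent case."""
    vessel = VesselSpec(length_um=4000.0, n_valves=0,
                        baseline_edd_um=160.0, sinus_bump_um=0.0)
    return make_field(velocity_mm_s=10.0, origin_um=2000.0,
                      amplitude_um=40.0, attenuation_um=1000.0,
                      vessel=vessel)
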