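"""Synthetic lymphatic vessel generator.

Produces ground-truth diameter fields, midpoint traces and rendered
video frames emulating a cannulated, pressurized collecting-lymphatic
segment: a tube 3–4.5 mm long and 160–180 µm internal diameter with
wider valve sinuses, spontaneous phasic contractions (rapid systolic
fall, slower diastolic recovery) initiated at a pacemaker site and
conducted along the vessel at ~10 mm/s, with pressure-dependent
frequency/amplitude, flow-dependent inhibition and imaging noise.

Every generative parameter is recorded so downstream analysis can be
tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .core import DiameterField, DiameterTrace, StageWindow, WaveTruth

__all__ = [
    "VesselSpec",
    "PacemakerSpec",
    "ModulationRules",
    "ProtocolSpec",
    "OpticsSpec",
    "standard_protocol",
    "stage_pacemaker",
    "simulate_diameter_field",
    "render_video",
    "simulate_trace",
]


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and passive mechanics of the vessel segment.

    ``tone_fraction`` is the resting active constriction relative to the
    passive diameter: baseline EDD ≈ (1 − tone) · D_MAX at the working
    pressure.  The passive pressure–diameter table (``passive_p_cmh2o``,
    ``passive_d_um``) plays the role of D_MAX(P), the calcium-free
    maximum diameter used to normalize contraction amplitude.
    """

    length_um: float = 4000.0
    n_valves: int = 4
    baseline_edd_um: float = 160.0
    sinus_bump_um: float = 12.0     # extra diameter at valve sinuses
    sinus_width_um: float = 120.0   # Gaussian sigma of each sinus bulge
    tone_fraction: float = 0.2
    passive_p_cmh2o: tuple[float, ...] = (0.1, 0.5, 1, 2, 3, 5, 8, 10, 15)
    passive_d_um: tuple[float, ...] = (
        146, 163, 176, 191, 200, 209, 216, 218, 222)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        if not 0 <= self.tone_fraction < 1:
            raise ValueError("tone_fraction must be in [0, 1)")
        if len(self.passive_p_cmh2o) != len(self.passive_d_um):
            raise ValueError("passive curve arrays must have equal length")
        if self.baseline_edd_um + self.sinus_bump_um > max(self.passive_d_um):
            raise ValueError("baseline EDD exceeds the passive maximum")

    def d_max(self, pressure_cmh2o: float) -> float:
        """Passive (calcium-free) diameter at the given pressure, µm."""
        return float(np.interp(pressure_cmh2o,
                               self.passive_p_cmh2o, self.passive_d_um))

    def edd_profile(self, x_um: np.ndarray) -> np.ndarray:
        """Resting end-diastolic diameter along the vessel, µm.

        Valve sinuses (evenly spaced, including both ends) are modelled
        as Gaussian bulges on a uniform baseline.
        """
        x = np.asarray(x_um, dtype=float)
        d = np.full_like(x, self.baseline_edd_um)
        if self.n_valves >= 1 and self.sinus_bump_um > 0:
            if self.n_valves == 1:
                centres = [self.length_um / 2]
            else:
                centres = np.linspace(0, self.length_um, self.n_valves)
            for c in centres:
                d += self.sinus_bump_um * np.exp(
                    -0.5 * ((x - c) / self.sinus_width_um) ** 2)
        return d


@dataclass(frozen=True)
class PacemakerSpec:
    """Pacemaker site and contraction-wave kinetics.

    ``conduction_velocity_mm_s`` is signed: positive = toward the
    outflow end (antegrade).  Waves spread away from ``origin_um`` at
    ``|velocity|`` in both available directions, so an interior origin
    produces bidirectional (V-shaped) activation.
    ``attenuation_um`` is the exponential decay length of the wave
    amplitude with conducted distance (``inf`` = no attenuation, the
    wave conducts the full vessel at full strength).
    """

    origin_um: float = 0.0
    frequency_per_min: float = 8.0
    conduction_velocity_mm_s: float = 10.0
    amplitude_um: float = 60.0
    attenuation_um: float = math.inf
    systole_s: float = 0.3
    diastole_tau_s: float = 1.0
    jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_per_min < 0:
            raise ValueError("frequency must be >= 0")
        if self.systole_s <= 0:
            raise ValueError("systole_s must be positive")
        if self.attenuation_um <= 0:
            raise ValueError("attenuation_um must be positive")
        if self.conduction_velocity_mm_s == 0:
            raise ValueError("conduction velocity must be nonzero")


@dataclass(frozen=True)
class ModulationRules:
    """Qualitative pressure/flow modulation of pacemaking, as multipliers.

    Defaults encode the qualitative behaviour of flow-responsive
    vessels: higher equal pressure raises frequency (pressure-induced
    chronotropy) and lowers amplitude above ~2 cmH2O; imposed forward
    flow (P_in − P_out > 0) inhibits frequency and amplitude and
    shortens the conduction length; selective P_out elevation moves the
    pacemaker to the outflow end (retrograde conduction); selective P_in
    elevation moves it to the inflow end (antegrade).  The magnitudes
    are plausible placeholders, not measured quantities — they exist so
    that protocol scenarios exercise the analysis, and are fully
    configurable.
    """

    freq_gain_per_cmh2o: float = 1.25       # per cmH2O mean pressure rise
    amp_loss_per_cmh2o_above2: float = 0.88
    flow_freq_loss_per_cmh2o: float = 0.80  # per cmH2O of added P_in − P_out
    flow_amp_loss_per_cmh2o: float = 0.85
    flow_attenuation_loss_per_cmh2o: float = 0.70
    pout_switch_threshold_cmh2o: float = 0.2
    pin_switch_threshold_cmh2o: float = 0.2
    flow_responsive: bool = True


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered pressure stages plus modulation rules.

    ``stages`` is a sequence of (name, duration_s, p_in, p_out).
    """

    stages: tuple[tuple[str, float, float, float], ...]
    rules: ModulationRules = field(default_factory=ModulationRules)

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        for name, dur, p_in, p_out in self.stages:
            if dur <= 0:
                raise ValueError(f"stage {name!r}: duration must be positive")
            if p_in < 0 or p_out < 0:
                raise ValueError(f"stage {name!r}: pressures must be >= 0")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s[1] for s in self.stages))

    def windows(self) -> list[StageWindow]:
        out, t = [], 0.0
        for name, dur, p_in, p_out in self.stages:
            out.append(StageWindow(name, t, t + dur, p_in, p_out))
            t += dur
        return out


def standard_protocol(number: int, stage_duration_s: float = 120.0,
                      rules: ModulationRules | None = None) -> ProtocolSpec:
    """The three standard four-stage pressure protocols.

    1 — imposed flow: from P_in = P_out = 3 cmH2O, P_in raised and P_out
        lowered by the same amount in two 1 cmH2O steps (midpoint
        pressure unchanged);
    2 — elevated outflow pressure: from 1/1 cmH2O, P_out raised in
        2 cmH2O steps to 5 cmH2O;
    3 — elevated inflow pressure: from 1/1 cmH2O, P_in raised in
        2 cmH2O steps to 5 cmH2O.

    Each protocol is control / step1 / step2 / recovery, nominally 2 min
    per stage.  Protocol 4 is the equal-pressure sweep used to map the
    pressure range of spontaneous contractions: both pressures stepped
    together from 3 down through 2, 1, 0.5, 0.2, 0.1 cmH2O, back to 3,
    then up through 5, 8, 10 and 15 cmH2O; it is summarized per
    pressure level rather than per control/step stage.
    """
    d = stage_duration_s
    if number == 4:
        levels = (3, 2, 1, 0.5, 0.2, 0.1, 3, 5, 8, 10, 15)
        stages = tuple((f"p{p:g}_{i}", d, float(p), float(p))
                       for i, p in enumerate(levels))
        return ProtocolSpec(stages=stages,
                            rules=rules if rules else ModulationRules())
    if number == 1:
        stages = (("control", d, 3, 3), ("step1", d, 4, 2),
                  ("step2", d, 5, 1), ("recovery", d, 3, 3))
    elif number == 2:
        stages = (("control", d, 1, 1), ("step1", d, 1, 3),
                  ("step2", d, 1, 5), ("recovery", d, 1, 1))
    elif number == 3:
        stages = (("control", d, 1, 1), ("step1", d, 3, 1),
                  ("step2", d, 5, 1), ("recovery", d, 1, 1))
    else:
        raise ValueError("protocol number must be 1, 2, 3 or 4")
    if rules is None:
        rules = ModulationRules()
    return ProtocolSpec(stages=stages, rules=rules)


def stage_pacemaker(pm: PacemakerSpec, stage: StageWindow,
                    control: StageWindow, rules: ModulationRules,
                    length_um: float) -> PacemakerSpec:
    """Effective pacemaker parameters during one protocol stage."""
    mean_p = (stage.p_in + stage.p_out) / 2
    mean_p0 = (control.p_in + control.p_out) / 2
    freq = pm.frequency_per_min * rules.freq_gain_per_cmh2o ** (mean_p - mean_p0)
    amp = pm.amplitude_um * rules.amp_loss_per_cmh2o_above2 ** (
        max(mean_p - 2.0, 0.0) - max(mean_p0 - 2.0, 0.0))
    atten = pm.attenuation_um

    dflow = max(stage.p_in - stage.p_out, 0.0) - max(
        control.p_in - control.p_out, 0.0)
    if rules.flow_responsive and dflow > 0:
        freq *= rules.flow_freq_loss_per_cmh2o ** dflow
        amp *= rules.flow_amp_loss_per_cmh2o ** dflow
        if math.isfinite(atten):
            atten *= rules.flow_attenuation_loss_per_cmh2o ** dflow
        else:
            atten = length_um * rules.flow_attenuation_loss_per_cmh2o ** dflow

    origin = pm.origin_um
    speed = abs(pm.conduction_velocity_mm_s)
    if (stage.p_out - control.p_out >= rules.pout_switch_threshold_cmh2o
            and stage.p_in <= control.p_in + 1e-9):
        origin = length_um           # outflow pacemaker -> retrograde
    elif stage.p_in - control.p_in >= rules.pin_switch_threshold_cmh2o:
        origin = 0.0                 # inflow pacemaker -> antegrade
    velocity = speed if origin <= length_um / 2 else -speed

    return replace(pm, origin_um=origin, frequency_per_min=freq,
                   amplitude_um=amp, attenuation_um=atten,
                   conduction_velocity_mm_s=velocity)


def _waveform(tau: np.ndarray, systole_s: float,
              diastole_tau_s: float) -> np.ndarray:
    """Normalized constriction time course: linear systolic rise to 1
    over ``systole_s`` then exponential diastolic decay."""
    w = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < systole_s)
    w[rising] = tau[rising] / systole_s
    decay = tau >= systole_s
    w[decay] = np.exp(-(tau[decay] - systole_s) / diastole_tau_s)
    return w


def _wave_extent(origin_um: float, amplitude_um: float, attenuation_um: float,
                 threshold_um: float, length_um: float) -> float:
    """Axial span (µm) over which A(x) = A0·exp(−|x−x0|/λ) ≥ threshold."""
    if amplitude_um < threshold_um:
        return 0.0
    if not math.isfinite(attenuation_um):
        return length_um
    reach = attenuation_um * math.log(amplitude_um / threshold_um)
    lo = max(origin_um - reach, 0.0)
    hi = min(origin_um + reach, length_um)
    return max(hi - lo, 0.0)


def simulate_diameter_field(vessel: VesselSpec, pacemaker: PacemakerSpec,
                            protocol: ProtocolSpec, dt: float = 0.025,
                            dx: float = 10.0, seed: int = 0,
                            amp_threshold_frac: float = 0.10,
                            ) -> DiameterField:
    """Simulate D(x, t) for a full protocol run.

    D(x,t) = EDD(x) − max_k A_k(x) · w(t − t_k − |x − x_k|/v), where
    contraction times ``t_k`` occur at regular intervals 60/frequency
    (optionally Gaussian-jittered), the amplitude decays exponentially
    from the origin with the attenuation length, and overlapping waves
    combine by the maximum constriction so the lumen never closes.

    ``amp_threshold_frac`` fixes the amplitude threshold (as a fraction
    of local EDD at the origin) used for the ground-truth conduction
    extent of each wave.

    Raises ``ValueError`` for non-positive or too-coarse ``dt``/``dx``,
    for stages too short to hold one full contraction cycle, and for
    amplitudes large enough to close the lumen.
    """
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 s to resolve systole")
    if dx > 20:
        raise ValueError("dx must be <= 20 µm to resolve conduction")

    rng = np.random.default_rng(seed)
    stages = protocol.windows()
    n_x = int(round(vessel.length_um / dx))
    x = (np.arange(n_x) + 0.5) * dx
    n_t = int(round(protocol.total_duration_s / dt))
    t = np.arange(n_t) * dt

    edd = vessel.edd_profile(x)
    constr = np.zeros((n_x, n_t))
    truths: list[WaveTruth] = []

    control = stages[0]
    for st in stages:
        eff = stage_pacemaker(pacemaker, st, control, protocol.rules,
                              vessel.length_um)
        if eff.frequency_per_min <= 0:
            continue
        period = 60.0 / eff.frequency_per_min
        if st.duration < period:
            raise ValueError(
                f"stage {st.name!r} ({st.duration} s) shorter than one "
                f"contraction cycle ({period:.1f} s)")
        speed_um_s = abs(eff.conduction_velocity_mm_s) * 1000.0
        x0 = float(np.clip(eff.origin_um, 0.0, vessel.length_um))
        amp_profile = eff.amplitude_um * np.exp(
            -np.abs(x - x0) / eff.attenuation_um)
        if np.any(amp_profile >= 0.95 * edd):
            raise ValueError(
                "contraction amplitude would (nearly) close the lumen; "
                "reduce amplitude_um or tone")
        onset_delay = np.abs(x - x0) / speed_um_s

        k = 0
        while True:
            t_k = st.t_start + period * (k + 0.5)
            if eff.jitter_sd_s > 0:
                t_k += rng.normal(0.0, eff.jitter_sd_s)
            k += 1
            if t_k >= st.t_end:
                break
            if t_k < st.t_start:
                continue
            # restrict to the time window this wave can influence
            t_lo = t_k
            t_hi = (t_k + onset_delay.max() + eff.systole_s
                    + 9.0 * eff.diastole_tau_s)
            j0 = max(int(t_lo / dt), 0)
            j1 = min(int(t_hi / dt) + 1, n_t)
            if j0 >= j1:
                continue
            tau = t[None, j0:j1] - (t_k + onset_delay)[:, None]
            w = _waveform(tau, eff.systole_s, eff.diastole_tau_s)
            np.maximum(constr[:, j0:j1], amp_profile[:, None] * w,
                       out=constr[:, j0:j1])

            thr = amp_threshold_frac * float(
                np.interp(x0, x, edd))
            sign = 1.0 if x0 <= vessel.length_um / 2 else -1.0
            truths.append(WaveTruth(
                t_start=float(t_k), origin_um=x0,
                velocity_mm_s=sign * abs(eff.conduction_velocity_mm_s),
                amplitude_um=float(eff.amplitude_um),
                attenuation_um=float(eff.attenuation_um),
                extent_um=_wave_extent(x0, eff.amplitude_um,
                                       eff.attenuation_um, thr,
                                       vessel.length_um),
                amp_threshold_um=thr, stage=st.name))

    diam = edd[:, None] - constr
    if np.any(diam <= 0):
        raise ValueError("overlapping waveforms drove diameter <= 0")
    d_cap = max(vessel.d_max((s.p_in + s.p_out) / 2) for s in stages)
    np.clip(diam, None, d_cap, out=diam)

    return DiameterField(
        diam=diam, dx_um=dx, dt_s=dt, stages=stages, ground_truth=truths,
        meta={"seed": seed, "vessel": asdict(vessel),
              "pacemaker": asdict(pacemaker),
              "rules": asdict(protocol.rules),
              "amp_threshold_frac": amp_threshold_frac})


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging geometry and grey levels for video rendering.

    Default pixel scale 0.98 px/µm matches typical videomicroscopy of
    these vessels; frame rates of 29–74 /s are realistic.  Bright walls
    bound a darker lumen on an intermediate background, 8-bit.
    """

    pixel_scale: float = 0.98       # pixels per µm
    frame_rate: float = 30.0        # frames per s
    image_height: int | None = None  # auto if None
    wall_px: int = 3
    wall_intensity: float = 220.0
    lumen_intensity: float = 40.0
    background_intensity: float = 130.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for v in (self.wall_intensity, self.lumen_intensity,
                  self.background_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must fit 8-bit range")
        if self.wall_px < 2:
            raise ValueError("walls must be at least 2 px thick")


def render_video(field: DiameterField, optics: OpticsSpec
                 ) -> tuple[np.ndarray, dict]:
    """Render a diameter field as an 8-bit grayscale frame stack.

    Each frame shows bright walls bounding a darker lumen whose
    per-column inner width equals the local diameter at the optics'
    pixel scale, centred on a fixed horizontal axis, with 1-px linear
    edge ramps (optical blur) and optional additive Gaussian noise.
    Returns ``(frames, metadata)`` with frames shaped
    ``(n_frames, height, width)``.
    """
    ps = optics.pixel_scale
    width = int(round(field.length_um * ps))
    half_max = float(field.diam.max()) * ps / 2
    need = int(math.ceil(2 * (half_max + optics.wall_px + 3)))
    height = optics.image_height if optics.image_height else need
    if 2 * (half_max + optics.wall_px) + 2 > height:
        raise ValueError(
            f"vessel ({2 * half_max:.0f} px + walls) wider than frame "
            f"height {height}")

    # frame times -> nearest field sample
    n_frames = int(round(field.n_t * field.dt_s * optics.frame_rate))
    frame_t = np.arange(n_frames) / optics.frame_rate
    col_idx = np.clip(np.round(frame_t / field.dt_s).astype(int),
                      0, field.n_t - 1)

    x_px = (np.arange(width) + 0.5) / ps
    centre = (height - 1) / 2
    dist = np.abs(np.arange(height) - centre)[:, None]   # (H, 1)

    rng = np.random.default_rng(optics.seed)
    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    for i, j in enumerate(col_idx):
        d_col = np.interp(x_px, field.x_um, field.diam[:, j])
        half = (d_col * ps / 2)[None, :]                 # (1, W)
        f1 = np.clip(dist - (half - 0.5), 0.0, 1.0)      # lumen -> wall
        f2 = np.clip(dist - (half + optics.wall_px - 0.5), 0.0, 1.0)
        img = optics.lumen_intensity * (1 - f1) + optics.wall_intensity * f1
        img = img * (1 - f2) + optics.background_intensity * f2
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    meta = {"pixel_scale_px_per_um": ps,
            "frame_rate_per_s": optics.frame_rate,
            "height_px": height, "width_px": width,
            "wall_px": optics.wall_px,
            "noise_sd": optics.noise_sd, "seed": optics.seed,
            "length_um": field.length_um,
            "stage_boundaries": [s.to_dict() for s in field.stages]}
    return frames, meta


def simulate_trace(field: DiameterField, x_um: float,
                   protocol: ProtocolSpec | None = None) -> DiameterTrace:
    """Diameter trace at axial position ``x_um`` with synchronized
    commanded-pressure columns (as recorded near the vessel midpoint in
    a pressure-myograph experiment)."""
    import pandas as pd

    d = field.column_at(x_um)
    t = field.t_s
    stages = field.stages or (protocol.windows() if protocol else [])
    p_in = np.zeros_like(t)
    p_out = np.zeros_like(t)
    for s in stages:
        m = (t >= s.t_start) & (t < s.t_end)
        p_in[m] = s.p_in
        p_out[m] = s.p_out
    df = pd.DataFrame({"time_s": t, "p_in_cmh2o": p_in,
                       "p_out_cmh2o": p_out, "diameter_um": d})
    return DiameterTrace(data=df, stages=list(stages), x_um=x_um,
                         meta={"dt_s": field.dt_s})
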