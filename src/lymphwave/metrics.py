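"""Contraction-cycle detection and lymphatic pump-function indices.

From a single-point diameter trace, each contraction cycle yields an
end-diastolic diameter (EDD, the pre-contraction maximum) and an
end-systolic diameter (ESD, the contraction minimum).  The standard
per-stage indices are

    AMP  = EDD − ESD                         (µm)
    normalized AMP = 100 · AMP / D_MAX       (% of passive diameter)
    EF   = (EDD² − ESD²) / EDD²              (ejection fraction)
    FREQ = contractions per minute
    FPF  = EF · FREQ                         (fractional pump flow, min⁻¹)

where D_MAX is the maximum passive (calcium-free) diameter at the
stage's intraluminal pressure.  A contraction-free segment is assigned
FREQ = 0 with no corresponding amplitude value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import DiameterTrace

__all__ = ["ContractionEvent", "IndexSet", "detect_contractions",
           "compute_indices"]


@dataclass(frozen=True)
class ContractionEvent:
    """One contraction cycle at a point."""

    t_edd_s: float
    t_esd_s: float
    edd_um: float
    esd_um: float
    period_to_next_s: float | None = None

    def __post_init__(self) -> None:
        if self.esd_um > self.edd_um:
            raise ValueError("ESD cannot exceed EDD")

    @property
    def amp_um(self) -> float:
        return self.edd_um - self.esd_um

    @property
    def ejection_fraction(self) -> float:
        return (self.edd_um ** 2 - self.esd_um ** 2) / self.edd_um ** 2


@dataclass(frozen=True)
class IndexSet:
    """Per-window contractile indices.  ``amp_um``, ``norm_amp_pct``
    and ``ef`` are NaN when the window has no contractions."""

    amp_um: float
    norm_amp_pct: float
    freq_per_min: float
    ef: float
    fpf_per_min: float
    d_max_um: float
    window_s: float
    n_events: int


def detect_contractions(trace: DiameterTrace, min_amp_um: float = 5.0,
                        refractory_s: float = 0.5,
                        smooth_halfwidth_s: float = 0.1
                        ) -> list[ContractionEvent]:
    """Detect contraction cycles in a diameter trace.

    Timing: the trace is Gaussian-smoothed with ``smooth_halfwidth_s``;
    local minima with prominence ``min_amp_um`` are ESD candidates and
    minima closer than ``refractory_s`` are merged keeping the deeper
    one.  Values: because heavy smoothing rounds off the sharp systolic
    trough, the ESD value is re-read from a lightly (one-sample)
    smoothed signal at the refined minimum, and the EDD value is the
    mean of the diastolic plateau around the preceding maximum —
    unbiased for both the asymmetric waveform and additive noise.
    Requires uniform sampling and a duration of at least two refractory
    periods.
    """
    d = trace.diameter.astype(float)
    t = trace.time
    if d.size == 0:
        raise ValueError("empty trace")
    dt = np.diff(t)
    if dt.size and (dt.max() - dt.min()) > 0.01 * np.median(dt):
        raise ValueError("trace sampling is not uniform")
    fs = 1.0 / trace.dt_s
    if trace.duration_s < 2 * refractory_s:
        raise ValueError("trace shorter than twice the refractory period")

    sigma = smooth_halfwidth_s * fs
    sm = gaussian_filter1d(d, sigma) if sigma > 0 else d
    light = gaussian_filter1d(d, 1.0)
    distance = max(int(round(refractory_s * fs)), 1)
    minima, _ = find_peaks(-sm, prominence=min_amp_um, distance=distance)
    if minima.size == 0:
        return []

    half = max(int(round(smooth_halfwidth_s * fs)), 2)
    n = d.size
    events: list[ContractionEvent] = []
    prev = 0
    for m in minima:
        # refine the trough on the lightly smoothed signal
        lo, hi = max(m - half, 0), min(m + half + 1, n)
        m_ref = lo + int(np.argmin(light[lo:hi]))
        esd = float(light[m_ref])
        # diastolic plateau before the trough
        seg = slice(prev, max(m_ref - half, prev + 1))
        j = prev + int(np.argmax(sm[seg]))
        plo, phi = max(j - half, 0), min(j + half + 1, n)
        edd = float(np.mean(d[plo:phi]))
        if edd - esd >= min_amp_um:
            events.append(ContractionEvent(
                t_edd_s=float(t[j]), t_esd_s=float(t[m_ref]),
                edd_um=edd, esd_um=min(esd, edd)))
        prev = m_ref
    for k in range(len(events) - 1):
        events[k] = ContractionEvent(
            t_edd_s=events[k].t_edd_s, t_esd_s=events[k].t_esd_s,
            edd_um=events[k].edd_um, esd_um=events[k].esd_um,
            period_to_next_s=events[k + 1].t_esd_s - events[k].t_esd_s)
    return events


def _window_pressure(trace: DiameterTrace, t0: float, t1: float) -> float:
    m = (trace.time >= t0) & (trace.time < t1)
    if not m.any():
        return float("nan")
    p = (trace.data.loc[m, "p_in_cmh2o"].to_numpy()
         + trace.data.loc[m, "p_out_cmh2o"].to_numpy()) / 2
    return float(p.mean())


def compute_indices(events: list[ContractionEvent], trace: DiameterTrace,
                    d_max_um: float | None = None,
                    passive_curve: tuple | None = None,
                    window: tuple[float, float] | None = None) -> IndexSet:
    """Pump-function indices over a time window.

    ``d_max_um`` may be given directly, or derived from a
    ``passive_curve`` = (pressures_cmh2o, diameters_um) table evaluated
    at the window's mean midpoint pressure (mean of P_in and P_out),
    linearly interpolated.  FREQ is the event count per window scaled
    to per-minute; a window with no events gets FREQ = 0 and missing
    (NaN) amplitude indices.
    """
    if window is None:
        t = trace.time
        window = (float(t[0]), float(t[-1]) + trace.dt_s)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")

    if d_max_um is None:
        if passive_curve is None:
            raise ValueError("provide d_max_um or a passive_curve table")
        p_mid = _window_pressure(trace, t0, t1)
        d_max_um = float(np.interp(p_mid, *passive_curve))
    if d_max_um <= 0:
        raise ValueError("D_MAX must be positive")

    sel = [e for e in events if t0 <= e.t_esd_s < t1]
    window_s = t1 - t0
    freq = 60.0 * len(sel) / window_s
    if not sel:
        return IndexSet(amp_um=math.nan, norm_amp_pct=math.nan,
                        freq_per_min=0.0, ef=math.nan, fpf_per_min=math.nan,
                        d_max_um=d_max_um, window_s=window_s, n_events=0)
    amp = float(np.mean([e.amp_um for e in sel]))
    ef = float(np.mean([e.ejection_fraction for e in sel]))
    return IndexSet(amp_um=amp, norm_amp_pct=100.0 * amp / d_max_um,
                    freq_per_min=freq, ef=ef, fpf_per_min=ef * freq,
                    d_max_um=d_max_um, window_s=window_s, n_events=len(sel))
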