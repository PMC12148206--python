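"""Quick-look figures for spatiotemporal maps and diameter traces."""

from __future__ import annotations

import numpy as np

from .core import DiameterTrace
from .stm import STM, BandMask


def plot_stm(stm: STM, bands: BandMask | None = None, events=None, ax=None):
    """Show an STM (outflow at top, time rightward), optionally with
    band outlines and fitted leading-edge lines coloured by direction
    (blue antegrade, red retrograde)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    extent = [0, stm.intensity.shape[1] * stm.dt_s, 0, stm.length_um / 1000]
    ax.imshow(stm.intensity, cmap="gray", aspect="auto", extent=extent,
              origin="upper")
    if bands is not None:
        ax.contour(bands.mask[::-1], levels=[0.5], colors="y",
                   linewidths=0.6, extent=extent, origin="lower")
    if events:
        for e in events:
            if e.velocity_mm_s is None:
                continue
            color = "tab:blue" if e.velocity_mm_s > 0 else "tab:red"
            ax.plot(e.onset_t_s, e.onset_x_um / 1000, ".", ms=1, color=color)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("axial position (mm, outflow top)")
    return ax


def plot_trace(trace: DiameterTrace, events=None, ax=None):
    """Diameter trace with detected EDD/ESD markers and stage shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    ax.plot(trace.time, trace.diameter, lw=0.8, color="k")
    for s in trace.stages:
        ax.axvspan(s.t_start, s.t_end, alpha=0.06,
                   color="tab:orange" if "step" in s.name else "tab:green")
    if events:
        ax.plot([e.t_edd_s for e in events], [e.edd_um for e in events],
                "^", ms=4, color="tab:green", label="EDD")
        ax.plot([e.t_esd_s for e in events], [e.esd_um for e in events],
                "v", ms=4, color="tab:red", label="ESD")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("diameter (µm)")
    return ax
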