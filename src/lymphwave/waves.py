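"""Per-band contraction-wave analysis.

For each contraction band in a thresholded STM: detect the leading
edge (earliest supra-threshold sample per axial row), fit a first-order
polynomial of onset time on axial position to obtain the slope and
conduction velocity, locate the origin (pacemaker site) as the row with
the earliest onset, assign a conduction-direction score in [−1, +1]
(+1 antegrade origin, −1 retrograde origin, fractional for interior
origins in proportion to the site), and measure the conduction extent
as the fraction of vessel length with supra-threshold contraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stm import STM, BandMask

__all__ = [
    "WaveEvent",
    "leading_edge",
    "fit_wave",
    "direction_score",
    "mean_direction",
    "conduction_extent",
    "analyze_bands",
    "link_interrupted",
]


@dataclass
class WaveEvent:
    """One analysed contraction wave."""

    label: int
    t_onset_s: float                 # earliest onset in the band
    onset_x_um: np.ndarray           # axial positions (inflow origin)
    onset_t_s: np.ndarray            # onset times per position
    slope_s_per_um: float | None
    velocity_mm_s: float | None      # signed; None if simultaneous
    origin_um: float
    score: float
    extent_fraction: float
    fit_r2: float
    flags: list[str] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return "censored" in self.flags

    @property
    def usable_for_direction(self) -> bool:
        return not self.censored and "ambiguous_origin" not in self.flags


def leading_edge(band_labels: np.ndarray, lbl: int, stm: STM
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Leading-edge onset times of one band component.

    For every axial row the component touches, the onset is the
    earliest supra-threshold sample of that row within the component
    (rows with gaps take their first onset).  Returns
    ``(x_um, onset_t_s, censored)`` with positions on the inflow-origin
    axis; ``censored`` is True when the band touches the start of the
    recording (its true onset is unobserved).
    """
    rows, cols = np.nonzero(band_labels == lbl)
    if rows.size == 0:
        raise ValueError(f"band label {lbl} not present")
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    urows, first = np.unique(rows, return_index=True)
    onset_cols = cols[first]
    censored = bool((onset_cols == 0).any())
    x_um = stm.row_to_x(urows)
    t_s = onset_cols * stm.dt_s
    order_x = np.argsort(x_um)
    return x_um[order_x], t_s[order_x], censored


def fit_wave(onset_x_um: np.ndarray, onset_t_s: np.ndarray,
             min_points: int = 5
             ) -> tuple[float | None, float | None, float, float]:
    """First-order polynomial fit of onset time on axial position.

    Returns ``(slope_s_per_um, velocity_mm_s, r2, origin_um)``.  The
    velocity is 1/slope converted to mm/s, positive toward the outflow
    end; a zero slope (simultaneous activation along the vessel) yields
    ``(0.0, None, r2, origin)``.  The origin is the position of the
    minimum onset time among band rows (median of ties), not the fit
    intercept.
    """
    x = np.asarray(onset_x_um, float)
    t = np.asarray(onset_t_s, float)
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} onset points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all onsets at the same position")

    slope, intercept = np.polyfit(x, t, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((t - pred) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    t_min = t.min()
    origin = float(np.median(x[t == t_min]))

    if slope == 0:
        return 0.0, None, r2, origin
    velocity = (1.0 / slope) / 1000.0     # s/µm -> µm/s -> mm/s
    return float(slope), float(velocity), float(r2), origin


def direction_score(origin_um: float, length_um: float,
                    end_zone: float = 0.15) -> float:
    """Conduction-direction score from the pacemaker site.

    Origins within ``end_zone`` of the inflow end score +1 (antegrade);
    within ``end_zone`` of the outflow end, −1 (retrograde); interior
    origins score fractionally, 1 − 2·x0/L, in proportion to the site.
    """
    if not 0 <= origin_um <= length_um:
        raise ValueError("origin outside vessel")
    if origin_um <= end_zone * length_um:
        return 1.0
    if origin_um >= (1 - end_zone) * length_um:
        return -1.0
    return 1.0 - 2.0 * origin_um / length_um


def mean_direction(scores) -> float:
    """Average the per-wave direction scores of one stage.

    E.g. 23 retrograde (−1) and 2 antegrade (+1) waves average to
    −0.84.  Raises on an empty list (stage has no scorable waves).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no uncensored waves: stage has no contractions")
    if np.any(np.abs(scores) > 1):
        raise ValueError("scores must lie in [-1, 1]")
    return float(scores.mean())


def conduction_extent(band_labels: np.ndarray, lbl: int, stm: STM) -> float:
    """Fraction of the vessel length with supra-threshold contraction.

    Counts the distinct axial rows with any supra-threshold pixel in
    the component, times dx, over L.
    """
    rows = np.unique(np.nonzero(band_labels == lbl)[0])
    return float(min(rows.size * stm.dx_um / stm.length_um, 1.0))


def analyze_bands(stm: STM, bands: BandMask, end_zone: float = 0.15,
                  min_points: int = 5, r2_bidirectional: float = 0.5
                  ) -> list[WaveEvent]:
    """Analyse every surviving band of a mask into :class:`WaveEvent`s.

    Events whose band touches the recording start are flagged
    ``censored`` and excluded from direction averaging.  Waves with
    onset spread under one frame over their extent are flagged
    ``simultaneous`` (velocity undefined); they keep an origin-based
    score only when the earliest-onset rows are a compact minority of
    the band, otherwise ``ambiguous_origin`` excludes them.  Interior
    origins with a poor linear fit are flagged ``bidirectional`` (the
    wave spread both ways from a mid-vessel pacemaker) and retain their
    fractional score.
    """
    L = stm.length_um
    events: list[WaveEvent] = []
    for lbl in range(1, bands.n_bands + 1):
        x, t, censored = leading_edge(bands.labels, lbl, stm)
        if x.size < min_points:
            continue
        flags: list[str] = []
        if censored:
            flags.append("censored")
        slope, velocity, r2, origin = fit_wave(x, t, min_points=min_points)

        t_min = t.min()
        tie = x[t == t_min]
        simultaneous = np.ptp(t) <= stm.dt_s
        if simultaneous:
            flags.append("simultaneous")
            velocity = None
            if tie.size * stm.dx_um > 0.5 * np.ptp(x):
                flags.append("ambiguous_origin")
        if (end_zone * L < origin < (1 - end_zone) * L
                and not simultaneous and r2 < r2_bidirectional):
            flags.append("bidirectional")

        score = direction_score(origin, L, end_zone)
        extent = conduction_extent(bands.labels, lbl, stm)
        events.append(WaveEvent(
            label=lbl, t_onset_s=float(t_min), onset_x_um=x, onset_t_s=t,
            slope_s_per_um=slope, velocity_mm_s=velocity, origin_um=origin,
            score=score, extent_fraction=extent, fit_r2=r2, flags=flags))
    events.sort(key=lambda e: e.t_onset_s)
    return events


def link_interrupted(events: list[WaveEvent], stm: STM,
                     max_dt_frames: float = 2.0, max_dx_rows: float = 2.0
                     ) -> list[tuple[int, int]]:
    """Identify pairs of bands that are one interrupted wave.

    Two components are linked when their time supports overlap and the
    velocity-extrapolated front of the earlier one aligns with the
    start of the other within ``max_dt_frames`` frames and
    ``max_dx_rows`` rows.  Linked pairs are reported alongside the
    individual events (both views are kept).
    """
    pairs: list[tuple[int, int]] = []
    for i, a in enumerate(events):
        if a.velocity_mm_s is None:
            continue
        v_um_s = a.velocity_mm_s * 1000.0
        for b in events[i + 1:]:
            t_overlap = (a.onset_t_s.min() <= b.onset_t_s.max() + max_dt_frames * stm.dt_s
                         and b.onset_t_s.min() <= a.onset_t_s.max() + max_dt_frames * stm.dt_s)
            if not t_overlap:
                continue
            # nearest approach of b's rows to a's extrapolated front
            x_b = b.onset_x_um
            t_pred = a.onset_t_s.min() + (x_b - a.origin_um) / v_um_s \
                if v_um_s > 0 else \
                a.onset_t_s.min() + (a.origin_um - x_b) / abs(v_um_s)
            dt_err = np.abs(b.onset_t_s - t_pred).min()
            gap_rows = min(abs(a.onset_x_um.min() - b.onset_x_um.max()),
                           abs(b.onset_x_um.min() - a.onset_x_um.max())
                           ) / stm.dx_um
            if dt_err <= max_dt_frames * stm.dt_s and gap_rows <= max_dx_rows + 1:
                pairs.append((a.label, b.label))
    return pairs


def events_table(events: list[WaveEvent], stage: str = "") -> pd.DataFrame:
    """Per-wave summary table (one row per wave)."""
    rows = []
    for e in events:
        rows.append({
            "stage": stage, "t_onset_s": e.t_onset_s,
            "origin_um": e.origin_um,
            "velocity_mm_s": np.nan if e.velocity_mm_s is None
            else e.velocity_mm_s,
            "score": e.score, "extent_fraction": e.extent_fraction,
            "r2": e.fit_r2, "flags": ";".join(e.flags)})
    return pd.DataFrame(rows, columns=[
        "stage", "t_onset_s", "origin_um", "velocity_mm_s", "score",
        "extent_fraction", "r2", "flags"])
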