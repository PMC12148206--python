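"""Shared data containers for the contraction-wave pipeline.

Axial convention used by every module: ``x = 0`` at the inflow (P_in)
cannula, increasing toward the outflow (P_out) cannula, in micrometres.
Antegrade conduction (the direction of normal lymph flow) is therefore
motion toward increasing ``x`` and carries positive velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "StageWindow",
    "WaveTruth",
    "DiameterField",
    "DiameterTrace",
]


@dataclass(frozen=True)
class StageWindow:
    """One protocol stage: name, time span and commanded pressures."""

    name: str
    t_start: float  # s
    t_end: float    # s
    p_in: float     # cmH2O
    p_out: float    # cmH2O

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class WaveTruth:
    """Ground truth for one simulated contraction wave.

    ``velocity_mm_s`` is signed on the shared axial convention
    (positive = antegrade, toward outflow).  ``extent_um`` is the axial
    span over which the local amplitude exceeds the recorded
    ``amp_threshold_um``.
    """

    t_start: float          # s, activation time at the origin
    origin_um: float        # x of the pacemaker site
    velocity_mm_s: float    # signed conduction velocity
    amplitude_um: float     # constriction amplitude at the origin
    attenuation_um: float   # exponential decay length (inf = none)
    extent_um: float        # supra-threshold axial span
    amp_threshold_um: float
    stage: str

    @property
    def antegrade(self) -> bool:
        return self.velocity_mm_s > 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if np.isinf(d["attenuation_um"]):
            d["attenuation_um"] = None
        return d


@dataclass
class DiameterField:
    """Internal diameter as a function of axial position and time.

    ``diam`` has shape ``(n_x, n_t)`` in µm with rows ordered inflow →
    outflow (ascending x).  This is the quantity a spatiotemporal map
    renders.
    """

    diam: np.ndarray                 # (n_x, n_t), µm
    dx_um: float
    dt_s: float
    stages: list[StageWindow] = field(default_factory=list)
    ground_truth: list[WaveTruth] | None = None
    infill_mask: np.ndarray | None = None   # True where values were infilled
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diam = np.asarray(self.diam, dtype=float)
        if self.diam.ndim != 2:
            raise ValueError("diam must be 2-D (n_x, n_t)")
        if self.dx_um <= 0 or self.dt_s <= 0:
            raise ValueError("dx_um and dt_s must be positive")

    @property
    def n_x(self) -> int:
        return self.diam.shape[0]

    @property
    def n_t(self) -> int:
        return self.diam.shape[1]

    @property
    def length_um(self) -> float:
        return self.n_x * self.dx_um

    @property
    def x_um(self) -> np.ndarray:
        """Axial sample centres, inflow origin."""
        return (np.arange(self.n_x) + 0.5) * self.dx_um

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt_s

    def column_at(self, x_um: float) -> np.ndarray:
        """Diameter trace at the axial sample nearest ``x_um``."""
        if not 0 <= x_um <= self.length_um:
            raise ValueError(
                f"x={x_um} µm outside vessel [0, {self.length_um}] µm"
            )
        i = int(np.clip(round(x_um / self.dx_um - 0.5), 0, self.n_x - 1))
        return self.diam[i]

    def flipped(self) -> "DiameterField":
        """Field with the axial axis reversed (inflow ↔ outflow)."""
        gt = None
        if self.ground_truth is not None:
            gt = [
                WaveTruth(
                    t_start=w.t_start,
                    origin_um=self.length_um - w.origin_um,
                    velocity_mm_s=-w.velocity_mm_s,
                    amplitude_um=w.amplitude_um,
                    attenuation_um=w.attenuation_um,
                    extent_um=w.extent_um,
                    amp_threshold_um=w.amp_threshold_um,
                    stage=w.stage,
                )
                for w in self.ground_truth
            ]
        return DiameterField(
            diam=self.diam[::-1].copy(),
            dx_um=self.dx_um,
            dt_s=self.dt_s,
            stages=list(self.stages),
            ground_truth=gt,
            infill_mask=None if self.infill_mask is None
            else self.infill_mask[::-1].copy(),
            meta=dict(self.meta),
        )


@dataclass
class DiameterTrace:
    """Diameter vs time at one axial location with synchronized pressures.

    Wraps a DataFrame with columns ``time_s, p_in_cmh2o, p_out_cmh2o,
    diameter_um`` sampled uniformly.
    """

    data: pd.DataFrame
    stages: list[StageWindow] = field(default_factory=list)
    x_um: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    REQUIRED = ("time_s", "p_in_cmh2o", "p_out_cmh2o", "diameter_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace missing columns: {missing}")
        t = self.data["time_s"].to_numpy()
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time column must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def diameter(self) -> np.ndarray:
        return self.data["diameter_um"].to_numpy()

    @property
    def dt_s(self) -> float:
        t = self.time
        if len(t) < 2:
            raise ValueError("trace too short to define a sampling interval")
        return float(np.median(np.diff(t)))

    @property
    def duration_s(self) -> float:
        t = self.time
        return float(t[-1] - t[0]) + self.dt_s

    def window(self, t0: float, t1: float) -> "DiameterTrace":
        """Sub-trace with t0 <= time_s < t1 (stage slicing)."""
        m = (self.data["time_s"] >= t0) & (self.data["time_s"] < t1)
        return DiameterTrace(
            data=self.data.loc[m].reset_index(drop=True),
            stages=[s for s in self.stages if s.t_start < t1 and s.t_end > t0],
            x_um=self.x_um,
            meta=dict(self.meta),
        )
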