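"""Spatiotemporal maps (STMs) and contraction-band segmentation.

An STM is an image of vessel diameter at every frame time (columns)
and every axial location (rows), with the **outflow end at the top**.
Contraction waves appear as slanted dark bands: intensity is inversely
related to constriction (darker bands = stronger contractions).
Thresholding the fractional constriction with a fixed, logged
threshold — never an eyeballed one — yields the band mask used for
conduction-direction and conduction-distance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.measure import label, regionprops

from .core import DiameterField

__all__ = ["STM", "BandMask", "build_stm", "threshold_bands",
           "rolling_baseline"]


@dataclass
class STM:
    """Spatiotemporal map of a diameter field.

    ``intensity`` is uint8, rows = axial position with the *outflow*
    end at row 0 (top), columns = time.  ``d_min``/``d_max`` allow the
    grey values to be inverted back to diameters.  ``diam`` keeps the
    underlying field (same row order) for quantitative work;
    ``baseline_edd`` is the per-row end-diastolic baseline estimate.
    """

    intensity: np.ndarray            # uint8, (n_x, n_t), outflow at top
    diam: np.ndarray                 # µm, same orientation
    baseline_edd: np.ndarray         # µm, per row
    dt_s: float
    dx_um: float
    d_min: float
    d_max: float
    orientation: str = "outflow_top"
    no_contractions: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def length_um(self) -> float:
        return self.n_rows * self.dx_um

    def row_to_x(self, rows: np.ndarray) -> np.ndarray:
        """Map STM row indices to axial position (µm, inflow origin)."""
        return (self.n_rows - 1 - np.asarray(rows) + 0.5) * self.dx_um

    def grey_to_diameter(self, grey: np.ndarray) -> np.ndarray:
        """Invert grey values to diameters (µm) using stored range."""
        if self.d_max == self.d_min:
            return np.full_like(np.asarray(grey, float), self.d_min)
        return self.d_min + np.asarray(grey, float) / 255.0 * (
            self.d_max - self.d_min)


@dataclass
class BandMask:
    """Thresholded constriction mask aligned to an STM.

    ``labels`` assigns a positive integer per surviving connected
    component (one candidate contraction band); 0 = background.
    """

    mask: np.ndarray                 # bool, same shape as STM
    labels: np.ndarray               # int32 component labels
    theta: float                     # fractional constriction threshold
    min_extent_frac: float
    min_duration_s: float
    n_bands: int

    def component_rows_cols(self, lbl: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.labels == lbl)


def rolling_baseline(diam: np.ndarray, dt_s: float, window_s: float,
                     q: float = 90.0) -> np.ndarray:
    """Per-row upper-percentile baseline of D over a sliding window.

    Implemented as a block-wise percentile (blocks of half the window)
    linearly interpolated between block centres: tracks slow tone
    changes across protocol stages while ignoring the brief systolic
    dips, at O(n) cost.  Returns an array the same shape as ``diam``.
    """
    n_x, n_t = diam.shape
    block = max(int(round(window_s / dt_s / 2)), 1)
    n_blocks = int(np.ceil(n_t / block))
    pad = n_blocks * block - n_t
    d = np.pad(diam, ((0, 0), (0, pad)), mode="edge") if pad else diam
    blocks = d.reshape(n_x, n_blocks, block)
    bvals = np.percentile(blocks, q, axis=2)          # (n_x, n_blocks)
    centres = (np.arange(n_blocks) + 0.5) * block
    t_idx = np.arange(n_t)
    out = np.empty_like(diam, dtype=float)
    for i in range(n_x):
        out[i] = np.interp(t_idx, centres, bvals[i])
    return out


def build_stm(field: DiameterField, baseline_window_s: float | None = None
              ) -> STM:
    """Render a :class:`DiameterField` as a spatiotemporal map.

    Rows are ordered outflow → inflow, top → bottom; grey level is the
    diameter linearly mapped over [min D, max D] so stronger
    constrictions are darker.  The per-row baseline EDD is a rolling
    90th-percentile of D over a window that should span at least two
    contraction periods (default 20 s).  A constant field (zero dynamic
    range) yields a valid STM flagged ``no_contractions``.
    """
    if field.infill_mask is not None and np.isnan(field.diam).any():
        raise ValueError("field contains NaN; infill before building an STM")
    window = 20.0 if baseline_window_s is None else baseline_window_s

    diam_top = field.diam[::-1].copy()     # outflow at top
    d_min = float(diam_top.min())
    d_max = float(diam_top.max())
    if d_max > d_min:
        grey = np.round((diam_top - d_min) / (d_max - d_min) * 255)
        flagged = False
    else:
        grey = np.full_like(diam_top, 128.0)
        flagged = True
    baseline = rolling_baseline(diam_top, field.dt_s, window)
    # no detectable dynamic range also when the max constriction is tiny
    if not flagged and (baseline - diam_top).max() < 1e-9:
        flagged = True

    return STM(intensity=grey.astype(np.uint8), diam=diam_top,
               baseline_edd=baseline, dt_s=field.dt_s, dx_um=field.dx_um,
               d_min=d_min, d_max=d_max, no_contractions=flagged,
               meta={"baseline_window_s": window,
                     "stage_boundaries": [s.to_dict() for s in field.stages]})


def constriction(stm: STM) -> np.ndarray:
    """Fractional constriction c(x,t) = (EDD(x) − D(x,t)) / EDD(x)."""
    base = stm.baseline_edd
    return (base - stm.diam) / np.where(base > 0, base, 1.0)


def threshold_bands(stm: STM, theta: float, min_extent_frac: float = 0.05,
                    min_duration_s: float = 0.2) -> BandMask:
    """Segment contraction bands by fixed fractional-constriction
    threshold.

    The mask is ``c(x,t) >= theta``; 8-connected components smaller
    than ``min_extent_frac`` of the vessel length in space or
    ``min_duration_s`` in time are removed as artefacts (e.g. the faint
    horizontal streaks left by residual fat/connective tissue in
    tracked recordings).  Each surviving component is one candidate
    contraction band.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must be in (0, 1)")
    c = constriction(stm)
    mask = c >= theta
    lab = label(mask, connectivity=2)
    min_rows = min_extent_frac * stm.n_rows
    min_cols = min_duration_s / stm.dt_s
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for p in regionprops(lab):
        r0, c0, r1, c1 = p.bbox
        if (r1 - r0) >= min_rows and (c1 - c0) >= min_cols:
            keep[p.label] = True
    lab = np.where(keep[lab], lab, 0)
    mask = lab > 0
    # relabel compactly, preserving time order of first appearance
    new = label(mask, connectivity=2)
    return BandMask(mask=mask, labels=new.astype(np.int32), theta=theta,
                    min_extent_frac=min_extent_frac,
                    min_duration_s=min_duration_s,
                    n_bands=int(new.max()))
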