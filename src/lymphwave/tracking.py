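"""Recover the internal-diameter profile per frame from video.

Per image column the two wall/lumen boundaries are located as the
extremal signed intensity gradients bracketing the lumen centreline,
with sub-pixel refinement by parabolic interpolation of the gradient
peak.  The vessel is assumed horizontal in the frame with fixed
geometry across a recording.  Faint residue streaks inside the lumen
(leftover fat/connective tissue) do not capture the edge search
because the wall/lumen gradients are the extremal ones per column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import DiameterField, StageWindow

__all__ = ["TrackingConfig", "track_frame", "track_stack", "FrameRejected"]


class FrameRejected(ValueError):
    """Raised when a frame has too few usable columns to track."""


@dataclass(frozen=True)
class TrackingConfig:
    """Settings for per-column wall-edge detection.

    ``roi`` is ((row0, row1), (col0, col1)) in pixels, end-exclusive;
    ``None`` uses the full frame.  ``invert`` flips the expected
    contrast (lumen brighter than walls).
    """

    roi: tuple[tuple[int, int], tuple[int, int]] | None = None
    smoothing_halfwidth: float = 1.0    # px, Gaussian sigma along rows
    gradient_min: float = 10.0          # grey-levels / pixel
    pixel_scale: float = 0.98           # pixels / µm
    invert: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be >= 0")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


def _resolve_roi(shape: tuple[int, int], cfg: TrackingConfig
                 ) -> tuple[int, int, int, int]:
    h, w = shape
    if cfg.roi is None:
        return 0, h, 0, w
    (r0, r1), (c0, c1) = cfg.roi
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"roi {cfg.roi} outside frame {shape}")
    return r0, r1, c0, c1


def _parabolic_shift(y0: np.ndarray, y1: np.ndarray, y2: np.ndarray
                     ) -> np.ndarray:
    """Sub-pixel offset of an extremum from three samples around it."""
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    return np.clip(shift, -1, 1)


def _edges_from_gradient(g: np.ndarray, centre: int, gradient_min: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Edge separation (px) per column from a gradient array.

    ``g`` is (..., rows, cols); the row axis is -2.  The upper wall
    edge is the most negative gradient at or above the centreline, the
    lower edge the most positive below it.  Returns
    ``(separation_px, valid)`` with NaN where no qualifying pair
    exists.
    """
    n_rows = g.shape[-2]
    top = g[..., :centre + 1, :]
    bot = g[..., centre:, :]
    i_top = np.argmin(top, axis=-2)
    i_bot = np.argmax(bot, axis=-2)

    def _take(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(arr, idx[..., None, :], axis=-2)[..., 0, :]

    g_top = _take(top, i_top)
    g_bot = _take(bot, i_bot)
    valid = (np.abs(g_top) >= gradient_min) & (np.abs(g_bot) >= gradient_min)

    it = np.clip(i_top, 1, top.shape[-2] - 2)
    ib = np.clip(i_bot, 1, bot.shape[-2] - 2)
    r_top = it + _parabolic_shift(_take(top, it - 1), _take(top, it),
                                  _take(top, it + 1))
    r_bot = centre + ib + _parabolic_shift(_take(bot, ib - 1), _take(bot, ib),
                                           _take(bot, ib + 1))
    sep = r_bot - r_top
    valid &= sep > 0
    return np.where(valid, sep, np.nan), valid


def _lumen_centre(sm: np.ndarray) -> int:
    """Fixed lumen centreline row: darkness-weighted centroid of the
    mean row profile over all columns (and frames, if 3-D).

    The centroid of below-midgrey darkness is robust to the flat
    intensity plateau inside the lumen, where a plain argmin would
    stick to the plateau's first row.
    """
    axes = tuple(i for i in range(sm.ndim) if i != sm.ndim - 2)
    profile = sm.mean(axis=axes)
    mid = (float(profile.min()) + float(profile.max())) / 2
    w = np.clip(mid - profile, 0.0, None)
    if w.sum() <= 0:
        return -1
    rows = np.arange(profile.size)
    return int(round(float((rows * w).sum() / w.sum())))


def track_frame(frame: np.ndarray, cfg: TrackingConfig) -> np.ndarray:
    """Per-column internal diameter (µm) of a single frame.

    Columns where no qualifying edge pair is found are NaN.  Raises
    :class:`FrameRejected` if more than half of the columns fail
    (e.g. an edge-free frame).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel 2-D")
    r0, r1, c0, c1 = _resolve_roi(frame.shape, cfg)
    sub = frame[r0:r1, c0:c1].astype(float)
    if cfg.invert:
        sub = -sub
    sm = gaussian_filter1d(sub, cfg.smoothing_halfwidth, axis=0) \
        if cfg.smoothing_halfwidth > 0 else sub
    centre = _lumen_centre(sm)
    if centre < 1 or centre > sm.shape[0] - 2:
        raise FrameRejected("no lumen found in frame")
    g = np.gradient(sm, axis=0)
    sep_px, valid = _edges_from_gradient(g, centre, cfg.gradient_min)
    if valid.sum() < 0.5 * sep_px.size:
        raise FrameRejected(
            f"only {int(valid.sum())}/{sep_px.size} columns have two "
            "qualifying wall edges")
    return sep_px / cfg.pixel_scale


def track_stack(frames: np.ndarray, cfg: TrackingConfig,
                frame_rate: float = 30.0,
                stages: list[StageWindow] | None = None,
                max_missing_frac: float = 0.20) -> DiameterField:
    """Track every frame and assemble a :class:`DiameterField`.

    Per-frame profiles are stacked; rejected frames and failed columns
    are infilled by nearest-neighbour interpolation **along time only**
    (never across columns, to avoid fabricating axial conduction), and
    the infill mask is kept on the result.  Aborts if more than
    ``max_missing_frac`` of all samples are missing.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, H, W) stack with >= 2 frames")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    r0, r1, c0, c1 = _resolve_roi(frames.shape[1:], cfg)

    sub = frames[:, r0:r1, c0:c1].astype(np.float32)
    if cfg.invert:
        sub = -sub
    sm = gaussian_filter1d(sub, cfg.smoothing_halfwidth, axis=1) \
        if cfg.smoothing_halfwidth > 0 else sub
    centre = _lumen_centre(sm)
    if centre < 1 or centre > sm.shape[1] - 2:
        raise ValueError("no lumen found in stack")
    g = np.gradient(sm, axis=1)
    sep_px, valid = _edges_from_gradient(g, centre, cfg.gradient_min)

    # whole-frame rejection: > 50% failed columns
    bad_frame = valid.sum(axis=1) < 0.5 * valid.shape[1]
    prof = sep_px.astype(float)
    prof[bad_frame, :] = np.nan

    missing = np.isnan(prof)
    frac = missing.mean()
    if frac > max_missing_frac:
        raise ValueError(
            f"{100 * frac:.1f}% of samples missing "
            f"(> {100 * max_missing_frac:.0f}%); tracking aborted")

    if missing.any():
        df = pd.DataFrame(prof)
        prof = (df.interpolate(method="nearest", axis=0,
                               limit_direction="both")
                  .ffill(axis=0).bfill(axis=0).to_numpy())

    diam = prof.T / cfg.pixel_scale      # (n_x, n_t), µm
    return DiameterField(
        diam=diam, dx_um=1.0 / cfg.pixel_scale, dt_s=1.0 / frame_rate,
        stages=list(stages) if stages else [],
        infill_mask=missing.T.copy(),
        meta={"tracking": {
            "smoothing_halfwidth_px": cfg.smoothing_halfwidth,
            "gradient_min": cfg.gradient_min,
            "pixel_scale_px_per_um": cfg.pixel_scale,
            "missing_fraction": float(frac)}})
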