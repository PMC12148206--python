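"""Readers, writers, run configuration and the umbrella pipeline.

Disk formats:

* diameter trace — delimited text with columns ``time_s, p_in_cmh2o,
  p_out_cmh2o, diameter_um`` (``#`` comments allowed);
* passive curve — two columns ``pressure_cmh2o, dmax_um``;
* diameter field — ``<stem>.npy`` matrix (position × time, µm) plus a
  JSON sidecar ``<stem>.json`` holding dt, dx, length, stage
  boundaries and (for synthetic fields) the ground truth;
* video — multi-page TIFF plus a JSON sidecar with pixel scale and
  frame rate.

Every pipeline output embeds the fully resolved configuration and a
checksum manifest, so a run is reproducible from its output directory
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import DiameterField, DiameterTrace, StageWindow, WaveTruth
from . import synthetic as syn
from .metrics import compute_indices, detect_contractions
from .stm import build_stm, threshold_bands
from .summary import partition_stages, record_to_dict, summarize_stages
from .tracking import TrackingConfig, track_stack
from .waves import analyze_bands, events_table, link_interrupted

__all__ = ["read_trace", "write_trace", "read_passive_curve",
           "save_field", "load_field", "write_video", "read_video",
           "RunConfig", "run_pipeline"]


def read_trace(path: str | Path) -> DiameterTrace:
    """Read a diameter trace from delimited text.

    Validates required columns and strictly increasing time; if the
    sampling jitter is below 1% of the median interval the time base is
    snapped to a uniform grid, otherwise the file is rejected.
    Comment lines prefixed with ``#`` are skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in DiameterTrace.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path.name}: time column not monotonic")
        med = float(np.median(dt))
        jitter = float(np.max(np.abs(dt - med)))
        if jitter > 0:
            if jitter > 0.01 * med:
                raise ValueError(
                    f"{path.name}: non-uniform sampling "
                    f"(jitter {jitter:.3g} s > 1% of dt {med:.3g} s)")
            df["time_s"] = t[0] + med * np.arange(len(t))
    return DiameterTrace(data=df[list(DiameterTrace.REQUIRED)].copy(),
                         meta={"source": str(path)})


def write_trace(trace: DiameterTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.data.to_csv(path, index=False, float_format="%.6g")
    return path


def read_passive_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Passive pressure–diameter table: columns pressure_cmh2o, dmax_um."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip() for c in df.columns]
    for c in ("pressure_cmh2o", "dmax_um"):
        if c not in df.columns:
            raise ValueError(f"passive curve missing column {c!r}")
    order = np.argsort(df["pressure_cmh2o"].to_numpy())
    return (df["pressure_cmh2o"].to_numpy(dtype=float)[order],
            df["dmax_um"].to_numpy(dtype=float)[order])


def _field_sidecar(field: DiameterField) -> dict[str, Any]:
    return {
        "dt_s": field.dt_s, "dx_um": field.dx_um,
        "length_um": field.length_um,
        "stage_boundaries": [s.to_dict() for s in field.stages],
        "ground_truth": None if field.ground_truth is None
        else [w.to_dict() for w in field.ground_truth],
    }


def save_field(field: DiameterField, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.json``."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    js = stem.with_suffix(".json")
    np.save(npy, field.diam)
    js.write_text(json.dumps(_field_sidecar(field), indent=1))
    return npy, js


def load_field(stem: str | Path) -> DiameterField:
    stem = Path(stem)
    diam = np.load(stem.with_suffix(".npy"))
    side = json.loads(stem.with_suffix(".json").read_text())
    stages = [StageWindow(**s) for s in side.get("stage_boundaries", [])]
    gt = None
    if side.get("ground_truth") is not None:
        gt = []
        for w in side["ground_truth"]:
            w = dict(w)
            if w.get("attenuation_um") is None:
                w["attenuation_um"] = math.inf
            gt.append(WaveTruth(**w))
    return DiameterField(diam=diam, dx_um=side["dx_um"], dt_s=side["dt_s"],
                         stages=stages, ground_truth=gt)


def write_video(frames: np.ndarray, meta: dict, stem: str | Path
                ) -> tuple[Path, Path]:
    """Multi-page TIFF + JSON metadata sidecar."""
    import tifffile

    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    js = stem.with_suffix(".meta.json")
    tifffile.imwrite(tif, frames)
    js.write_text(json.dumps(meta, indent=1))
    return tif, js


def read_video(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack (or AVI via imageio) and its JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        frames = iio.imread(path)
        if frames.ndim == 4:          # RGB video -> grayscale
            frames = frames.mean(axis=-1).astype(np.uint8)
    side = path.with_suffix(".meta.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return frames, meta


# ---------------------------------------------------------------------------
# run configuration and umbrella pipeline

@dataclass
class RunConfig:
    """All tunables of one reproducible pipeline run.

    No hidden defaults: the resolved configuration (and its hash) is
    embedded in every output.
    """

    out_dir: str = "lymphwave_run"
    seed: int = 0
    protocol: int = 2
    stage_duration_s: float = 60.0
    theta: float = 0.10
    min_extent_frac: float = 0.05
    min_duration_s: float = 0.2
    end_zone: float = 0.15
    mixed_band: float = 1 / 3
    drop_fraction: float = 0.2
    recovery_min_fraction: float = 0.75
    baseline_window_s: float = 20.0
    # contraction detector
    min_amp_um: float = 5.0
    refractory_s: float = 0.5
    smooth_halfwidth_s: float = 0.1
    # synthetic source (used when video is None)
    dt_s: float = 1 / 30
    dx_um: float = 10.0
    vessel: dict = dc_field(default_factory=dict)
    pacemaker: dict = dc_field(default_factory=dict)
    rules: dict = dc_field(default_factory=dict)
    render_video: bool = False
    optics: dict = dc_field(default_factory=dict)
    # video source (tracked instead of simulated when given)
    video: str | None = None
    tracking: dict = dc_field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            cfg = tomllib.loads(path.read_text())
        else:
            cfg = json.loads(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def resolved(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in self.resolved().items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run simulate/track → STM → wave analysis → metrics → summary.

    Writes the diameter field, per-wave table, per-stage summaries and
    a manifest with the resolved config and output checksums.  Fully
    deterministic given the seed.  Returns a result bundle with the
    vessel record, per-wave table and output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vessel = syn.VesselSpec(**config.vessel)
    protocol = syn.standard_protocol(
        config.protocol, config.stage_duration_s,
        rules=syn.ModulationRules(**config.rules))

    try:
        if config.video is not None:
            frames, vmeta = read_video(config.video)
            tcfg = TrackingConfig(**config.tracking)
            field = track_stack(
                frames, tcfg,
                frame_rate=vmeta.get("frame_rate_per_s", 1 / config.dt_s),
                stages=protocol.windows())
        else:
            pacemaker = syn.PacemakerSpec(**config.pacemaker)
            field = syn.simulate_diameter_field(
                vessel, pacemaker, protocol, dt=config.dt_s,
                dx=config.dx_um, seed=config.seed)
            if config.render_video:
                optics = syn.OpticsSpec(seed=config.seed, **config.optics)
                frames, vmeta = syn.render_video(field, optics)
                write_video(frames, vmeta, out / "video")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc

    save_field(field, out / "field")
    trace = syn.simulate_trace(field, field.length_um / 2, protocol)
    write_trace(trace, out / "trace.csv")

    try:
        stm = build_stm(field, baseline_window_s=config.baseline_window_s)
        bands = threshold_bands(stm, config.theta, config.min_extent_frac,
                                config.min_duration_s)
        events = analyze_bands(stm, bands, end_zone=config.end_zone)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'stm' failed: {exc}") from exc

    try:
        windows = partition_stages(trace, protocol)
        stage_events = {
            w.name: [e for e in events if w.t_start <= e.t_onset_s < w.t_end]
            for w in windows}
        all_contr = detect_contractions(
            trace, config.min_amp_um, config.refractory_s,
            config.smooth_halfwidth_s)
        passive = (np.asarray(vessel.passive_p_cmh2o),
                   np.asarray(vessel.passive_d_um))
        stage_indices = {
            w.name: compute_indices(all_contr, trace,
                                    passive_curve=passive,
                                    window=(w.t_start, w.t_end))
            for w in windows}
        record = summarize_stages(
            stage_events, stage_indices, vessel_id=out.name,
            protocol=config.protocol, mixed_band=config.mixed_band,
            drop_fraction=config.drop_fraction,
            recovery_min_fraction=config.recovery_min_fraction)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'summary' failed: {exc}") from exc

    cfg_hash = config.digest()
    waves_df = pd.concat(
        [events_table(evs, stage=name)
         for name, evs in stage_events.items()],
        ignore_index=True)
    waves_df["config_hash"] = cfg_hash
    waves_df.to_csv(out / "waves.csv", index=False, float_format="%.6g")

    rec = record_to_dict(record)
    rec["config"] = config.resolved()
    rec["config_hash"] = cfg_hash
    rec["interrupted_wave_links"] = [
        list(p) for p in link_interrupted(events, stm)]
    (out / "record.json").write_text(json.dumps(rec, indent=1))

    # 8-bit STM export
    import tifffile
    tifffile.imwrite(out / "stm.tif", stm.intensity)
    (out / "stm.json").write_text(json.dumps(
        {"dt_s": stm.dt_s, "dx_um": stm.dx_um,
         "orientation": stm.orientation, "d_min": stm.d_min,
         "d_max": stm.d_max, "theta": config.theta,
         "no_contractions": stm.no_contractions}, indent=1))

    outputs = ["field.npy", "field.json", "trace.csv", "waves.csv",
               "record.json", "stm.tif", "stm.json"]
    manifest = {"config": config.resolved(), "config_hash": cfg_hash,
                "outputs": {n: _sha256(out / n) for n in outputs
                            if (out / n).exists()}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {"record": record, "waves": waves_df, "field": field,
            "stm": stm, "bands": bands, "out_dir": out,
            "manifest": manifest}
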