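"""Per-protocol stage partitioning, vessel classification and
direction/index tabulation.

A protocol run has four stages (control, step 1, step 2, recovery),
each nominally 2 min.  Stage boundaries are taken from the
commanded-pressure change times.  Vessels are classified by their
predominant initial conduction direction (antegrade / retrograde /
mixed — mixed vessels are excluded from direction summaries) and by
flow-responsiveness (flow-induced inhibition of amplitude and/or
frequency).  A run is only valid for summary analysis if the recovery
amplitude reaches at least 75% of control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import DiameterTrace, StageWindow
from .metrics import IndexSet
from .synthetic import ProtocolSpec
from .waves import WaveEvent

__all__ = [
    "StageSummary", "VesselRecord", "partition_stages",
    "classify_initial_direction", "classify_flow_responsive",
    "tabulate_directions", "summarize_stages", "pressure_sweep_table",
]

STAGE_NAMES = ("control", "step1", "step2", "recovery")


@dataclass
class StageSummary:
    """Per-stage averages of all indices plus direction statistics."""

    stage: str
    indices: IndexSet | None
    mean_score: float | None
    n_antegrade: int
    n_retrograde: int
    n_fractional: int
    mean_extent: float | None
    extent_norm_to_control: float | None = None

    @property
    def n_waves(self) -> int:
        return self.n_antegrade + self.n_retrograde + self.n_fractional


@dataclass
class VesselRecord:
    """One vessel × protocol run, summarized per stage."""

    vessel_id: str
    protocol: int
    stages: list[StageSummary]
    initial_direction: str = "unclassifiable"   # antegrade/retrograde/mixed
    flow_responsive: bool | None = None
    recovery_valid: bool | None = None
    meta: dict = field(default_factory=dict)

    def stage_named(self, name: str) -> StageSummary | None:
        for s in self.stages:
            if s.stage == name:
                return s
        return None


def partition_stages(trace: DiameterTrace, protocol: ProtocolSpec,
                     pressure_tol: float = 0.05) -> list[StageWindow]:
    """Stage slices from the commanded-pressure change times.

    Boundaries are the samples where the (P_in, P_out) pair changes;
    slices are non-overlapping and cover the record.  The detected
    pressure sequence must match the protocol's (a missing recovery
    stage is tolerated and reported by omission); any other mismatch
    raises with the detected-vs-expected schedule.
    """
    p_in = trace.data["p_in_cmh2o"].to_numpy()
    p_out = trace.data["p_out_cmh2o"].to_numpy()
    t = trace.time
    change = np.flatnonzero((np.abs(np.diff(p_in)) > pressure_tol)
                            | (np.abs(np.diff(p_out)) > pressure_tol)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(t)]))
    detected = [(float(np.median(p_in[a:b])), float(np.median(p_out[a:b])))
                for a, b in zip(starts, ends)]
    expected = [(s[2], s[3]) for s in protocol.stages]

    if len(detected) not in (len(expected), len(expected) - 1):
        raise ValueError(
            f"pressure schedule mismatch: detected {detected}, "
            f"expected {expected}")
    for (dp_in, dp_out), (ep_in, ep_out) in zip(detected, expected):
        if abs(dp_in - ep_in) > pressure_tol or abs(dp_out - ep_out) > pressure_tol:
            raise ValueError(
                f"pressure schedule mismatch: detected {detected}, "
                f"expected {expected}")

    dt = trace.dt_s
    windows = []
    for (a, b), spec_stage in zip(zip(starts, ends), protocol.stages):
        windows.append(StageWindow(spec_stage[0], float(t[a]),
                                   float(t[b - 1]) + dt,
                                   spec_stage[2], spec_stage[3]))
    return windows


def classify_initial_direction(control_scores: Sequence[float],
                               mixed_band: float = 1 / 3) -> str:
    """Predominant conduction direction before the pressure/flow steps.

    Mean control score ≤ −mixed_band → retrograde; ≥ +mixed_band →
    antegrade; in between the vessel shows an approximately equal
    mixture of directions → 'mixed' (excluded from direction
    summaries).  Raises if the control stage has no scorable waves.
    """
    scores = np.asarray(list(control_scores), float)
    if scores.size == 0:
        raise ValueError("no control waves: vessel unclassifiable")
    m = scores.mean()
    if m <= -mixed_band:
        return "retrograde"
    if m >= mixed_band:
        return "antegrade"
    return "mixed"


def classify_flow_responsive(control: IndexSet,
                             flow_steps: Sequence[IndexSet],
                             drop_fraction: float = 0.2) -> bool:
    """Did imposed flow inhibit amplitude and/or frequency?

    Responsive when, during either flow step, AMP or FREQ falls to
    ≤ (1 − drop_fraction) of control, or contractions cease entirely.
    """
    if control.freq_per_min <= 0:
        raise ValueError("control stage has no contractions")
    thr = 1.0 - drop_fraction
    for step in flow_steps:
        if step.n_events == 0:
            return True
        if step.freq_per_min <= thr * control.freq_per_min:
            return True
        if (not math.isnan(step.amp_um) and not math.isnan(control.amp_um)
                and step.amp_um <= thr * control.amp_um):
            return True
    return False


def tabulate_directions(classes: Sequence[str]) -> dict:
    """Direction-class counts and the percentage retrograde.

    ``classes`` holds one entry per vessel test: 'antegrade',
    'retrograde' or 'mixed'.  The percentage retrograde uses the total
    including mixed vessels, rounded half-up to the nearest integer.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("no classified records")
    bad = set(classes) - {"antegrade", "retrograde", "mixed"}
    if bad:
        raise ValueError(f"unknown direction classes: {bad}")
    n_retro = classes.count("retrograde")
    n_ante = classes.count("antegrade")
    n_mixed = classes.count("mixed")
    n_total = len(classes)
    pct = int(math.floor(100.0 * n_retro / n_total + 0.5))
    return {"n_retrograde": n_retro, "n_antegrade": n_ante,
            "n_mixed": n_mixed, "n_total": n_total,
            "pct_retrograde": pct}


def _score_counts(events: Sequence[WaveEvent]) -> tuple[int, int, int]:
    n_a = sum(1 for e in events if e.score == 1.0)
    n_r = sum(1 for e in events if e.score == -1.0)
    n_f = len(events) - n_a - n_r
    return n_a, n_r, n_f


def summarize_stages(stage_events: dict[str, list[WaveEvent]],
                     stage_indices: dict[str, IndexSet],
                     vessel_id: str = "", protocol: int = 0,
                     mixed_band: float = 1 / 3,
                     drop_fraction: float = 0.2,
                     recovery_min_fraction: float = 0.75) -> VesselRecord:
    """Assemble a :class:`VesselRecord` from per-stage wave events and
    indices.

    Direction statistics use only uncensored, unambiguous waves.  The
    mean conduction extent of each stage is normalized to the control
    stage (control ≡ 1).  ``flow_responsive`` compares the step stages
    against control; ``recovery_valid`` requires recovery amplitude
    ≥ ``recovery_min_fraction`` of control.
    """
    summaries: list[StageSummary] = []
    control_extent = None
    for name in STAGE_NAMES:
        if name not in stage_events and name not in stage_indices:
            continue
        events = [e for e in stage_events.get(name, [])
                  if e.usable_for_direction]
        idx = stage_indices.get(name)
        n_a, n_r, n_f = _score_counts(events)
        mean_score = (float(np.mean([e.score for e in events]))
                      if events else None)
        mean_extent = (float(np.mean([e.extent_fraction for e in events]))
                       if events else None)
        if name == "control":
            control_extent = mean_extent
        summaries.append(StageSummary(
            stage=name, indices=idx, mean_score=mean_score,
            n_antegrade=n_a, n_retrograde=n_r, n_fractional=n_f,
            mean_extent=mean_extent))
    for s in summaries:
        if s.mean_extent is not None and control_extent:
            s.extent_norm_to_control = s.mean_extent / control_extent

    record = VesselRecord(vessel_id=vessel_id, protocol=protocol,
                          stages=summaries)

    control = record.stage_named("control")
    if control is not None and control.n_waves > 0:
        ctrl_scores = [e.score for e in stage_events.get("control", [])
                       if e.usable_for_direction]
        record.initial_direction = classify_initial_direction(
            ctrl_scores, mixed_band)

    steps = [record.stage_named(n) for n in ("step1", "step2")]
    step_idx = [s.indices for s in steps if s is not None and s.indices]
    if (control is not None and control.indices
            and control.indices.freq_per_min > 0 and step_idx):
        record.flow_responsive = classify_flow_responsive(
            control.indices, step_idx, drop_fraction)

    recovery = record.stage_named("recovery")
    if (control is not None and recovery is not None
            and control.indices and recovery.indices
            and not math.isnan(control.indices.amp_um)):
        if recovery.indices.n_events == 0:
            record.recovery_valid = False
        else:
            record.recovery_valid = bool(
                recovery.indices.amp_um
                >= recovery_min_fraction * control.indices.amp_um)

    record.meta.update({"mixed_band": mixed_band,
                        "drop_fraction": drop_fraction,
                        "recovery_min_fraction": recovery_min_fraction})
    return record


def pressure_sweep_table(trace: DiameterTrace, protocol: ProtocolSpec,
                         passive_curve: tuple,
                         min_amp_um: float = 5.0, refractory_s: float = 0.5,
                         smooth_halfwidth_s: float = 0.1):
    """Per-pressure contractile indices for an equal-pressure sweep.

    The pressure-range protocol (both pressures stepped together)
    reduces to repeated index computation per stage; returns one row
    per stage with the commanded pressure and the full index set.
    """
    import pandas as pd

    from .metrics import compute_indices, detect_contractions

    windows = partition_stages(trace, protocol)
    events = detect_contractions(trace, min_amp_um, refractory_s,
                                 smooth_halfwidth_s)
    rows = []
    for w in windows:
        idx = compute_indices(events, trace, passive_curve=passive_curve,
                              window=(w.t_start, w.t_end))
        rows.append({"stage": w.name,
                     "pressure_cmh2o": (w.p_in + w.p_out) / 2,
                     "amp_um": idx.amp_um,
                     "norm_amp_pct": idx.norm_amp_pct,
                     "freq_per_min": idx.freq_per_min,
                     "ef": idx.ef, "fpf_per_min": idx.fpf_per_min,
                     "n_events": idx.n_events})
    return pd.DataFrame(rows)


def record_to_dict(record: VesselRecord) -> dict:
    """JSON-serializable view of a vessel record."""
    out = {"vessel_id": record.vessel_id, "protocol": record.protocol,
           "initial_direction": record.initial_direction,
           "flow_responsive": record.flow_responsive,
           "recovery_valid": record.recovery_valid,
           "meta": record.meta, "stages": []}
    for s in record.stages:
        d = {"stage": s.stage, "mean_score": s.mean_score,
             "n_antegrade": s.n_antegrade, "n_retrograde": s.n_retrograde,
             "n_fractional": s.n_fractional, "mean_extent": s.mean_extent,
             "extent_norm_to_control": s.extent_norm_to_control,
             "indices": None if s.indices is None else asdict(s.indices)}
        out["stages"].append(d)
    return out
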