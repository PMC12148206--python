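# Methods

`lymphwave` implements the quantitative analysis of contraction waves in
collecting lymphatic vessels: from a videomicroscopy recording (or a
simulated diameter field) to a spatiotemporal map (STM), per-wave
conduction direction, velocity and distance, contractile pump indices,
and per-protocol stage summaries. This note documents the model behind
the synthetic generator, the algorithms of each analysis stage, the
tunable parameters and their defaults, the numerical choices, and the
known limitations.

## The measurement problem

Collecting lymphatic vessels pump lymph by spontaneous phasic
contractions. Each contraction starts as an action potential at a
pacemaker site and conducts along the vessel at roughly 10 mm/s,
producing a travelling wave of constriction. In a pressure-myograph
preparation the vessel (3–4.5 mm long, 160–180 µm internal diameter in
rat mesentery) is cannulated at both ends with independently commanded
pressures P_in and P_out (cmH2O), and the internal diameter is imaged
continuously (≈1 px/µm, 29–74 frames/s). Four-stage pressure protocols
(control, two steps, recovery; nominally 2 min per stage) probe how
pressure and imposed flow modulate pacemaking:

1. *imposed flow* — from 3/3 cmH2O, P_in raised and P_out lowered in two
   equal 1 cmH2O steps (midpoint pressure unchanged);
2. *elevated outflow pressure* — from 1/1 cmH2O, P_out raised in 2 cmH2O
   steps to 5 cmH2O;
3. *elevated inflow pressure* — from 1/1 cmH2O, P_in raised in 2 cmH2O
   steps to 5 cmH2O.

The analysis quantifies, per stage: wave direction (antegrade = toward
outflow, retrograde = toward inflow), conduction velocity, the fraction
of the vessel over which the contraction stays above a fixed strength
threshold, and the pump indices below.

## Axial convention

All modules share one axis: x = 0 at the inflow cannula, increasing
toward the outflow end, in µm. Antegrade waves have positive velocity.
STM images put the **outflow end at the top row**; the analysis code
converts between row order and the x axis internally.

## Synthetic vessel generator (`synthetic`)

The generator is a kinematic emulator, not a biophysical lymphangion
model: its purpose is to produce diameter fields with the statistical
structure the analysis assumes, under fully known ground truth.

Diameter field:

    D(x, t) = EDD(x) − max_k A_k(x) · w(t − t_k − |x − x_k|/v)

* `EDD(x)` — resting end-diastolic profile: a uniform baseline
  (default 160 µm) with Gaussian bulges (default +12 µm, σ = 120 µm) at
  evenly spaced valve sinuses.
* `w(τ)` — normalized contraction waveform: linear systolic rise to 1
  over `systole_s` (default 0.3 s) followed by exponential diastolic
  decay with `diastole_tau_s` (default 1.0 s), matching the rapid
  ejection / slower relaxation shape of a 1–3 s contraction cycle.
* `A_k(x) = A0 · exp(−|x − x_k|/λ)` — amplitude decaying from the
  pacemaker site with attenuation length λ (∞ = the wave conducts the
  full vessel at full strength). A0 defaults to 60 µm.
* Contraction times `t_k` are regular at 60/frequency s with optional
  Gaussian jitter — a timing model, deliberately not a pacemaker ODE.
* Waves spread from the origin at speed |v| in both available
  directions, so an interior origin produces a V-shaped (bidirectional)
  activation pattern.
* Overlapping waves combine by **maximum constriction**, not
  summation, so the lumen never closes; amplitudes that would close
  the lumen (A ≥ 0.95·EDD) are rejected.

Ground truth recorded per wave: activation time, origin, signed
velocity, amplitude, attenuation length, and the supra-threshold extent
from the closed-form inversion of the exponential decay,
`λ·ln(A0/threshold)` clipped to the vessel.

Pressure/flow modulation (`ModulationRules`) applies per-stage
multipliers that encode the qualitative physiology: higher mean
pressure raises contraction frequency (chronotropy; ×1.25 per cmH2O by
default) and lowers amplitude above 2 cmH2O (×0.88 per cmH2O); imposed
forward flow (P_in − P_out above control) lowers frequency (×0.80 per
cmH2O) and amplitude (×0.85 per cmH2O) and shortens the attenuation
length (×0.70 per cmH2O) in flow-responsive vessels; selective P_out
elevation (≥ 0.2 cmH2O) moves the pacemaker to the outflow end
(retrograde conduction) and selective P_in elevation moves it to the
inflow end. **The magnitudes are placeholders** chosen to produce
realistic-looking scenarios; no quantitative dose-response is implied,
and all of them are configurable and logged.

Rendering (`render_video`): 8-bit grayscale frames with bright walls
(≥ 2 px thick) bounding a darker lumen whose per-column inner width is
the local diameter at the pixel scale (default 0.98 px/µm), centred on
a fixed horizontal axis, 1-px linear edge ramps standing in for optical
blur, and seeded additive Gaussian noise.

## Diameter tracking (`tracking`)

Per image column, the two wall/lumen boundaries are the extremal signed
intensity gradients bracketing the lumen centreline, after Gaussian
smoothing along rows (σ default 1 px); sub-pixel positions come from
parabolic interpolation of the gradient peak. The centreline is the
darkness-weighted centroid of the mean row profile — robust to the flat
intensity plateau inside the lumen, where an argmin would stick to the
plateau's first row. Columns whose best gradients fall below
`gradient_min` (default 10 grey-levels/px) are missing; frames with
more than 50% missing columns are rejected whole.

Missing samples are infilled by nearest-neighbour interpolation **along
time only** — never across columns, which would fabricate axial
conduction — and the infill mask is preserved. Tracking aborts if more
than 20% of all samples are missing. The vessel is assumed horizontal
with fixed geometry; there is no rotation or drift estimation.

Faint horizontal residue streaks (leftover fat/connective tissue) do
not capture the edge search, because the wall/lumen gradients are the
extremal ones per column; any residual static per-row bias is absorbed
by the per-row baseline estimate in the STM stage, and transient thin
artefacts are removed by the band-size filters.

## Spatiotemporal maps and band segmentation (`stm`)

The STM is the diameter matrix with rows ordered outflow → inflow (top
→ bottom) and columns = frame times, linearly mapped to 8-bit grey over
[min D, max D] so stronger constrictions are darker; the stored range
inverts grey back to µm within one quantization step.

The per-row baseline EDD is a rolling 90th-percentile of D over a
window that should span **at least two contraction periods** (default
20 s). It is computed block-wise (blocks of half the window, linearly
interpolated between block centres), which is O(n) and equivalent to a
true rolling percentile for the slow tone drifts it must track. A
per-row (rather than global) baseline makes the constriction measure
invariant to static per-row offsets and to slow tone changes across
protocol stages.

Fractional constriction c(x,t) = (EDD(x) − D(x,t))/EDD(x) is
thresholded at θ (no default is silently assumed — θ is a required,
logged parameter; 0.10 is the conventional choice used throughout the
examples and tests). 8-connected components smaller than
`min_extent_frac`·L in space (default 0.05) or `min_duration_s` in
time (default 0.2 s) are removed as artefacts. Each surviving
component is one candidate contraction band. The threshold is defined
on *fractional* constriction; an absolute-µm threshold would be an
equally defensible convention, and the choice is documented rather than
asserted.

## Per-wave analysis (`waves`)

* **Leading edge** — per axial row intersecting a band, the onset is
  the earliest supra-threshold sample of that row within the component
  (rows with gaps take their first onset). Bands touching the start of
  the recording are censored: their onset is unobservable, and they
  are excluded from direction averaging.
* **Slope/velocity** — ordinary least squares of onset time on axial
  position (first-order polynomial). Velocity = 1/slope, converted to
  mm/s, positive toward the outflow end. A zero slope over the band
  (onset spread under one frame) is flagged *simultaneous*: velocity
  undefined.
* **Origin** — the position of the minimum onset time among band rows
  (median of ties), *not* the fit intercept, which is robust to
  curvature of the onset profile. Simultaneous waves keep an
  origin-based score only if the earliest-onset rows are a compact
  minority of the band; otherwise the origin is ambiguous and the wave
  is excluded from direction statistics.
* **Direction score** — +1 for origins within `end_zone` (default
  0.15) of the inflow end, −1 within `end_zone` of the outflow end,
  and the fractional value 1 − 2·x0/L for interior origins, in
  proportion to the site of origin. Nearly all real contraction waves
  initiate at or near a vessel end; the end-zone width is a
  convention, configurable and logged. Stage values are arithmetic
  means of per-wave scores (23 retrograde and 2 antegrade waves
  average to −0.84).
* **Bidirectional waves** — interior origin with a poor linear fit
  (r² < 0.5): flagged, fractional score retained. The fitted-slope
  sign and the origin rule can disagree for these; the score follows
  the origin, and both are reported.
* **Conduction extent** — distinct axial rows with any supra-threshold
  pixel in the component, × dx / L. Interrupted waves (components with
  overlapping time support whose velocity-extrapolated fronts align
  within 2 frames / 2 rows) are reported both separately and as linked
  pairs.

## Contraction metrics (`metrics`)

Cycle detection on the midpoint diameter trace: Gaussian smoothing
(halfwidth 0.1 s), local minima with prominence ≥ `min_amp_um`
(default 5 µm) as ESD candidates, minima closer than `refractory_s`
(default 0.5 s) merged keeping the deeper one, each paired with the
preceding diastolic maximum as EDD. Because heavy smoothing rounds the
sharp systolic trough of the asymmetric waveform, the ESD *value* is
re-read from a lightly (one-sample) smoothed signal at the refined
minimum and the EDD value is the mean of the diastolic plateau — both
choices are unbiased under additive noise and recover injected
amplitudes within 5% at ≤ 2 µm RMS noise.

Indices per window (default the whole stage; 2–5 min is the
conventional averaging period):

    AMP  = EDD − ESD                      µm
    normalized AMP = 100 · AMP / D_MAX    % of passive diameter
    EF   = (EDD² − ESD²) / EDD²
    FREQ = 60 · (event count) / window    min⁻¹
    FPF  = EF · FREQ                      min⁻¹

`D_MAX` is the passive (calcium-free) diameter at the stage's midpoint
pressure — the mean of P_in and P_out — linearly interpolated from the
caller's passive pressure–diameter table. FREQ is computed from the
event count per window rather than the mean inter-event interval so
that a contraction-free window is naturally assigned FREQ = 0 with no
corresponding amplitude value (the standard convention; amplitude and
EF are reported missing, not zero).

## Protocol summaries (`summary`)

Stage boundaries come from the *commanded*-pressure change times, not
measured pressures, to avoid transient artefacts at step changes. A
detected schedule must match the protocol (a missing recovery stage is
tolerated and reported); any other mismatch is an error listing
detected vs expected steps.

Vessel classification: predominant initial direction from the mean
control-stage score with `mixed_band` = 1/3 (a 2:1 majority required
for "predominant"; vessels inside the band show an approximately equal
mixture and are excluded from direction summaries).
Flow-responsiveness: amplitude or frequency during either flow step
≤ (1 − `drop_fraction`) of control (default 0.2), or complete
cessation of contractions. A run is only valid for summary analysis if
the recovery amplitude reaches ≥ 75% of control. Direction
tabulations report counts per class and the percentage retrograde over
the total including mixed vessels, rounded half-up.

## Validation design (`validation`)

The end-to-end check runs simulate → render → track → STM → analyze on
a 3 mm straight vessel (160 µm EDD) imaged at 0.4 px/µm and 30
frames/s, 6 s per run with one jittered wave — problem sizes chosen so
a full grid of 8 velocities × 20 seeds × 2 noise arms stays
desk-sized. Two noise arms share each rendered/tracked cell:
noise-free, and with 2 px of white tracking noise injected into the
tracked field.

The velocity/direction runs use non-attenuating waves (full-length
"solid bands", the common case in healthy vessels). With a fixed
constriction threshold, an axially decaying amplitude shifts the
threshold-crossing time differently at each position — a genuine
property of threshold-based front detection, not a tracking defect —
so conduction-extent recovery is checked in dedicated attenuated runs
(λ = 2 mm, A0 = 60 µm on 160 µm at θ = 0.10) against the closed form,
where extent does not depend on the fitted slope. The baseline window
for these single-stage runs spans the whole recording (two contraction
periods), making the per-row baseline a constant, as the baseline rule
requires.

What passing these tests does and does not show: the generator has
sharp two-level walls, additive Gaussian noise, a perfectly horizontal
vessel and an exactly exponential amplitude decay. Real recordings add
wall texture, residual-tissue occlusions, focus drift, axial buckling
at high pressure, and JPEG compression; tracking accuracy and the
attenuation closed form are not guaranteed under those conditions, and
the streak test covers only the static-residue case.

## Numerical choices and degenerate inputs

* Simulation requires dt ≤ 0.05 s and dx ≤ 20 µm; each stage must hold
  at least one full contraction cycle.
* The sampled waveform peak sits within one sample of the true peak;
  amplitude bookkeeping is exact to within A·(1 − e^(−dt/τ)).
* A constant field yields a valid, flagged ("no contractions") STM,
  not an error; θ outside (0,1) is an error.
* Degenerate wave fits (all onsets at one position, or fewer than 5
  points) are errors; zero-slope fits are flagged, not errors.
* Ties at the onset minimum take the median position.
* All randomness flows from explicit integer seeds; identical seeds
  give bit-identical fields, frames and output files. Pipeline outputs
  embed the resolved configuration and its hash (output paths
  excluded from the hash), plus SHA-256 checksums of every file.

## Limitations

* No biomechanical or electrophysiological lymphangion model: timing
  is a jittered clock, and pressure/flow modulation magnitudes are
  placeholder multipliers.
* No valve-flow simulation, no NO kinetics, no spectral STM analysis.
* The tracker assumes a horizontal, non-rotating vessel and was
  validated against this package's own renderer, not against any
  external tracking software.
* Group-level physiological comparisons (ANOVAs across vessels) are
  out of scope; the pipeline emits the per-vessel, per-stage layer
  beneath them.
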