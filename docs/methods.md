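# Methods

## Scope and model

`branchnet` models the assembly of branched microtubule (MT) networks of
the kind generated in *Xenopus* egg extract: a single de novo MT nucleates
at t = 0 and every subsequent MT is born on the lattice of an existing
mother, at a shallow angle, with the same polarity.  Geometry is 2-D and
MTs are straight rays.  Dynamic instability is not modeled explicitly in
the kinetic core: plus-ends advance at the constant *net* speed
`v_pe = 0.09 µm/s`, which subsumes growth, pause and catastrophe phases.
Motor-driven transport is excluded (the experimental reference condition
uses vanadate), so minus-ends and deposited sites are immobile.

Two branching mechanisms are implemented.

**Single-step model.**  Nucleators bind the lattice and fire instantly.
Per step Δt the number of new branches is Poisson with mean `k·Δt·L(t)`,
`L(t)` the total MT length at the start of the step; the branch origin is
uniform over the existing lattice.  Default `k = 1.1×10⁻³ µm⁻¹s⁻¹`.
On a single growing mother the first-branch hazard is `k·v_pe·t`, giving
the Rayleigh survival law `S(t) = exp(−k·v_pe·t²/2)` and mean mother
length `√(π·v_pe/2k) ≈ 11.3 µm`.  The fractional branch position along
the mother is exactly Uniform(0, 1).

**Sequential model.**  Inactive nucleation sites are deposited first
(Poisson, mean `k_bind·Δt·L(t)`, uniform over the lattice; default
`k_bind = 0.1 µm⁻¹s⁻¹`) and each unconsumed site later fires independently
with per-step probability `1 − exp(−k_branch·Δt)` (default
`k_branch = 2.5×10⁻⁴ s⁻¹`).  Sites are one-shot and fixed in arc position.
Because sites accumulate on old lattice while the plus-end keeps growing,
branching is biased toward the minus-end and a dead zone appears at the
plus-end.  The first-branch cumulative hazard has the closed form
`Λ(t) = k_bind·v_pe·(t²/2 − t/k_branch + (1−e^{−k_branch·t})/k_branch²)`;
the mean first-branch time (`≈ 124 s` at the defaults, hence mean mother
length `≈ 11.2 µm`) is obtained by quadrature of `exp(−Λ)`.  In the
slow-firing limit this reduces to the cubic law
`S(t) ≈ exp(−k_bind·v_pe·k_branch·t³/6)`.

Branch angles are Gaussian with mean 0° and sd 9°, the rotation sign a
fair coin.  The regime of the sequential model is controlled by the
dimensionless ratio `k_branch/√(k_bind·v_pe)`: for values ≪ 1 the
minus-end bias is maximal and insensitive to the rates; above ~100 the
model converges to the single-step (uniform) limit.  `parameter_scan`
traverses this ratio while co-varying `k_bind` and `k_branch` so that the
oracle mean first-branch length — the observable used to calibrate both
models — is held fixed.  The minus-end bias is summarized as
`1 − 2·mean(fraction)` (0 for a uniform profile, → 1 for extreme minus-end
concentration); this definition is isolated in `bias_statistic`.

**Numerical choices.**  Δt defaults to 1 s, guarded by the requirement
`Δt·k_branch < 0.1` and verified by a step-halving convergence test
(ensemble means move < 1%).  Event placement uses `L(t)` at the start of
the step; daughters materialize at the end of the step.  Ensemble
first-branch statistics use a vectorized implementation of the same
per-step recipe in which site firing delays are drawn geometrically —
exactly the waiting time of the per-step Bernoulli trials — so that
n = 4000 ensembles run in seconds; a KS test asserts agreement with the
full per-network simulator.  The asymptotic count growth rate is
`√(k·v_pe)` (single-step) and the positive root of
`λ²(λ+k_branch) = k_bind·k_branch·v_pe` (sequential), from the moment
ODEs of the branching process.

## Synthetic microscopy

The `imaging` module generates every input the analysis stages consume,
with exact ground truth.

* Tubulin stacks: each MT is splatted as a line of `tubulin_amp·pixel_size`
  au/px and blurred with a Gaussian PSF (kernel 30 px, σ 1.5 px); blur
  conserves total intensity to < 1%.  Tracking stacks default to 0.13 µm
  pixels at 2 s/frame; TPX2 stacks to 0.16 µm at 5 s/frame (two cameras).
* EB1 stacks: anisotropic Gaussian comets (FWHM 10 × 4 px) at each growing
  plus-end, long axis along the direction of motion.
* Illumination: Gaussian-beam fields, maximal at the image center.  For
  correction fixtures the beam sd is chosen ≫ the 30-px smoothing sigma of
  the flattening filter, as for a real sCMOS field of view — otherwise
  smoothing reshapes the beam itself.
* Photobleach traces: `amplitude·1[t < t_bleach] + offset + noise`.
* TPX2 kymographs: pixel p becomes lattice when the plus-end passes it;
  bound molecules then accumulate as cumulative Poisson counts with mean
  rate `rate·pixel_size` per second on top of a constant background
  (default 7 molecules), scaled by the single-molecule intensity
  (default 2700 au).

**Track fragmentation** (`fragment_tracks`) emulates how EB1 comet tracks
break in real data.  The trajectory is re-parametrized by arc length so
that a pause freezes the end (the comet vanishes, the lattice stays), a
catastrophe moves it back by 3–10 px before regrowth, and detection
dropouts remove single frames; Gaussian jitter (sd 1 px) is added to
visible detections.  Defaults: pause rate 0.01/frame with durations
2–15 frames, dropout 5%, catastrophe rate 0.001/frame (catastrophes are
rare in the vanadate condition).  Because any practical comet linker
closes very short gaps internally before a dedicated merge stage runs,
the fragmenter also closes gaps ≤ 5 frames within its search radius
(9 px forward, 4 px for stationary fluctuation) between segments of the
same trajectory, and reports only the remaining, harder gaps as ground
truth.  What this fixture does **not** emulate: comet intensity dimming
(comets are fully visible or fully absent), curved MTs, crossing-induced
detection merging, and camera-specific noise; merge results on real data
will additionally depend on those.

## Trajectory reconstruction

`temporal_median_filter` subtracts a 15-frame moving median per pixel
(truncated at the stack edges), removing static background while moving
comets survive.  `detect_comets` finds local maxima above 12 robust
(MAD-based) standard deviations with 5×5 centroid refinement.
`link_comets` is a deliberately simple greedy nearest-neighbor linker
(radius 9 px) with internal short-gap closing (≤ 5 frames) restricted to a
20° forward cone so that a comet appearing behind a tip — typically a
newborn branch — cannot capture the track; tracks shorter than 3 frames
with < 2 px displacement or < 1 px/frame net speed are discarded.  It is
a stand-in for a full-featured particle tracker, not a contribution.

**Greedy gap merging** (`merge_tracks`) is the heart of the tracking
module.  Track ends are processed in order of appearance; for each end i
every later-starting segment j within Δt_max = 30 frames is scored:

1. zero-frame gaps require end-to-start distance ≤ r_fluc = 3 px;
2. for long segments (> 3·r_fluc) the end of i must be i's closest
   approach to j's start (tolerance r_fluc for jitter); this applies to
   forward candidates only — a catastrophe's restart point is necessarily
   closest to an interior point of the track it continues;
3. forward gaps must satisfy the speed caps (≤ 2 px/frame, or ≤ 5 px/frame
   for gaps ≤ 6 frames), must not be nearly stationary beyond the pause
   window (≥ 0.5 px/frame once t_gap > 15 — a paused end is a pause, not
   a forward gap), and pass direction gates: 40° between dir_i, dir_j and
   the merged-track orientation when either segment is small, else a 20°
   forward cone.  Small segments borrow the merged-track orientation as
   their direction estimate, since a jittered 3-point direction is noise;
4. catastrophes (backward steps) are capped at 10 px with a 30° direction
   gate and a 90° fallback for the gap region;
5. pauses (d_ends ≤ r_fluc, ≤ 15 frames) need lattice evidence
   I_MT > I_cutoff/4 or d_ends ≤ 1 px;
6. all candidates with gap-chord tubulin evidence I_MT < I_cutoff are
   rejected, where I_cutoff = 20 × mean(processed tubulin)/8.8 px.

Survivors compete on `cost = 1.03^t_gap · D_min` and the minimum wins;
gaps are closed by linear interpolation and trajectories spanning < 6
frames are dropped.

On the default fixture (batches of 16–24 networks, ≤ 12 MTs each) the
merge recovers ~94% of ground-truth gap pairs (89–96% across independent
seed batches).  The residual false merges (~6% of all merges) are
dominated by one irreducible confusion: a
daughter MT born at a shallow angle (σ = 9°) within a few pixels and a few
frames of another track's broken end is geometrically indistinguishable
from a pause or catastrophe resumption — every gate (distance, direction,
lattice evidence) passes because the daughter genuinely sits on bright
lattice and grows nearly parallel to it.  Tightening any threshold, or adding
image evidence about whether the candidate start sits at a lattice tip,
trades these for missed true pairs roughly one-for-one (verified by A/B
over 88 networks), so the defaults keep the published gates as they are.

Lengths come from a smoothing spline fit to x(t), y(t) with end points
weighted 10×, reported as cumulative arc length (a raw polyline
overestimates lengths under jitter); net plus-end speed is final length /
lifespan, computed only for tracks spanning ≥ 50 frames.

## Architecture statistics

`assign_mothers` matches every non-first trajectory to the earlier
trajectory whose recorded lattice passes closest to the daughter's origin:
D_min to the closest point recorded before the daughter's birth, gates at
|angle| ≤ 150° and D_min, D_perp ≤ 20 px, backward extrapolation of the
daughter when the geometry is ambiguous (D_perp > 8 px or tracks within
9°), and rejection of candidates whose path the daughter crosses (tested
with shapely, ignoring the first 3 px where a daughter legitimately
touches its mother).  With > 3 surviving candidates the cost switches from
D_min to D_min + 1 − N_dot.  The signed angle between the daughter's
initial direction and the mother's local direction (total-least-squares
over ≤ 10 points) is the branch angle; on simulated ensembles the median
is ~0° and the sd ~9°, and ≥ 90% of daughters are assigned to the correct
mother.

First-branch profiles, plus/minus-end distance distributions (per-frame
self-normalized by the largest distance, frames filtered to a comet-count
window, default 10–55), percentile bootstrap CIs (default 1000 resamples,
95%), exponential count fits (`a·exp(kt)` via least squares with a
log-linear fallback) and two-sample KS self-similarity statistics follow
directly; all are seeded.

## Kinetics and intensities

Illumination correction divides the image by the blank smoothed with a
110-px/σ30 Gaussian, rescaled by the blank mean; pixels where the filtered
blank falls below 10⁻³ of its maximum are masked.  The tubulin profile is
measured inside the convex hull of the thresholded, morphologically closed
MT mask (the manual hull of an interactive workflow replaced by an
automated one): background (outside-hull mean) subtracted, intensities
normalized by the in-hull mean, distances by the largest in-hull distance.

The TPX2 binding rate is the per-pixel slope of intensity vs time from
lattice arrival (truth-supplied on fixtures, else first excursion above
background + 3 sd) to the trace end, converted as
`rate = slope / (single_intensity · pixel_size)`; windows shorter than
5 frames are skipped and a constant background offset cannot affect the
slope.  Single-molecule intensity comes from a least-squares Heaviside
fit (grid search over the step frame, closed-form level means); fits that
explain < 50% of the variance, or that a straight line explains at least
as well (a ramp has no step), are flagged and excluded from the ensemble.

## Pipeline

`run_pipeline` chains simulate → render → track → analyze from one YAML
config; every stage derives its seed deterministically from the global
seed and the stage name (CRC32), and the manifest records files, seeds and
a parameter hash, making reruns bit-for-bit reproducible.
`compare_models_report` emits first-branch tables for both models plus the
0.2× and 9.6× rate-rescaling scenarios; lowering either sequential rate
lengthens the naked-mother phase (branch distances grow), raising it
shortens them, and the non-dimensional fractional bias is invariant.

## Problem sizes

Default analysis runs use: 2000–4000 first-branch replicates per ensemble,
20–24 networks (≤ 20 MTs) for branch-angle recovery, 16–24 fragmented
networks for merge validation, 60 networks (≤ 60 MTs) per model for
self-similarity, 32 kymograph pixels × 120 frames, and 10 bleach traces ×
80 frames.  These sizes put Monte-Carlo error comfortably below each
check's tolerance while the full suite completes in minutes on one core.

## Known limitations

* Straight 2-D rays; no bending, no 3-D, no motor transport.
* The gap model's pauses and catastrophes warp individual trajectories;
  daughter birth positions still come from the constant-speed network, so
  mother lattice and daughter origin can disagree by a few pixels in
  heavily warped fixtures.
* Detection/linking are minimal stand-ins; quantitative tracking claims
  are made only for the merge and assignment stages, which are validated
  against truth tables.
* The false-merge floor from shallow-angle branch births (above) is a
  property of the data geometry, not of thresholds.
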