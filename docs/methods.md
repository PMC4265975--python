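# Methods

`sonasim` re-creates an MR-HIFU control tool-chain with physics
simulators standing in for the therapy hardware and the MR scanner.  This
note records the models, their assumptions, the default parameters and
why they were chosen, and what the synthetic setting does and does not
demonstrate.

## Protocol model and engine semantics

A treatment protocol is an ordered command list; each command carries an
order index and a scheduled time index.  The two are distinct: the order
index is what "step *n*" refers to in modifications, while the time index
is a not-before time on the device clock.  The engine dispatches commands
**strictly sequentially**: a command starts at the later of its time
index and the completion of its predecessor.  This makes the canonical
five-step protocols (move → pause → expose → off-marker → hold) well
defined even when the preceding step has a state-dependent duration
(e.g. a mechanical move whose travel time depends on the current
position).  Under sequential dispatch a `pause(wait_for_previous)` is a
pure synchronization point; an empty pause (no duration, no wait flag) is
an indefinite hold that only a modification with a goto releases — this
is how "remain inactive" final steps behave.

Modifications edit named attributes of named command positions and are
applied atomically; a command's *kind* cannot be changed, only its
parameters.  A goto rebases the target command's time index to the
current clock and restarts from there, stopping anything in flight.
Exposures may be open-ended (`duration = inf`) and stopped later by a
duration edit; the bundled applications use finite durations plus an
off-marker pause, which matches how the hardware protocols phrase
"turn off ultrasound after *t* seconds".

Device realism knobs (the hardware values are not public; both are
configurable): transducer translation at 5 mm/s and rotation at 10 deg/s,
so the moving/idle indicator has meaning; reflected power reported as a
fixed 2% of forward power.

Time is simulated: `advance_clock(dt)` is the only way time passes, which
makes every run exactly reproducible; a wall-clock driver wraps it for
interactive use.  The TCP layer (newline-delimited JSON, one thread per
session, a lock serializing engine access) adds transport without
changing semantics — a session's `execute` is byte-equivalent to the
in-process call.

## Acoustic model

The therapy array is a spherical-shell aperture, 120-mm radius of
curvature and 130-mm diameter, carrying 256 circular elements.  The real
element arrangement is proprietary, so elements are packed with a
deterministic sunflower spiral, area-uniform over the cap; the default
element radius fills 60% of the cap area (≈3.3 mm).  Layout, count and
radius are all pluggable.

Pressure fields use the Rayleigh–Sommerfeld integral over each element's
surface, treated as a flat disc in its tangent plane and discretized into
patches no larger than λ/4 at 1.5 MHz (0.25 mm in water) by default.
Field points closer to a patch than its equivalent radius use a
regularized distance.  Attenuation enters as exp(−αfd) with α in
Np/m/MHz.  The model is linear — no nonlinearity, cavitation, refraction
or cross-talk — and each run uses one homogeneous medium.

Verification anchors: the on-axis flat-piston closed form
|p| = 2ρcu₀|sin(k/2(√(z²+a²)−z))| (≤1% over z ∈ [a, 4F] with λ/8
patches; the λ/4 default is within ~1.6% at the closest point),
superposition exactness, and steering accuracy (field maximum within one
1-mm cell of the target for offsets ≤15 mm).

Steering phases are φ_n = k(|r_n − r_f| − F), wrapped to (−π, π].  Heat
deposition is Q = 2α_abs·|p|²/(2ρc), with the source velocity scaled so
the radiated power equals the commanded acoustic power via the
plane-piston radiation impedance, P = Σ_n (ρc/2)(a_n u₀)² A_n — the
surface-side statement of "intensity integrated over a plane just past
the aperture", exact in the same plane-wave approximation and simpler to
evaluate.

For application runs the heat source is computed on a local box
(half-width 8 mm) around each steered focal position with coarser patches
(3.5 mm, i.e. near-point elements) and cached per focal position: at
120 mm range and ≤9-mm steering the element directivity correction is
negligible compared to the phantom-property uncertainty, and this keeps a
100-focal-position run inside a desk-scale budget.

## Bioheat model

Pennes equation, explicit FTCS on a regular grid, Dirichlet
(baseline-clamped) boundaries by default — the grid edge is kept ≥14 mm
from any heated segment — and Neumann (insulated) boundaries for
conservation checks.  Stability dt ≤ dx²ρc/(6k) is enforced with
automatic sub-stepping (for the default phantom at 1-mm spacing the bound
is 1.2 s; the applications step at 0.05 s during exposures and 0.5 s
during cooling).  Focal trajectory hopping (25-ms dwell) is faster than
the solver step, so the deposition is time-averaged over the focal
points visited within each step, weighted by dwell time.

Default phantom thermal properties: k = 0.5 W/m/K, ρc = 3.6 MJ/m³/K,
no perfusion (a polymer phantom does not perfuse), baseline 20 °C.  The
small-animal demo uses w_b c_b = 2000 W/m³/K and T_a = 37 °C, a mid-range
muscle perfusion.

Verification anchors: point-impulse diffusion vs the Gaussian Green's
function (RMSE ≤2% of peak at σ = 3 dx), perfusion-only exponential
relaxation (≤0.5%), and closed-box energy conservation (≤1%, exact for
the replicated-edge Laplacian).

## Virtual scanner and phantoms

Images are sampled from 3-D phantom property maps by trilinear
interpolation onto the stack's pixel grid (FOV/matrix-defined, voxel
centres, LR increasing with +x; slices outside the phantom yield zeros).
Signal model per pixel: magnitude S_e = PD·exp(−TE_e/T₂(T)) with
T₂(T) = T₂₀ + slope·ΔT, and phase 2πγB₀αTE·ΔT·wf + drift, wrapped to
(−π, π], with complex Gaussian noise added before magnitude/phase
extraction.  The water fraction `wf` gates the PRFS phase: marrow
(wf ≈ 0.05) contributes essentially none, which is exactly why the T2
route exists for bone marrow.  There is no k-space model; ETL, NEX and
flip angle are metadata only, so passing tests say nothing about
k-space artefacts, partial-Fourier effects or motion.

B0 drift is injected as a spatially uniform phase, linear in dynamic
number, default 0.02 rad/dynamic.  That default suits slow dynamics
(e.g. 9.7-s two-echo imaging).  The pattern application images every
0.59 s, where 0.02 rad/dynamic would be ~2 rad/min — far beyond real
magnet drift and enough to alias between a letter's reference and its
last frames — so that application sets 0.001 rad/dynamic (~0.1 rad/min,
a typical drift rate).  Drift correction subtracts the mean over a
non-heated ROI (zeroth order, making the correction idempotent and the
corrected ROI mean exactly zero); a first-order planar fit is available
behind a flag.  Inter-dynamic phase unwrapping beyond ±π is out of
scope; the magnitude threshold (5% of the frame maximum) is the validity
mask.

Phantoms are generated programmatically: a homogeneous polymer block
(wf = 1, T₂ = 80 ms), a femur cross-section (marrow core with
T₂ = 100 ms and the calibrated 20 ms/°C slope, low-signal cortical
shell, aqueous soft tissue), and a small-animal soft-tissue block.
Values are representative literature numbers defining the synthetic
conditions, not measurements.

## Applications and problem sizes

*Element scan*: per channel, the five-step protocol (all off → element
*n* on → 1.8-s pulsed exposure → off marker → hold) runs; completion is
detected by polling the engine status at 0.05 s, the virtual hydrophone
burst is collected (40 cycles at 1.2 MHz, 64 averages reducing additive
noise by 1/√64), and a modification switches to the next element and
restarts at step 1.  The per-channel budget is 2.3 s (1.8 s exposure +
0.5 s transfer/modification overhead), so 256 channels take 588.8 s of
simulated time.

*'HIFU' pattern*: letters H, I, F, U in 18×18-mm boxes at 25-mm pitch
(the published figure shows the layout but no coordinates; with every
stroke an exact 18-mm segment the natural box is 18×18 mm), ten segments
steered in 2-mm steps at 25-ms dwell, 80 W for 8 s per segment, 60-s
cooling, one reference image per letter taken after the move completes.
The thermal grid is a 1-mm slab (121×49×17 voxels) around the pattern;
imaging is 224² at 0.59-s dynamics.  Standard tissue-mimicking acoustics
(0.5 dB/cm/MHz, 90% absorbed) give a peak rise of ~5 °C — the same mild
regime as the hardware experiment, though the absolute peak is only
qualitative: it depends on phantom absorption and on the 1-mm grid
under-resolving the ~1.1-mm focal width.  The run reports its own
simulated duration (~711 s: exposures + cooling + moves + pauses) rather
than forcing the hardware run's wall time, whose overlap of cooling and
transfer is not documented.

*Small-animal demo*: a 64-element, 50-mm-focus, 32-mm-aperture array at
3 MHz (a synthetic stand-in for the dedicated small-animal transducer;
the element split is a modelling convenience), 9-s exposure at 25 or
35 W, 0.35-s dynamics, drift-corrected PRFS in an annular reference
region.  The absorbed fraction (0.25) is calibrated so the 25-W, 9-s
exposure produces the mild-ablative focal rise this treatment operates
at (~18 °C in tissue truth; the 1-mm imaging grid reads a partial-volume
peak of ~8 °C): a homogeneous-medium model otherwise over-deposits,
since the real beam path is mostly water.

## Determinism and seeds

Every stochastic element (hydrophone noise, image noise) draws from a
`numpy` generator seeded from the run configuration; engines, solvers
and the scanner are seed-free and exactly deterministic.  Identical
inputs produce identical event logs, frames and reports.

## Known limitations

* Linear acoustics in one homogeneous medium; no aberration through
  bone, no standing waves, no element cross-talk.
* No thermal dose (CEM43), no temperature-dependent tissue properties,
  no damage model.
* No k-space simulation; imaging artefacts and true SNR behaviour of the
  sequences are out of scope.
* The byte-level wire protocol of the real scanner/therapy hardware is
  replaced by a defined JSON schema; only the behavioural contract
  (sessions, queues, status) is reproduced.
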