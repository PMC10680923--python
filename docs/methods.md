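# Methods

This note records the models behind `exotwin`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a user should know before trusting a result.

## Kinematics

Frame: right-handed, z up, delta robot mounted above the arena with arms
reaching down; the working volume is at negative z. Joint angle 0 puts a
proximal link horizontal and positive angles rotate it upward, so the
[−90°, +45°] limits span mostly-down postures.

Inverse kinematics is the geometric method: per arm, the loop closure
`r cosθ + h sinθ = k` in the arm plane has two elbow branches; the
knuckles-out branch (larger elbow radial coordinate `L_p cosθ`) is
selected deterministically, matching physical delta robots. Forward
kinematics intersects the three distal-link spheres (trilateration) and
keeps the lower-z branch. Round-trip identities hold to ≤1e−9 m/rad on
the knuckles-out manifold; configurations with an elbow folded the other
way are not fixed points of ik∘fk and are outside the working set.

The goniometer drops a₁ below the platform to the common rotation point
and extends a₄ to the virtual pivot. Rotation order: pitch (lateral
axis), roll, then yaw about the extension line itself; because yaw is the
final, pivot-aligned axis, pure yaw never translates the pivot — the
property that permits unlimited yaw through a slip ring. Which axis is
physically proximal is not public; this ordering is a documented
assumption.

The 6×6 Jacobian is assembled from the vector-method delta block (rows
`s_i/(s_i·∂E_i/∂θ_i)` of the inverse, inverted) and the analytic
pitch/roll swing of the a₄ extension; orientation rows are the identity.
Configurations with condition number above 1e6 are flagged singular.

The workspace sweep evaluates vectorized FK on a regular joint grid
(default 0.5°, ~2×10⁷ triples), bins reachable positions into 1 cm
voxels, and grows the largest centered axis-aligned square per z slice.
The 1 cm cell and the centered-square search quantize the answer to even
centimetres; at the default geometry the best slice (z ≈ −0.45 m) covers
an 80 cm square, the open-field design goal.

## Dynamics

The published delta-dynamics formulation is in an inaccessible
supplement, so the twin uses a transparent lumped point-mass surrogate
that preserves every testable mechanical invariant:

* each proximal link (uniform rod about its joint) is replaced by its
  exact two-point equivalent — 3m/4 at 2L/3 (the m/4 at the stationary
  joint drops out);
* distal links are split between elbow and platform ends (default 0.5);
* the platform lump carries the platform, platform-end distal masses, and
  the goniometer links rigid with it; the final link + payload (1–1.5 kg
  headstage) sit at the pivot, so goniometer motion reacts on the delta
  platform as an additional wrench.

Torques follow d'Alembert: τ = Σ_k J_kᵀ m_k (a_k + g ẑ). All Jacobians
are analytic except dJ/dt of the implicit platform Jacobian, which is a
single directional central difference (h = 1e−6); the energy balance
Σ τ_i q̇_i = dE/dt consequently holds to better than 1e−6 relative on
smooth trajectories, and the gravitational/velocity/acceleration
decomposition (ID(q,0,0); ID(q,q̇,0)−·; ID(q,q̇,q̈)−ID(q,q̇,0)) sums to the
total identically. Point masses carry no rotational inertia, so the yaw
joint sees zero torque in this model and is checked against its velocity
limit only; joint friction is deliberately unmodeled (the hardware aims
for low-friction joints, and friction would obscure the energy checks).
Default link masses (0.25/0.15/0.8/0.5 kg) are labeled estimates — only
feasibility checks, which have order-of-magnitude margin, depend on them.

## Admittance controller

Per mouse-relevant axis (forward x, lateral y, yaw):
dead-band → frame rotation → a = (F − c·v)/m → explicit-Euler double
integration at the 10 ms cycle → velocity saturation. Constants that are
hardware facts: dead-bands ±25 mN (x, y) and ±0.3 mN·m (yaw); forward
limit 0.16 m/s; 100 Hz cycle. The dead-band subtracts the threshold
outside the band (continuous; a raw-passthrough variant is switchable)
because a 25 mN output step would excite the loop — the hardware's
convention on this point is unspecified. The tuned virtual mass/damping
were published only graphically; the defaults m = 0.2 kg, c = 0.6 N·s/m
(yaw 0.002 kg·m², 0.006 N·m·s/rad) are *plausible-tuned* values chosen so
that F = ma + cv at the reported peak velocity (0.13 m/s) and
acceleration (0.35 m/s²) lands near the reported ~0.16 N peak force;
nothing that asserts hardware constants depends on them. The inner
velocity/position loops are abstracted as a first-order lag (5 ms
default) — they were tuned on hardware and their internals are out of
scope.

## Loop model and bandwidth

Apparent admittance: Y_app(s) = Y_virt(s)·D(s) with Y_virt = 1/(ms + c)
and D(s) = e^(−sT)/(1 + sτ), where T = 1.5·cycle + sensor delay (half a
cycle of zero-order hold plus a full-cycle computation latency — the
standard discrete-loop equivalence) and τ is the inner lag. Bandwidth is
the lowest frequency where the *complex deviation* |Y_app/Y_virt − 1|
reaches −3 dB (1/√2), bisection-refined to 1e−3 Hz. The deviation must be
measured on the complex error rather than on magnitudes alone: a pure
delay leaves |Y_app/Y_virt| = 1 at all frequencies yet is precisely the
degradation of interest. The complex-error criterion reduces to the
corner frequency for a delay-free lag and gives ω·T = 2 asin(1/(2√2)) for
a pure delay (bandwidth ∝ 1/T exactly); a magnitude-only variant remains
switchable for comparison. At the defaults (10 ms cycle, 10 ms sensor
delay, 5 ms lag) the bandwidth is ≈3.9 Hz, and cutting the cycle from
50 ms to 10 ms improves it ≈3-fold — consistent with the low-single-digit
Hz regime and the 2–4× cycle-time improvement reported for the hardware.

## Virtual mouse

Mice move in bouts. Each bout is a warped half-sine speed pulse
v(t) = V sin(π(t/T)^γ); the default γ = 2 places the acceleration peak at
≈61 % of peak speed, inside the 50–75 % range seen in freely behaving
animals' arching velocity-acceleration loops (γ = 1 recovers the
symmetric pulse with peak acceleration πV/T). Bout peak speeds are
log-normal (σ = 0.4) with μ solved in closed form from the truncated-mean
identity E[X | X > q₀.₈] = e^(μ+σ²/2)·Φ(σ−z₀.₈)/0.2 so the population
top-20 % mean equals 13 cm/s; bout durations are log-normal (σ = 0.15)
with the median (≈0.88 s) solved the same way so the implied acceleration
peaks (a_peak = κV/T, κ ≈ 2.28 for γ = 2) hit a top-20 % mean of
35 cm/s². Rest gaps are exponential (mean 1.2 s, min 0.3 s) and heading
changes are yaw half-sines placed in the gaps. The ~3 % shortfall the
analysis pipeline reads back (12.5 cm/s, 33.5 cm/s²) is filter
attenuation and discretization, well inside the published ±2 cm/s and
±10 cm/s² spreads.

The muscle model is a saturating proportional pull,
F = clip(k(v_intent − v_actual), ±0.25 N) per axis, with k = 15 N/(m/s)
representing a *trained* animal that tracks its intent tightly (the
regime in which published free and exoskeleton profiles became
statistically indistinguishable); closed-loop top-20 % force peaks come
out ≈0.13 N, inside the reported 0.16 ± 0.03 N band.

What the generator does **not** emulate: darting, rapid head turns,
grooming, posture, limb biomechanics, or any coupling between successive
bouts. Passing tests therefore certify the pipeline arithmetic and the
loop's statistical transparency for bout-structured locomotion — not
fidelity to any individual animal's trajectory.

## Arenas and tasks

Oval track: 27 cm straights joined by 33 cm-diameter semicircles, the
controlled path 3 cm inside the outer wall (semicircle path radius
13.5 cm). 8-maze: goal-arm circles with 18 cm/10 cm wall radii (8 cm
channel, centerline radius 14 cm) overlapping at a triangular turning
zone; the triangle (1 cm entry matching the 1 × 3 cm transition zone,
widening over 10 cm to span both arm entrances) and door/beam positions
are configuration values because the construction drawings are not
public. The turning-zone yaw limit ramps linearly ±20°→±45° over the
first 5 cm of penetration and clamps beyond; position limits scale the
proposed step magnitude (direction preserved, bisection to the boundary)
so the end position never leaves the polygon. The transition zone ramps
lateral/yaw velocity linearly to zero (cosine switchable). Goal-arm
trajectory control re-terminates the tangential admittance velocity onto
the arc (radial projection of the raw endpoint), eliminating secular
drift; the yaw servo acts on the *sine* of the heading error, computed in
vector form, so there is no ±π wrap discontinuity. The linearized path
coordinate runs entry → turning zone → chosen arm → return with half-open
bins.

## Behavior analytics

Kinematics: finite differences first, then a 13-point median and a
5-point mean filter, centered windows shrinking at the edges. Only
positive local maxima enter peak statistics (peaks are approximately
independent observations where raw samples are not); distribution
comparisons subsample to n = 100 peaks, seeded, without replacement.
The admittance plane F = ma + cv is fit by least squares without
intercept; all-zero acceleration falls back to the damping-only estimate
with mass flagged indeterminate. Turn scoring: incorrect iff the x-y path
deviates strictly >1 cm from the midline toward the side contralateral to
the turn. Tortuosity: arc-chord ratio (the source does not define it).
Gait: stance = filtered paw speed ≤0.5 cm/s for ≥3 samples (a literal
0 cm/s never survives tracking noise); step length = displacement between
stance centroids; cadence = inverse onset-to-onset interval (also
undefined at the source; documented here); exclusions: length outside
[1, 10] cm or duration <0.05 s. Clopper-Pearson intervals come from beta
quantiles with closed ends at k = 0 and k = n.

## Neural encoding

ΔF/F = 100·BP(F_cell − 0.7 F_neu)/mean(F_cell − 0.7 F_neu), with BP a
zero-phase 4th-order Butterworth 0.05–5 Hz band-pass. The denominator
uses the **raw** corrected-trace mean: band-passing removes DC, so the
literal filtered mean would be near zero and the ratio ill-defined. Any
unipolar transient loses roughly 2·f_hp·(area/peak) of its amplitude to
the 0.05 Hz edge, so amplitude recovery is quantitative only for
sub-second transients. Cell criteria (3·sd < max; sd < 50 %; max in
[20, 500] %; soma 20–400 px; aspect 0.7–1.4) treat "between" as inclusive.

Ephys: common mode = mean over in-brain channels, subtracted from all;
250 Hz 4th-order high-pass for waveform metrics; spike rates = counts in
50 ms windows stepped 20 ms (50 S/s), convolved with a Gaussian pulse of
260 ms width / 20 ms sd, z-scored per cell with zero-variance cells
flagged and kept as zeros.

Design matrix: one-hot half-open location bins along the linearized path
(reference configurations: 82 bins ≈ 2 cm for imaging, 196 ≈ 1 cm for
ephys — shipped as named configs because the two published counts imply
slightly different path coverages); diagonalized events expand each onset
into causal lagged indicators spanning 0–1 s at the activity sample rate;
continuous covariates are z-scored. Kernels: K = pinv(X)·Y (minimum-norm
under rank deficiency) or reduced-rank regression (OLS then SVD
truncation of the fitted values). Activity rows during stationarity
(speed <0.5 cm/s, the behavior module's convention) are zeroed before the
fit; kernel rows whose predictor column has <5 nonzero samples are zeroed
afterwards ("fewer than 5 instances" is interpreted as samples; a
distinct-visit variant would be a small change). Rank selection is left
to the user; full rank reproduces OLS.

Synthetic sessions: Gaussian place tuning over the linearized path
(centers evenly spread with jitter, widths 3–8 cm, peaks 2–10 Hz,
baseline 0.1 Hz), Poisson spiking, exponential calcium kernel (0.4 s),
optional white noise and shared neuropil. Recovery at zero noise is ≥95 %
of peak bins within 1 bin; under Poisson shot noise the achievable
accuracy is set by the ratio of shot-noise SE to the adjacent-bin tuning
contrast — with 1.2 cm bins and ≥4 Hz peaks a 400 s session keeps ≥80 %
of cells within 2 bins, degrading smoothly (not cliff-like) as peak rates
fall.

## Problem sizes in the shipped checks

Workspace sweeps use the full 0.5° grid (~2×10⁷ FK evaluations, ~10 s);
calibration checks use 10 × 600 s sessions at 100 S/s; encoding recovery
uses 400–600 s sessions at 15 S/s with 30–40 cells. These sizes give
Monte-Carlo errors comfortably below every tolerance asserted.

## Known limitations

* No forward dynamics, contact, structural compliance, or motor
  electrical models; the inner servo loops are a single lag.
* The goniometer axis ordering and the turning-zone polygon are
  documented assumptions where construction details are not public.
* The virtual mouse is a statistics-matching generator, not a behavioral
  model; it cannot validate perceptual claims about the interface.
* Spike inference, cell segmentation, and spike sorting are upstream:
  the neural module consumes traces and spike times.
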