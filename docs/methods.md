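# Model and methods

`striderswarm` is an individual-based model of a group of water striders
(*Gerris*) living on a bounded patch of water surface.  Individuals differ in
size, feed on discrete food portions that appear at random, grow or shrink
depending on their foraging success, enter the population as small recruits,
and leave it when their stored mass reaches either critical bound.  The
package also implements the measurement pipeline used to compare such a model
with field video of a natural population: a perspective camera-to-ground
transform, ellipsoid body-volume estimation, and two-sample
Kolmogorov–Smirnov comparisons of nearest-neighbor-distance (NND) and
body-volume histograms.

All quantities are in abstract model units of length, time, and mass; nothing
is calibrated to SI.

## Equations of motion

Each animal j with position r_j, velocity v_j and mass m_j obeys

    m_j dv_j/dt = F_j(r, t) − η_j v_j,

with surface drag η_j = η₀ m_j^β (β = 1/3: drag grows with leg span, i.e.
body length).  The force F_j is the sum of:

- **Pair repulsion** (private territory):
  f_jk = B_jk^rep (r_j − r_k) exp(−|r_j − r_k|²/(R_jk^rep)²).
- **Pair attraction** (tendency to aggregate): same Gaussian form with the
  opposite sign, amplitude B_jk^att < B_jk^rep and radius
  R_jk^att > R_jk^rep.
- **Soft boundary walls** at x = 0, Lx and y = 0, Ly, each pushing inward
  with magnitude B_bound exp(−d/R_bound) in the perpendicular distance d to
  that wall; walls are superposed independently.
- **Food attraction** toward every portion n:
  −B_food0 m_j^α (r_j − r_n) exp(−|r_j − r_n|²/R_food²), with α = 2/3
  (foraging strength grows like a cross-sectional area).
- **Wave of fear** (optional): during periodic active windows, the dangerous
  wall x = 0 emits B_wave m_j^α exp(−x/R_wave) directed into the arena, with
  R_wave far larger than R_bound so nearly everyone feels it.

Pair amplitudes scale with the mean of the two animals' strengths
(m^α each) and pair radii with the mean of their body-length scales
(m^β each), keeping every pair force symmetric so Newton's third law holds
exactly.  Because repulsion and attraction carry the same mass factors, the
pair equilibrium distance has the closed form

    R_min = sqrt( ln(B_rep/B_att) / (1/R_rep² − 1/R_att²) ),

which scales with body length (∝ m^β).  This closed form is the analytic
oracle used throughout the tests.

The m^α amplitude of the wave force is a deliberate design choice: combined
with η ∝ m^β it gives a terminal escape drift ∝ m^(α−β) = m^(1/3), so big,
strong animals flee faster and farther from the dangerous shore, which is the
behavior the model is meant to express.  A mass-independent wave amplitude
would predict the opposite ordering.

## Integration

The velocity update is the exact solution of the linear ODE above for a force
held constant across one step:

    v ← F/η + (v − F/η) · exp(−Δt·η/m),   r ← r + Δt·v.

This exponential (exact-for-constant-force) update is unconditionally stable
under strong damping and reproduces force-free velocity decay exactly at any
Δt, which is why the free-decay check passes at the default step size.  A
plain semi-implicit Euler division by (1 + Δt·η/m) was rejected because its
per-decade decay error (≈ Δt·η/2m ≈ 1% at the defaults) is visible at the
accuracy the package promises.

The wall is the stiffest feature of the force field: its decay length
R_bound must resolve the fastest approach speeds.  With R_bound = 0.4 and
the default rates, the wall is stable at Δt = 0.02 including fear-wave
arrivals; the wall exponent is additionally capped (at e⁴⁰) so that a
pathological excursion produces a huge finite restoring kick rather than a
floating-point overflow.  Validation warns when Δt exceeds 5% of the fastest
velocity-relaxation time m/η over the recruit-mass range.

## Per-step schedule and randomness

Each step runs a fixed phase order: forces → integration → consumption and
mass update → cull → recruitment → food deposition → recording.  The order
is part of the reproducibility contract (a newborn cannot die in its birth
step).  Every stochastic draw — birth trial, birth position, birth mass, food
trial, food position — comes from one `numpy.random.Generator` in that fixed
order, so a run is bit-identical given (parameters, seed) despite the
variable-length animal and food arrays.

## Demography and foraging

- **Recruitment**: one Bernoulli trial per step with probability p_birth; a
  success appends one animal at a uniform-random position, at rest, with mass
  uniform in [m_s − m_s_spread, m_s + m_s_spread].  The uniform distribution
  was chosen for bounded support and trivial verifiability; only "randomly
  distributed around a small starting mass" is prescribed by the model idea.
- **Removal**: any animal with m ≤ m_min (starved) or m ≥ m_max (full grown)
  is removed immediately; comparisons are inclusive.  Both exits are tallied
  separately but together form the cumulative "died/left" count, since the
  model does not distinguish them downstream.
- **Food**: one Bernoulli trial per step with probability p_food deposits a
  portion holding q_food mass units.  An animal within R_food_thres of a
  portion feeds from the nearest one (ties to the oldest portion) at rate
  dm/dt = μ m; co-feeders split the remainder in proportion to their demands,
  so portions are emptied exactly and removed.  Every animal then pays the
  metabolic cost λ m Δt.  With λ = 0, deposited food mass is conserved
  exactly (cumulative intake + remaining = cumulative deposits), a property
  the tests assert to rounding error.
- Assimilation efficiency is 1: intake mass equals body mass gained, since
  the model treats stored energy and mass as the same quantity.

## Default parameters

| parameter | value | units | why |
|---|---|---|---|
| Lx, Ly | 30 | length | ~100 animals at spacing R_min ≈ 2.2 fill about half the arena, leaving voids between groups |
| dt | 0.02 | time | ≤ 5% of the fastest m/η over recruit masses |
| B_repuls0, R_repuls0 | 2, 1 | — | unit-mass repulsion defines the length scale |
| B_attract0, R_attract0 | 0.05, 2 | — | weak, longer-ranged cohesion; see below |
| B_bound, R_bound | 20, 0.4 | — | ≫ pair repulsion, ≪ R_min; stable at dt=0.02 |
| B_food0, R_food, R_food_thres | 2, 3, 0.5 | — | detection range larger than R_min; contact-range feeding gate |
| η₀ | 1 | — | sets the time scale of velocity relaxation |
| μ, λ | 0.2, 0.01 | 1/time | growth bursts fast against a slow metabolic drain, so foraging luck drives the size distribution |
| m_s ± spread | 1 ± 0.2 | mass | recruits enter small, well inside (m_min, m_max) |
| m_min, m_max | 0.5, 4 | mass | an 8-fold mass span (2× body length) |
| p_birth, p_food, q_food | 0.02, 0.015, 2 | — | food input ≈ metabolic drain at N ≈ 150–200, giving a quasi-stationary population |
| class edges | thirds of [m_min, m_max] | mass | no intrinsic edges exist; equal thirds |
| N0 | 100 | — | starting group size |

No numeric values for amplitudes, radii, rates or thresholds are prescribed
by the model statement — only inequalities (B_att < B_rep, R_att > R_rep,
B_bound ≫ B_rep, R_bound ≪ R_min, B_wave > B_bound, R_wave ≫ R_bound) and
the exponents α = 2/3, β = 1/3.  The defaults above were fixed once by
requiring, in addition to those inequalities, that the model's qualitative
behaviors actually emerge: packed groups spaced near R_min, a stationary
size distribution independent of the initial one, small-class prevalence,
speed increasing with size, and wave-driven redistribution.  The attraction
amplitude is the most delicate of these: collective attraction from many
neighbors compresses packed groups below the *pair* equilibrium distance, so
B_attract0 must be small (0.05) and R_attract0 moderate (2) for the NND
histogram mode to sit at R_min.  Stronger or longer-ranged cohesion
(e.g. B_att = 0.5, R_att = 3) collapses groups to near-contact spacing.

The fear-wave scenario uses B_wave = 25, R_wave = 10, period 50, duration 5:
the wave just overpowers the wall (25 > 20) while keeping escape speeds
resolvable at Δt = 0.02, and its reach R_wave = Lx/3 spans the arena's
dangerous third.  The periodic (rather than random) schedule accumulates
statistics faster and is the regular forcing variant preferred for analysis.

## Observables

- **NND**: per-animal distance to its closest conspecific, via a k-d tree;
  an O(N²) brute-force oracle in the tests matches it exactly.
- **Histogram accumulators** keep the last snapshot's instant counts and the
  long-run sum; out-of-range observations go to a logged overflow counter,
  never silently dropped.  Default bin widths: R_min/10 for NND,
  (m_max − m_min)/40 for mass.
- **Velocity–mass curve**: mean |v| per mass bin, pooled over snapshots;
  empty bins are missing (NaN), not zero.  For the rank-correlation summary
  the package uses 10 coarse bins with ≥ 50 pooled observations each, since
  the 40-bin histogram resolution leaves single-animal tail bins too noisy
  for a stable rank statistic.
- **Time–volume map**: per-snapshot mass histograms stacked into a
  (time × mass) matrix (volume ∝ mass at unit density).
- **Density profiles**: time-averaged 1D histograms along x (the axis facing
  the dangerous wall) for food, all animals, and each size class.

## Field-data reduction

The camera transform maps sensor pixels to ground coordinates through the
tilt angle, horizontal view angle, height, and sensor resolution; the image
center maps to the field origin.  The package adds the exact inverse (needed
to synthesize test scenes), a local pixel-scale helper (ground distance per
horizontal pixel, by central differences), the two-axis ellipsoid volume
V = factor · (π/6) L W² (thickness taken equal to width; the unknown
thickness-to-width ratio is an explicit configurable factor), and a
two-sample KS test whose D statistic is evaluated exactly at the pooled
sample points, with the asymptotic p-value at effective size
n_a n_b/(n_a + n_b).

The synthetic-scene generator is a stand-in for processed field video: it
projects known ground-truth positions and body axes through the inverse
transform, adds Gaussian pixel noise to the centroids, and emits the
detection table (frame, x_c, y_c, len_px, wid_px) that the reduction
consumes.  It emulates perspective foreshortening and centroid noise; it
does not emulate segmentation errors, missed detections, occlusion, or
tracking ambiguity, so passing end-to-end tests demonstrate the *reduction
math*, not robustness to real detection failure modes.  The wave-speed
helper only checks a user-supplied calibration against the known 0.24 m/s
surface-wave speed; it does not fit the camera pose.

## Problem sizes used in tests and the acceptance script

Deterministic-law checks use one or two animals for a few hundred steps.
The spatial-order experiment runs N = 100 animals with demography and
foraging disabled for 30 000 steps (600 time units), folding the second half
into the long-run NND histogram.  The convergence experiment runs three
seeds × two extreme initial size distributions for 40 000 steps (800 time
units, several metabolic turnover times) and analyzes the final quarter; the
fear-wave experiment runs 30 000 steps and discards the first quarter as
transient.  These horizons were chosen as the shortest at which the
stationary phase is clearly established; the statistics they produce are
stable across seeds.

## Known limitations

- Frozen-pattern dynamics: without food events the model relaxes to a static
  packing; all sustained motion is driven by foraging and demographic events,
  so speed statistics are episodic and need heavy pooling.
- The stationary mass distribution has a flat top spanning ~3 histogram
  bins, so a single run's mode estimate can wander within that plateau;
  mode-based comparisons need the stated sampling horizons.
- No hydrodynamic or capillary-wave interaction between individuals, no
  spatial habitat structure, no sex or wing-morph differences, no discrete
  instars (size is continuous), and no explicit predation — death occurs
  only through the mass thresholds.
- The O(N²) force evaluation is comfortable at N ~ 10²–10³ but is the
  scaling bottleneck beyond that.
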