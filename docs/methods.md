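# Methods

## The model

`sidestep` simulates lateral (frontal-plane) bipedal locomotion with the
smallest mechanically meaningful architecture: three point masses — a trunk
and two feet — connected by three linear actuators (the two legs and one
inter-leg "hip" element that abducts/adducts the legs relative to each
other). Each actuator is paralleled by a passive spring-damper. The
equation of motion per mass is

    m ẍ = F_active + m g + F_passive

integrated with explicit (forward) Euler at a fixed step dt = 1e-5 s.
Forward Euler at this step was chosen over higher-order or adaptive
schemes for exact reproducibility: a run is a pure function of the
parameter set, and identical configurations produce bit-identical
trajectories.

Passive elements:

* **Leg springs** about the natural length L0 (the side of the initial
  equilateral trunk-feet triangle, ≈ 1.062 m for a 0.92 m trunk height),
  with a larger elastic coefficient during foot contact than in flight,
  and a piecewise-linear *extension limit*: beyond 1.1·L0 the elastic
  coefficient is multiplied by `ext_stiffen_mult` (force continuous at
  the breakpoint).
* **Inter-leg spring-damper** between the feet about the same natural
  length.
* **Ground**: unilateral vertical Kelvin–Voigt (spring-damper clamped to
  push only) plus horizontal viscous resistance while the foot is at or
  below ground level. A compliant ground is required because ground
  elasticity is one of the swept sensitivity parameters.
* **Auxiliary trunk tether**: when the horizontal trunk-foot distance
  drops below 0.15 m, a horizontal viscoelastic force pair pushes trunk
  and foot apart. This element prevents the trunk from falling over a
  foot and is the model's stand-in for everything a real body does to
  avoid stepping on itself.

All thresholds use strict inequalities. A trial fails when the trunk
drops below 0.4 m (roughly half the standing height; the failure
criterion is a package choice, as no such threshold is part of the
control law).

## Switching mobility control

The controller is distributed: each actuator i autonomously splits the
global desired velocity v_d (a horizontal vector, the only external
command) into a *local* part it can generate along its own unit axis
e_xi and a *residual* it asks the other actuators to produce:

    v_di^l = a_i (e_xi · v_d) e_xi ,    v_di^r = v_d − v_di^l

The inter-leg axis runs from the trailing to the leading foot; the leg
axes run from foot to trunk (so positive actuator action drives the
trunk). The discrete *switching coefficient* a_i ∈ {−1, −½, 0, ½, 1}
reassigns roles from contact phase and geometry:

* Legs: +1 (propulsion) when grounded; magnitude halves in flight (the
  leg cannot push on the ground); the sign flips to −1 when the trunk
  comes horizontally within 0.2 m of the *anterior* leg (balance, any
  phase), or when a *posterior* leg in flight is stretched beyond its
  natural length (swing — pull the leg back under the trunk). Balance
  takes precedence over swing; the flight ½-factor composes
  multiplicatively with the sign.
* Inter-leg: 0 whenever the posterior foot is grounded, ½ in double
  flight; the sign flips when the posterior leg is longer than 0.6·L0
  during double flight or anterior-leg support (again with the flight
  ½-factor), which swings the trailing leg toward the trunk.

A *mobility index*

    k_i = exp[ −4 ln2 (‖v_di^l − v_i‖² + ε₁) / (‖v_di^l‖² + ε₂) ]

(ε₁ = 1e−10, ε₂ = 1e−4) scores each actuator between immobile (→0) and
mobile (→1), where v_i is the actuator's currently produced velocity
(endpoint relative velocity projected on its axis). Actuators then mix
their own local command with the others' residual requests
v_dic_j = (e_xi · v_dj^r) e_xi, weighted by mobility:

    ṽ_di = Π_{j≠i} (1 − k_j) · v_di^l + Σ_{j≠i} k_j · v_dic_j
    F_ai  = G (ṽ_di − v_i),   G = 3000 kg/s

applied as an equal-and-opposite axial force pair, so control adds no
net force to the system. The first term is an inhibitory interaction
(mobile neighbours suppress an actuator's own agenda), the second an
excitatory one (mobile actuators absorb the others' residuals).

Interpretation choices the published rule set leaves open, fixed here
and isolated in the code: the leg axis direction (foot → trunk), the
endpoint pair of the inter-leg actuator (the two feet), the neutral
inter-leg baseline during trailing-leg stance, and the balance-over-
swing precedence.

## Default parameters

Masses, gravity, thresholds, gain, tolerances and dt are fixed by the
model definition (trunk 48 kg, g = 9.8 m/s², 0.15 m / 0.2 m / 1.1·L0 /
0.6·L0 thresholds, G = 3000 kg/s, dt = 1e−5 s). The viscoelastic
constants of legs, inter-leg, ground and tether — for which no reference
table is available — are a calibrated set: a randomized search followed
by coordinate-wise hill-climbing selected constants under which the
default model (a) locomotes laterally with an irregular step rhythm
(mean lateral speed ≈ 0.46 m/s and a leading-leg step interval
≈ 0.31 s over the stable-step window, as recomputed by
`scripts/acceptance.py`), (b) completes the direction change at *every*
one of the 101 switch timings of the evaluation grid (mean reaching
time ≈ 4.0 s, slower from trailing-leg-stance switches than from other
phases), and (c) keeps succeeding across most of the half-decade
parameter scalings (ground elasticity fully; leg elasticity and gain at
most timings). The calibration selected equal flight- and contact-phase
leg elasticity; the phase-dependent switch remains in the force law and
the contact coefficient is constrained to be at least the flight one.

The calibrated values are deliberately stored at full floating-point
precision in `params.py`. The closed-loop dynamics are chaotic — a
relative parameter perturbation of 1e−11 fully decorrelates a 20 s
trajectory — so rounding "for tidiness" would change every emergent
observable. Sweep-level means (over the 101-trial grid) are stable
functionals; single-trajectory quantities (a long run's mean speed or
step interval) vary more under parameter dialects and should be read as
order-of-magnitude-faithful rather than digit-faithful.

## Evaluation protocol

* **Straight sidestep**: from a motionless equilateral double-support
  stance (trunk at (0, 0.92) m), command v_d = +2 m/s. The commanded
  speed is intentionally not tracked closely — the trunk accelerates
  only around foot contact — and the emergent mean speed is well below
  the command, with a strongly irregular gait mixing single support,
  double support, repeated same-foot contacts and double flight. The
  leading foot steps roughly twice as often as the trailing foot. On
  the default set the gait is *metastable*: it steps steadily for about
  40 s (≈ 140 leading-foot steps, covering the full stable-step
  analysis window and every switch timing of the protocol) and then
  settles into a quiescent double-support stance, one of the closed
  loop's coexisting attractors.
* **Direction-change trial**: flip the command to −2 m/s at switch time
  t_s; the *reaching time* is the interval until the trunk has moved
  2 m (relative to its position at t_s) in the new direction. Failure =
  fall (trunk below 0.4 m) or a 15 s timeout.
* **Timing sweep**: 101 trials with t_s = 1.5 s + j·0.03 s. The grid
  start (1.5 s, after locomotion is established) and the grid size
  (101, matching the df = 99 statistics of the reference analysis) are
  package defaults and configurable. The pre-switch trajectory is
  shared across trials via snapshots, which is exact because the grid
  times land on integer step counts.
* **Trial grouping**: a trial is "trailing-leg stance" when the
  trailing (posterior w.r.t. the pre-switch direction) foot is grounded
  at the switch instant; the leading foot's state is ignored.
* **Sensitivity sweep**: leg elasticity, ground elasticity, and
  actuator gain are multiplied by 10^{−1}, 10^{−1/2}, 1, 10^{1/2}, 10,
  each rerunning a reduced 10-timing sweep (spacing 0.3 s) to keep the
  runtime proportionate.

## Gait metrics

Touchdown/liftoff events are crossings of z = 0 in the decimated log
(1 ms by default). A 20 ms debounce removes contact chatter: short
flight regimes are merged first (a bounce within the window does not
split a stance), then short contact regimes (a grazing tap is not a
step). A "step" is a touchdown; the k-th step's interval is the time
since touchdown k−1, and the stable-step analyses use steps 11–100
(90 intervals), skipping the start-up transient. Peak foot heights are
per-flight-phase maxima, optionally normalized by the 0.92 m trunk
height. Pearson correlation and the pooled-variance (Student) unpaired
t-test report df = n−2 and n1+n2−2 respectively; Student rather than
Welch matches the df = 99 convention of the reference analysis with a
101-trial sweep.

## Numerical and engineering notes

* The compiled engine (`engine.py`, numba) restates the controller and
  mechanics in scalar form; the test suite holds it to the plain-Python
  modules at 1e−12 relative tolerance step-by-step (measured agreement
  is bit-exact on the development platform).
* Summation orders are arranged so that the mirror map (x → −x, feet
  swapped, v_d negated) commutes with the full control+dynamics step to
  floating-point identity; the test suite asserts bitwise equality of
  mirrored trajectories.
* Contact classification uses z ≤ 0; the anterior/posterior tie at
  exactly equal foot stations is broken toward the desired direction,
  keeping the mirror property exact.
* Event-detection idempotence holds for decimation factors up to the
  debounce window; the default 1 ms log with a 20 ms debounce leaves a
  wide margin.

## Limitations

* 2D frontal plane only; no joints, muscle dynamics, or torque limits;
  the feet are point masses, so "foot contact" has no rollover.
* The ground has no static friction — horizontal anchoring is viscous —
  so grounded feet creep under sustained load. A consequence is a
  family of quiescent stance attractors: when the actuators' commands
  balance the passive springs between switching thresholds, the model
  freezes. Direction-change failures at scaled parameters, and the
  finite lifetime of the default straight gait, are this attractor
  capturing the dynamics.
* The parameter set is a calibrated stand-in for an unavailable
  reference table. On it, the direction change succeeds at all 101
  timings, the trailing-stance/other ordering of reaching times and
  the positive steps-vs-reaching-time correlations hold, and the
  stable-window speed and leading-leg step interval land within ~20%
  and ~3% of the reference operating point — but the absolute reaching
  times run ≈ 45% long, the stance-group contrast does not reach
  p < 0.05 with only 13 trailing-stance trials, the steps-reaching
  correlation is stronger than the reference value, and the
  step-interval coefficient of variation is just under 0.5. The
  acceptance suite encodes the reference values and leaves these checks
  failing rather than widening the bands.
* Reaching-time statistics are deterministic functionals of the timing
  grid, not random samples; the reported t/r statistics follow the
  reference analysis in treating trials as independent observations.
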