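# Methods

This document describes the model, the controller calibration, and the
evaluation protocols implemented by `elbowsim`.

## 1. Skeletal plant (`elbowsim.plant`)

A single hinge joint (elbow) moves a rigid forearm in the horizontal
plane; the shoulder is locked at 30°, so gravity does not enter the
dynamics (a constant bias torque can mimic a gravitational load). The
equation of motion is

```
(I + ΔI) · φ̈ = τ_muscle − (b + Δb) · φ̇ + τ_bias + τ_impulse(t)
```

with baseline inertia `I = 0.15 kg·m²` about the elbow (forearm plus
exoskeleton), intrinsic damping `b` (0 by default), and three perturbation
channels:

- **inertia change** `ΔI ∈ {+0.039, −0.032} kg·m²` (≈ ±25 % of baseline),
  active for the whole trial;
- **damping change** `Δb ∈ {+0.30, −0.31} N·m·s/rad`, whole trial;
- **torque impulse** `±5 N·m` for 37.5 ms, latched the first time the
  movement has traversed 25 % of its amplitude (located by integrator
  event detection, never re-fired).

The anatomical range 5°–150° is enforced; leaving it aborts the run with
`RangeError`.

## 2. Muscle-tendon units (`elbowsim.mtu`)

Each of the four muscles (monoarticular elbow flexor/extensor and two
"biarticular-like" muscles with shoulder-side paths) is a four-element
Hill-type model:

- **CE** — contractile element with a Gaussian isometric force-length
  curve (width 0.45) and a Hill hyperbola for shortening
  (`a_rel = 0.25`, `b_rel = 2.25 s⁻¹`), extended by an eccentric branch
  with force asymptote 1.5 ·F_iso and slope ratio 2 at zero velocity;
- **PEE** — parallel elastic element, quadratic above the optimal fiber
  length;
- **SEE** — serial elastic element, quadratic toe region (strain 0.015)
  then linear;
- **SDE** — serial damping element, linear in the fiber-vs-path velocity
  difference.

The contraction dynamics integrate the fiber length: the internal force
balance `F_CE(v_ce) + F_PEE = F_SEE + F_SDE` is solved for the fiber
velocity in closed form per Hill branch (a quadratic obtained by
substituting the hyperbola), with a bracketed root solve as fallback.

Activation dynamics follow the Hatze formulation,

```
ȧ = m · (a∞(u, l_n) − a),     a∞ = (a_min + (ρ l_n u)^ν) / (1 + (ρ l_n u)^ν)
```

with `m = 11.3 s⁻¹`, `ρ = 6`, `ν = 3`, `a_min = 0.005`.

## 3. Muscle routing (`elbowsim.routing`)

Muscle paths run from an origin on the upper arm to an insertion on the
forearm and may be deflected by ellipses rigidly attached to either
segment (an obstacle-set representation). The taut path is the shortest
non-penetrating route: straight segments meeting elliptical arcs at
kink-free tangency points, found via an affine map of each ellipse to a
circle. The construction yields per elbow angle:

- the path length `L(φ)` and moment arm `r(φ) = −dL/dφ` (computed from
  the moment of the applied tension and verified against the tendon
  excursion derivative);
- the muscle-bone contact force at each ellipse per unit tension;
- the net force on the forearm, from which the elbow constraint force
  follows by a Newton–Euler balance.

Because these quantities are smooth in `φ`, they are precomputed on a
241-point grid and sampled by cubic splines during integration
(`RoutingTables`).

## 4. Desired trajectories (`elbowsim.planner`)

Point-to-point movements (default 60°→90° in 0.6 s, onset at 0.1 s)
follow a minimum-jerk fifth-order polynomial with zero velocity and
acceleration at both ends; outside the movement window the desired state
holds the respective posture.

## 5. Controller (`elbowsim.controller`)

**Open loop.** Stimulation is piecewise constant in four phases
(posture hold, acceleration, braking, final hold). The holding and braking
stimulation sets are equilibrium-point solutions: minimize
`Σ (u_i − u_des)²` subject to zero net static joint torque (balancing any
bias torque) at the target posture, solved by SLSQP; `u_des = 0.1` for the
holds and `u_des = u_des_dec` (calibrated) for braking. During the
acceleration phase the agonists receive `u_acc` and the antagonists the
floor `u_min = 0.005`. The free parameters `(u_acc, t1)` — agonist level
and braking onset — are optimized to track the minimum-jerk trajectory
(squared RMS deviation over the movement window) by seeded Bayesian
optimization (Gaussian-process surrogate, Matérn 5/2 plus white noise,
expected-improvement acquisition) over `(log u_acc, t1)`, followed by a
deterministic compass-search polish. Rejected candidates (range violation)
receive a finite penalty to keep the surrogate conditioned. Typical
tracking accuracy: 0.7–1.1° RMS.

**Feedback.** Delayed proportional-derivative feedback on the fiber
length/velocity error of every muscle:

```
u_closed,i(t) = k_p/l_opt,i · (l_ce,i − λ_i)(t−δ) + k_d/l_opt,i · (v_ce,i − λ̇_i)(t−δ)
u_total = clip(u_open + u_closed, 0, 1)
```

The reference `(λ, λ̇)` is recorded from the calibrated unperturbed
open-loop movement. To make the unperturbed closed-loop replay exact
(`max|u_closed| < 1e-6`), the reference evaluates the recording's own
dense piecewise ODE solutions, and the recording run is segmented exactly
like the delayed replay.

**Integration.** The closed loop is a delay differential equation solved
by the method of steps: LSODA segments no longer than the delay, with the
delayed state read from the accumulated dense solution history. Output is
sampled at 1 kHz.

**Gain calibration.** `(k_p, k_d, u_des_dec)` are chosen by pattern
search to minimize a normalized squared deviation between the simulated
perturbation-induced changes of two kinematic metrics (early velocity and
dysmetria, four static perturbation types, differences to the unperturbed
trial) and a reference table of experimental summary statistics. The
shipped table is a **synthetic fixture** (the original experimental
statistics are not published numerically): it prescribes partial
compensation — roughly 60 % of the open-loop response magnitudes with the
experimentally reported signs. The acceleration phase is re-optimized per
braking level (memoized).

## 6. Protocols and metrics (`elbowsim.experiments`)

**Static protocol.** One unperturbed reference plus the four
inertia/damping trials, all with the identical calibrated controller
(perturbations are never compensated by re-calibration).

**Dynamic protocol.** Flexion (60°→90°) and extension (90°→60°)
movements under a −1.5 N·m bias torque, each with a with-movement and an
against-movement ±5 N·m, 37.5 ms impulse at 25 % traversal. The open-loop
pattern is recalibrated per direction under the bias.

**Metrics** (per trial):

- *early velocity*: signed angular velocity 155 ms after the speed first
  exceeds 10 °/s;
- *dysmetria*: position at trial end (1 s) minus position at the first
  correction (speed < 2 °/s, or acceleration < 2 °/s² once the speed is
  below the onset threshold; both evaluated after the peak speed);
- *velocity quotients*: velocity at impulse onset over velocity 37.5 ms
  and 100 ms later;
- *feedback contribution*: maximum over samples and muscles of
  `|u_closed| / max(u_total, 1e-3)` with the total after clipping.

**Torque-driven comparison model.** An ideal torque source replays the
active joint torque recorded from the calibrated muscle run, optionally
with joint-angle PD feedback (delay 100 ms, `k_p = 15 N·m/rad`,
`k_d = 0.5 N·m·s/rad`). The *preflex* analysis compares the velocity
change across an identical impulse window: the muscle model resists more
(|Δω| smaller) than the torque model, whose response matches
`impulse·duration / inertia` within 1 %.

## 7. Known deviations

- The feedback-contribution targets and one impulse-response bracket fail
  honestly; see README → Limitations for the analysis.
- The experimental reference table for gain calibration is synthetic
  (see §5); all other constants are either published values or documented
  design decisions in the configuration.
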