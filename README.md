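# elbowsim

Neuro-musculoskeletal simulation of goal-directed elbow movements under
mechanical perturbations.

A one-degree-of-freedom arm (shoulder locked at 30°, movements in the
horizontal plane) is driven by four Hill-type muscle-tendon units routed
around deflection ellipses. Movements are controlled by an intermittent
open-loop controller — a triphasic stimulation pattern built from
equilibrium-point stimulation sets plus an optimized acceleration phase —
with optional time-delayed proportional-derivative muscle-spindle feedback
on fiber length and velocity. The package reproduces two perturbation
protocols (static inertia/damping changes and dynamic torque impulses),
evaluates kinematic response metrics, and compares against an idealized
torque-driven model.

## Quick start

```bash
# calibrate the controller (open-loop pattern + feedback gains, 25 ms delay)
elbowsim calibrate --out runs/calib --delay 25 --seed 1

# unperturbed movement, open- or closed-loop
elbowsim simulate --out runs/sim --variant open --seed 1

# one perturbation protocol (static = inertia/damping, dynamic = impulses)
elbowsim perturb --out runs/static --protocol static --variant closed \
    --delay 25 --seed 1

# metrics from a saved time series
elbowsim evaluate runs/sim/run.csv

# parameter sweep over any scalar config field
elbowsim sweep --out runs/sweep --param geometry.forearm_inertia_about_elbow \
    --values 0.10,0.15,0.20

# the whole study for one delay: calibration, all eight perturbation runs,
# torque-model baselines, metrics table, property checklist
elbowsim reproduce-all --out runs/repro25 --delay 25 --seed 1
```

All commands accept `--config <yaml>` (defaults to the shipped
configuration; `elbowsim.config.save_config` writes a template) and refuse
to overwrite existing outputs unless `--overwrite` is given. Every output
directory receives the resolved configuration and a `manifest.json`
recording the invocation.

From Python:

```python
from elbowsim import default_config
from elbowsim.simulate import ModelContext
from elbowsim.study import run_full_study

study = run_full_study(default_config(), delay=0.025, seed=1)
print(study["checklist"], 100 * study["max_contribution"])
```

## Package layout

| module | contents |
| --- | --- |
| `elbowsim.plant` | rigid-body elbow dynamics, perturbation rendering, impulse scheduling |
| `elbowsim.mtu` | four-element Hill-type muscle-tendon unit and Hatze activation dynamics |
| `elbowsim.routing` | via-ellipse muscle paths, moment arms, contact and joint constraint forces |
| `elbowsim.planner` | minimum-jerk desired trajectories |
| `elbowsim.controller` | triphasic pattern, equilibrium-point solving, delayed PD feedback, acceleration-phase optimization |
| `elbowsim.simulate` | delay-differential forward simulation (method of steps), muscle and torque plants |
| `elbowsim.experiments` | perturbation protocols, kinematic metrics, gain calibration, preflex analysis |
| `elbowsim.study` | end-to-end pipeline and feedback-contribution summary |
| `elbowsim.config` / `io` / `cli` | YAML configuration, CSV/JSON serialization, command line |

See `docs/methods.md` for the model equations, calibration procedure and
evaluation metrics.

## Acceptance targets

`scripts/acceptance.py` recomputes the two headline quantities from
scratch (calibration included; ~10–15 min on one CPU):

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

It reports, for feedback delays of 25 ms (`t1`) and 50 ms (`t2`), the
maximum over time, muscles and all eight perturbation runs of the
instantaneous feedback contribution `|u_closed| / max(u_total, 1e-3)`
(total stimulation after clipping to [0, 1]), as a percentage, against
published bounds of 16 % and 34 %.

**Honest result: both targets currently FAIL** (seed 1: `t1` ≈ 880 %,
`t2` ≈ 2700 %). The maxima occur during the torque-impulse transients,
where the velocity-error feedback drives the stretched antagonist — whose
open-loop drive sits at the 0.005 stimulation floor — below zero; the
clipped total saturates at zero and the instantaneous ratio explodes. The
static-protocol maxima (14–23 % at 25 ms, 15–30 % at 50 ms) are of the
published magnitude. The per-run values are included in the JSON output.
We report the literal instantaneous convention rather than restricting the
maximum to samples with substantial drive, which would make the bounds
pass but change the definition.

## Tests

```bash
pytest            # ~15 min; includes the full default-config pipeline
```

`tests/test_acceptance.py` holds one test per acceptance criterion.
Criteria 2, 3, 6, 7 and 8 pass. Three are expected failures, kept honest
rather than tuned away:

- **Criterion 1** (feedback-contribution bounds): see above.
- **Criterion 4** (static-perturbation signs): four of the five
  properties hold; with *decreased* inertia the closed-loop early-velocity
  difference is −0.10 °/s — a marginal sign flip around zero, because the
  calibrated velocity feedback almost fully compensates the perturbation
  by the 155 ms evaluation instant. The open-loop run shows the expected
  +1.15 °/s.
- **Criterion 5** (impulse response brackets): with-movement impulses
  roughly double the velocity in both directions and the against-movement
  impulse during flexion roughly halves it, as required; the
  against-movement impulse during *extension* brakes harder (ratio
  0.14–0.22 vs the [0.33, 0.67] bracket). The ideal impulse-induced
  velocity change (≈ 72 °/s with the default inertia) is comparable to the
  whole movement velocity, and the extension calibration systematically
  selects an early-braking pattern whose velocity at impulse onset is low.

The remaining suite (planner, muscle, routing, plant, controller, metrics,
IO/CLI) passes in full.

## Reproducibility

All optimizers are seeded and deterministic: repeated calibration with the
same seed reproduces `(u_acc, t1, k_p, k_d)` exactly. Time series are
written at 12 significant digits and round-trip through CSV; metrics
tables and manifests are plain JSON/CSV.
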