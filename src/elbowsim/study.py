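"""End-to-end study pipeline: calibrate, perturb, evaluate, check.

``run_full_study`` chains the whole reproduction for one feedback delay:
feedback-gain calibration on the static protocol, the static and dynamic
perturbation protocols with open- and closed-loop control, the
torque-driven comparison runs, the preflex analysis, the metrics table,
the qualitative-property checklist, and the feedback-contribution summary
(the maximum instantaneous closed-loop share of the total stimulation
across all eight perturbation runs).
"""

from __future__ import annotations

import logging
import math
import time

import numpy as np

from .config import ModelConfig
from .experiments import (CalibratedController, calibrate_feedback_gains,
                          dynamic_controller, feedback_contribution,
                          metrics_of, preflex_comparison, run_dynamic_protocol,
                          run_static_protocol, static_perturbations,
                          torque_model_run)
from .simulate import ModelContext

logger = logging.getLogger(__name__)

__all__ = ["run_full_study", "max_feedback_contribution"]


def _metrics_row(protocol: str, perturbation: str, variant: str,
                 metrics) -> dict:
    row = {"protocol": protocol, "perturbation": perturbation,
           "variant": variant}
    row.update(metrics.as_dict())
    return row


def _causality_check(reference, perturbed, onset: float | None,
                     tol: float = 1e-7) -> bool:
    """Trajectories must agree before the perturbation onset."""
    if onset is None:
        return False
    mask = perturbed.t < onset - 1e-9
    return bool(np.all(np.abs(perturbed.phi[mask] - reference.phi[mask])
                       < tol))


def run_full_study(cfg: ModelConfig, delay: float, seed: int,
                   include_torque_model: bool = True) -> dict:
    """Run the complete study for one feedback delay.

    Returns a dict with the calibration info, all simulation results,
    the flat metrics rows, the qualitative-property checklist, and the
    feedback-contribution summary.
    """
    t_start = time.time()
    ctx = ModelContext(cfg)
    target = math.radians(cfg.case.end_angle_deg)

    logger.info("stage 1/5: feedback-gain calibration (delay %.0f ms)",
                1e3 * delay)
    controller, calib_info = calibrate_feedback_gains(ctx, delay, seed)

    logger.info("stage 2/5: static protocol")
    static_closed = run_static_protocol(ctx, controller, feedback_on=True)
    static_open = run_static_protocol(ctx, controller, feedback_on=False)

    logger.info("stage 3/5: dynamic protocol")
    dynamic_closed, dynamic_open = {}, {}
    for direction in ("flexion", "extension"):
        dyn_ctrl = dynamic_controller(ctx, direction, controller.feedback,
                                      seed=seed)
        dynamic_closed[direction] = run_dynamic_protocol(ctx, dyn_ctrl,
                                                         feedback_on=True)
        dynamic_open[direction] = run_dynamic_protocol(ctx, dyn_ctrl,
                                                       feedback_on=False)

    rows = []
    for variant, proto in (("closed", static_closed), ("open", static_open)):
        for name, m in proto.metrics.items():
            rows.append(_metrics_row("static", name, variant, m))
    for variant, protos in (("closed", dynamic_closed),
                            ("open", dynamic_open)):
        for direction, proto in protos.items():
            for name, m in proto.metrics.items():
                rows.append(_metrics_row(
                    "dynamic", f"{direction}_{name}", variant, m))

    logger.info("stage 4/5: torque-model baselines and preflex analysis")
    torque_runs = {}
    preflex = None
    checklist = {}
    if include_torque_model:
        inertia_up = static_perturbations(cfg)["inertia_up"]
        torque_runs["unperturbed_open"] = torque_model_run(
            ctx, controller, feedback_on=False)
        torque_runs["inertia_up_open"] = torque_model_run(
            ctx, controller, feedback_on=False, pert=inertia_up)
        torque_runs["inertia_up_closed"] = torque_model_run(
            ctx, controller, feedback_on=True, pert=inertia_up)
        preflex = preflex_comparison(ctx, controller)

        # qualitative-property checklist (pass/fail booleans)
        checklist["torque_replay_identity"] = bool(np.max(np.abs(
            torque_runs["unperturbed_open"].phi - controller.recording.phi))
            < math.radians(1.0))
        checklist["preflex_muscle_resists_more"] = (
            abs(preflex["domega_muscle"]) < abs(preflex["domega_torque"]))
        checklist["torque_model_matches_ideal_impulse"] = (
            abs(preflex["domega_torque"] - preflex["domega_ideal"])
            <= 0.01 * abs(preflex["domega_ideal"]))
        checklist["inertia_up_muscle_overshoots"] = bool(
            np.max(static_closed.runs["inertia_up"].phi) > target)
        checklist["inertia_up_torque_open_undershoots"] = bool(
            np.max(torque_runs["inertia_up_open"].phi) < target)

    checklist["reference_u_closed_zero"] = bool(np.max(np.abs(
        static_closed.reference.u_closed)) < 1e-6)
    checklist["inertia_up_lowers_early_velocity"] = (
        static_closed.deltas["inertia_up"][0] < 0)
    checklist["inertia_down_raises_early_velocity"] = (
        static_closed.deltas["inertia_down"][0] > 0)
    checklist["damping_signs_opposite"] = (
        static_closed.deltas["damping_up"][0] < 0
        < static_closed.deltas["damping_down"][0])

    flex = dynamic_closed["flexion"]
    w_with = flex.runs["with"]
    w_against = flex.runs["against"]

    def _ratio(run):
        w0 = float(np.interp(run.impulse_onset, run.t, run.omega))
        w1 = float(np.interp(run.impulse_offset, run.t, run.omega))
        return w1 / w0

    checklist["impulse_with_speeds_up"] = _ratio(w_with) > 1.0
    checklist["impulse_against_slows_down"] = _ratio(w_against) < 1.0

    # feedback direction: against-movement impulse raises flexor drive
    fb_onset = w_against.impulse_onset + delay
    mask = (w_against.t >= fb_onset) & (w_against.t <= fb_onset + 0.2)
    flexor_idx = np.where(cfg.agonist_mask(flexion=True))[0]
    extra = (w_against.u_total[mask][:, flexor_idx]
             - w_against.u_open[mask][:, flexor_idx])
    checklist["feedback_raises_flexors_against_impulse"] = bool(
        np.max(extra) > 0)

    checklist["dynamic_causality"] = all(
        _causality_check(dc.reference, dc.runs[label],
                         dc.runs[label].impulse_onset)
        for dc in dynamic_closed.values() for label in ("with", "against"))

    # feedback contributions over the eight perturbation runs
    perturbation_runs = dict(static_closed.runs)
    for direction, dc in dynamic_closed.items():
        for label, run in dc.runs.items():
            perturbation_runs[f"{direction}_{label}"] = run
    contributions = {name: feedback_contribution(run)
                     for name, run in perturbation_runs.items()}
    max_contribution = max(contributions.values())

    logger.info("stage 5/5: done in %.1f s; max feedback contribution "
                "%.1f%%", time.time() - t_start, 100 * max_contribution)
    return {
        "delay": delay,
        "seed": seed,
        "calibration": calib_info,
        "controller": controller,
        "static_closed": static_closed,
        "static_open": static_open,
        "dynamic_closed": dynamic_closed,
        "dynamic_open": dynamic_open,
        "torque_runs": torque_runs,
        "preflex": preflex,
        "metrics_rows": rows,
        "checklist": checklist,
        "contributions": contributions,
        "max_contribution": max_contribution,
        "runtime_s": time.time() - t_start,
    }


def max_feedback_contribution(cfg: ModelConfig, delay: float,
                              seed: int) -> dict:
    """Calibrate and run the eight perturbation trials for one delay.

    Returns the maximum instantaneous feedback contribution (fraction)
    plus the per-run values.  This is the quantity the acceptance targets
    compare against the published bounds.
    """
    study = run_full_study(cfg, delay, seed, include_torque_model=False)
    return {
        "max_contribution": study["max_contribution"],
        "per_run": study["contributions"],
        "calibration": study["calibration"],
        "n_runs": len(study["contributions"]),
    }
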