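"""Model configuration: schema, validation, defaults, YAML round-trip.

The configuration fully determines a simulation study: arm geometry,
muscle parameters and path geometry, movement plan, controller settings
(triphasic pattern machinery, feedback gains and delay, optimization
budgets), perturbation magnitudes, and solver tolerances.  Angles are
expressed in degrees at the file interface (fields suffixed ``_deg``) and
radians internally.

The shipped defaults describe a generic adult arm attached to an elbow
exoskeleton: the baseline forearm inertia of 0.15 kg m^2 is chosen such
that the two experimental inertia perturbations (+0.039 / -0.032 kg m^2)
correspond to roughly +-25% of the baseline, consistent with the
perturbation protocol this package reproduces.  Muscle constants are
generic literature-range values for elbow flexors/extensors, and the
deflection-ellipse placements are calibration fixtures tuned so that
flexor moment arms peak mid-flexion in the 2-4 cm range.  All of them are
replaceable through the config file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields

import yaml

from .mtu import MTUParams
from .plant import ArmGeometry
from .routing import DeflectionEllipse, PathSpec, solve_path

__all__ = [
    "FeedbackConfig",
    "TorqueModelConfig",
    "OptimizationConfig",
    "ExperimentalReference",
    "PerturbationMagnitudes",
    "MovementCase",
    "SolverConfig",
    "MuscleConfig",
    "ModelConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Invalid, inconsistent or unknown configuration content."""


@dataclass(frozen=True)
class FeedbackConfig:
    """Delayed proportional-derivative muscle-spindle feedback settings.

    Gains are dimensionless (``k_d`` carries seconds) because the length
    and velocity errors are normalized by the optimal fiber length.
    """

    k_p: float = 0.0
    k_d: float = 0.0
    delay: float = 0.050        # s; 0.025 = short-latency, 0.050 = long-latency
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ConfigError("feedback delay must be >= 0")
        if self.k_p < 0 or self.k_d < 0:
            raise ConfigError("feedback gains must be >= 0")


@dataclass(frozen=True)
class TorqueModelConfig:
    """Joint-angle PD feedback of the torque-driven comparison model."""

    delay: float = 0.100        # s
    k_p: float = 15.0           # N m / rad
    k_d: float = 0.5            # N m s / rad


@dataclass(frozen=True)
class OptimizationConfig:
    """Budgets and bounds of the two calibration optimizers."""

    bayes_budget: int = 40
    bayes_n_init: int = 12
    u_acc_bounds: tuple[float, float] = (0.01, 1.0)
    t1_bounds: tuple[float, float] = (0.15, 0.55)
    seed: int = 0
    pattern_search_budget: int = 24
    k_p_bounds: tuple[float, float] = (0.0, 5.0)
    k_d_bounds: tuple[float, float] = (0.0, 0.3)
    u_des_dec_bounds: tuple[float, float] = (0.01, 0.2)


@dataclass(frozen=True)
class ExperimentalReference:
    """Synthetic target table for the feedback-gain calibration cost.

    Means and standard deviations of the perturbation-induced differences
    (perturbed minus reference) in early velocity (deg/s) and dysmetria
    (deg) for the four static perturbation types.  The experimental
    summary statistics behind the original calibration are not published
    as numbers, so this table is a SYNTHETIC stand-in with the
    experimentally reported signs (inertia up -> early velocity down and
    overshoot; inertia down -> early velocity up; damping with the
    opposite early-velocity/dysmetria pairing).  Magnitudes are set to a
    fraction of the open-loop model response, consistent with partial
    (but not complete) feedback compensation of the perturbations; a table
    with magnitudes exceeding the open-loop response would degenerate the
    gain calibration to zero gains, since feedback can only shrink the
    perturbation-induced differences.
    Users with access to experimental summary data can replace it in the
    config file.  Dysmetria is signed as final position minus
    first-correction position, so an overshoot that settles back is
    negative.
    """

    early_velocity_mean: dict = field(default_factory=lambda: {
        "inertia_up": -1.2, "inertia_down": 0.8,
        "damping_up": -3.0, "damping_down": 3.5,
    })
    early_velocity_sd: dict = field(default_factory=lambda: {
        "inertia_up": 1.5, "inertia_down": 1.5,
        "damping_up": 1.5, "damping_down": 1.5,
    })
    dysmetria_mean: dict = field(default_factory=lambda: {
        "inertia_up": -0.4, "inertia_down": 0.2,
        "damping_up": 0.1, "damping_down": -1.5,
    })
    dysmetria_sd: dict = field(default_factory=lambda: {
        "inertia_up": 0.5, "inertia_down": 0.5,
        "damping_up": 0.5, "damping_down": 0.5,
    })

    def __post_init__(self) -> None:
        for d in (self.early_velocity_sd, self.dysmetria_sd):
            if any(v <= 0 for v in d.values()):
                raise ConfigError("reference standard deviations must be > 0")


@dataclass(frozen=True)
class PerturbationMagnitudes:
    """Magnitudes of the experimental perturbation protocols."""

    inertia_up: float = 0.039        # kg m^2
    inertia_down: float = -0.032     # kg m^2
    damping_up: float = 0.30         # N m s / rad
    damping_down: float = -0.31      # N m s / rad
    bias_torque: float = -1.5        # N m, gravity-mimicking, dynamic protocol
    impulse_magnitude: float = 5.0   # N m (applied as +/-)
    impulse_onset_fraction: float = 0.25
    impulse_duration: float = 0.0375  # s


@dataclass(frozen=True)
class MovementCase:
    """Start/end posture and timing of one movement condition (degrees)."""

    start_angle_deg: float = 60.0
    end_angle_deg: float = 90.0
    movement_onset: float = 0.1      # s; start of the acceleration phase
    movement_duration: float = 0.6   # s
    t2: float = 0.7                  # s; start of the final (holding) phase
    horizon: float = 1.0             # s


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-5
    atol: float = 1e-8
    method: str = "LSODA"
    output_dt: float = 0.001         # s, dense output sampling

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.output_dt <= 0:
            raise ConfigError("solver tolerances and output_dt must be > 0")


@dataclass(frozen=True)
class MuscleConfig:
    params: MTUParams
    path: PathSpec
    flexor: bool                    # True if the muscle flexes the elbow


@dataclass(frozen=True)
class ModelConfig:
    geometry: ArmGeometry
    muscles: tuple[MuscleConfig, ...]
    case: MovementCase = MovementCase()
    feedback: FeedbackConfig = FeedbackConfig()
    torque_model: TorqueModelConfig = TorqueModelConfig()
    optimization: OptimizationConfig = OptimizationConfig()
    reference: ExperimentalReference = ExperimentalReference()
    perturbations: PerturbationMagnitudes = PerturbationMagnitudes()
    solver: SolverConfig = SolverConfig()
    u_min: float = 0.005             # fixed antagonist stimulation, acceleration phase
    u_des_hold: float = 0.1          # co-contraction target of initial/final phases
    u_des_dec: float = 0.03          # co-contraction target of the braking phase

    def __post_init__(self) -> None:
        names = [m.params.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate muscle names")
        if not any(m.flexor for m in self.muscles) or all(m.flexor for m in self.muscles):
            raise ConfigError("need at least one flexor and one extensor")
        for lo, hi in (self.optimization.u_acc_bounds,):
            if not 0 <= lo < hi <= 1:
                raise ConfigError("u_acc bounds must satisfy 0 <= lo < hi <= 1")
        for u in (self.u_min, self.u_des_hold, self.u_des_dec):
            if not 0 <= u <= 1:
                raise ConfigError("stimulation levels must lie in [0, 1]")

    @property
    def muscle_names(self) -> list[str]:
        return [m.params.name for m in self.muscles]

    def agonist_mask(self, flexion: bool):
        import numpy as np
        return np.array([m.flexor == flexion for m in self.muscles])

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------
# defaults
# --------------------------------------------------------------------------

def _default_paths() -> dict[str, PathSpec]:
    elbow_cap_large = DeflectionEllipse(
        center=(0.30, 0.0), semi_axes=(0.022, 0.022), owning_segment="upper_arm")
    elbow_cap_small = DeflectionEllipse(
        center=(0.30, 0.0), semi_axes=(0.018, 0.018), owning_segment="upper_arm")
    shoulder_cap = DeflectionEllipse(
        center=(0.0, 0.0), semi_axes=(0.025, 0.025), owning_segment="upper_arm")
    return {
        "elbow_flexor": PathSpec(
            name="elbow_flexor",
            origin_point=(0.18, 0.020),
            insertion_point=(0.038, 0.010),
            deflection_ellipses=(elbow_cap_large,),
        ),
        "elbow_extensor": PathSpec(
            name="elbow_extensor",
            origin_point=(0.15, -0.022),
            insertion_point=(-0.022, -0.010),
            deflection_ellipses=(elbow_cap_small,),
        ),
        "biart_flexor": PathSpec(
            name="biart_flexor",
            origin_point=(-0.02, 0.020),
            insertion_point=(0.042, 0.010),
            deflection_ellipses=(shoulder_cap, elbow_cap_large),
        ),
        "biart_extensor": PathSpec(
            name="biart_extensor",
            origin_point=(-0.02, -0.020),
            insertion_point=(-0.022, -0.008),
            deflection_ellipses=(shoulder_cap, elbow_cap_small),
        ),
    }


_DEFAULT_MUSCLE_NUMBERS = {
    # name: (f_max N, l_ce_opt m, flexor?)
    "elbow_flexor": (1200.0, 0.090, True),
    "elbow_extensor": (1400.0, 0.090, False),
    "biart_flexor": (800.0, 0.130, True),
    "biart_extensor": (1000.0, 0.130, False),
}


def default_config() -> ModelConfig:
    """The shipped generic arm + controller configuration.

    Tendon rest lengths are derived from the path geometry so that each
    contractile element sits at its optimal length, with the tendon at
    rest, when the elbow is at the middle of the default movement
    (75 degrees flexion).
    """
    geometry = ArmGeometry()
    paths = _default_paths()
    phi_ref = math.radians(75.0)
    muscles = []
    for name, (f_max, l_opt, flexor) in _DEFAULT_MUSCLE_NUMBERS.items():
        path = paths[name]
        l_path = solve_path(phi_ref, path, geometry.upper_arm_length).mtu_length
        see_rest = l_path - l_opt
        if see_rest <= 0:
            raise ConfigError(f"{name}: path too short for chosen l_ce_opt")
        params = MTUParams(name=name, f_max=f_max, l_ce_opt=l_opt,
                           see_rest_length=see_rest)
        muscles.append(MuscleConfig(params=params, path=path, flexor=flexor))
    return ModelConfig(geometry=geometry, muscles=tuple(muscles))


def fast_config() -> ModelConfig:
    """Default model with reduced calibration budgets (for smoke tests)."""
    cfg = default_config()
    return cfg.replace(optimization=OptimizationConfig(
        bayes_budget=8, bayes_n_init=5, pattern_search_budget=4))


# --------------------------------------------------------------------------
# YAML round-trip with strict validation
# --------------------------------------------------------------------------

def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value
    return obj


def _from_dict(cls, data, where: str):
    if not dataclasses.is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.type if isinstance(f.type, type) else None
        target = _NESTED.get((cls.__name__, name))
        if target is not None:
            if isinstance(value, list):
                kwargs[name] = tuple(
                    _from_dict(target, v, f"{where}.{name}[{i}]")
                    for i, v in enumerate(value))
            else:
                kwargs[name] = _from_dict(target, value, f"{where}.{name}")
        else:
            if isinstance(value, str) and name not in _STRING_FIELDS:
                try:
                    value = float(value)
                except ValueError:
                    raise ConfigError(f"{where}.{name}: expected a number, "
                                      f"got {value!r}") from None
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_NESTED = {
    ("ModelConfig", "geometry"): ArmGeometry,
    ("ModelConfig", "muscles"): None,   # handled specially below
    ("ModelConfig", "case"): MovementCase,
    ("ModelConfig", "feedback"): FeedbackConfig,
    ("ModelConfig", "torque_model"): TorqueModelConfig,
    ("ModelConfig", "optimization"): OptimizationConfig,
    ("ModelConfig", "reference"): ExperimentalReference,
    ("ModelConfig", "perturbations"): PerturbationMagnitudes,
    ("ModelConfig", "solver"): SolverConfig,
    ("MuscleConfig", "params"): MTUParams,
    ("MuscleConfig", "path"): PathSpec,
    ("PathSpec", "deflection_ellipses"): DeflectionEllipse,
}
_NESTED[("ModelConfig", "muscles")] = MuscleConfig
_STRING_FIELDS = {"name", "owning_segment", "method"}


def config_to_dict(cfg: ModelConfig) -> dict:
    return _to_dict(cfg)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_dict(ModelConfig, data, "config")
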