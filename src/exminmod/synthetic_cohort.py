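"""Virtual subjects and study-design-faithful synthetic datasets.

The clinical dataset behind this model family is not deposited, so every
other module is exercised against synthetic cohorts that emulate the study
design: closed-loop control from 15:30 (minute 930 of the visit day), a
60-min session at 60% VO2max starting at 18:00 (minute 1080), a 30-min
recovery, venous samples every 30 min pre-exercise / 10 min during / 15 min
after (14 samples), and 2%-CV multiplicative glucose measurement noise.

Default subject parameters are drawn log-normally around the selected
model's (variant 6) reported cross-subject medians; the spreads are chosen
to resemble the reported interquartile ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .inference import SubjectDataset
from .model_core import ExerciseSession, ModelParameters
from .simulate import ForcingFunction, simulate

__all__ = [
    "CohortSpec",
    "build_schedule",
    "sample_cohort",
    "generate_dataset",
    "default_exercise_trace",
    "default_insulin_profile",
    "make_study_dataset",
    "DEFAULT_PARAM_LOC",
    "DEFAULT_PARAM_SCALE",
]

logger = logging.getLogger("exminmod")

# cross-subject geometric means: the selected variant's reported medians
DEFAULT_PARAM_LOC: Dict[str, float] = {
    "Gp0": 32.1,
    "p1": 0.0021,
    "p2": 0.031,
    "p3": 1.6e-5,
    "e1": 1.60,
    "e2": 0.778,
}
# log-scale spreads loosely matching the reported interquartile ranges
DEFAULT_PARAM_SCALE: Dict[str, float] = {
    "Gp0": 0.30,
    "p1": 0.25,
    "p2": 0.30,
    "p3": 0.30,
    "e1": 0.20,
    "e2": 0.30,
}

# study-design defaults (absolute minutes from 00:00 of the visit day)
CONTROL_START_MIN = 930.0  # 15:30
EXERCISE_START_MIN = 1080.0  # 18:00
EXERCISE_DURATION_MIN = 60.0
RECOVERY_MIN = 30.0
EXERCISE_INTENSITY = 0.6  # fraction of VO2max

VO2_REST_DEFAULT = 3.5  # mL/kg/min
VO2_MAX_DEFAULT = 40.0  # mL/kg/min

NOISE_CV_DEFAULT = 0.02
INSB_LOC_DEFAULT = 10.0  # mU/L
INSB_SCALE_DEFAULT = 0.2


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a virtual cohort (reproducible under a fixed seed)."""

    n_subjects: int = 12
    param_loc: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_LOC))
    param_scale: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PARAM_SCALE))
    insb_loc: float = INSB_LOC_DEFAULT
    insb_scale: float = INSB_SCALE_DEFAULT
    variant: int = 6
    noise_cv: float = NOISE_CV_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for name in DEFAULT_PARAM_LOC:
            if name not in self.param_loc or name not in self.param_scale:
                raise ValueError(f"cohort spec missing parameter {name!r}")


def build_schedule(
    control_start: float = CONTROL_START_MIN,
    exercise_start: float = EXERCISE_START_MIN,
    exercise_dur: float = EXERCISE_DURATION_MIN,
    recovery: float = RECOVERY_MIN,
) -> np.ndarray:
    """Sampling times: every 30 min pre-exercise, 10 min during, 15 min after.

    The defaults (15:30 control start, 18:00 exercise start, 60-min session,
    30-min recovery) yield the study's 14 sample times.
    """
    if not control_start < exercise_start:
        raise ValueError("control_start must precede exercise_start")
    if not exercise_dur > 0:
        raise ValueError("exercise_dur must be > 0")
    if recovery < 0:
        raise ValueError("recovery must be >= 0")
    n_pre = int(np.floor((exercise_start - control_start) / 30.0))
    pre = control_start + 30.0 * np.arange(n_pre + 1)
    pre = pre[pre <= exercise_start]
    n_dur = int(np.floor(exercise_dur / 10.0))
    during = exercise_start + 10.0 * np.arange(1, n_dur + 1)
    exercise_end = exercise_start + exercise_dur
    n_rec = int(np.floor(recovery / 15.0))
    post = exercise_end + 15.0 * np.arange(1, n_rec + 1)
    return np.unique(np.concatenate([pre, during, post]))


def sample_cohort(spec: CohortSpec) -> List[ModelParameters]:
    """Draw ``n_subjects`` parameter sets log-normally; fixed seed, fixed cohort."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    names = sorted(DEFAULT_PARAM_LOC)
    for i in range(spec.n_subjects):
        draws = {
            name: float(
                spec.param_loc[name]
                * np.exp(spec.param_scale[name] * rng.standard_normal())
            )
            for name in names
        }
        insb = float(spec.insb_loc * np.exp(spec.insb_scale * rng.standard_normal()))
        cohort.append(
            ModelParameters(
                Gp0=draws["Gp0"],
                p1=draws["p1"],
                p2=draws["p2"],
                p3=draws["p3"],
                Insb=insb,
                e1=draws["e1"],
                e2=draws["e2"],
                variant=spec.variant,
            )
        )
    return cohort


def default_exercise_trace(
    intensity: float = EXERCISE_INTENSITY,
    duration: float = EXERCISE_DURATION_MIN,
    t_start: float = EXERCISE_START_MIN,
    vo2_rest: float = VO2_REST_DEFAULT,
    vo2_max: float = VO2_MAX_DEFAULT,
    ramp: float = 2.0,
) -> ExerciseSession:
    """Constant-intensity VO2 trace with brief linear on/off ramps (<= 2 min).

    The ramps stand in for the on-kinetics of oxygen uptake and avoid a
    discontinuous forcing that measured breath-by-breath data would not
    contain.
    """
    if not 0 < intensity <= 1:
        raise ValueError("intensity must lie in (0, 1]")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    ramp = min(ramp, duration / 4.0)
    level = vo2_rest + intensity * (vo2_max - vo2_rest)
    t_end = t_start + duration
    times = np.array([t_start, t_start + ramp, t_end, t_end + ramp])
    values = np.array([vo2_rest, level, level, vo2_rest])
    return ExerciseSession(
        t_start=t_start,
        duration=duration,
        vo2_rest=vo2_rest,
        vo2_max=vo2_max,
        vo2_times=times,
        vo2_values=values,
    )


def default_insulin_profile(
    insb: float,
    session: ExerciseSession,
    t0: float = CONTROL_START_MIN,
    recovery: float = RECOVERY_MIN,
    suspension_fraction: float = 0.6,
) -> ForcingFunction:
    """Basal plasma-insulin plateau with a piecewise-linear decline during
    exercise and recovery back to basal afterwards.

    A clearly labelled stand-in for unavailable closed-loop dosing: insulin
    infusion is typically suspended during exercise, so plasma insulin
    drifts down toward ``suspension_fraction * insb`` by the end of the
    session.
    """
    t_end = session.t_end
    times = np.array([t0, session.t_start, t_end, t_end + recovery])
    values = np.array([insb, insb, suspension_fraction * insb, insb])
    return ForcingFunction(times=times, values=values)


def generate_dataset(
    params: ModelParameters,
    schedule: Optional[Sequence[float]] = None,
    insulin_profile: Optional[ForcingFunction] = None,
    session: Optional[ExerciseSession] = None,
    noise_cv: float = NOISE_CV_DEFAULT,
    seed: int = 0,
    subject_id: str = "S0",
) -> SubjectDataset:
    """Simulate one subject-session and corrupt glucose with multiplicative noise.

    Observations are ``Ghat(t_i) * (1 + noise_cv * eps_i)`` with iid standard
    normal ``eps_i``; non-positive draws are redrawn (and logged). Insulin
    and VO2 are recorded noise-free on the same schedule.
    """
    if schedule is None:
        schedule = build_schedule()
    schedule = np.asarray(schedule, dtype=float)
    if session is None:
        session = default_exercise_trace()
    if insulin_profile is None:
        insulin_profile = default_insulin_profile(params.Insb, session)

    traj = simulate(params, insulin_profile, session=session, t_grid=schedule)
    rng = np.random.default_rng(seed)
    glucose = traj.G * (1.0 + noise_cv * rng.standard_normal(schedule.size))
    bad = glucose <= 0
    while np.any(bad):
        logger.info(
            "redrawing %d non-positive glucose observation(s) for %s",
            int(np.sum(bad)), subject_id,
        )
        glucose[bad] = traj.G[bad] * (
            1.0 + noise_cv * rng.standard_normal(int(np.sum(bad)))
        )
        bad = glucose <= 0

    return SubjectDataset(
        subject_id=subject_id,
        times=schedule,
        glucose=glucose,
        insulin=insulin_profile(schedule),
        vo2=session.vo2(schedule),
        session=session,
        symptoms=np.zeros(schedule.size, dtype=bool),
        meta={"seed": seed, "noise_cv": noise_cv, "true_params": params.to_record()},
    )


def make_study_dataset(
    params: ModelParameters, seed: int = 0, subject_id: str = "S0"
) -> SubjectDataset:
    """Convenience wrapper: the default 14-point study-design dataset."""
    return generate_dataset(params, seed=seed, subject_id=subject_id)
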