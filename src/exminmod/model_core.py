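"""Exercise-extended Bergman minimal models of glucose dynamics.

The kernel is a two-state minimal model of plasma glucose ``G`` (mmol/L)
and remote insulin action ``X`` (1/min), driven by measured plasma insulin
``Ins(t)`` (mU/L):

    dX/dt = -p2*X + p3*(1 + inc2(t))*Ins(t)
    dG/dt = -p1*(1 + inc1(t))*G - X*G + p1*Gp0

``inc1`` (increase in glucose effectiveness) and ``inc2`` (increase in
insulin sensitivity) are zero outside the exercise window; inside it they
take one of six variant-specific forms combining fixed gains ``e1``/``e2``,
exercise intensity (percentage of VO2max above rest, ``pvo2``), and elapsed
exercise time normalised by 60 min (``te``):

    variant 1:  inc1 = e1,        inc2 = e2
    variant 2:  inc1 = 0,         inc2 = e1
    variant 3:  inc1 = e1,        inc2 = 0
    variant 4:  inc1 = e1*pvo2,   inc2 = e2*pvo2
    variant 5:  inc1 = e1*te,     inc2 = e2*te
    variant 6:  inc1 = e1*pvo2,   inc2 = e2*(pvo2 + te)

Variant 6 — intensity-driven glucose effectiveness plus intensity- and
duration-driven insulin sensitivity — is the model this family is built
around; variants 1-5 are its ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ModelParameters",
    "GlucoseState",
    "ExerciseSession",
    "InvalidSessionError",
    "ConfigurationError",
    "pvo2max",
    "exercise_time",
    "inc_terms",
    "rhs",
    "steady_state",
    "N_VARIANTS",
    "VARIANTS",
]

N_VARIANTS = 6
VARIANTS = tuple(range(1, N_VARIANTS + 1))

#: duration (min) by which elapsed exercise time is normalised
TE_NORMALISATION_MIN = 60.0

#: glucose floor (mmol/L) applied inside solvers to keep X*G well behaved
GLUCOSE_FLOOR = 1e-6


class InvalidSessionError(ValueError):
    """An exercise session's VO2 calibration is unusable (vo2_max <= vo2_rest)."""


class ConfigurationError(ValueError):
    """An unknown model variant or inconsistent configuration was requested."""


@dataclass(frozen=True)
class ModelParameters:
    """Physiological constants of one (virtual) subject.

    Parameters
    ----------
    Gp0 : float
        Glucose level at zero plasma insulin (mmol/L).
    p1 : float
        Glucose effectiveness (1/min).
    p2 : float
        Time constant of the remote-insulin compartment (1/min).
    p3 : float
        Insulin sensitivity gain (1/min^2 per mU/L).
    Insb : float
        Basal plasma insulin (mU/L); enters only through the steady-state
        initial condition. May be zero (the zero-insulin limit).
    e1, e2 : float
        Exercise gains, stored as dimensionless fractions (a value printed
        as "160%" is stored as 1.60).
    variant : int
        Exercise-model variant, 1-6.
    """

    Gp0: float
    p1: float
    p2: float
    p3: float
    Insb: float
    e1: float = 0.0
    e2: float = 0.0
    variant: int = 6

    def __post_init__(self) -> None:
        for name in ("Gp0", "p1", "p2", "p3"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (np.isfinite(self.Insb) and self.Insb >= 0):
            raise ValueError(f"Insb must be non-negative, got {self.Insb!r}")
        if self.e1 < 0 or self.e2 < 0:
            raise ValueError("e1 and e2 must be non-negative")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )

    def to_record(self) -> dict:
        """Flat key-value record (the serialization form of a subject)."""
        return {
            "Gp0": self.Gp0,
            "p1": self.p1,
            "p2": self.p2,
            "p3": self.p3,
            "Insb": self.Insb,
            "e1": self.e1,
            "e2": self.e2,
            "variant": self.variant,
        }

    @classmethod
    def from_record(cls, record: dict) -> "ModelParameters":
        return cls(
            Gp0=float(record["Gp0"]),
            p1=float(record["p1"]),
            p2=float(record["p2"]),
            p3=float(record["p3"]),
            Insb=float(record["Insb"]),
            e1=float(record.get("e1", 0.0)),
            e2=float(record.get("e2", 0.0)),
            variant=int(record.get("variant", 6)),
        )

    def with_variant(self, variant: int) -> "ModelParameters":
        return replace(self, variant=variant)


@dataclass(frozen=True)
class GlucoseState:
    """Instantaneous model state: plasma glucose G (mmol/L), remote insulin X (1/min)."""

    G: float
    X: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.G) and self.G > 0):
            raise ValueError(f"G must be strictly positive, got {self.G!r}")
        if not (np.isfinite(self.X) and self.X >= 0):
            raise ValueError(f"X must be non-negative, got {self.X!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.X], dtype=float)


@dataclass(frozen=True)
class ExerciseSession:
    """One exercise bout (or bout structure) on the absolute visit timeline.

    The VO2 trace is stored as piecewise-linear knots (``vo2_times``,
    ``vo2_values``) with constant extrapolation beyond the sampled range;
    values are clipped to [vo2_rest, vo2_max] before use, since measured
    breath-by-breath data overshoot.
    """

    t_start: float
    duration: float
    vo2_rest: float
    vo2_max: float
    vo2_times: np.ndarray = field(repr=False)
    vo2_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidSessionError(f"duration must be > 0, got {self.duration!r}")
        if not self.vo2_max > self.vo2_rest:
            raise InvalidSessionError(
                f"vo2_max ({self.vo2_max!r}) must exceed vo2_rest ({self.vo2_rest!r})"
            )
        times = np.asarray(self.vo2_times, dtype=float)
        values = np.asarray(self.vo2_values, dtype=float)
        if times.size == 0 or times.shape != values.shape:
            raise InvalidSessionError("vo2 trace needs matching, non-empty knot arrays")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidSessionError("vo2 trace times must be strictly increasing")
        object.__setattr__(self, "vo2_times", times)
        object.__setattr__(self, "vo2_values", values)

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def in_window(self, t) -> np.ndarray:
        """Exercise window membership; half-open so inc terms vanish at t_end."""
        t = np.asarray(t, dtype=float)
        return (t >= self.t_start) & (t < self.t_end)

    def vo2(self, t) -> np.ndarray:
        raw = np.interp(np.asarray(t, dtype=float), self.vo2_times, self.vo2_values)
        return np.clip(raw, self.vo2_rest, self.vo2_max)

    def pvo2(self, t) -> np.ndarray:
        return pvo2max(self.vo2(t), self.vo2_rest, self.vo2_max)

    def te(self, t) -> np.ndarray:
        return exercise_time(t, self.t_start)

    @classmethod
    def constant(
        cls,
        t_start: float,
        duration: float,
        intensity: float,
        vo2_rest: float = 3.5,
        vo2_max: float = 40.0,
    ) -> "ExerciseSession":
        """Rectangular session at a fixed fraction of the rest-to-max VO2 span."""
        level = vo2_rest + intensity * (vo2_max - vo2_rest)
        return cls(
            t_start=t_start,
            duration=duration,
            vo2_rest=vo2_rest,
            vo2_max=vo2_max,
            vo2_times=np.array([t_start, t_start + duration]),
            vo2_values=np.array([level, level]),
        )


def pvo2max(vo2, vo2_rest: float, vo2_max: float):
    """Exercise intensity as fraction of the rest-to-max oxygen-uptake span.

    Returns ``(vo2 - vo2_rest) / (vo2_max - vo2_rest)`` clipped to [0, 1].
    """
    if not vo2_max > vo2_rest:
        raise InvalidSessionError(
            f"vo2_max ({vo2_max!r}) must exceed vo2_rest ({vo2_rest!r})"
        )
    frac = (np.asarray(vo2, dtype=float) - vo2_rest) / (vo2_max - vo2_rest)
    out = np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def exercise_time(t, t_start: float):
    """Elapsed exercise time normalised by 60 min; 0 before the session starts."""
    te = (np.asarray(t, dtype=float) - t_start) / TE_NORMALISATION_MIN
    out = np.maximum(te, 0.0)
    return out if out.ndim else float(out)


def inc_terms(
    variant: int,
    e1: float,
    e2: float,
    pvo2: float = 0.0,
    te: float = 0.0,
    in_exercise: bool = True,
) -> Tuple[float, float]:
    """Exercise increments (inc1, inc2) for one model variant.

    Outside the exercise window both increments are identically zero for
    every variant (no post-exercise carry-over is modelled).
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown model variant {variant!r}")
    if not in_exercise:
        return 0.0, 0.0
    if variant == 1:
        return e1, e2
    if variant == 2:
        return 0.0, e1
    if variant == 3:
        return e1, 0.0
    if variant == 4:
        return e1 * pvo2, e2 * pvo2
    if variant == 5:
        return e1 * te, e2 * te
    return e1 * pvo2, e2 * (pvo2 + te)  # variant 6


def rhs(
    state: GlucoseState,
    t: float,
    params: ModelParameters,
    ins: float,
    inc1: float = 0.0,
    inc2: float = 0.0,
) -> Tuple[float, float]:
    """Time derivatives (dG/dt, dX/dt) of the minimal model.

    Pure function of the supplied state, insulin level and exercise
    increments; ``t`` is accepted for interface symmetry but the dynamics
    are non-autonomous only through ``ins``/``inc``.
    """
    del t
    G, X = state.G, state.X
    dX = -params.p2 * X + params.p3 * (1.0 + inc2) * ins
    dG = -params.p1 * (1.0 + inc1) * G - X * G + params.p1 * params.Gp0
    return dG, dX


def steady_state(params: ModelParameters) -> GlucoseState:
    """Pre-exercise equilibrium at Ins = Insb with no exercise.

    X(0) = (p3/p2) * Insb and G(0) = Gp0 * p1 / (p1 + X(0)) — the unique
    reading of the initial conditions under which the derivatives vanish.
    """
    X0 = params.p3 / params.p2 * params.Insb
    G0 = params.Gp0 * params.p1 / (params.p1 + X0)
    return GlucoseState(G=G0, X=X0)
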