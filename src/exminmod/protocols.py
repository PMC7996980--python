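"""In-silico exercise-protocol replay on a virtual cohort.

Two validation scenarios are implemented on top of the selected exercise
model (variant 6):

* **Study 1** — postprandial exercise 90 min after a 75-g-carbohydrate
  breakfast, on an 8-arm grid of exercise intensity (25/50/75% VO2max),
  duration (30/60 min) and premeal bolus reduction (0/50/75%).
* **Study 2** — a 60-min session at 50% VO2max split into four 15-min
  bouts with 5-min rests, under three basal strategies: pump stop at
  exercise onset, 80% basal reduction 90 min pre-exercise, or 50% basal
  reduction 90 min pre-exercise.

The meal and insulin submodels are standard linear chains implemented
behind a small kinetics interface: subcutaneous insulin absorption is a
two-compartment chain (time-to-peak ~55 min) with first-order plasma
clearance, and meal glucose appearance is a gamma-shaped curve
(time-to-peak ~40 min, bioavailability 0.8) already scaled by the glucose
distribution volume so it adds directly to dG/dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import ExerciseSession, ModelParameters
from .simulate import ForcingFunction, Trajectory, simulate
from .synthetic_cohort import VO2_MAX_DEFAULT, VO2_REST_DEFAULT, default_exercise_trace

__all__ = [
    "InsulinKinetics",
    "MealKinetics",
    "ProtocolSpec",
    "OutcomeReport",
    "STUDY1_PROTOCOLS",
    "STUDY2_STRATEGIES",
    "insulin_submodel",
    "meal_submodel",
    "basal_rate_for",
    "run_study1",
    "run_study2",
    "glycemic_outcomes",
]

MMOL_PER_G_GLUCOSE = 1000.0 / 180.16


@dataclass(frozen=True)
class InsulinKinetics:
    """Two-compartment subcutaneous absorption with plasma clearance.

    S1' = u(t) - S1/tmax;  S2' = (S1 - S2)/tmax;  I' = S2/(tmax*Vi) - ke*I

    A constant basal rate u converges to the plateau I = u / (ke * Vi).
    """

    tmax: float = 55.0  # min, time-to-peak of absorption
    ke: float = 0.138  # 1/min, plasma insulin elimination
    vi: float = 8.4  # L, insulin distribution volume (0.12 L/kg x 70 kg)
    icr: float = 10.0  # g carbohydrate per unit, for meal boluses

    def steady_plasma(self, basal_mU_min: float) -> float:
        return basal_mU_min / (self.ke * self.vi)


@dataclass(frozen=True)
class MealKinetics:
    """Gamma-shaped glucose appearance, scaled by the distribution volume.

    Ra(t) = D * f * (t - tm) * exp(-(t - tm)/tmax) / tmax^2 / Vg
    integrates to carbs * bioavailability / Vg in glucose units.
    """

    tmax: float = 40.0  # min, time-to-peak of appearance
    bioavailability: float = 0.8
    vg: float = 11.2  # L, glucose distribution volume (0.16 L/kg x 70 kg)


@dataclass(frozen=True)
class ProtocolSpec:
    """One validation arm: meal, insulin-reduction strategy, exercise pattern."""

    intensity: float  # fraction of VO2max
    duration: float  # total exercise time including rests, min
    exercise_start: float  # min on the protocol timeline
    meal_carbs: float = 0.0  # g
    meal_time: Optional[float] = None
    bolus_reduction: float = 0.0  # fraction of the full meal bolus withheld
    basal_reduction: float = 0.0  # fraction of basal withheld
    basal_reduction_lead: float = 0.0  # min before exercise the reduction starts
    pump_suspend: bool = False  # basal -> 0 at exercise onset
    bouts: Optional[Tuple[Tuple[float, float], ...]] = None  # (work, rest) min
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.bolus_reduction <= 1:
            raise ValueError("bolus_reduction must lie in [0, 1]")
        if not 0 <= self.basal_reduction <= 1:
            raise ValueError("basal_reduction must lie in [0, 1]")
        strategies = (self.bolus_reduction > 0) + (self.basal_reduction > 0) + self.pump_suspend
        if strategies > 1:
            raise ValueError("at most one insulin-reduction strategy per arm")
        if self.bouts is not None:
            total = sum(w for w, _ in self.bouts) + sum(
                r for _, r in self.bouts[:-1]
            )
            if not np.isclose(total, self.duration):
                raise ValueError(
                    f"bout structure spans {total} min, stated duration {self.duration}"
                )

    @property
    def exercise_end(self) -> float:
        return self.exercise_start + self.duration


# Study 1: breakfast at minute 120, exercise 90 min later.
_S1_MEAL_TIME = 120.0
_S1_EX_START = _S1_MEAL_TIME + 90.0

STUDY1_PROTOCOLS: Dict[int, ProtocolSpec] = {
    pid: ProtocolSpec(
        intensity=vo2,
        duration=dur,
        exercise_start=_S1_EX_START,
        meal_carbs=75.0,
        meal_time=_S1_MEAL_TIME,
        bolus_reduction=red,
        label=f"protocol {pid}: {vo2:.0%} VO2max, {dur:.0f} min, {red:.0%} bolus reduction",
    )
    for pid, (vo2, dur, red) in {
        1: (0.25, 60.0, 0.0),
        2: (0.25, 60.0, 0.50),
        3: (0.50, 60.0, 0.50),
        4: (0.50, 60.0, 0.75),
        5: (0.50, 30.0, 0.0),
        6: (0.50, 30.0, 0.50),
        7: (0.75, 30.0, 0.0),
        8: (0.75, 30.0, 0.75),
    }.items()
}

# Study 2: four 15-min bouts at 50% VO2max with 5-min rests (75-min window),
# insulin strategy set 90 min pre-exercise (or pump stop at onset).
_S2_EX_START = 180.0
_S2_BOUTS = ((15.0, 5.0), (15.0, 5.0), (15.0, 5.0), (15.0, 0.0))
_S2_DURATION = 75.0

STUDY2_STRATEGIES: Dict[str, ProtocolSpec] = {
    "pump-stop": ProtocolSpec(
        intensity=0.5, duration=_S2_DURATION, exercise_start=_S2_EX_START,
        pump_suspend=True, bouts=_S2_BOUTS, label="pump stop at exercise onset",
    ),
    "basal-80-90min": ProtocolSpec(
        intensity=0.5, duration=_S2_DURATION, exercise_start=_S2_EX_START,
        basal_reduction=0.80, basal_reduction_lead=90.0, bouts=_S2_BOUTS,
        label="80% basal reduction 90 min pre-exercise",
    ),
    "basal-50-90min": ProtocolSpec(
        intensity=0.5, duration=_S2_DURATION, exercise_start=_S2_EX_START,
        basal_reduction=0.50, basal_reduction_lead=90.0, bouts=_S2_BOUTS,
        label="50% basal reduction 90 min pre-exercise",
    ),
}


def basal_rate_for(insb: float, kinetics: InsulinKinetics = InsulinKinetics()) -> float:
    """Basal infusion rate (mU/min) whose steady plasma level equals ``insb``."""
    return insb * kinetics.ke * kinetics.vi


def insulin_submodel(
    basal_profile: Sequence[Tuple[float, float]],
    boluses: Sequence[Tuple[float, float]] = (),
    kinetics: InsulinKinetics = InsulinKinetics(),
    t_span: Tuple[float, float] = (0.0, 360.0),
    dt: float = 1.0,
) -> ForcingFunction:
    """Plasma insulin (mU/L) from a basal step profile plus discrete boluses.

    ``basal_profile`` is a piecewise-constant schedule ``[(t, rate), ...]``
    in U/h (each rate holds from its time until the next entry); ``boluses``
    are ``(time, units)`` pairs injected into the first subcutaneous
    compartment. The chain starts at the steady state of the initial basal
    rate.
    """
    if not basal_profile:
        raise ValueError("basal_profile must contain at least one (time, rate) entry")
    times = [t for t, _ in basal_profile]
    if sorted(times) != times:
        raise ValueError("basal_profile times must be non-decreasing")
    for _, rate in basal_profile:
        if rate < 0:
            raise ValueError("negative basal rate")
    for _, units in boluses:
        if units < 0:
            raise ValueError("negative bolus dose")

    def rate_mU_min(t: float) -> float:
        current = basal_profile[0][1]
        for t_k, r_k in basal_profile:
            if t >= t_k:
                current = r_k
            else:
                break
        return current * 1000.0 / 60.0

    u0 = rate_mU_min(t_span[0])
    tmax, ke, vi = kinetics.tmax, kinetics.ke, kinetics.vi
    y = np.array([u0 * tmax, u0 * tmax, kinetics.steady_plasma(u0)])

    events = sorted(
        {t for t, _ in basal_profile} | {t for t, _ in boluses} | set(t_span)
    )
    events = [t for t in events if t_span[0] <= t <= t_span[1]]
    if events[0] > t_span[0]:
        events.insert(0, t_span[0])
    if events[-1] < t_span[1]:
        events.append(t_span[1])

    grid = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)
    out = np.empty_like(grid)
    out[grid == events[0]] = y[2]

    bolus_at = {}
    for t_b, units in boluses:
        bolus_at[t_b] = bolus_at.get(t_b, 0.0) + units * 1000.0  # U -> mU

    for a, b in zip(events[:-1], events[1:]):
        if a in bolus_at:
            y = y + np.array([bolus_at[a], 0.0, 0.0])
        u = rate_mU_min(0.5 * (a + b))

        def f(t, s, u=u):
            s1, s2, i = s
            return (
                u - s1 / tmax,
                (s1 - s2) / tmax,
                s2 / (tmax * vi) - ke * i,
            )

        mask = (grid > a) & (grid <= b)
        t_eval = np.unique(np.concatenate([grid[mask], [b]]))
        sol = solve_ivp(f, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=1e-9, atol=1e-12)
        if not sol.success:  # pragma: no cover - linear chain does not fail
            raise RuntimeError(f"insulin submodel integration failed: {sol.message}")
        if np.any(mask):
            idx = np.searchsorted(sol.t, grid[mask])
            out[mask] = sol.y[2][idx]
        y = sol.y[:, -1]

    return ForcingFunction(times=grid, values=np.maximum(out, 0.0))


def meal_submodel(
    carbs: float,
    meal_time: float,
    kinetics: MealKinetics = MealKinetics(),
    t_span: Tuple[float, float] = (0.0, 360.0),
    dt: float = 0.5,
) -> ForcingFunction:
    """Glucose appearance Ra(t)/Vg (mmol/L/min) for one carbohydrate load."""
    if carbs < 0:
        raise ValueError("carbs must be non-negative")
    grid = np.arange(t_span[0], t_span[1] + 0.5 * dt, dt)
    tau = np.maximum(grid - meal_time, 0.0)
    total = carbs * MMOL_PER_G_GLUCOSE * kinetics.bioavailability / kinetics.vg
    ra = total * tau * np.exp(-tau / kinetics.tmax) / kinetics.tmax**2
    return ForcingFunction(times=grid, values=ra)


def _bout_session(spec: ProtocolSpec, ramp: float = 1.0) -> ExerciseSession:
    """VO2 trace for a work/rest bout structure (VO2 returns to rest between bouts)."""
    if spec.bouts is None:
        return default_exercise_trace(
            intensity=spec.intensity,
            duration=spec.duration,
            t_start=spec.exercise_start,
        )
    level = VO2_REST_DEFAULT + spec.intensity * (VO2_MAX_DEFAULT - VO2_REST_DEFAULT)
    times: List[float] = []
    values: List[float] = []
    t = spec.exercise_start
    for work, rest in spec.bouts:
        times += [t, t + ramp, t + work - ramp, t + work]
        values += [VO2_REST_DEFAULT, level, level, VO2_REST_DEFAULT]
        t += work + rest
    return ExerciseSession(
        t_start=spec.exercise_start,
        duration=spec.duration,
        vo2_rest=VO2_REST_DEFAULT,
        vo2_max=VO2_MAX_DEFAULT,
        vo2_times=np.array(times),
        vo2_values=np.array(values),
    )


def _simulate_arm(
    params: ModelParameters,
    spec: ProtocolSpec,
    kinetics: InsulinKinetics,
    meal_kinetics: MealKinetics,
    follow_up: float = 60.0,
    grid_dt: float = 1.0,
) -> Trajectory:
    horizon = spec.exercise_end + follow_up
    t_span = (0.0, horizon)
    basal_U_h = basal_rate_for(params.Insb, kinetics) * 60.0 / 1000.0

    profile: List[Tuple[float, float]] = [(0.0, basal_U_h)]
    if spec.pump_suspend:
        profile.append((spec.exercise_start, 0.0))
    elif spec.basal_reduction > 0:
        profile.append(
            (
                spec.exercise_start - spec.basal_reduction_lead,
                basal_U_h * (1.0 - spec.basal_reduction),
            )
        )

    boluses: List[Tuple[float, float]] = []
    appearance = None
    if spec.meal_carbs > 0 and spec.meal_time is not None:
        full_bolus = spec.meal_carbs / kinetics.icr
        boluses.append((spec.meal_time, full_bolus * (1.0 - spec.bolus_reduction)))
        appearance = meal_submodel(
            spec.meal_carbs, spec.meal_time, kinetics=meal_kinetics, t_span=t_span
        )

    insulin = insulin_submodel(profile, boluses, kinetics=kinetics, t_span=t_span)
    session = _bout_session(spec)
    grid = np.arange(0.0, horizon + 0.5 * grid_dt, grid_dt)
    return simulate(
        params.with_variant(params.variant),
        insulin,
        session=session,
        t_grid=grid,
        init="steady",
        appearance=appearance,
    )


@dataclass
class OutcomeReport:
    """Per-subject and cohort glycemic outcomes over a stated window."""

    window: Tuple[float, float]
    per_subject: pd.DataFrame  # index subject; pct_4_8 pct_4_10 pct_below_4
    # pct_below_3_3 start_glucose end_glucose drop
    label: str = ""

    def __post_init__(self) -> None:
        df = self.per_subject
        pct_cols = [c for c in df.columns if c.startswith("pct_")]
        if ((df[pct_cols] < -1e-9) | (df[pct_cols] > 100 + 1e-9)).any().any():
            raise ValueError("percentages must lie in [0, 100]")
        if (df["pct_4_8"] > df["pct_4_10"] + 1e-9).any():
            raise ValueError("band nesting violated: pct_4_8 must be <= pct_4_10")

    def cohort_mean(self, column: str) -> float:
        return float(self.per_subject[column].mean())

    def cohort_sd(self, column: str) -> float:
        return float(self.per_subject[column].std(ddof=1))

    def cohort_median(self, column: str) -> float:
        return float(self.per_subject[column].median())

    def cohort_iqr(self, column: str) -> Tuple[float, float]:
        q = self.per_subject[column].quantile([0.25, 0.75])
        return float(q.iloc[0]), float(q.iloc[1])

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path)

    def summary_text(self) -> str:
        rows = [
            ("Time spent between 4-8 mmol/L", "pct_4_8"),
            ("Time spent between 4-10 mmol/L", "pct_4_10"),
            ("Time spent below 4 mmol/L", "pct_below_4"),
            ("Time spent below 3.3 mmol/L", "pct_below_3_3"),
        ]
        lines = [f"Glycemic outcomes {self.label}".rstrip()]
        lines.append(f"window: {self.window[0]:g}-{self.window[1]:g} min")
        for title, col in rows:
            lines.append(
                f"{title}: {self.cohort_mean(col):.0f} ({self.cohort_sd(col):.0f})"
            )
        lines.append(
            "Glucose drop start-to-end of exercise: "
            f"{self.cohort_mean('drop'):.2f} ({self.cohort_sd('drop'):.2f}) mmol/L"
        )
        return "\n".join(lines)


def _band_percent(t: np.ndarray, g: np.ndarray, lo: float, hi: float) -> float:
    """Exact occupancy (%) of a band for a piecewise-linear trace."""
    total = t[-1] - t[0]
    inside = 0.0
    for k in range(t.size - 1):
        dt = t[k + 1] - t[k]
        a, b = g[k], g[k + 1]
        g_min, g_max = (a, b) if a <= b else (b, a)
        if g_max <= lo or g_min >= hi:
            continue
        if g_max == g_min:
            inside += dt if lo <= g_min <= hi else 0.0
        else:
            overlap = min(g_max, hi) - max(g_min, lo)
            if overlap > 0:
                inside += dt * overlap / (g_max - g_min)
    return 100.0 * inside / total


def glycemic_outcomes(
    trajectories: Mapping[str, Trajectory],
    window: Tuple[float, float],
    label: str = "",
) -> OutcomeReport:
    """Time-in-range metrics and exercise glucose drop for a set of trajectories."""
    lo, hi = window
    if not hi > lo:
        raise ValueError("empty outcome window")
    rows = {}
    for sid, traj in trajectories.items():
        if lo < traj.times[0] or hi > traj.times[-1]:
            raise ValueError(
                f"window ({lo:g}, {hi:g}) outside trajectory span for {sid!r}"
            )
        mask = (traj.times >= lo) & (traj.times <= hi)
        t = traj.times[mask]
        g = traj.G[mask]
        start = float(np.interp(lo, traj.times, traj.G))
        end = float(np.interp(hi, traj.times, traj.G))
        rows[sid] = {
            "pct_4_8": _band_percent(t, g, 4.0, 8.0),
            "pct_4_10": _band_percent(t, g, 4.0, 10.0),
            "pct_below_4": _band_percent(t, g, -np.inf, 4.0),
            "pct_below_3_3": _band_percent(t, g, -np.inf, 3.3),
            "start_glucose": start,
            "end_glucose": end,
            "drop": start - end,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "subject"
    return OutcomeReport(window=window, per_subject=df, label=label)


def run_study1(
    cohort: Sequence[ModelParameters],
    protocol_id: int,
    kinetics: InsulinKinetics = InsulinKinetics(),
    meal_kinetics: MealKinetics = MealKinetics(),
    follow_up: float = 60.0,
) -> Tuple[Dict[str, Trajectory], OutcomeReport]:
    """Replay one Study-1 arm (postprandial exercise, bolus reduction) on a cohort."""
    if protocol_id not in STUDY1_PROTOCOLS:
        raise ValueError(
            f"protocol_id must be one of {sorted(STUDY1_PROTOCOLS)}, got {protocol_id!r}"
        )
    spec = STUDY1_PROTOCOLS[protocol_id]
    trajectories = {
        f"S{i:02d}": _simulate_arm(p, spec, kinetics, meal_kinetics, follow_up)
        for i, p in enumerate(cohort)
    }
    report = glycemic_outcomes(
        trajectories,
        window=(spec.exercise_start, spec.exercise_end + follow_up),
        label=spec.label,
    )
    return trajectories, report


def run_study2(
    cohort: Sequence[ModelParameters],
    strategy: str,
    kinetics: InsulinKinetics = InsulinKinetics(),
    follow_up: float = 30.0,
) -> Tuple[Dict[str, Trajectory], OutcomeReport]:
    """Replay one Study-2 basal-reduction arm (intermittent 50% VO2max session)."""
    if strategy not in STUDY2_STRATEGIES:
        raise ValueError(
            f"strategy must be one of {sorted(STUDY2_STRATEGIES)}, got {strategy!r}"
        )
    spec = STUDY2_STRATEGIES[strategy]
    trajectories = {
        f"S{i:02d}": _simulate_arm(p, spec, kinetics, MealKinetics(), follow_up)
        for i, p in enumerate(cohort)
    }
    report = glycemic_outcomes(
        trajectories,
        window=(spec.exercise_start, spec.exercise_end),
        label=spec.label,
    )
    return trajectories, report
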