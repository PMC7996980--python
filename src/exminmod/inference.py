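"""Bayesian per-subject parameter estimation by adaptive MCMC.

The observation model treats plasma insulin and VO2 as measured forcings
(open-loop identification) and plasma glucose observations as

    y_i ~ Normal(Ghat(t_i), sigma_i),   sigma_i = cv * Ghat(t_i)

with a measurement coefficient of variation of 2% by default. The noise
scale is proportional to the model prediction, not the observation, so the
likelihood stays a proper density in the parameters.

Sampling runs an adaptive random-walk Metropolis on log-transformed
parameters with log-normal priors; the proposal covariance and global
scale adapt during burn-in (Haario-style empirical covariance plus a
Robbins-Monro scale targeting ~30% acceptance) and are frozen afterwards
to preserve detailed balance in the kept portion of the chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import ExerciseSession, ModelParameters
from .simulate import ForcingFunction

__all__ = [
    "SubjectDataset",
    "PriorSpec",
    "PosteriorChains",
    "PosteriorSummary",
    "GlucoseLikelihood",
    "log_likelihood",
    "deviance",
    "sample_posterior",
    "adaptive_metropolis",
    "summarize",
    "filter_sessions",
    "free_parameters",
    "FAST_N_ITER",
    "FAST_N_BURN",
    "FULL_N_ITER",
    "FULL_N_BURN",
]

logger = logging.getLogger("exminmod")

PARAM_NAMES = ("Gp0", "p1", "p2", "p3", "e1", "e2")

# chain-length defaults: full runs keep the last 20,000 of 100,000
# iterations; fast mode keeps the last 2,000 of 10,000.
FULL_N_ITER, FULL_N_BURN = 100_000, 80_000
FAST_N_ITER, FAST_N_BURN = 10_000, 8_000

#: measurement coefficient of variation of plasma glucose
MEASUREMENT_CV = 0.02

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def free_parameters(variant: int) -> Tuple[str, ...]:
    """Names of the parameters estimated for a variant.

    Variants 2 and 3 have a single exercise gain (stored in ``e1``); the
    other variants estimate both ``e1`` and ``e2``.
    """
    if variant in (2, 3):
        return PARAM_NAMES[:5]
    return PARAM_NAMES


@dataclass
class SubjectDataset:
    """One subject-session of observations, the unit the likelihood consumes."""

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    vo2: np.ndarray
    session: Optional[ExerciseSession]
    symptoms: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        n = self.times.size
        for name in ("glucose", "insulin", "vo2"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")
        if n < 2:
            raise ValueError("a dataset needs at least two observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose observations must be strictly positive")
        if self.symptoms is not None:
            self.symptoms = np.asarray(self.symptoms, dtype=bool)
            if self.symptoms.size != n:
                raise ValueError("symptoms length does not match times")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    @property
    def basal_insulin(self) -> float:
        """Insb fixed to the mean of pre-exercise insulin observations."""
        if self.session is None:
            return float(np.mean(self.insulin))
        pre = self.times <= self.session.t_start
        if not np.any(pre):
            return float(np.mean(self.insulin))
        return float(np.mean(self.insulin[pre]))

    def insulin_forcing(self) -> ForcingFunction:
        return ForcingFunction(times=self.times, values=self.insulin)


# --------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-normal priors, parameterised by geometric mean and log-sd.

    The defaults centre the rate constants on literature-plausible values
    (p1 = 0.0025 /min, p2 = 0.03 /min, p3 = 1.5e-5, Gp0 = 35 mmol/L) with
    log-sd 0.5, and the exercise gains on 1.0 with log-sd 1.0 — deliberately
    weak, since the short pre-exercise window carries little information
    about p1 and p2 on its own.
    """

    loc: Mapping[str, float] = field(
        default_factory=lambda: {
            "Gp0": 35.0,
            "p1": 0.0025,
            "p2": 0.03,
            "p3": 1.5e-5,
            "e1": 1.0,
            "e2": 1.0,
        }
    )
    log_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "Gp0": 0.5,
            "p1": 0.5,
            "p2": 0.5,
            "p3": 0.5,
            "e1": 1.0,
            "e2": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.loc or name not in self.log_sd:
                raise ValueError(f"prior missing parameter {name!r}")
            if not self.loc[name] > 0:
                raise ValueError(f"prior location for {name!r} must be positive")
            if not self.log_sd[name] > 0:
                raise ValueError(f"prior log-sd for {name!r} must be positive")

    def mu_z(self, names: Sequence[str]) -> np.ndarray:
        return np.array([np.log(self.loc[n]) for n in names])

    def sd_z(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.log_sd[n] for n in names])

    def log_prior_z(self, names: Sequence[str], z: np.ndarray) -> float:
        """Gaussian log-density of the log-parameters (the sampling scale)."""
        mu = self.mu_z(names)
        sd = self.sd_z(names)
        r = (z - mu) / sd
        return float(-0.5 * np.sum(r * r) - np.sum(np.log(sd)) - len(names) * _LOG_SQRT_2PI)

    def sample(self, names: Sequence[str], rng: np.random.Generator) -> Dict[str, float]:
        mu, sd = self.mu_z(names), self.sd_z(names)
        z = rng.normal(mu, sd)
        return dict(zip(names, np.exp(z)))


# --------------------------------------------------------------------------
# likelihood


class GlucoseLikelihood:
    """Cached per-dataset likelihood evaluator using the compiled RK4 kernel.

    On construction the dataset's integration grid (observation times,
    forcing knots, exercise-window edges, subdivided to <= ``dt``-min steps)
    is tabulated once — insulin, exercise intensity and normalised exercise
    time at every RK4 stage — so each parameter evaluation is pure
    arithmetic.
    """

    def __init__(
        self,
        data: SubjectDataset,
        variant: int,
        dt: float = _kernels.DEFAULT_DT,
        noise_cv: float = MEASUREMENT_CV,
    ):
        self.data = data
        self.variant = int(variant)
        self.dt = float(dt)
        self.noise_cv = float(noise_cv)
        self.insb = data.basal_insulin

        t0, t1 = data.times[0], data.times[-1]
        session = data.session
        pts = [data.times]
        if session is not None:
            edges = np.array([session.t_start, session.t_end])
            pts.append(edges[(edges >= t0) & (edges <= t1)])
            knots = session.vo2_times
            pts.append(knots[(knots >= t0) & (knots <= t1)])
        breaks = np.unique(np.concatenate(pts))
        is_obs = np.isin(breaks, data.times)
        self._y = data.glucose

        ins_interp = lambda t: np.interp(t, data.times, data.insulin)
        if session is not None:
            pvo2_interp = session.pvo2
            te_of = session.te
            in_window = session.in_window
        else:
            pvo2_interp = lambda t: np.zeros_like(np.asarray(t, dtype=float))
            te_of = pvo2_interp
            in_window = lambda t: False
        tab = _kernels.tabulate_grid(
            breaks, is_obs, self.dt, ins_interp, pvo2_interp, te_of, in_window
        )
        self._tab = tab
        self._tab_args = (
            tab["h"], tab["ins"], tab["pvo2"], tab["te"],
            tab["in_ex"], tab["rec"], tab["rec_first"],
        )

    def _theta(self, params: ModelParameters) -> Tuple[float, ...]:
        return (params.Gp0, params.p1, params.p2, params.p3, params.e1, params.e2)

    def predict(self, params: ModelParameters) -> np.ndarray:
        """Model glucose at the observation times, from the basal steady state."""
        Gp0, p1, p2, p3, e1, e2 = self._theta(params)
        X0 = p3 / p2 * params.Insb
        G0 = Gp0 * p1 / (p1 + X0)
        tab = self._tab
        return _kernels.predict_tab(
            tab["h"], tab["ins"], tab["pvo2"], tab["te"], tab["in_ex"],
            tab["rec"], tab["rec_first"], self.data.n_obs,
            G0, X0, Gp0, p1, p2, p3, e1, e2, self.variant,
        )

    def __call__(self, params: ModelParameters) -> float:
        Gp0, p1, p2, p3, e1, e2 = self._theta(params)
        return float(
            _kernels.loglike_tab(
                self._y, self.noise_cv, params.Insb, *self._tab_args,
                Gp0, p1, p2, p3, e1, e2, self.variant,
            )
        )


def log_likelihood(params: ModelParameters, data: SubjectDataset, **kwargs) -> float:
    """Gaussian log-likelihood of the glucose observations under ``params``."""
    return GlucoseLikelihood(data, params.variant, **kwargs)(params)


def deviance(params: ModelParameters, data: SubjectDataset, **kwargs) -> float:
    """Deviance D(theta) = -2 log p(y | theta)."""
    return -2.0 * log_likelihood(params, data, **kwargs)


# --------------------------------------------------------------------------
# sampler


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], Tuple[float, float]],
    x0: np.ndarray,
    n_iter: int,
    n_burn: int,
    seed: int,
    target_accept: float = 0.3,
    init_scale: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Adaptive random-walk Metropolis with frozen post-burn-in proposal.

    ``log_post`` maps a parameter vector to ``(log posterior, aux)``; the
    aux value (here: the log-likelihood) is recorded alongside each kept
    draw. Returns ``(samples, aux, acceptance_rate)`` where the acceptance
    rate refers to the kept (post-burn-in) portion.
    """
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp, aux = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")

    base_scale = 2.38 / np.sqrt(d)
    log_s = np.log(init_scale)
    cov = np.eye(d)
    chol = np.linalg.cholesky(cov)

    mean_acc = np.zeros(d)
    m2 = np.zeros((d, d))
    n_hist = 0

    n_keep = n_iter - n_burn
    samples = np.empty((n_keep, d))
    aux_out = np.empty(n_keep)
    accepted_kept = 0

    for it in range(n_iter):
        step = np.exp(log_s) * base_scale * (chol @ rng.standard_normal(d))
        x_prop = x + step
        lp_prop, aux_prop = log_post(x_prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp, aux = x_prop, lp_prop, aux_prop

        if it < n_burn:
            # running empirical covariance of the adaptation history
            n_hist += 1
            delta = x - mean_acc
            mean_acc += delta / n_hist
            m2 += np.outer(delta, x - mean_acc)
            gamma = (it + 1) ** -0.6
            log_s += gamma * ((1.0 if accept else 0.0) - target_accept)
            if n_hist > 2 * d and it % 50 == 0:
                emp = m2 / (n_hist - 1) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(emp)
                except np.linalg.LinAlgError:
                    pass
        else:
            k = it - n_burn
            samples[k] = x
            aux_out[k] = aux
            accepted_kept += int(accept)

    acc_rate = accepted_kept / max(n_keep, 1)
    return samples, aux_out, acc_rate


@dataclass
class PosteriorChains:
    """Kept MCMC draws (natural scale) plus the per-iteration deviance."""

    params: Dict[str, np.ndarray]
    deviance: np.ndarray
    accept_rate: float
    seed: int
    n_iter: int
    n_burn: int
    variant: int
    insb: float
    subject_id: str = ""
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.deviance.size
        for name, arr in self.params.items():
            if arr.size != n:
                raise ValueError(f"chain for {name!r} has mismatched length")
        if not np.all(np.isfinite(self.deviance)):
            raise ValueError("non-finite deviance in kept chain")

    @property
    def n_kept(self) -> int:
        return int(self.deviance.size)

    def parameters_at(self, i: int) -> ModelParameters:
        rec = {name: arr[i] for name, arr in self.params.items()}
        rec.setdefault("e2", 0.0)
        rec.update(Insb=self.insb, variant=self.variant)
        return ModelParameters.from_record(rec)

    def posterior_mean_parameters(self, scale: str = "init") -> ModelParameters:
        """Posterior mean point, as a parameter set.

        ``scale`` selects the parameterisation in which coordinate means
        are taken:

        * ``"init"`` (default) — geometric means of (G0, p1, p2, p3, e1,
          e2), where G0 is the per-draw steady-state initial glucose, with
          Gp0 backed out afterwards. The data pin G0 tightly while leaving
          wide, strongly curved ridges in the raw parameters, so this is
          the coordinate system in which the posterior is closest to
          Gaussian and a coordinate mean stays on the data-constrained
          manifold.
        * ``"log"`` — geometric means of the raw parameters (the sampling
          scale).
        * ``"natural"`` — coordinate-wise arithmetic means.
        """
        if scale == "init":
            g = {
                name: float(np.exp(np.mean(np.log(arr))))
                for name, arr in self.params.items()
            }
            x0_draws = self.params["p3"] / self.params["p2"] * self.insb
            g0_draws = (
                self.params["Gp0"] * self.params["p1"] / (self.params["p1"] + x0_draws)
            )
            g0_bar = float(np.exp(np.mean(np.log(g0_draws))))
            x0_bar = g["p3"] / g["p2"] * self.insb
            g["Gp0"] = g0_bar * (g["p1"] + x0_bar) / g["p1"]
            rec = g
        elif scale == "log":
            rec = {
                name: float(np.exp(np.mean(np.log(arr))))
                for name, arr in self.params.items()
            }
        elif scale == "natural":
            rec = {name: float(np.mean(arr)) for name, arr in self.params.items()}
        else:
            raise ValueError(f"unknown scale {scale!r}")
        rec.setdefault("e2", 0.0)
        rec.update(Insb=self.insb, variant=self.variant)
        return ModelParameters.from_record(rec)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params)
        df["deviance"] = self.deviance
        return df


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter location and spread of a posterior sample."""

    stats: pd.DataFrame  # index: parameter; columns: median q25 q75 mean sd cv

    def median(self, name: str) -> float:
        return float(self.stats.loc[name, "median"])

    def iqr(self, name: str) -> Tuple[float, float]:
        return (float(self.stats.loc[name, "q25"]), float(self.stats.loc[name, "q75"]))

    def cv(self, name: str) -> float:
        return float(self.stats.loc[name, "cv"])


def summarize(chains: PosteriorChains) -> PosteriorSummary:
    """Median, interquartile range, mean, sd and CV = sd/mean per parameter."""
    if chains.n_kept == 0:
        raise ValueError("empty chains")
    rows = {}
    for name, arr in chains.params.items():
        q25, med, q75 = np.percentile(arr, [25, 50, 75])
        mean = float(np.mean(arr))
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        rows[name] = {
            "median": float(med),
            "q25": float(q25),
            "q75": float(q75),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else np.nan,
        }
    return PosteriorSummary(stats=pd.DataFrame(rows).T)


def sample_posterior(
    data: SubjectDataset,
    variant: int,
    prior: Optional[PriorSpec] = None,
    n_iter: int = FULL_N_ITER,
    n_burn: int = FULL_N_BURN,
    seed: int = 0,
    fast: bool = False,
    dt: float = _kernels.DEFAULT_DT,
    noise_cv: float = MEASUREMENT_CV,
) -> PosteriorChains:
    """Draw from the posterior of one subject under one model variant.

    With ``fast=True`` the chain length drops to 10,000 iterations keeping
    the last 2,000 — enough for smoke tests and cohort-level model ranking,
    not for publication-grade posterior summaries.
    """
    prior = prior or PriorSpec()
    if fast:
        n_iter, n_burn = FAST_N_ITER, FAST_N_BURN
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    names = free_parameters(variant)
    like = GlucoseLikelihood(data, variant, dt=dt, noise_cv=noise_cv)
    insb = like.insb

    samples_z, ll_kept, acc = _kernels.run_chain(
        prior.mu_z(names),
        prior.sd_z(names),
        n_iter,
        n_burn,
        seed,
        0.3,
        0.1,
        data.glucose,
        noise_cv,
        insb,
        *like._tab_args,
        variant,
        variant not in (2, 3),
    )
    if not np.all(np.isfinite(ll_kept)):
        raise RuntimeError("non-finite log-likelihood in kept chain")
    nat = np.exp(samples_z)
    chains = PosteriorChains(
        params={name: nat[:, i].copy() for i, name in enumerate(names)},
        deviance=-2.0 * ll_kept,
        accept_rate=acc,
        seed=seed,
        n_iter=n_iter,
        n_burn=n_burn,
        variant=variant,
        insb=insb,
        subject_id=data.subject_id,
    )
    if acc < 0.01:
        msg = (
            f"acceptance rate {acc:.3%} below 1% for subject {data.subject_id!r}, "
            f"variant {variant}"
        )
        chains.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    logger.info(
        "fit subject=%s variant=%d n_iter=%d kept=%d accept=%.1f%%",
        data.subject_id, variant, n_iter, chains.n_kept, 100 * acc,
    )
    return chains


# --------------------------------------------------------------------------
# study-design filtering


def filter_sessions(
    datasets: Iterable[SubjectDataset],
    glucose_symptomatic: float = 3.3,
    glucose_any: float = 3.0,
) -> List[SubjectDataset]:
    """Apply the hypoglycemia exclusion rule and return the retained datasets.

    A session is excluded when any pre- or during-exercise sample shows
    glucose below ``glucose_symptomatic`` (3.3 mmol/L) with symptoms, or
    below ``glucose_any`` (3.0 mmol/L) irrespective of symptoms. Missing
    symptom flags are treated as asymptomatic with a logged warning.
    """
    retained: List[SubjectDataset] = []
    for ds in datasets:
        if ds.session is None:
            scope = np.ones(ds.n_obs, dtype=bool)
        else:
            scope = ds.times <= ds.session.t_end
        if ds.symptoms is None:
            logger.warning(
                "dataset %s has no symptom flags; treating all samples as asymptomatic",
                ds.subject_id,
            )
            symptoms = np.zeros(ds.n_obs, dtype=bool)
        else:
            symptoms = ds.symptoms
        g = ds.glucose[scope]
        s = symptoms[scope]
        hypo = np.any((g < glucose_any) | ((g < glucose_symptomatic) & s))
        if hypo:
            logger.info(
                "excluding dataset %s: hypoglycemia before/during exercise "
                "(min glucose %.2f mmol/L)",
                ds.subject_id,
                float(np.min(g)),
            )
        else:
            retained.append(ds)
    return retained
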