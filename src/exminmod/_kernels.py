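"""Compiled inner loops for the MCMC likelihood path.

The posterior sampler evaluates the glucose trajectory up to a hundred
thousand times per fit, so the observation-time predictor is a numba-jitted
fixed-step classical Runge-Kutta (RK4) integrator working from
*pre-tabulated* forcing values: the integration grid of a given dataset is
fixed (segments between the sorted union of observation times, forcing
knots and exercise-window edges, subdivided to steps <= 0.5 min), so
insulin, exercise intensity and normalised exercise time are evaluated once
per dataset at every RK4 stage time and reused for every parameter draw.

The system's time constants (1/p1 ~ 500 min, 1/p2 ~ 30 min) put a 0.5-min
step deep inside RK4's stability and accuracy region, and exercise-window
membership is decided per segment so no step straddles a discontinuity in
the right-hand side.

``run_chain`` is the fully compiled adaptive random-walk Metropolis used by
``sample_posterior``: Gaussian priors on the log-parameters, proposal
covariance adapted from the chain history during burn-in (with a
Robbins-Monro global scale targeting ~30% acceptance), frozen afterwards.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: default fixed step (min) of the likelihood integrator
DEFAULT_DT = 0.5

_GLUCOSE_FLOOR = 1e-6
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def tabulate_grid(breaks: np.ndarray, is_obs: np.ndarray, dt: float,
                  ins_interp, pvo2_interp, te_of, in_window) -> dict:
    """Precompute per-step integration tables for one dataset.

    ``ins_interp``/``pvo2_interp``/``te_of`` are vectorised callables of
    absolute time; ``in_window`` maps a time to exercise-window membership.
    Returns arrays indexed by RK4 step: step size, stage forcings at
    (t, t+h/2, t+h), window flag, and the observation slot filled after the
    step (-1 for none).
    """
    h_list, rec_list, inex_list = [], [], []
    t0_list = []
    obs_slot = 0
    rec_first = -1
    if is_obs[0]:
        rec_first = 0
        obs_slot = 1
    for k in range(breaks.size - 1):
        a, b = breaks[k], breaks[k + 1]
        n = max(int(np.ceil((b - a) / dt)), 1)
        h = (b - a) / n
        mid = 0.5 * (a + b)
        inex = bool(in_window(mid))
        for i in range(n):
            t0_list.append(a + i * h)
            h_list.append(h)
            inex_list.append(inex)
            rec_list.append(-1)
        if is_obs[k + 1]:
            rec_list[-1] = obs_slot
            obs_slot += 1
    t0 = np.asarray(t0_list)
    h = np.asarray(h_list)
    stages = np.stack([t0, t0 + 0.5 * h, t0 + h])  # (3, n_steps)
    inex = np.asarray(inex_list)
    ins = ins_interp(stages)
    pvo2 = np.where(inex[None, :], pvo2_interp(stages), 0.0)
    te = np.where(inex[None, :], te_of(stages), 0.0)
    return {
        "h": h,
        "ins": ins,
        "pvo2": pvo2,
        "te": te,
        "in_ex": inex.astype(np.int8),
        "rec": np.asarray(rec_list, dtype=np.int64),
        "rec_first": rec_first,
        "n_obs": obs_slot if rec_first < 0 else obs_slot,
    }


@njit(cache=True)
def _inc12(variant, e1, e2, pvo2, te):
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
    return e1 * pvo2, e2 * (pvo2 + te)


@njit(cache=True, fastmath=False)
def predict_tab(
    h,
    ins,
    pvo2,
    te,
    in_ex,
    rec,
    rec_first,
    n_obs,
    G0,
    X0,
    Gp0,
    p1,
    p2,
    p3,
    e1,
    e2,
    variant,
):
    """RK4 over the tabulated grid; returns G at the observation slots."""
    out = np.empty(n_obs)
    G = G0
    X = X0
    if rec_first == 0:
        out[0] = G
    for s in range(h.shape[0]):
        hs = h[s]
        ex = in_ex[s] != 0
        # stage derivative evaluations
        kG = np.empty(4)
        kX = np.empty(4)
        for stage in range(4):
            col = stage if stage < 2 else (1 if stage == 2 else 2)
            if stage == 0:
                Gs, Xs = G, X
            elif stage == 1:
                Gs, Xs = G + 0.5 * hs * kG[0], X + 0.5 * hs * kX[0]
            elif stage == 2:
                Gs, Xs = G + 0.5 * hs * kG[1], X + 0.5 * hs * kX[1]
            else:
                Gs, Xs = G + hs * kG[2], X + hs * kX[2]
            inc1 = 0.0
            inc2 = 0.0
            if ex:
                inc1, inc2 = _inc12(variant, e1, e2, pvo2[col, s], te[col, s])
            Gc = Gs if Gs > _GLUCOSE_FLOOR else _GLUCOSE_FLOOR
            kX[stage] = -p2 * Xs + p3 * (1.0 + inc2) * ins[col, s]
            kG[stage] = -p1 * (1.0 + inc1) * Gc - Xs * Gc + p1 * Gp0
        G = G + hs / 6.0 * (kG[0] + 2.0 * kG[1] + 2.0 * kG[2] + kG[3])
        X = X + hs / 6.0 * (kX[0] + 2.0 * kX[1] + 2.0 * kX[2] + kX[3])
        if G < _GLUCOSE_FLOOR:
            G = _GLUCOSE_FLOOR
        r = rec[s]
        if r >= 0:
            out[r] = G
    return out


@njit(cache=True)
def loglike_tab(
    y,
    cv,
    insb,
    h,
    ins,
    pvo2,
    te,
    in_ex,
    rec,
    rec_first,
    Gp0,
    p1,
    p2,
    p3,
    e1,
    e2,
    variant,
):
    """Gaussian log-likelihood with sigma_i = cv * Ghat_i; -inf on failure."""
    X0 = p3 / p2 * insb
    G0 = Gp0 * p1 / (p1 + X0)
    ghat = predict_tab(
        h, ins, pvo2, te, in_ex, rec, rec_first, y.shape[0],
        G0, X0, Gp0, p1, p2, p3, e1, e2, variant,
    )
    ll = 0.0
    for i in range(y.shape[0]):
        g = ghat[i]
        if not np.isfinite(g) or g <= 0.0:
            return -np.inf
        sigma = cv * g
        r = (y[i] - g) / sigma
        ll += -0.5 * r * r - np.log(sigma) - _LOG_SQRT_2PI
    return ll


@njit(cache=True)
def run_chain(
    mu_z,
    sd_z,
    n_iter,
    n_burn,
    seed,
    target_accept,
    init_scale,
    y,
    cv,
    insb,
    h,
    ins,
    pvo2,
    te,
    in_ex,
    rec,
    rec_first,
    variant,
    has_e2,
):
    """Adaptive random-walk Metropolis on the log-parameters.

    Parameter order: (Gp0, p1, p2, p3, e1[, e2]). Returns kept log-samples,
    kept log-likelihoods and the post-burn-in acceptance rate.
    """
    np.random.seed(seed)
    d = mu_z.shape[0]
    z = mu_z.copy()

    def _post(zv):
        g = np.exp(zv)
        e2v = g[5] if has_e2 else 0.0
        ll = loglike_tab(
            y, cv, insb, h, ins, pvo2, te, in_ex, rec, rec_first,
            g[0], g[1], g[2], g[3], g[4], e2v, variant,
        )
        if not np.isfinite(ll):
            return -np.inf, -np.inf
        lp = 0.0
        for j in range(d):
            rj = (zv[j] - mu_z[j]) / sd_z[j]
            lp += -0.5 * rj * rj - np.log(sd_z[j]) - _LOG_SQRT_2PI
        return lp + ll, ll

    lp, ll = _post(z)
    base_scale = 2.38 / np.sqrt(d)
    log_s = np.log(init_scale)
    chol = np.eye(d)

    mean_hist = np.zeros(d)
    m2 = np.zeros((d, d))
    n_hist = 0

    n_keep = n_iter - n_burn
    samples = np.empty((n_keep, d))
    ll_out = np.empty(n_keep)
    accepted_kept = 0

    for it in range(n_iter):
        eps = np.random.standard_normal(d)
        z_prop = z + np.exp(log_s) * base_scale * (chol @ eps)
        ok = True
        for j in range(d):
            if np.abs(z_prop[j]) > 50.0:
                ok = False
        accept = False
        if ok:
            lp_prop, ll_prop = _post(z_prop)
            if np.log(np.random.random()) < lp_prop - lp:
                z = z_prop
                lp = lp_prop
                ll = ll_prop
                accept = True

        if it < n_burn:
            n_hist += 1
            delta = z - mean_hist
            mean_hist += delta / n_hist
            m2 += np.outer(delta, z - mean_hist)
            gamma = (it + 1.0) ** -0.6
            log_s += gamma * ((1.0 if accept else 0.0) - target_accept)
            if n_hist > 2 * d and it % 50 == 0:
                emp = m2 / (n_hist - 1) + 1e-10 * np.eye(d)
                chol_new = np.linalg.cholesky(emp)
                chol = chol_new
        else:
            k = it - n_burn
            samples[k] = z
            ll_out[k] = ll
            if accept:
                accepted_kept += 1

    acc_rate = accepted_kept / max(n_keep, 1)
    return samples, ll_out, acc_rate
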