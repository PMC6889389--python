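"""Independent oracles used by the test suite.

These deliberately re-derive quantities through routes that do not share
code with the library: a dense matrix Kalman filter for the linear-Gaussian
special case, a bootstrap particle filter for the nonlinear likelihood, and
brute-force Monte-Carlo simulators.
"""
from __future__ import annotations

import math

import numpy as np

from leukossm import PatientRecord, TcmParameters, make_dose_fn


def substep_lengths(t0: float, t1: float, dt0: float) -> list[float]:
    span = t1 - t0
    n = max(1, math.ceil(span / dt0 - 1e-12))
    return [dt0] * (n - 1) + [span - (n - 1) * dt0]


def linear_tcm_matrices(p: TcmParameters, d: float, dt: float):
    """One-substep transition of the (M, L) system when the proliferation
    feedback is negligible (k_pl_max ~ 0), where the model is exactly
    linear-Gaussian: x' = F x + c + noise."""
    a = math.exp(-p.k_me * dt)
    m_ss = p.e_tgn * d / (d + p.h) if d > 0 else 0.0
    F = np.array([[a, 0.0], [-dt, 1.0]])
    c = np.array([m_ss * (1.0 - a), dt * (p.k_pl_max * 0.5 - p.k_L)])
    # with k_pl_max ~ 0 the feedback term is ~ k_pl_max * rho^g/(rho^g+e^{gL});
    # we freeze it at its value for L = log(rho) (= k_pl_max/2), which is exact
    # in the k_pl_max -> 0 limit used by the tests
    Q = np.diag([0.0, p.sigma_L ** 2 * dt])
    return F, c, Q


def exact_kalman_loglik(record: PatientRecord, p: TcmParameters) -> float:
    """Exact Kalman-filter log-likelihood for the linear-Gaussian limit of
    TCM (k_pl_max ~ 0), via dense matrix algebra."""
    mask = record.leukocyte_mask()
    times = record.obs_times[mask]
    obs = np.log(record.leukocyte[mask])
    dose_fn = make_dose_fn(record, p.t_dur)
    H = np.array([[0.0, 1.0]])
    R = np.array([[p.sigma_leuk ** 2]])
    mean = np.array([0.0, obs[0]])
    cov = np.diag([0.0, 0.5])
    t = times[0]
    ll = 0.0
    for tk, yk in zip(times, obs):
        while t < tk - 1e-12:
            for dt in substep_lengths(t, tk, p.dt):
                F, c, Q = linear_tcm_matrices(p, dose_fn(t), dt)
                mean = F @ mean + c
                cov = F @ cov @ F.T + Q
                t += dt
        S = H @ cov @ H.T + R
        resid = yk - (H @ mean)[0]
        ll += -0.5 * (math.log(2 * math.pi * S[0, 0]) + resid ** 2 / S[0, 0])
        K = cov @ H.T / S[0, 0]
        mean = mean + (K * resid).ravel()
        cov = cov - K @ H @ cov
    return ll


def particle_filter_loglik(record: PatientRecord, p: TcmParameters,
                           n_particles: int, rng: np.random.Generator) -> float:
    """Bootstrap particle filter estimate of the TCM log-likelihood."""
    mask = record.leukocyte_mask()
    times = record.obs_times[mask]
    obs = np.log(record.leukocyte[mask])
    dose_fn = make_dose_fn(record, p.t_dur)
    rg = p.rho ** p.gamma
    M = np.zeros(n_particles)
    L = obs[0] + math.sqrt(0.5) * rng.standard_normal(n_particles)
    t = times[0]
    ll = 0.0
    s = p.sigma_leuk
    for tk, yk in zip(times, obs):
        if tk > t + 1e-12:
            for dt in substep_lengths(t, tk, p.dt):
                d = dose_fn(t)
                drift = p.k_pl_max * rg / (rg + np.exp(p.gamma * L)) - M - p.k_L
                L = L + dt * drift + p.sigma_L * math.sqrt(dt) \
                    * rng.standard_normal(n_particles)
                m_ss = p.e_tgn * d / (d + p.h) if d > 0 else 0.0
                M = (M - m_ss) * math.exp(-p.k_me * dt) + m_ss
                t += dt
        logw = -0.5 * (math.log(2 * math.pi * s * s) + ((yk - L) / s) ** 2)
        shift = logw.max()
        w = np.exp(logw - shift)
        ll += shift + math.log(w.mean())
        # systematic resampling
        cum = np.cumsum(w / w.sum())
        u = (rng.uniform() + np.arange(n_particles)) / n_particles
        idx = np.searchsorted(cum, u)
        M, L = M[idx], L[idx]
    return ll
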