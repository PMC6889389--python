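"""EKF marginal likelihood, MAP estimation and predictive distributions.

The likelihood of the state-space models is computed by the extended Kalman
filter's prediction-error decomposition: each observation contributes the
log-density of its innovation under the predicted observation distribution.
MAP estimates maximise log-likelihood plus independent Gaussian priors on
the logarithms of the free parameters (mean 0, variance 10 by default),
using Nelder–Mead in log-parameter space.  The OU infection hyperparameters
theta_V = (sigma_ou, theta_ou, beta_crp) of TCM-CRP are estimated jointly
across patients and then held fixed in per-patient fits.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from . import jm_model
from .jm_model import PredictionFailure
from .patient_data import PatientRecord, make_dose_fn
from .ssm_models import (NmParameters, ObservationVector, StateBelief,
                         TcmCrpParameters, TcmParameters, initial_belief,
                         observe_with_loglik, transition)

logger = logging.getLogger(__name__)

PENALTY = 1e10  # objective value for infeasible/failed evaluations


@dataclass
class PriorSpec:
    """Independent Gaussian prior on the log of each free parameter."""

    mean: float = 0.0
    var: float = 10.0

    def logpdf(self, log_params: np.ndarray) -> float:
        return float(np.sum(norm.logpdf(log_params, self.mean, math.sqrt(self.var))))


@dataclass
class MapFitResult:
    parameters: object
    log_posterior: float
    converged: bool
    n_evaluations: int
    model_id: str
    trace: Optional[list] = None

    def __post_init__(self) -> None:
        if self.converged and not math.isfinite(self.log_posterior):
            raise ValueError("converged fit must have finite log posterior")


@dataclass
class PredictionSet:
    """Per-target-time predictive means/variances.  ``scale`` is ``"log"``
    (mean/var describe log counts; point prediction is exp(mean)) or
    ``"linear"`` (NM)."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    scale: str = "log"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.mean = np.asarray(self.mean, float)
        self.var = np.asarray(self.var, float)
        if self.scale not in ("log", "linear"):
            raise ValueError("scale must be 'log' or 'linear'")

    def __len__(self) -> int:
        return self.times.size

    def point_predictions(self) -> np.ndarray:
        """Point predictions on the linear (1e9/L) scale."""
        return np.exp(self.mean) if self.scale == "log" else self.mean.copy()

    def intervals(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Central (equal-tailed) alpha% predictive intervals on the linear
        scale."""
        z = norm.ppf(0.5 + alpha / 200.0)
        sd = np.sqrt(self.var)
        lo, hi = self.mean - z * sd, self.mean + z * sd
        if self.scale == "log":
            lo, hi = np.exp(lo), np.exp(hi)
        return lo, hi


# ---------------------------------------------------------------------------
# EKF filtering

def _observation_rows(record: PatientRecord, with_crp: bool,
                      t_max: float | None = None):
    """(time, l, v) triples from the first leukocyte observation onward;
    l/v are None when missing.  CRP-only rows before the first leukocyte
    observation are dropped (V starts at its stationary law)."""
    leuk_mask = record.leukocyte_mask()
    if not leuk_mask.any():
        raise ValueError("record has no leukocyte observations")
    t_first = record.obs_times[leuk_mask][0]
    rows = []
    for t, y, c in zip(record.obs_times, record.leukocyte, record.crp):
        if t < t_first or (t_max is not None and t > t_max):
            continue
        l = math.log(y) if not math.isnan(y) else None
        v = math.log(c + 1.0) if (with_crp and not math.isnan(c)) else None
        if l is None and v is None:
            continue
        rows.append((float(t), l, v))
    return rows


@dataclass
class FilterResult:
    loglik: float
    belief: StateBelief                 # belief after the last assimilated row
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    filtered_mean_l: np.ndarray = field(default_factory=lambda: np.empty(0))
    filtered_var_l: np.ndarray = field(default_factory=lambda: np.empty(0))


def ekf_filter(record: PatientRecord, p: TcmParameters,
               t_max: float | None = None, mask_leuk: bool = False,
               use_crp: bool | None = None, collect: bool = False) -> FilterResult:
    """Run the EKF over a record up to ``t_max``.

    ``mask_leuk`` treats every leukocyte count as missing (used for the
    in-sample fitted mean; CRP is still assimilated for TCM-CRP).  With
    ``collect``, the filtered mean/variance of L at each observation row is
    returned.
    """
    with_crp = isinstance(p, TcmCrpParameters) if use_crp is None else use_crp
    rows = _observation_rows(record, with_crp, t_max)
    if not rows:
        raise ValueError("no observations to filter")
    t1, l1, _ = rows[0]
    if l1 is None:
        l1 = math.log(record.leukocyte[record.leukocyte_mask()][0])
    belief = initial_belief(p, l1, time=t1)
    dose_fn = make_dose_fn(record, p.t_dur)
    loglik = 0.0
    times, means, variances = [], [], []
    for t, l, v in rows:
        if t > belief.time:
            belief = transition(belief, p, dose_fn, t)
        l_use = None if mask_leuk else l
        if l_use is not None or v is not None:
            belief, ll = observe_with_loglik(
                belief, ObservationVector(l=l_use, v=v), p)
            loglik += ll
        if collect:
            times.append(t)
            means.append(belief.mean[1])
            variances.append(belief.cov[1, 1])
    return FilterResult(loglik, belief, np.array(times), np.array(means),
                        np.array(variances))


def ekf_loglik(record: PatientRecord, p: TcmParameters,
               t_max: float | None = None) -> float:
    """EKF prediction-error-decomposition log-likelihood of a record under
    TCM (leukocyte channel) or TCM-CRP (leukocyte and CRP channels)."""
    return ekf_filter(record, p, t_max=t_max).loglik


# ---------------------------------------------------------------------------
# MAP estimation

def fit_nm(record: PatientRecord, t_max: float | None = None,
           ddof: int = 1) -> MapFitResult:
    """Closed-form fit of the naive mean model: sample mean and SD of the
    observed leukocyte counts (linear scale)."""
    mask = record.leukocyte_mask()
    if t_max is not None:
        mask &= record.obs_times <= t_max
    y = record.leukocyte[mask]
    if y.size == 0:
        raise ValueError("no leukocyte observations in the training window")
    mu = float(np.mean(y))
    sigma = float(np.std(y, ddof=ddof)) if y.size > ddof else 0.0
    params = NmParameters(mu, sigma)
    # degenerate sigma = 0 (constant counts): report a zero log-likelihood
    ll = float(np.sum(norm.logpdf(y, mu, sigma))) if sigma > 0 else 0.0
    return MapFitResult(params, ll, True, y.size, "nm")


def _nelder_mead(objective, x0: np.ndarray, maxiter: int, maxfev: int | None,
                 xatol: float, fatol: float):
    return minimize(objective, x0, method="Nelder-Mead",
                    options={"xatol": xatol, "fatol": fatol,
                             "maxiter": maxiter,
                             **({"maxfev": maxfev} if maxfev else {})})


def map_fit(record: PatientRecord, model_id: str, params_init,
            prior: PriorSpec | None = None, t_max: float | None = None,
            maxiter: int = 2000, maxfev: int | None = None,
            xatol: float = 1e-6, fatol: float = 1e-8,
            keep_trace: bool = False) -> MapFitResult:
    """MAP estimation by Nelder–Mead over the log free parameters.

    ``params_init`` is a full parameter object whose free-parameter values
    serve as the starting point; fixed parameters are taken from it
    unchanged.  Deterministic given the starting point and tolerances.
    """
    if model_id == "nm":
        return fit_nm(record, t_max=t_max)
    prior = prior or PriorSpec()
    if model_id in ("tcm", "tcm-crp"):
        loglik_fn = lambda q: ekf_loglik(record, q, t_max=t_max)
    elif model_id == "jm":
        loglik_fn = lambda q: jm_model.jm_loglik(
            q, record if t_max is None else record.truncate_observations(t_max))
    else:
        raise ValueError(f"unknown model id {model_id!r}")

    x0 = np.log(params_init.free_values())
    trace: list = [] if keep_trace else None
    n_bad = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_bad
        try:
            q = params_init.with_free_values(np.exp(x))
            lp = loglik_fn(q) + prior.logpdf(x)
        except (ValueError, OverflowError, FloatingPointError, PredictionFailure):
            n_bad += 1
            return PENALTY
        if not math.isfinite(lp):
            n_bad += 1
            return PENALTY
        if trace is not None:
            trace.append((x.copy(), lp))
        return -lp

    res = _nelder_mead(objective, x0, maxiter, maxfev, xatol, fatol)
    if res.fun >= PENALTY:
        return MapFitResult(params_init, -math.inf, False, res.nfev, model_id,
                            trace)
    params = params_init.with_free_values(np.exp(res.x))
    # a maxfev-capped run has success=False but still carries a usable point;
    # callers treat a finite log posterior as usable and `converged` as the
    # optimiser's own verdict
    return MapFitResult(params, -float(res.fun), bool(res.success),
                        res.nfev, model_id, trace)


def map_fit_multistart(record: PatientRecord, model_id: str, params_init,
                       n_starts: int = 5, jitter_sd: float = 0.3,
                       seed: int = 0, **kwargs) -> list[MapFitResult]:
    """Seeded multi-start MAP fits (log-scale Gaussian jitter of the
    starting point); results sorted by decreasing log posterior."""
    rng = np.random.default_rng(seed)
    results = [map_fit(record, model_id, params_init, **kwargs)]
    x0 = np.log(params_init.free_values())
    for _ in range(n_starts - 1):
        start = params_init.with_free_values(
            np.exp(x0 + jitter_sd * rng.standard_normal(x0.size)))
        results.append(map_fit(record, model_id, start, **kwargs))
    return sorted(results, key=lambda r: -r.log_posterior)


# ---------------------------------------------------------------------------
# joint estimation of the infection hyperparameters

THETA_V_NAMES = ("sigma_ou", "theta_ou", "beta_crp")


@dataclass
class JointFitResult:
    theta_v: dict
    per_patient: list[MapFitResult]
    log_posterior: float
    converged: bool


def joint_fit_theta_v(records: Sequence[PatientRecord],
                      params_init: TcmCrpParameters,
                      prior: PriorSpec | None = None,
                      method: str = "stacked", n_sweeps: int = 2,
                      maxiter: int = 4000, maxfev: int | None = None,
                      patient_maxfev: int | None = 400) -> JointFitResult:
    """Estimate theta_V = (sigma_ou, theta_ou, beta_crp) by maximising the
    product over patients of posterior-contributions with shared theta_V.

    ``method="stacked"`` runs one Nelder–Mead over the concatenated
    per-patient free parameters plus theta_V; ``method="blockwise"``
    alternates per-patient fits with a 3-dimensional theta_V fit, which is
    more robust for larger cohorts.  All parameters, including theta_V, are
    optimised on the log scale (beta_crp is taken positive).
    """
    if len(records) < 1:
        raise ValueError("at least one record required")
    with_crp = [np.any(~np.isnan(r.crp)) for r in records]
    if len(records) >= 2 and sum(with_crp) < 2:
        raise ValueError("need >=2 patients with CRP data")
    prior = prior or PriorSpec()
    k = len(params_init.FREE)

    if method == "stacked":
        x0 = np.concatenate([np.log(params_init.free_values())] * len(records)
                            + [np.log([getattr(params_init, n)
                                       for n in THETA_V_NAMES])])

        def objective(x: np.ndarray) -> float:
            lp = prior.logpdf(x)
            tv = dict(zip(THETA_V_NAMES, np.exp(x[-3:])))
            try:
                for i, rec in enumerate(records):
                    q = replace(params_init.with_free_values(
                        np.exp(x[i * k:(i + 1) * k])), **tv)
                    lp += ekf_loglik(rec, q)
            except (ValueError, OverflowError, FloatingPointError):
                return PENALTY
            return -lp if math.isfinite(lp) else PENALTY

        res = _nelder_mead(objective, x0, maxiter, maxfev, 1e-6, 1e-8)
        if res.fun >= PENALTY:
            return JointFitResult({n: getattr(params_init, n)
                                   for n in THETA_V_NAMES}, [], -math.inf, False)
        tv = dict(zip(THETA_V_NAMES, np.exp(res.x[-3:])))
        fits = []
        for i in range(len(records)):
            q = replace(params_init.with_free_values(
                np.exp(res.x[i * k:(i + 1) * k])), **tv)
            fits.append(MapFitResult(q, -float(res.fun), True, 0, "tcm-crp"))
        return JointFitResult(tv, fits, -float(res.fun), True)

    if method != "blockwise":
        raise ValueError("method must be 'stacked' or 'blockwise'")

    current = [params_init] * len(records)
    tv = {n: getattr(params_init, n) for n in THETA_V_NAMES}
    fits: list[MapFitResult] = []
    for _ in range(n_sweeps):
        fits = []
        for rec, start in zip(records, current):
            start = replace(start, **tv)
            fits.append(map_fit(rec, "tcm-crp", start, prior=prior,
                                maxfev=patient_maxfev))
        current = [f.parameters if math.isfinite(f.log_posterior)
                   else replace(s, **tv) for f, s in zip(fits, current)]

        def tv_objective(x: np.ndarray) -> float:
            tv_trial = dict(zip(THETA_V_NAMES, np.exp(x)))
            lp = prior.logpdf(x)
            try:
                for rec, q in zip(records, current):
                    lp += ekf_loglik(rec, replace(q, **tv_trial))
                    lp += prior.logpdf(np.log(q.free_values()))
            except (ValueError, OverflowError, FloatingPointError):
                return PENALTY
            return -lp if math.isfinite(lp) else PENALTY

        res = _nelder_mead(tv_objective, np.log([tv[n] for n in THETA_V_NAMES]),
                           maxiter, maxfev, 1e-6, 1e-8)
        if res.fun < PENALTY:
            tv = dict(zip(THETA_V_NAMES, np.exp(res.x)))
    return JointFitResult(tv, fits, -float(res.fun), res.fun < PENALTY)


# ---------------------------------------------------------------------------
# prediction

def predict_horizon(record: PatientRecord, model_id: str, params,
                    t_from: float, horizon: float,
                    condition_crp: bool = False) -> PredictionSet:
    """Predictive distribution of the leukocyte observations in the window
    (t_from, t_from + horizon].

    State-space models filter the data up to ``t_from`` and then propagate
    without leukocyte updates; by default the horizon is fully unobserved
    (``condition_crp=True`` lets TCM-CRP assimilate CRP measurements inside
    the window).  JM solves the ODE forward with the recorded doses; NM is
    the constant N(mu_nm, sigma_nm^2).  The dose schedule used is the one in
    the record (the actually administered doses).
    """
    t_end = t_from + horizon
    target_mask = (record.obs_times > t_from) & (record.obs_times <= t_end) \
        & record.leukocyte_mask()
    target_times = record.obs_times[target_mask]
    if horizon <= 0 or target_times.size == 0:
        scale = "linear" if model_id == "nm" else "log"
        return PredictionSet(np.empty(0), np.empty(0), np.empty(0), scale)

    if model_id == "nm":
        mu, sd = params.mu_nm, params.sigma_nm
        return PredictionSet(target_times, np.full(target_times.size, mu),
                             np.full(target_times.size, sd ** 2), "linear")

    if model_id == "jm":
        dt_times, amounts = jm_model.jm_dose_schedule(record)
        t0 = min(record.start_time, float(record.obs_times[0]))
        traj = jm_model.jm_solve(params, dt_times, amounts, target_times, t0=t0)
        return PredictionSet(target_times, traj,
                             np.full(target_times.size, params.sigma_leuk ** 2),
                             "log")

    if model_id not in ("tcm", "tcm-crp"):
        raise ValueError(f"unknown model id {model_id!r}")
    belief = ekf_filter(record, params, t_max=t_from).belief
    dose_fn = make_dose_fn(record, params.t_dur)
    crp_events = []
    if condition_crp and isinstance(params, TcmCrpParameters):
        crp_mask = (record.obs_times > t_from) & (record.obs_times <= t_end) \
            & ~np.isnan(record.crp)
        crp_events = list(zip(record.obs_times[crp_mask],
                              np.log(record.crp[crp_mask] + 1.0)))
    events = sorted([(float(t), "target", None) for t in target_times]
                    + [(float(t), "crp", v) for t, v in crp_events])
    means, variances = {}, {}
    for t, kind, v in events:
        if t > belief.time:
            belief = transition(belief, params, dose_fn, t)
        if kind == "target":
            means[t] = belief.mean[1]
            variances[t] = belief.cov[1, 1] + params.sigma_leuk ** 2
        else:
            belief, _ = observe_with_loglik(
                belief, ObservationVector(v=v), params)
    return PredictionSet(target_times,
                         np.array([means[float(t)] for t in target_times]),
                         np.array([variances[float(t)] for t in target_times]),
                         "log")
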