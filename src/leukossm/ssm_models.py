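"""Transition and observation kernels of the two-compartment state-space
models of leukocyte dynamics under 6-MP.

TCM couples a one-compartment K-PD cytotoxicity state M (driven by the
BSA-normalised daily dose through a saturating Emax term and eliminated at
rate ``k_me``) to the log leukocyte count L, which follows an
Euler–Maruyama-discretised SDE with a Hill-type proliferation feedback::

    M_k = (M_{k-1} - e_tgn d/(d+h)) exp(-k_me dt) + e_tgn d/(d+h)
    L_k = L_{k-1} + dt (k_pl_max rho^g / (rho^g + exp(g L_{k-1})) - M_{k-1} - k_L)
          + sigma_L sqrt(dt) zeta_k

TCM-CRP adds a latent infection level V — a mean-reverting
Ornstein–Uhlenbeck process observed through log(CRP+1) — that inflates the
leukopoiesis volatility, sigma_L(V) = sigma_L0 exp(beta_crp V), making the
model a stochastic-volatility one.  Observations are the log leukocyte
count (l = L + eps, eps ~ N(0, sigma_leuk^2)) and, for TCM-CRP, the
log(CRP+1) value (v = V + eps', eps' ~ N(0, sigma_crp^2)).

The module exposes both the scalar kernels (used directly by the filtering
loops for speed) and Gaussian-belief operations (`transition`, `observe`)
for EKF prediction and update.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Callable, Optional

import numpy as np

from .config import default_config

__all__ = [
    "TcmParameters", "TcmCrpParameters", "NmParameters", "StateBelief",
    "ObservationVector", "m_update", "l_drift", "l_drift_jacobian",
    "l_update_mean", "ou_update", "sigma_L_of_v", "transition", "observe",
    "initial_belief", "default_tcm_parameters", "default_tcm_crp_parameters",
]


@dataclass
class TcmParameters:
    """TCM parameters.  Free (estimated) parameters are
    ``e_tgn, h, k_pl_max, k_L, sigma_L``; the rest are held fixed."""

    e_tgn: float      # 1/day, maximal drug-effect rate
    h: float          # mg/m^2, half-saturation dose
    k_pl_max: float   # 1/day, maximal proliferation rate
    k_L: float        # 1/day, leukocyte elimination rate
    sigma_L: float    # 1/sqrt(day), leukopoiesis SD
    gamma: float      # Hill exponent (fixed)
    k_me: float       # 1/day, cytotoxicity elimination rate (fixed)
    rho: float        # 1e9/L, feedback scale (fixed)
    sigma_leuk: float = 0.057  # log-scale measurement SD (fixed)
    t_dur: float = 1.0         # days, dose window
    dt: float = 0.25           # days, discretisation step

    FREE = ("e_tgn", "h", "k_pl_max", "k_L", "sigma_L")
    _SIGN_FREE = frozenset()  # fields allowed to be non-positive

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name not in self._SIGN_FREE and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @property
    def state_dim(self) -> int:
        return 2

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.FREE])

    def with_free_values(self, values) -> "TcmParameters":
        return replace(self, **dict(zip(self.FREE, map(float, values))))

    def steady_state_log_leuk(self, m: float = 0.0) -> float:
        """Drug-free (or constant-M) steady state of L; requires
        k_L + m < k_pl_max."""
        ratio = self.k_pl_max / (self.k_L + m) - 1.0
        if ratio <= 0:
            raise ValueError("no finite steady state: k_L + m >= k_pl_max")
        return math.log(self.rho) + math.log(ratio) / self.gamma


@dataclass
class TcmCrpParameters(TcmParameters):
    """TCM-CRP parameters: TCM's with sigma_L read as the baseline
    volatility sigma_L0, plus the OU infection-process hyperparameters
    theta_V = (sigma_ou, theta_ou, beta_crp) and the CRP measurement SD."""

    theta_ou: float = 0.15  # 1/day, OU mean-reversion rate
    sigma_ou: float = 0.7   # 1/sqrt(day), OU diffusion SD
    beta_crp: float = 0.25  # volatility coupling (may be any sign)
    sigma_crp: float = 0.1  # log(CRP+1) measurement SD (fixed)

    _SIGN_FREE = frozenset({"beta_crp"})

    @property
    def sigma_L0(self) -> float:
        return self.sigma_L

    @property
    def state_dim(self) -> int:
        return 3

    @property
    def stationary_var_v(self) -> float:
        return self.sigma_ou ** 2 / (2.0 * self.theta_ou)


@dataclass
class NmParameters:
    """Naive mean model: counts i.i.d. N(mu_nm, sigma_nm^2) on the linear
    scale."""

    mu_nm: float
    sigma_nm: float

    def __post_init__(self) -> None:
        if self.sigma_nm < 0:
            raise ValueError("sigma_nm must be non-negative")


@dataclass
class ObservationVector:
    """One visit's measurements on the model's observation scale:
    l = log leukocyte count, v = log(CRP + 1); None marks missing."""

    l: Optional[float] = None
    v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.l is None and self.v is None:
            raise ValueError("at least one observation component required")


@dataclass
class StateBelief:
    """Gaussian belief over the latent state (M, L[, V]) at one time."""

    time: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
            raise ValueError("covariance must be PSD")


# ---------------------------------------------------------------------------
# scalar kernels

def m_update(m_prev: float, d_bsa: float, p: TcmParameters, dt: float) -> float:
    """Exact one-step update of M: exponential relaxation toward the
    saturating drug effect e_tgn d/(d+h) at rate k_me (the closed-form
    solution of the piecewise-linear cytotoxicity ODE over [0, dt])."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if d_bsa < 0:
        raise ValueError("dose must be non-negative")
    m_ss = p.e_tgn * d_bsa / (d_bsa + p.h) if d_bsa > 0 else 0.0
    return (m_prev - m_ss) * math.exp(-p.k_me * dt) + m_ss


def l_drift(l: float, m: float, p: TcmParameters) -> float:
    """Drift of log leukocyte count:
    k_pl_max rho^g / (rho^g + exp(g l)) - m - k_L."""
    rg = p.rho ** p.gamma
    return p.k_pl_max * rg / (rg + math.exp(p.gamma * l)) - m - p.k_L


def l_drift_jacobian(l: float, p: TcmParameters) -> float:
    """Analytic d(drift)/dL used for EKF linearisation."""
    rg = p.rho ** p.gamma
    eg = math.exp(p.gamma * l)
    return -p.k_pl_max * rg * p.gamma * eg / (rg + eg) ** 2


def l_update_mean(l_prev: float, m_prev: float, p: TcmParameters, dt: float) -> float:
    """Euler–Maruyama drift step for L (noise term zero); the associated
    process variance of the step is sigma_L^2 * dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return l_prev + dt * l_drift(l_prev, m_prev, p)


def ou_update(v_prev: float, p: TcmCrpParameters, dt: float) -> tuple[float, float]:
    """Exact conditional mean and variance of the OU infection level after
    ``dt`` days: mean v e^{-theta dt}, variance
    sigma_ou^2/(2 theta) (1 - e^{-2 theta dt})."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-p.theta_ou * dt)
    var = p.sigma_ou ** 2 / (2.0 * p.theta_ou) * (1.0 - decay * decay)
    return v_prev * decay, var


def sigma_L_of_v(v: float, p: TcmCrpParameters) -> float:
    """State-dependent leukopoiesis volatility sigma_L0 exp(beta_crp v)."""
    return p.sigma_L * math.exp(p.beta_crp * v)


# ---------------------------------------------------------------------------
# EKF prediction/update over Gaussian beliefs
#
# The sub-step loops are written with plain floats (symmetric covariance
# stored entrywise) because they sit in the innermost loop of likelihood
# evaluation; the array-based StateBelief API wraps them.

def _substeps(t0: float, t1: float, dt0: float):
    """Yield sub-step lengths covering (t0, t1]: ceil((t1-t0)/dt0) steps of
    dt0 with a shorter final step if the interval is not a multiple."""
    span = t1 - t0
    n = max(1, math.ceil(span / dt0 - 1e-12))
    for i in range(n - 1):
        yield dt0
    yield span - (n - 1) * dt0


def _propagate_tcm(t: float, t_next: float, m: float, l: float,
                   pmm: float, pml: float, pll: float,
                   p: TcmParameters, dose_fn: Callable[[float], float]):
    # inlined kernels: this loop dominates likelihood evaluation
    exp = math.exp
    k_me, sig2 = p.k_me, p.sigma_L ** 2
    e_tgn, h, kpl, kL, gam = p.e_tgn, p.h, p.k_pl_max, p.k_L, p.gamma
    rg = p.rho ** gam
    dt0 = p.dt
    a0 = exp(-k_me * dt0)
    for dt in _substeps(t, t_next, dt0):
        d = dose_fn(t)
        a = a0 if dt == dt0 else exp(-k_me * dt)
        eg = exp(gam * l)
        denom = rg + eg
        fb = kpl * rg / denom
        g = 1.0 - dt * fb * gam * eg / denom
        f = -dt
        m_ss = e_tgn * d / (d + h) if d > 0.0 else 0.0
        m_new = (m - m_ss) * a + m_ss
        l_new = l + dt * (fb - m - kL)
        pll = f * f * pmm + 2.0 * f * g * pml + g * g * pll + sig2 * dt
        pml = a * (f * pmm + g * pml)
        pmm = a * a * pmm
        m, l = m_new, l_new
        t += dt
    return m, l, pmm, pml, pll


def _propagate_tcmcrp(t: float, t_next: float, m: float, l: float, v: float,
                      pmm: float, pml: float, pmv: float,
                      pll: float, plv: float, pvv: float,
                      p: TcmCrpParameters, dose_fn: Callable[[float], float]):
    exp = math.exp
    k_me, theta = p.k_me, p.theta_ou
    ou_scale = p.sigma_ou ** 2 / (2.0 * theta)
    e_tgn, h, kpl, kL, gam = p.e_tgn, p.h, p.k_pl_max, p.k_L, p.gamma
    sigL0, beta = p.sigma_L, p.beta_crp
    rg = p.rho ** gam
    dt0 = p.dt
    a0, b0 = exp(-k_me * dt0), exp(-theta * dt0)
    for dt in _substeps(t, t_next, dt0):
        d = dose_fn(t)
        if dt == dt0:
            a, b = a0, b0
        else:
            a, b = exp(-k_me * dt), exp(-theta * dt)
        eg = exp(gam * l)
        denom = rg + eg
        fb = kpl * rg / denom
        g = 1.0 - dt * fb * gam * eg / denom
        f = -dt
        sig = sigL0 * exp(beta * v)  # volatility at the sub-step start
        q_l = sig * sig * dt
        q_v = ou_scale * (1.0 - b * b)
        m_ss = e_tgn * d / (d + h) if d > 0.0 else 0.0
        m_new = (m - m_ss) * a + m_ss
        l_new = l + dt * (fb - m - kL)
        pll = f * f * pmm + 2.0 * f * g * pml + g * g * pll + q_l
        plv = b * (f * pmv + g * plv)
        pml = a * (f * pmm + g * pml)
        pmv = a * b * pmv
        pmm = a * a * pmm
        pvv = b * b * pvv + q_v
        m, l, v = m_new, l_new, b * v
        t += dt
    return m, l, v, pmm, pml, pmv, pll, plv, pvv


def transition(belief: StateBelief, p: TcmParameters,
               dose_fn: Callable[[float], float], t_next: float) -> StateBelief:
    """EKF prediction: propagate a Gaussian belief from ``belief.time`` to
    ``t_next`` by Euler–Maruyama sub-steps of length ``p.dt`` (final partial
    step if needed), linearising the L-drift at the current mean.  Process
    noise enters L (TCM) or L and V (TCM-CRP, with sigma_L evaluated at the
    current mean of V)."""
    if t_next <= belief.time:
        raise ValueError("t_next must exceed belief.time")
    mean, P = belief.mean, belief.cov
    if isinstance(p, TcmCrpParameters):
        m, l, v, pmm, pml, pmv, pll, plv, pvv = _propagate_tcmcrp(
            belief.time, t_next, mean[0], mean[1], mean[2],
            P[0, 0], P[0, 1], P[0, 2], P[1, 1], P[1, 2], P[2, 2], p, dose_fn)
        return StateBelief(t_next, np.array([m, l, v]),
                           np.array([[pmm, pml, pmv],
                                     [pml, pll, plv],
                                     [pmv, plv, pvv]]))
    m, l, pmm, pml, pll = _propagate_tcm(
        belief.time, t_next, mean[0], mean[1], P[0, 0], P[0, 1], P[1, 1],
        p, dose_fn)
    return StateBelief(t_next, np.array([m, l]),
                       np.array([[pmm, pml], [pml, pll]]))


def _kalman_scalar_update(mean: np.ndarray, P: np.ndarray, idx: int,
                          y: float, r: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Conjugate update for a scalar observation of state component ``idx``
    with noise variance ``r``; returns (mean, cov, log predictive density)."""
    s = P[idx, idx] + r
    resid = y - mean[idx]
    loglik = -0.5 * (math.log(2.0 * math.pi * s) + resid * resid / s)
    k = P[:, idx] / s
    mean = mean + k * resid
    P = P - np.outer(k, P[idx, :])
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, np.maximum(P.diagonal(), 0.0))
    return mean, P, loglik


def observe(belief: StateBelief, obs: ObservationVector,
            p: TcmParameters) -> StateBelief:
    """Kalman update with the linear observation map selecting L (and V for
    TCM-CRP); missing components are skipped.  Since the measurement noises
    are independent, the components are assimilated sequentially, which is
    exact."""
    belief, _ = observe_with_loglik(belief, obs, p)
    return belief


def observe_with_loglik(belief: StateBelief, obs: ObservationVector,
                        p: TcmParameters) -> tuple[StateBelief, float]:
    """As :func:`observe`, additionally returning the log predictive density
    of the assimilated components (the innovation decomposition terms)."""
    mean, P = belief.mean.copy(), belief.cov.copy()
    loglik = 0.0
    if obs.l is not None:
        mean, P, ll = _kalman_scalar_update(mean, P, 1, obs.l, p.sigma_leuk ** 2)
        loglik += ll
    if obs.v is not None:
        if not isinstance(p, TcmCrpParameters):
            raise ValueError("CRP observation supplied to a model without V")
        mean, P, ll = _kalman_scalar_update(mean, P, 2, obs.v, p.sigma_crp ** 2)
        loglik += ll
    return StateBelief(belief.time, mean, P), loglik


def initial_belief(p: TcmParameters, first_log_leuk: float,
                   time: float = 0.0) -> StateBelief:
    """Initial state distribution: M ~ N(0, 0) (degenerate), L ~ N(l_1, 0.5)
    and, for TCM-CRP, V at its stationary law N(0, sigma_ou^2/(2 theta_ou))."""
    if first_log_leuk is None or not math.isfinite(first_log_leuk):
        raise ValueError("first observed log leukocyte count required")
    if isinstance(p, TcmCrpParameters):
        mean = np.array([0.0, first_log_leuk, 0.0])
        cov = np.diag([0.0, 0.5, p.stationary_var_v])
    else:
        mean = np.array([0.0, first_log_leuk])
        cov = np.diag([0.0, 0.5])
    return StateBelief(time, mean, cov)


# ---------------------------------------------------------------------------
# constructors from configuration

def default_tcm_parameters(config: dict | None = None, **overrides) -> TcmParameters:
    cfg = config or default_config()
    values = {**cfg["tcm_init"],
              **{k: cfg["fixed"][k] for k in
                 ("gamma", "k_me", "rho", "sigma_leuk", "t_dur", "dt")}}
    values.update(overrides)
    return TcmParameters(**values)


def default_tcm_crp_parameters(config: dict | None = None, **overrides) -> TcmCrpParameters:
    cfg = config or default_config()
    values = {**cfg["tcm_init"], **cfg["tcm_crp_init"],
              **{k: cfg["fixed"][k] for k in
                 ("gamma", "k_me", "rho", "sigma_leuk", "t_dur", "dt")},
              "sigma_crp": cfg["fixed"]["sigma_crp"]}
    values.update(overrides)
    return TcmCrpParameters(**values)
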