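"""The 8-compartment ODE comparator model (JM).

Three-compartment 6-MP pharmacokinetics (gut -> plasma -> red-blood-cell
TGN) coupled to a five-compartment leukopoiesis maturation chain written in
log-transformed cell variables: stem cells S, three maturation stages
C1..C3, and circulating leukocytes L.  TGN diminishes stem-cell production
through a saturating Emax term.  Doses enter the gut compartment as
impulses; the system is integrated with a stiff-capable solver restarted at
each dose time.  Log leukocyte observations are i.i.d. Gaussian about the
solved L trajectory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

from .config import default_config
from .patient_data import PatientRecord, bsa_at

__all__ = ["JmParameters", "PredictionFailure", "jm_rhs", "jm_steady_state_init",
           "jm_solve", "jm_loglik", "default_jm_parameters"]

STATE_NAMES = ("X_gut", "X_plasma", "X_tgn", "S", "C1", "C2", "C3", "L")


class PredictionFailure(RuntimeError):
    """The ODE solver (or an optimisation built on it) failed to produce a
    trajectory; callers must handle this explicitly, never a silent NaN."""


@dataclass
class JmParameters:
    """PK constants (k_ab, k_el, k_cm, k, v_cm, k_me) and leukopoiesis
    parameters (k_pl_max, gamma, rho, e_max, e_C50, k_tr, k_L) plus the
    observation SD.  The conventional free set is
    {k_cm, k_tr, k_pl_max, k_L, gamma, e_max, sigma_leuk}."""

    k_ab: float
    k_el: float
    k_cm: float
    k: float
    v_cm: float
    k_me: float
    k_pl_max: float
    gamma: float
    rho: float
    e_max: float
    e_C50: float
    k_tr: float
    k_L: float
    sigma_leuk: float = 0.057

    FREE = ("k_cm", "k_tr", "k_pl_max", "k_L", "gamma", "e_max", "sigma_leuk")

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.FREE])

    def with_free_values(self, values) -> "JmParameters":
        return replace(self, **dict(zip(self.FREE, map(float, values))))


def default_jm_parameters(config: dict | None = None, **overrides) -> JmParameters:
    cfg = config or default_config()
    values = dict(cfg["jm"])
    values.update(overrides)
    return JmParameters(**values)


def jm_rhs(t: float, state: np.ndarray, p: JmParameters) -> np.ndarray:
    """Time derivatives of (X_gut, X_plasma, X_tgn, S, C1, C2, C3, L).

    The dose input d(t) is an impulse train and therefore does not appear
    here; :func:`jm_solve` realises each dose as an instantaneous addition
    to X_gut with a solver restart, which is equivalent to the delta-input
    convention.
    """
    xg, xp, xt, s, c1, c2, c3, l = state
    mm = p.k_cm * xp / (p.k + xp)          # Michaelis-Menten metabolisation
    drug = p.e_max * xt / (p.e_C50 + xt)   # Emax effect of TGN on stem cells
    rg = p.rho ** p.gamma
    feedback = p.k_pl_max * rg / (rg + math.exp(p.gamma * l))
    return np.array([
        -p.k_ab * xg,
        p.k_ab * xg - p.k_el * xp - mm,
        p.v_cm * mm - p.k_me * xt,
        feedback - drug - p.k_tr,
        p.k_tr * math.exp(s - c1) - p.k_tr,
        p.k_tr * math.exp(c1 - c2) - p.k_tr,
        p.k_tr * math.exp(c2 - c3) - p.k_tr,
        p.k_tr * math.exp(c3 - l) - p.k_L,
    ])


def jm_steady_state_init(p: JmParameters) -> np.ndarray:
    """Drug-free steady state: X compartments at zero and cell compartments
    such that all time derivatives vanish::

        L(0)  = log(rho) + log(k_pl_max/k_tr - 1)/gamma
        C3(0) = log(k_L) - log(k_tr) + L(0)
        S(0)  = C1(0) = C2(0) = C3(0)

    Requires k_tr < k_pl_max.
    """
    if p.k_tr >= p.k_pl_max:
        raise ValueError("steady state requires k_tr < k_pl_max")
    l0 = math.log(p.rho) + math.log(p.k_pl_max / p.k_tr - 1.0) / p.gamma
    c3 = math.log(p.k_L) - math.log(p.k_tr) + l0
    return np.array([0.0, 0.0, 0.0, c3, c3, c3, c3, l0])


def jm_solve(p: JmParameters, dose_times: np.ndarray, dose_amounts: np.ndarray,
             t_eval: np.ndarray, x0: np.ndarray | None = None,
             t0: float = 0.0, rtol: float = 1e-6, atol: float = 1e-9,
             method: str = "LSODA", full_state: bool = False) -> np.ndarray:
    """Solve the JM system with dose impulses, returning L at ``t_eval``
    (or the full 8-state trajectory if ``full_state``).

    ``dose_amounts`` are additions to the gut compartment at ``dose_times``
    (BSA-normalised upstream if desired).  Raises :class:`PredictionFailure`
    if the solver reports failure anywhere.
    """
    t_eval = np.asarray(t_eval, float)
    if t_eval.size and np.any(np.diff(t_eval) < 0):
        raise ValueError("t_eval must be ascending")
    state = jm_steady_state_init(p) if x0 is None else np.asarray(x0, float).copy()
    t_end = max(t_eval.max(initial=t0), t0)
    dose_times = np.asarray(dose_times, float)
    dose_amounts = np.asarray(dose_amounts, float)
    in_range = (dose_times > t0) & (dose_times <= t_end)
    # a dose exactly at t0 is applied before integration starts
    state[0] += dose_amounts[dose_times == t0].sum()
    events = list(zip(dose_times[in_range], dose_amounts[in_range]))

    out = np.empty((t_eval.size, 8))
    done = np.zeros(t_eval.size, dtype=bool)
    hit = t_eval == t0
    out[hit] = state
    done |= hit
    t_cur = t0
    for t_stop, amount in events + [(t_end, 0.0)]:
        if t_stop > t_cur:
            mask = (~done) & (t_eval > t_cur) & (t_eval <= t_stop)
            sol = solve_ivp(jm_rhs, (t_cur, t_stop), state, method=method,
                            args=(p,), rtol=rtol, atol=atol,
                            dense_output=bool(mask.any()))
            if not sol.success:
                raise PredictionFailure(f"ODE solver failed near t={t_cur}: "
                                        f"{sol.message}")
            if mask.any():
                out[mask] = sol.sol(t_eval[mask]).T
                done |= mask
            state = sol.y[:, -1]
            t_cur = t_stop
        state = state.copy()
        state[0] += amount
    if not done.all():
        raise PredictionFailure("internal: evaluation times not all covered")
    if not np.all(np.isfinite(out)):
        raise PredictionFailure("non-finite trajectory values")
    return out if full_state else out[:, 7]


def jm_dose_schedule(record: PatientRecord, normalise_bsa: bool = True):
    """Dose times/amounts for :func:`jm_solve` from a patient record, with
    amounts divided by the interpolated BSA by default."""
    amounts = record.doses.astype(float).copy()
    if normalise_bsa:
        amounts = amounts / np.asarray(bsa_at(record, record.dose_times), float)
    return record.dose_times, amounts


def jm_loglik(p: JmParameters, record: PatientRecord,
              rtol: float = 1e-6) -> float:
    """I.i.d. Gaussian log-likelihood of the observed log leukocyte counts
    about the solved L trajectory."""
    mask = record.leukocyte_mask()
    if not mask.any():
        raise ValueError("record has no leukocyte observations")
    times = record.obs_times[mask]
    obs = np.log(record.leukocyte[mask])
    dt_times, amounts = jm_dose_schedule(record)
    t0 = min(record.start_time, float(times[0]))
    traj = jm_solve(p, dt_times, amounts, times, t0=t0, rtol=rtol)
    resid = obs - traj
    s2 = p.sigma_leuk ** 2
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * s2) + resid ** 2 / s2))
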