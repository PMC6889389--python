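"""Synthetic maintenance-therapy cohorts.

Generates patient records with the statistical structure the state-space
models assume: daily 6-MP dosing with stepwise intensification (and
occasional ~20-day pauses), weekly-to-biweekly irregularly jittered visits
with leukocyte and CRP measurements, a slowly growing BSA series, and
latent dynamics simulated by the exact forward recursion of the discretised
TCM-CRP (or TCM) model at dt = 0.25 days.  Treatment lengths are drawn from
the 227–524 day range.  Latent paths are returned alongside each record so
oracle tests can compare against the truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .patient_data import PatientRecord
from .ssm_models import (TcmCrpParameters, TcmParameters,
                         default_tcm_crp_parameters, l_drift, m_update,
                         ou_update, sigma_L_of_v)

__all__ = ["DosingPolicy", "SimulationScenario", "simulate_dosing",
           "simulate_patient", "make_cohort"]


@dataclass
class DosingPolicy:
    """Stepwise-intensification dosing: start low, step up toward a target
    daily dose, with optional pauses after which the ramp restarts."""

    start_dose: float = 25.0       # mg/day
    target_dose: float = 50.0      # mg/day
    step: float = 12.5             # mg increment at each intensification
    escalation_interval: float = 21.0   # days between intensifications
    pause_probability: float = 0.5      # chance of one pause in the course
    pause_length: float = 20.0     # days of zero dose
    jitter_days: float = 7.0       # randomisation of step timing


@dataclass
class SimulationScenario:
    """Study conditions for one simulated patient."""

    params: TcmParameters = field(default_factory=default_tcm_crp_parameters)
    n_days: float = 400.0
    obs_interval: float = 7.0       # nominal days between visits
    biweekly_fraction: float = 0.3  # fraction of gaps stretched to ~2 weeks
    obs_jitter: float = 1.0         # SD (days) of visit-time jitter
    crp_measured_fraction: float = 0.9
    dosing: DosingPolicy = field(default_factory=DosingPolicy)
    # clinical hold: dosing pauses while the latent count is below
    # ``hold_below`` (1e9/L) and resumes once it recovers past
    # ``resume_above`` -- mimicking protocol holds on severe leukopenia
    # and preventing unbounded suppression for strong-responder draws
    hold_below: float = 1.0
    resume_above: float = 1.5
    bsa_start: float = 1.05         # m^2 at treatment start
    bsa_growth_per_year: float = 0.08
    bsa_record_interval: float = 28.0
    seed: int = 0


def simulate_dosing(policy: DosingPolicy, n_days: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Daily dose schedule (times 0..n_days-1, one dose per day)."""
    times = np.arange(0.0, float(n_days))
    doses = np.empty_like(times)
    level = policy.start_dose
    next_step = policy.escalation_interval + rng.uniform(0, policy.jitter_days)
    pause_at = (rng.uniform(0.3, 0.7) * n_days
                if rng.uniform() < policy.pause_probability else None)
    pause_until = -1.0
    for i, t in enumerate(times):
        if pause_at is not None and t >= pause_at:
            pause_until = t + policy.pause_length
            level = policy.start_dose   # ramp restarts after the pause
            next_step = pause_until + policy.escalation_interval
            pause_at = None
        if t < pause_until:
            doses[i] = 0.0
            continue
        if t >= next_step and level < policy.target_dose:
            level = min(level + policy.step, policy.target_dose)
            next_step = t + policy.escalation_interval + rng.uniform(
                0, policy.jitter_days)
        doses[i] = level
    return times, doses


def _visit_times(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    times = [0.0]
    t = 0.0
    while True:
        gap = scenario.obs_interval
        if rng.uniform() < scenario.biweekly_fraction:
            gap *= 2.0
        t += gap + rng.normal(0.0, scenario.obs_jitter)
        if t >= scenario.n_days:
            break
        times.append(t)
    out = np.unique(np.round(np.asarray(times), 2))
    return out[out >= 0]


def simulate_patient(scenario: SimulationScenario,
                     rng: Optional[np.random.Generator] = None,
                     patient_id: str = "sim") -> tuple[PatientRecord, dict]:
    """Simulate one patient by the exact forward recursion of the
    discretised model; returns the record and the latent truth.

    The latent truth dict holds the dt-grid ``t``, paths ``M``, ``L`` (and
    ``V`` for TCM-CRP) and the generating parameters.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    p = scenario.params
    with_crp = isinstance(p, TcmCrpParameters)
    dose_times, doses = simulate_dosing(scenario.dosing, scenario.n_days, rng)

    bsa_times = np.arange(0.0, scenario.n_days + 1, scenario.bsa_record_interval)
    bsa = scenario.bsa_start + scenario.bsa_growth_per_year * bsa_times / 365.25

    dt = p.dt
    n_steps = int(math.ceil(scenario.n_days / dt))
    grid = np.arange(n_steps + 1) * dt
    m_path = np.empty(n_steps + 1)
    l_path = np.empty(n_steps + 1)
    v_path = np.empty(n_steps + 1) if with_crp else None

    l0 = p.steady_state_log_leuk() + math.sqrt(0.5) * rng.standard_normal()
    m_path[0], l_path[0] = 0.0, l0
    if with_crp:
        v_path[0] = math.sqrt(p.stationary_var_v) * rng.standard_normal()

    dose_idx = np.clip(np.searchsorted(dose_times, grid[:-1], side="right") - 1,
                       0, len(dose_times) - 1)
    bsa_grid = np.interp(grid[:-1], bsa_times, bsa)
    window_ok = (dose_times[dose_idx] > grid[:-1] - p.t_dur) \
        & (dose_times[dose_idx] <= grid[:-1])

    zeta = rng.standard_normal(n_steps)
    eta = rng.standard_normal(n_steps) if with_crp else None
    given = doses.copy()   # scheduled doses after clinical holds
    on_hold = False
    prev_day = -1
    for k in range(n_steps):
        m, l = m_path[k], l_path[k]
        day = int(grid[k])
        if day != prev_day:          # dose decision at the day's start
            count = math.exp(l)
            if on_hold and count >= scenario.resume_above:
                on_hold = False
            elif not on_hold and count < scenario.hold_below:
                on_hold = True
            if on_hold and day < given.size:
                given[day] = 0.0
            prev_day = day
        d = given[dose_idx[k]] / bsa_grid[k] if window_ok[k] else 0.0
        sig = sigma_L_of_v(v_path[k], p) if with_crp else p.sigma_L
        l_path[k + 1] = l + dt * l_drift(l, m, p) + sig * math.sqrt(dt) * zeta[k]
        m_path[k + 1] = m_update(m, float(d), p, dt)
        if with_crp:
            mean_v, var_v = ou_update(v_path[k], p, dt)
            v_path[k + 1] = mean_v + math.sqrt(var_v) * eta[k]

    visit_times = _visit_times(scenario, rng)
    idx = np.clip(np.round(visit_times / dt).astype(int), 0, n_steps)
    visit_times = grid[idx]  # snap to the simulation grid
    leuk = np.exp(l_path[idx] + p.sigma_leuk * rng.standard_normal(idx.size))
    crp = np.full(idx.size, np.nan)
    if with_crp:
        measured = rng.uniform(size=idx.size) < scenario.crp_measured_fraction
        v_obs = v_path[idx] + p.sigma_crp * rng.standard_normal(idx.size)
        crp[measured] = np.maximum(np.exp(v_obs[measured]) - 1.0, 0.0)

    record = PatientRecord(patient_id, dose_times, given, visit_times,
                           leuk, crp, bsa_times, bsa)
    truth = {"t": grid, "M": m_path, "L": l_path, "params": p}
    if with_crp:
        truth["V"] = v_path
    return record, truth


def make_cohort(n_patients: int, base_scenario: SimulationScenario | None = None,
                seed: int = 0, heterogeneity_sd: float = 0.15,
                length_range: tuple[float, float] = (227.0, 524.0),
                return_truth: bool = False):
    """Independent synthetic patients with log-normally jittered free
    parameters and treatment lengths drawn uniformly from ``length_range``
    (the cohort's observed span of therapy durations).  Deterministic given
    ``seed``."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = base_scenario or SimulationScenario()
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n_patients):
        p = base.params
        # redraw until the jittered parameters admit a finite drug-free
        # steady state (k_L < k_pl_max), as any real baseline implies
        for _ in range(1000):
            jitter = np.exp(heterogeneity_sd * rng.standard_normal(len(p.FREE)))
            params = p.with_free_values(p.free_values() * jitter)
            if params.k_L < params.k_pl_max:
                break
        else:
            raise RuntimeError("could not draw a valid parameter set")
        scenario = replace(base, params=params,
                           n_days=float(rng.uniform(*length_range)),
                           bsa_start=float(rng.uniform(0.75, 1.45)))
        rec, truth = simulate_patient(scenario, rng,
                                      patient_id=f"sim{i + 1:03d}")
        records.append(rec)
        truths.append(truth)
    return (records, truths) if return_truth else records
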