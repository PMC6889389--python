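"""Rolling-origin (time-series) cross-validation and predictive metrics.

The protocol: the first training window spans the first 8 weeks of a
patient's data (extended, if necessary, until it contains at least two
leukocyte observations); each round predicts the observations in the next
`horizon` days; the training window then absorbs the prediction window and
the process repeats until the data are exhausted.  A final window shorter
than the horizon is still evaluated.  Metrics are RMSE and MAE of the
linear-scale point predictions and the empirical coverage CP_alpha of the
central alpha% predictive intervals (closed-interval membership).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .inference import (MapFitResult, PredictionSet, fit_nm, map_fit,
                        predict_horizon)
from .patient_data import PatientRecord

FIRST_WINDOW_DAYS = 56.0  # 8 weeks


@dataclass
class TscRound:
    train_end: float
    window_end: float
    predictions: Optional[PredictionSet]
    observations: np.ndarray          # held-out counts, linear scale
    failed: bool = False
    fit: Optional[MapFitResult] = None


@dataclass
class TscReport:
    patient_id: str
    model_id: str
    horizon: float
    rounds: list[TscRound] = field(default_factory=list)

    def pooled(self) -> tuple[np.ndarray, PredictionSet]:
        """All held-out observations and predictions from non-failed rounds."""
        obs, times, mean, var = [], [], [], []
        scale = "log"
        for rnd in self.rounds:
            if rnd.failed or rnd.predictions is None:
                continue
            scale = rnd.predictions.scale
            obs.append(rnd.observations)
            times.append(rnd.predictions.times)
            mean.append(rnd.predictions.mean)
            var.append(rnd.predictions.var)
        if not obs:
            empty = np.empty(0)
            return empty, PredictionSet(empty, empty, empty, scale)
        cat = np.concatenate
        return cat(obs), PredictionSet(cat(times), cat(mean), cat(var), scale)

    def metrics(self) -> dict:
        """Per-patient RMSE/MAE/CP50/CP90 over all non-failed rounds."""
        obs, preds = self.pooled()
        if obs.size == 0:
            return {k: math.nan for k in ("rmse", "mae", "cp50", "cp90", "n")}
        rmse, mae = point_metrics(obs, preds)
        out = {"rmse": rmse, "mae": mae, "n": int(obs.size)}
        for alpha in (50, 90):
            out[f"cp{alpha}"] = coverage_probability(obs, preds.intervals(alpha))
        return out

    @property
    def n_failed(self) -> int:
        return sum(r.failed for r in self.rounds)


def tsc_split(record: PatientRecord, horizon: float,
              first_window: float = FIRST_WINDOW_DAYS,
              min_first_obs: int = 2) -> list[tuple[float, float]]:
    """(train_end, window_end) pairs of the rolling-origin protocol.

    Train ends advance by ``horizon`` from the end of the first window; a
    final partial window is kept; rounds whose window holds no leukocyte
    observation are dropped.  Returns an empty list (with a warning) if the
    record is too short.
    """
    leuk_times = record.obs_times[record.leukocyte_mask()]
    t0 = record.start_time
    t_last = leuk_times[-1] if leuk_times.size else t0
    train_end = t0 + first_window
    if (leuk_times <= train_end).sum() < min_first_obs:
        later = leuk_times[min_first_obs - 1:]
        if later.size == 0:
            warnings.warn(f"{record.patient_id}: too few leukocyte observations "
                          "for cross-validation")
            return []
        train_end = float(leuk_times[min_first_obs - 1])
    if t_last <= train_end:
        warnings.warn(f"{record.patient_id}: record does not extend past the "
                      "first training window")
        return []
    splits = []
    while train_end < t_last:
        window_end = min(train_end + horizon, t_last)
        held = (leuk_times > train_end) & (leuk_times <= train_end + horizon)
        if held.any():
            splits.append((float(train_end), float(window_end)))
        train_end += horizon
    return splits


def coverage_probability(observations: np.ndarray,
                         intervals: tuple[np.ndarray, np.ndarray]) -> float:
    """Fraction of observations inside their (closed) predictive interval."""
    lo, hi = intervals
    observations = np.asarray(observations, float)
    if observations.size == 0:
        raise ValueError("coverage of an empty set is undefined")
    if len(lo) != observations.size or len(hi) != observations.size:
        raise ValueError("length mismatch between observations and intervals")
    return float(np.mean((observations >= lo) & (observations <= hi)))


def point_metrics(observations: np.ndarray,
                  predictions: PredictionSet | np.ndarray) -> tuple[float, float]:
    """(RMSE, MAE) on the linear 1e9/L scale; log-scale predictions are
    exponentiated first."""
    observations = np.asarray(observations, float)
    point = (predictions.point_predictions()
             if isinstance(predictions, PredictionSet)
             else np.asarray(predictions, float))
    if point.size != observations.size:
        raise ValueError("length mismatch between observations and predictions")
    err = observations - point
    return float(np.sqrt(np.mean(err ** 2))), float(np.mean(np.abs(err)))


def tsc_run(record: PatientRecord, model_id: str, horizon: float,
            params_init=None, condition_crp: bool = False,
            maxfev: int | None = 400, **fit_kwargs) -> TscReport:
    """Run the full rolling-origin protocol for one patient and model.

    Each round refits the model on the training data (fresh start from
    ``params_init``) and predicts the held-out window using the actually
    administered doses.  Failed fits or predictions are flagged and excluded
    from metrics, mirroring how problematic rounds are treated upstream.
    """
    report = TscReport(record.patient_id, model_id, horizon)
    for train_end, window_end in tsc_split(record, horizon):
        held_mask = ((record.obs_times > train_end)
                     & (record.obs_times <= train_end + horizon)
                     & record.leukocyte_mask())
        observations = record.leukocyte[held_mask]
        try:
            if model_id == "nm":
                fit = fit_nm(record, t_max=train_end)
            else:
                fit = map_fit(record, model_id, params_init, t_max=train_end,
                              maxfev=maxfev, **fit_kwargs)
            if not math.isfinite(fit.log_posterior):
                raise RuntimeError("fit failed (non-finite posterior)")
            preds = predict_horizon(record, model_id, fit.parameters,
                                    train_end, horizon,
                                    condition_crp=condition_crp)
            report.rounds.append(TscRound(train_end, window_end, preds,
                                          observations, False, fit))
        except Exception as exc:  # noqa: BLE001 - failures are data, per protocol
            warnings.warn(f"{record.patient_id} round at t={train_end:.0f} "
                          f"failed: {exc}")
            report.rounds.append(TscRound(train_end, window_end, None,
                                          observations, True, None))
    return report


def in_sample_fit(record: PatientRecord, model_id: str, params) -> PredictionSet:
    """Fitted-mean series at the leukocyte observation times, given
    parameters estimated from the full record.

    State-space models: an EKF pass with every leukocyte count masked (CRP
    still assimilated for TCM-CRP), exponentiated L-means; JM: the
    exponentiated ODE solution; NM: the constant mu_nm.  Variances are
    predictive (state variance plus measurement variance) for CP metrics.
    """
    from . import jm_model
    from .inference import ekf_filter

    mask = record.leukocyte_mask()
    times = record.obs_times[mask]
    if model_id == "nm":
        return PredictionSet(times, np.full(times.size, params.mu_nm),
                             np.full(times.size, params.sigma_nm ** 2), "linear")
    if model_id == "jm":
        dt_times, amounts = jm_model.jm_dose_schedule(record)
        t0 = min(record.start_time, float(times[0]))
        traj = jm_model.jm_solve(params, dt_times, amounts, times, t0=t0)
        return PredictionSet(times, traj,
                             np.full(times.size, params.sigma_leuk ** 2), "log")
    res = ekf_filter(record, params, mask_leuk=True, collect=True)
    keep = np.isin(res.times, times)
    return PredictionSet(res.times[keep], res.filtered_mean_l[keep],
                         res.filtered_var_l[keep] + params.sigma_leuk ** 2,
                         "log")


def in_sample_metrics(record: PatientRecord, model_id: str, params) -> dict:
    """RMSE/MAE/CP metrics of the in-sample fitted mean."""
    preds = in_sample_fit(record, model_id, params)
    obs = record.leukocyte[record.leukocyte_mask()]
    obs = obs[np.isin(record.obs_times[record.leukocyte_mask()], preds.times)]
    rmse, mae = point_metrics(obs, preds)
    out = {"rmse": rmse, "mae": mae, "n": int(obs.size)}
    for alpha in (50, 90):
        out[f"cp{alpha}"] = coverage_probability(obs, preds.intervals(alpha))
    return out


@dataclass
class MetricsSummary:
    """Patientwise means and SDs per metric (the reporting convention:
    mean with SD in parentheses)."""

    model_id: str
    horizon: float
    mean: dict
    sd: dict
    n_patients: int

    def __str__(self) -> str:
        cells = ", ".join(f"{k}={self.mean[k]:.3f} ({self.sd[k]:.2f})"
                          for k in ("cp50", "cp90", "mae", "rmse"))
        return (f"{self.model_id} h={self.horizon:g}d over "
                f"{self.n_patients} patients: {cells}")


def summarize(reports: Sequence[TscReport]) -> MetricsSummary:
    """Means and SDs over patients of CP50/CP90/MAE/RMSE; patients whose
    every round failed are excluded (as problematic fits are upstream)."""
    if not reports:
        raise ValueError("no reports to summarise")
    rows = [r.metrics() for r in reports]
    rows = [m for m in rows if math.isfinite(m["mae"])]
    if not rows:
        raise ValueError("no successful rounds in any report")
    keys = ("cp50", "cp90", "mae", "rmse")
    mean = {k: float(np.mean([m[k] for m in rows])) for k in keys}
    # single-patient summaries report SD = 0 by convention
    sd = {k: float(np.std([m[k] for m in rows], ddof=1)) if len(rows) > 1
          else 0.0 for k in keys}
    return MetricsSummary(reports[0].model_id, reports[0].horizon,
                          mean, sd, len(rows))
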