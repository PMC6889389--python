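# Methods

## Setting

During maintenance therapy (MT) for childhood acute lymphoblastic
leukaemia, patients take daily oral 6-mercaptopurine (6-MP); clinicians
steer the dose to hold the leukocyte count in a target band (1.5–3.0
×10⁹/L).  The response to a dose change is delayed by drug metabolism and
the leukopoiesis pipeline, and infections add fluctuations of their own, so
dose-conditional forecasts of the leukocyte count are genuinely useful.
This package provides such forecasts through discrete-time nonlinear
Gaussian state-space models fitted per patient, together with an ODE
comparator, a naive baseline, and the evaluation machinery to compare them.

## Models

### TCM — two-compartment K-PD state-space model

Latent state: cytotoxicity level `M` (1/day) and log leukocyte count `L`.
Between observation times the state advances on a sub-step grid
(`dt = 0.25` day):

    M_k = (M_{k-1} − e_tgn·d/(d+h)) · exp(−k_me Δt) + e_tgn·d/(d+h)
    L_k = L_{k-1} + Δt·( k_pl_max·ρ^γ/(ρ^γ + exp(γ L_{k-1})) − M_{k-1} − k_L )
          + σ_L √Δt · ζ_k,        ζ_k ~ N(0,1)

`d` is the BSA-normalised dose administered in the trailing 24 h window
(`T_dur = 1` day), so the drug input is a K-PD term: no measured
concentrations, a saturating Emax response with half-saturation dose `h`,
and first-order elimination at `k_me`.  The `M` update is the exact
solution of its piecewise-linear ODE; the `L` update is an Euler–Maruyama
step of an SDE whose drift combines a Hill-type proliferation feedback
(scale `ρ`, exponent `γ`) with linear drug kill and elimination `k_L`.
Observations are `l_k = L_k + ε_k`, `ε_k ~ N(0, σ_leuk²)`, with
`σ_leuk = 0.057` fixed at a literature value for count-measurement
accuracy.  Initial law: `M₁ ~ N(0,0)` (no drug on board), `L₁ ~ N(l₁, 0.5)`
anchored at the first observed log count.

Free parameters per patient: `e_tgn, h, k_pl_max, k_L, σ_L`.  Fixed:
`γ, k_me, ρ, σ_leuk, T_dur, dt`.

### TCM-CRP — stochastic-volatility extension

A third latent component `V`, the infection level, follows a mean-reverting
Ornstein–Uhlenbeck process with exact Gaussian transition
(mean `V e^{−θ_ou Δt}`, variance `σ_ou²(1−e^{−2θ_ou Δt})/(2θ_ou)`), observed
through `v_k = V_k + ε'_k` on the log(CRP+1) scale with `σ_crp = 0.1`
(≈10 % CV of CRP assays).  `V` does not move the mean of `L`; it inflates
its volatility, `σ_L(V) = σ_L⁰ exp(β_crp V)`, so counts measured during
infection are down-weighted rather than regressed on CRP.  `V₁` starts at
the stationary law `N(0, σ_ou²/(2θ_ou))`.  The hyperparameters
`θ_V = (σ_ou, θ_ou, β_crp)` are estimated once, jointly across the cohort
(product of per-patient posterior contributions), then fixed in per-patient
fits — per-patient estimation of `β_crp` is hopeless for patients without
infections.

Mapping a zero-mean `V` directly to log(CRP+1) ≥ 0 implies a baseline
tension (a healthy patient's CRP sits near 0, i.e. `v ≈ 0`, which is also
the process mean, so negative `V` excursions have no observable
counterpart).  The observation map is implemented literally; the simulator
clips negative implied CRP at zero.

### JM — 8-compartment ODE comparator

Three-compartment 6-MP pharmacokinetics (gut → plasma → red-cell TGN with
Michaelis–Menten metabolisation) feeding a five-compartment log-scale
leukopoiesis maturation chain (stem cells → three transit stages →
circulation) in which TGN suppresses stem-cell production through an Emax
term.  Cell compartments start at the drug-free steady state (closed form;
requires `k_tr < k_pl_max`), drug compartments at zero.  Doses are
impulses: an instantaneous addition to the gut compartment with a solver
restart, integrated by `scipy.integrate.solve_ivp` (LSODA, rtol 1e-6).
Log counts are i.i.d. Gaussian about the solved `L` trajectory.  Solver
failures surface as an explicit `PredictionFailure`, never silent NaNs —
the model is known to be fragile under sparse clinical fitting, which is
part of what the comparison is about.

### NM — naive mean baseline

Counts i.i.d. `N(μ_nm, σ_nm²)` on the linear scale; fitted by the sample
mean and SD (ddof 1).  It ignores dosing entirely and exists to calibrate
expectations for the other models.

## Inference

The state-space likelihood is the extended Kalman filter's
prediction-error decomposition.  Prediction linearises the `L`-drift at the
current mean with the analytic Jacobian
`∂drift/∂L = −k_pl_max ρ^γ γ e^{γL}/(ρ^γ+e^{γL})²`; observation intervals
are divided into `⌈Δ/0.25⌉` sub-steps with a shorter final step, the dose
evaluated at each sub-step's start, and `σ_L(V)` frozen at the mean of `V`
at the sub-step start (standard EKF treatment of stochastic volatility).
Because the leukocyte and CRP noises are independent and observe distinct
components, updates are applied sequentially as scalar conjugate-Gaussian
steps, which is exact and keeps covariances symmetric by construction;
diagonal entries are floored at zero against round-off.  The degenerate
`N(0,0)` prior on `M₁` is handled by allowing exact zero variances.

The first observation is assimilated like any other: since `L₁` is anchored
at `l₁`, its innovation term is a θ-free constant for TCM, so including it
changes no estimate.  CRP-only rows before the first leukocyte observation
are skipped.

MAP estimation maximises log-likelihood plus independent `N(0, 10)`
(variance 10) priors on the logs of the free parameters, with Nelder–Mead
in log space (xatol 1e-6, fatol 1e-8, max 2000 iterations; optional seeded
multi-start).  Failed or non-finite evaluations receive a large penalty;
an all-failed fit returns an explicit failure result.  The joint `θ_V`
objective is maximised either as one stacked Nelder–Mead (default) or by
block-coordinate alternation between per-patient fits and a 3-parameter
`θ_V` fit — the alternation is markedly more robust for cohorts of more
than a few patients and is what the heavier studies use.

Forecasts filter the record to the forecast origin and propagate without
leukocyte updates; the predictive variance of an observation adds
`σ_leuk²`.  By default the horizon is fully unobserved; a switch allows
TCM-CRP to assimilate CRP measurements inside the horizon.  Intervals are
central Gaussian intervals on the log scale with exponentiated endpoints
(closed-interval membership for coverage).

## Evaluation protocol

Rolling-origin cross-validation: first training window = first 8 weeks of
the patient's data, extended if needed until it contains two leukocyte
observations; each round predicts the next `horizon` days (14 or 28) using
the actually administered doses; the training window then absorbs the
window and the process repeats until the data are exhausted.  A final
window shorter than the horizon is still evaluated; windows containing no
leukocyte observation are dropped.  Point metrics (RMSE, MAE) are computed
on the linear scale (point prediction = exponentiated predictive mean of
the log count); coverage CP₅₀/CP₉₀ counts observations inside their
central intervals.  Rounds whose fit or prediction fails are flagged and
excluded from metrics.  Summaries are means over patients with SDs (SD = 0
for a single patient by convention).

## Synthetic cohorts

The simulator is the exact forward recursion of the discretised TCM-CRP
(or TCM) model and therefore shares its assumptions; latent paths are
returned for oracle testing.  Study conditions emulated:

- treatment lengths drawn from 227–524 days;
- daily dosing with stepwise intensification (25 → 50 mg in 12.5 mg steps
  every ~3 weeks), a ~20-day pause in about half the patients with
  re-intensification afterwards;
- weekly visits with ~1-day jitter, ~30 % of gaps stretched to two weeks;
  CRP measured at 90 % of visits;
- BSA starting at 0.75–1.45 m² with slow growth, recorded monthly;
- mild log-normal interindividual spread (SD 0.15 on the log scale) on the
  free parameters, redrawn when a draw admits no finite steady state;
- OU infection level with `θ_ou = 0.15`/day and `σ_ou = 0.7` (stationary SD
  ≈ 1.28 on the log(CRP+1) scale), sized so that roughly two thirds of
  simulated patients record at least one CRP ≥ 10 mg/L, matching the
  prevalence of infection reported for real MT cohorts.

What the simulator does **not** emulate: dose decisions reacting to the
simulated counts (real dosing is feedback control, which correlates doses
with counts), discrete infection episodes with characteristic CRP shapes
(the OU surrogate is stationary and symmetric; an episodic stress mode can
be added via the latent paths), assay detection limits, missing-visit
bursts, or model misspecification of any kind.  Passing tests on these
cohorts therefore demonstrate internal correctness and well-specified-case
behaviour, not clinical performance.

### Fixed-parameter defaults

The shipped defaults (`src/leukossm/data/defaults.yaml`, all overridable)
are chosen for a paediatric MT setting: `k_me = 0.07`/day gives the
multi-week delay to steady-state response; `ρ = 4.67` ×10⁹/L and
`k_pl_max/k_L = 2` put the drug-free steady state near 4.7 ×10⁹/L and a
fully dosed patient (≈36 mg/m²/day) near 2.5 ×10⁹/L, inside the
therapeutic band; `h = 15` mg/m² places typical doses in the upper half of
the saturation curve.  The JM PK constants (`k_ab = 4.8`, `k_el = 5.0`/day,
Michaelis constant 2.1) make absorption and plasma clearance fast relative
to daily dosing with slow TGN accumulation, reproducing the hourly-vs-
weekly timescale separation that motivates the simpler K-PD model.

## Numerical choices and known limitations

- **Problem sizes.**  The heavier studies use scaled-down cohorts chosen as
  sensible defaults for a workstation: the recovery study uses 50 patients
  at 400 days (25 at 100 days), the calibration study 12 patients × ~17
  windows, cross-validation demonstrations 4–6 patients; per-round
  refitting caps Nelder–Mead at a few hundred evaluations, which the
  convergence experiments show is past the point of diminishing returns.
- **EKF approximation.**  Against a 10⁴-particle bootstrap filter the EKF
  log-likelihood agrees to within the particle filter's own sampling noise
  (differences of ~0.05–0.25 log-units over 200-day series, both signs).
- **Identifiability.**  Clinical-style dosing keeps `d/(d+h)` nearly
  constant, so `e_tgn` and `h` form a likelihood ridge (and `k_pl_max`,
  `k_L` a softer one): converged MAP fits can beat the generating
  parameters' posterior while sitting far from them along the ridge, with
  median relative errors for `h` near 90 % even on 400-day series.
  Predictions are insensitive to position along the ridge — which is
  precisely why the models predict robustly while their parameters should
  not be over-interpreted.  Recovery error does fall with series length.
- **Variance behaviour.**  The mean-reverting feedback drives the forecast
  variance toward the process' stationary variance, so predictive variance
  is not monotone in lead time once near equilibrium.
- **Rebound dynamics.**  After a dose pulse the JM feedback overshoots
  baseline on recovery (rebound leukocytosis); monotone "suppression
  forever" intuitions hold only through the nadir phase.
- **PSD maintenance.**  The scalar update forms cannot produce asymmetric
  covariances; tiny negative diagonal round-off is floored at zero.
- Dose times are taken at the recorded day's start; intra-day timing is
  not modelled.
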