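# Methods note

This note records what `pathmed` computes, the assumptions under which the
output has a causal reading, every default that affects numbers, and the
known limitations. Empirical statements here are limited to quantities
computed by the test suite or by `scripts/acceptance.py`.

## 1. Estimand

Data per patient: randomised arm `A ∈ {0,1}`, baseline covariates `L0`,
visits at fixed times `tau_1 < ... < tau_K` at which time-varying confounders
`V_k` and mediators `M_k` are recorded (only if the patient is still under
follow-up, `T > tau_k`), an event/censoring time `T` and event indicator `E`.

The estimand is the path-specific survival curve

    S_{a,a*}(t) = P(T_{a,a*} > t),

the survival probability in the hypothetical world where every treatment
arrow in the causal graph carries arm `a` except the arrows pointing into
the mediator assessments `M_1..M_K`, which carry arm `a*`. All paths from
treatment into any mediator are bundled into the "mediated" channel; paths
through the confounders `V_k` that do not pass through a mediator belong to
the direct channel. Bundling avoids the recanting-witness obstruction and
keeps the effect identified when confounders are treatment-responsive.

Contrasts (module `effects`):

* indirect (mediated): `S_{1,1}` vs `S_{1,0}`,
* direct: `S_{1,0}` vs `S_{0,0}`,
* mediated proportion: `(S11 − S10)/(S11 − S00)` on the difference scale,
  reported as NaN wherever `|S11 − S00| ≤ mp_threshold` (default `1e-3`) —
  a proportion of a vanishing total is not meaningful.

## 2. Identification assumptions

1. Randomised (or conditionally ignorable given `L0`) treatment.
2. Sequential exchangeability for the mediators: at each visit, `(L0, V_1..V_k,
   M_1..M_{k-1}, survival to tau_k, A)` suffices to deconfound `M_k` from the
   outcome. No unmeasured mediator–outcome confounding.
3. Censoring independent of the event given arm and recorded history.
4. Consistency/NPSEM: the data are generated by structural equations in
   which intervening on the treatment arrows is well defined.
5. Positivity: both arms retain patients at risk at every visit.

An unmeasured frailty shared *among the mediator assessments only* (`U_m`
in the simulator) does not break assumption 2; a frailty linking confounders
to the outcome (`U_l`) does. The simulator exposes both so the sensitivity
is measurable.

## 3. The nested sequential-regression estimator (module `gcomp`)

Fix a horizon `t` and let `k̄ = max{k : tau_k ≤ t}` (`floor_visit`). Risk-set
convention: at risk at visit `k` iff `T > tau_k` strictly. Working backwards
from `Q^{k̄}`, initialised by the terminal step, each visit `k` applies four
steps; `Q^{k-1}` lives on the (larger) risk set of visit `k−1`, and the
estimate is the mean of `Q^0` over all patients.

1. **Terminal (Cox)**: fit a proportional-hazards model in arm `a` among
   patients at risk at `k̄`, covariates `(L0, V_1..V_k̄, M_1..M_k̄)`, left
   truncated at `tau_k̄`; set `Q^{k̄} = exp{−Λ̂0(t) e^{xβ̂}}` for every at-risk
   patient (both arms).
2. **Mediator integration (quasi-binomial logit)**: regress `Q^k` on
   `(L0, V_1..V_k, M_1..M_{k-1})` — the current mediator excluded — among
   arm-`a*` patients at risk at `k`; replace `Q` by the fitted probabilities
   for all at-risk patients. This is the only place arm `a*` enters.
3. **Confounder integration (quasi-binomial logit)**: regress the result on
   `(L0, V_1..V_{k-1}, M_1..M_{k-1})` among arm-`a` patients at risk at `k`,
   and predict on the risk set of visit `k−1` — the prediction set is
   deliberately larger than the fitting set, which is how patients dying in
   `(tau_{k-1}, tau_k]` re-enter the calculation.
4. **Visit survival (Cox)**: multiply by the fitted arm-`a` probability of
   surviving from `tau_{k-1}` to `tau_k` given the same shorter history.

Fitted-mean (congeniality) robustness: a logistic fit with an intercept
reproduces the response mean over its fitting set exactly, so when `a = a*`
steps 2–3 merely re-average step-1 output and the same-arm curves are
insensitive to logit misspecification. Measured: deleting both time-varying
confounders from every logit step moves `Ŝ_{a,a}` by < 1e-5 at n = 10 000
(acceptance criterion bound 0.005) while the crossed curve moves by an order
of magnitude more (`congeniality_same_arm_max_shift` in the acceptance
report).

Conventions: `S(0) = 1` exactly; for `t < tau_1` the recursion degenerates
to a single Cox step in arm `a` marginalised over `L0` (the mediator arm is
then irrelevant).

## 4. Model fitting (module `hazard`)

* **Cox**: hand-rolled Newton–Raphson on the partial likelihood with the
  Breslow convention for ties, step halving, relative coefficient tolerance
  `1e-8`, max 100 iterations. Baseline cumulative hazard by the Breslow
  estimator (jump `d_j / Σ_{risk} e^{xβ̂}`), anchored at the entry time for
  left-truncated fits. Constant columns are dropped with a warning (the
  arm indicator is constant within an arm-restricted fit by design);
  collinear designs raise. Agreement with an independent implementation
  (lifelines) is asserted to `1e-5` in the test suite.
* **Quasi-binomial logit**: statsmodels `GLM` with a binomial family, which
  accepts fractional responses; the quasi-likelihood point estimates equal
  the binomial ones, with dispersion estimated by Pearson chi-square (only
  relevant to unused model-based SEs — inference is by bootstrap).
  Predictions are clamped to `[1e-12, 1 − 1e-12]`.

## 5. Bootstrap (module `effects`)

Nonparametric bootstrap resampling whole patients with replacement
(optionally within arm), rerunning the full three-curve estimator per
resample, percentile intervals at level 0.95 by default. Resamples on which
any fit fails are skipped and counted; > 10 % failures triggers a warning.
Defaults: `B = 1000` in the CLI (a compromise between percentile-interval
granularity and runtime; the acceptance run uses `B = 200`, which resolves
the 2.5 % tails to 5 draws). Measured at n = 1000 under a null design: the
95 % interval for the survival-difference indirect effect covered 0 at every
grid point and zero resamples failed.

## 6. Additive-hazard closed form (module `dynpath`)

With one mediator wave at `tau_1`, additive hazard
`λ(t) = λ0(t) + λ1(t)A + λ2(t)M1·I(t > tau_1)` and
`M1 | T > tau_1, A ~ N(α0 + α1 A, σ²)`, the estimand integrates exactly: with
`ΔΛ2(t) = Λ2(t) − Λ2(tau_1)`,

    S_{a,a*}(t) = exp{−Λ0(t) − aΛ1(t) − ΔΛ2(t)(α0 + α1 a*) + ΔΛ2(t)² σ²/2}

by the normal moment generating function evaluated at `−ΔΛ2(t)`. The
variance term carries a **plus** sign: averaging `exp(−ΔΛ2 M)` over `M` lies
above its value at the mean mediator (Jensen); this is confirmed against
forward simulation in the test suite. Ratio effects:
`PDE(t) = exp{−Λ1(t)}` and `PIE(t) = exp{−ΔΛ2(t) α1}` (1 for `t ≤ tau_1`),
and `PDE·PIE = S11/S00` identically (machine-precision check in the
acceptance suite). Classical dynamic path analysis uses `Λ2(t)` where
`ΔΛ2(t)` belongs, i.e. ignores events before the first mediator assessment;
its indirect effect differs by the constant factor `exp{−Λ2(tau_1)α1}`
(= 1.018 for the reference design, `early_event_correction_factor`).

## 7. Simulator scope (module `simulate`)

Structural-equation generator: baseline `L0 ~ N`, linear-Gaussian visit
equations for confounders and mediators (with optional frailties `U_m`,
`U_l`), piecewise-constant interval hazards that are log-linear (or, for the
additive designs, additive) in arm and history, exponential plus
administrative censoring. Event times are drawn interval by interval by
inverting the piecewise-exponential survival function. Visit values are
blanked after the end of follow-up, exactly as a trial stops recording.

`oracle_S` produces ground truth by *forward simulation under the edge
intervention*: every equation receives arm `a` except the mediator
equations, which receive `a*`; censoring is off. Under the structural model
this is the estimand exactly, including when `U_m` is present (the
marginalisation over the frailty is implicit in the simulation), which is
why the oracle is trusted as the reference in the recovery tests.

Reference designs and why their parameters look the way they do:

* `two_visit_config` — visits at months 3 and 9, 24-month study, mediator
  and confounders on an HbA1c-like scale near 62. Defaults
  `mediator_effect = −4` (a clinically large biomarker shift),
  `direct_effect = −0.10` on the log hazard, `confounder_effect = −1.5`
  (a treatment-responsive confounder, the case that breaks naive
  mediation adjustment), hazard intercepts set so that a meaningful
  fraction of patients (about a quarter of the control arm by month 24, by
  forward simulation of the design) have events at n = 5000 — large enough for stable
  Cox fits in every interval, small enough to keep risk sets deep at
  visit 2.
* `mediator_null_config` / `null_config` — switch off the
  treatment→mediator edge (then `S_{1,0} = S_{1,1}` by construction) or
  every treatment edge (for coverage checks under the null).
* `dpa_config` / `dpa_params` — the additive-hazard single-visit design
  matched to its closed form, with `tau_1 = 1`, horizon 3, and a baseline
  additive hazard of 0.08 so that a non-negligible share of patients fail
  *before* the mediator assessment, making the early-event correction
  active.

Problem sizes in the acceptance materials (n = 5000–10 000 patients, oracle
with 200 000 draws) were chosen so that Monte-Carlo noise sits comfortably
inside the stated tolerances on a single CPU in minutes.

## 8. Numerical choices

* Cox: tolerance `1e-8`, max 100 Newton iterations, step halving; group
  sums over event times vectorised with reverse cumulative sums.
* Logit predictions clamped at `1e-12` from both ends.
* Long-CSV round trips are exact: floats written with `%.17g` and read with
  pandas' `round_trip` parser.
* All simulation seeds are explicit; derived seeds in
  `scripts/acceptance.py` come from a `SeedSequence` spawn reduced mod 2³¹.

## 9. Limitations

* Estimation (not identification) assumes the working models — Cox per
  interval, logistic integration steps — are adequate for the crossed curve
  `S_{1,0}`; only the same-arm curves enjoy the congeniality protection.
* No model-based standard errors; only bootstrap percentile intervals (no
  BCa correction).
* Visits must follow one fixed schedule shared by all patients; irregular
  individual visit times are out of scope.
* Censoring is assumed independent given arm and history; inverse-weighting
  for dependent censoring is not implemented.
* One mediator and one confounder block per visit per reference design;
  the estimator itself accepts vector-valued `V_k`/`M_k`, but the bundled
  effect never decomposes into per-mediator contributions.
* The mediated proportion is unstable where the total effect is small; it
  is deliberately suppressed (NaN) below `mp_threshold`.
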