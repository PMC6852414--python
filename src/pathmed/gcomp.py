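"""Nested sequential-regression estimator of path-specific survival curves.

The estimand ``S_{a,a*}(t)`` is the probability of being event free at time
``t`` when every treatment pathway carries arm ``a`` except the direct edges
from treatment into the mediator assessments, which carry arm ``a*``.  Under
randomisation, no unmeasured mediator-outcome confounding at each visit, and
a structural model with independent errors, it is identified by a nested
g-formula over the visit history, which this module evaluates by alternating
regressions rather than by modelling the joint covariate distribution:

1. a terminal proportional-hazards step on the patients event free at the
   last visit ``k = floor(t)`` before ``t`` in arm ``a``, predicting the
   chance ``Q^k(t)`` of surviving to ``t`` given the full observed history;
2. then, walking visits down from ``k`` to 1:

   (a) *mediator integration*: regress ``Q^k(t)`` on the history excluding
       the visit-``k`` mediator, among arm-``a*`` patients at risk at visit
       ``k``; predicting for everyone at risk replaces the visit-``k``
       mediator distribution by its arm-``a*`` law (``Qm^k``);
   (b) *confounder integration*: regress ``Qm^k(t)`` on the history up to
       visit ``k-1``, among arm-``a`` patients at risk at visit ``k``;
       predict for everyone at risk at visit ``k-1`` -- including patients
       who failed in between (``Ql^{k-1}``);
   (c) *visit survival*: a proportional-hazards fit for surviving the
       interval ``(tau_{k-1}, tau_k]`` in arm ``a``; ``Q^{k-1}`` is the
       predicted interval survival times ``Ql^{k-1}``.

3. the average of ``Q^0(t)`` over *all* patients (the empirical baseline
   distribution) estimates ``S_{a,a*}(t)``.

The asymmetry of (a) and (b) -- fit in one arm, predict on the pooled at-risk
set, with the prediction set growing in (b) -- mirrors the construction of
the nested counterfactual and is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import HistoryDesign, LongitudinalMediationDataset, build_history, risk_set
from .hazard import (
    HazardFit,
    LogitFit,
    fit_cox,
    fit_quasibinomial_logit,
    predict_interval_survival,
    predict_logit,
)


@dataclass
class EstimatorConfig:
    """Model choices for the sequential estimator.

    By default every regression uses main effects of the full observed
    history (baseline covariates, all confounders and mediators up to the
    depth each step permits).  ``logit_exclude`` removes named columns from
    the two logistic steps only -- useful for probing the robustness of
    same-arm curves to logit misspecification.  ``cox_exclude`` does the same
    for the proportional-hazards steps.  When ``enforce_congeniality`` is
    set, columns excluded from a Cox step are propagated to the downstream
    logistic steps so the regressions keep matching structure.
    """

    logit_exclude: tuple[str, ...] = ()
    cox_exclude: tuple[str, ...] = ()
    enforce_congeniality: bool = True
    min_fit_margin: int = 2  # required excess of fitting patients over columns

    def _apply(self, design: HistoryDesign, exclude: tuple[str, ...]) -> HistoryDesign:
        if not exclude:
            return design
        keep = [j for j, nm in enumerate(design.names) if nm not in exclude]
        return HistoryDesign(
            k=design.k,
            patients=design.patients,
            X=design.X[:, keep],
            names=[design.names[j] for j in keep],
        )

    def cox_design(self, ds, patients, j, m) -> HistoryDesign:
        return self._apply(build_history(ds, patients, j, m), self.cox_exclude)

    def logit_design(self, ds, patients, j, m) -> HistoryDesign:
        exclude = self.logit_exclude
        if self.enforce_congeniality:
            exclude = tuple(dict.fromkeys(exclude + self.cox_exclude))
        return self._apply(build_history(ds, patients, j, m), exclude)


@dataclass
class NestedPrediction:
    """Per-patient working values of one recursion step.

    ``values`` has one entry per patient in the dataset, NaN outside the
    subset on which the quantity is defined (``subset`` is a positional-index
    array)."""

    kind: str            # "Q", "Qm", or "Ql"
    k: int               # visit index the quantity refers to
    t: float             # target time of the recursion
    values: np.ndarray
    subset: np.ndarray
    model: HazardFit | LogitFit | None = None

    def on_subset(self) -> np.ndarray:
        return self.values[self.subset]


@dataclass
class PathSpecificSurvival:
    """Estimated curve ``S_{a,a*}(.)`` on a time grid."""

    a: int
    astar: int
    times: np.ndarray
    estimates: np.ndarray
    fit_log: list[dict] = field(default_factory=list)

    def __call__(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} not on the estimated grid")
        return float(self.estimates[i])


class _FrozenModels(dict):
    """Optional store of pre-fitted step models, keyed by (step, visit).

    Step keys: ``("terminal", k)``, ``("med", k)``, ``("conf", k)``,
    ``("visit", k)``.  When a key is present the step skips fitting and only
    runs its prediction side -- the replay mode used for worked examples."""


# ---------------------------------------------------------------------------
# The four steps
# ---------------------------------------------------------------------------


def terminal_step(
    ds: LongitudinalMediationDataset,
    a: int,
    t: float,
    cfg: EstimatorConfig,
    model: HazardFit | None = None,
) -> NestedPrediction:
    """Step 1: Cox fit on arm ``a`` patients event free at ``k = floor(t)``,
    using the full history to visit ``k``; predict survival through ``t`` for
    every at-risk patient in either arm."""
    k = ds.schedule.floor_visit(t)
    fit_idx = risk_set(ds, k, a)
    if len(fit_idx) == 0:
        raise ValueError(f"empty risk set at visit {k} in arm {a}")
    entry = ds.schedule.tau(k)
    if model is None:
        design = cfg.cox_design(ds, fit_idx, k, k)
        model = fit_cox(design.X, ds.T[fit_idx], ds.E[fit_idx], entry_time=entry,
                        names=design.names)
    pred_idx = risk_set(ds, k, "both")
    Xp = cfg.cox_design(ds, pred_idx, k, k)
    # align columns with the model in case a replay model orders differently
    Xmat = _reorder(Xp, model.names)
    values = np.full(ds.n, np.nan)
    values[pred_idx] = predict_interval_survival(model, Xmat, t)
    return NestedPrediction("Q", k, t, values, pred_idx, model)


def mediator_integration_step(
    ds: LongitudinalMediationDataset,
    qk: NestedPrediction,
    k: int,
    astar: int,
    cfg: EstimatorConfig,
    model: LogitFit | None = None,
) -> NestedPrediction:
    """Step 2(a): regress ``Q^k(t)`` on ``(L0, V_1..V_k, M_1..M_{k-1})``
    among arm-``a*`` patients at risk at visit ``k``; predict ``Qm^k`` for
    all at-risk patients.  Excluding ``M_k`` from the regressors is what
    replaces its law with the arm-``a*`` one."""
    fit_idx = risk_set(ds, k, astar)
    if model is None:
        design = cfg.logit_design(ds, fit_idx, k, k - 1)
        if len(fit_idx) < design.X.shape[1] + cfg.min_fit_margin:
            raise ValueError(
                f"only {len(fit_idx)} arm-{astar} patients at visit {k} for "
                f"{design.X.shape[1]} regressors"
            )
        model = fit_quasibinomial_logit(design.X, qk.values[fit_idx], names=design.names)
    pred_idx = risk_set(ds, k, "both")
    Xp = cfg.logit_design(ds, pred_idx, k, k - 1)
    values = np.full(ds.n, np.nan)
    values[pred_idx] = predict_logit(model, _reorder(Xp, model.names))
    return NestedPrediction("Qm", k, qk.t, values, pred_idx, model)


def confounder_integration_step(
    ds: LongitudinalMediationDataset,
    qmk: NestedPrediction,
    k: int,
    a: int,
    cfg: EstimatorConfig,
    model: LogitFit | None = None,
) -> NestedPrediction:
    """Step 2(b): regress ``Qm^k(t)`` on ``(L0, V_1..V_{k-1}, M_1..M_{k-1})``
    among arm-``a`` patients at risk at visit ``k``; predict ``Ql^{k-1}`` for
    everyone at risk at visit ``k-1`` -- a strictly larger set whenever
    events occurred in ``(tau_{k-1}, tau_k]``."""
    fit_idx = risk_set(ds, k, a)
    if model is None:
        design = cfg.logit_design(ds, fit_idx, k - 1, k - 1)
        if len(fit_idx) < design.X.shape[1] + cfg.min_fit_margin:
            raise ValueError(
                f"only {len(fit_idx)} arm-{a} patients at visit {k} for "
                f"{design.X.shape[1]} regressors"
            )
        model = fit_quasibinomial_logit(design.X, qmk.values[fit_idx], names=design.names)
    pred_idx = risk_set(ds, k - 1, "both")
    Xp = cfg.logit_design(ds, pred_idx, k - 1, k - 1)
    values = np.full(ds.n, np.nan)
    values[pred_idx] = predict_logit(model, _reorder(Xp, model.names))
    return NestedPrediction("Ql", k - 1, qmk.t, values, pred_idx, model)


def visit_survival_step(
    ds: LongitudinalMediationDataset,
    qlk: NestedPrediction,
    k: int,
    a: int,
    cfg: EstimatorConfig,
    model: HazardFit | None = None,
) -> NestedPrediction:
    """Step 2(c): Cox fit for the interval ``(tau_{k-1}, tau_k]`` among
    arm-``a`` patients at risk at ``k-1`` (administratively censored at
    ``tau_k``); ``Q^{k-1}`` is the predicted interval survival multiplied by
    ``Ql^{k-1}``."""
    fit_idx = risk_set(ds, k - 1, a)
    t_lo, t_hi = ds.schedule.tau(k - 1), ds.schedule.tau(k)
    if model is None:
        design = cfg.cox_design(ds, fit_idx, k - 1, k - 1)
        times = np.minimum(ds.T[fit_idx], t_hi)
        events = (ds.E[fit_idx] == 1) & (ds.T[fit_idx] <= t_hi)
        model = fit_cox(design.X, times, events, entry_time=t_lo, names=design.names)
    pred_idx = risk_set(ds, k - 1, "both")
    Xp = cfg.cox_design(ds, pred_idx, k - 1, k - 1)
    surv = predict_interval_survival(model, _reorder(Xp, model.names), t_hi)
    values = np.full(ds.n, np.nan)
    values[pred_idx] = surv * qlk.values[pred_idx]
    return NestedPrediction("Q", k - 1, qlk.t, values, pred_idx, model)


def _reorder(design: HistoryDesign, names: list[str]) -> np.ndarray:
    if design.names == list(names):
        return design.X
    pos = {nm: j for j, nm in enumerate(design.names)}
    try:
        cols = [pos[nm] for nm in names]
    except KeyError as exc:
        raise ValueError(f"prediction design lacks column {exc}") from exc
    return design.X[:, cols]


# ---------------------------------------------------------------------------
# Full recursion
# ---------------------------------------------------------------------------


def run_recursion(
    ds: LongitudinalMediationDataset,
    a: int,
    astar: int,
    t: float,
    cfg: EstimatorConfig | None = None,
    models: _FrozenModels | dict | None = None,
    cache: dict | None = None,
    keep_steps: bool = False,
):
    """Run the full nested recursion for one target time ``t``.

    Returns ``(estimate, steps)`` where ``steps`` (if requested) is the list
    of :class:`NestedPrediction` in execution order.  ``models`` supplies
    frozen pre-fitted models for replay; ``cache`` shares proportional-hazards
    fits, which do not depend on ``t`` beyond the visit index, across grid
    points of the same curve.
    """
    cfg = cfg or EstimatorConfig()
    models = models or {}
    cache = cache if cache is not None else {}
    kt = ds.schedule.floor_visit(t)

    key = ("terminal", kt)
    q = terminal_step(ds, a, t, cfg, model=models.get(key) or cache.get(key))
    cache.setdefault(key, q.model)
    steps = [q]
    for k in range(kt, 0, -1):
        qm = mediator_integration_step(ds, q, k, astar, cfg, model=models.get(("med", k)))
        ql = confounder_integration_step(ds, qm, k, a, cfg, model=models.get(("conf", k)))
        vkey = ("visit", k)
        q = visit_survival_step(ds, ql, k, a, cfg, model=models.get(vkey) or cache.get(vkey))
        cache.setdefault(vkey, q.model)
        if keep_steps:
            steps += [qm, ql, q]
    estimate = float(np.mean(q.values[risk_set(ds, 0, "both")]))
    return estimate, (steps if keep_steps else None)


def estimate_S(
    ds: LongitudinalMediationDataset,
    a: int,
    astar: int,
    t_grid,
    cfg: EstimatorConfig | None = None,
    models: dict | None = None,
) -> PathSpecificSurvival:
    """Estimate ``S_{a,a*}(t)`` on a grid of times.

    ``S_{a,a}`` (same-arm) curves run through the identical code path with
    ``astar = a``.  At ``t = 0`` the estimate is exactly 1.  Failures at a
    grid point (e.g. an empty risk set) are re-raised with the offending time
    attached.
    """
    cfg = cfg or EstimatorConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("grid times must be nonnegative")
    cache: dict = {}
    out = np.empty(len(t_grid))
    log: list[dict] = []
    for i, t in enumerate(t_grid):
        if t == 0:
            out[i] = 1.0
            continue
        try:
            est, _ = run_recursion(ds, a, astar, float(t), cfg, models=models, cache=cache)
        except Exception as exc:
            raise RuntimeError(f"estimation failed at grid time t={t:g}: {exc}") from exc
        out[i] = est
    for key, model in sorted(cache.items(), key=str):
        log.append({"step": key[0], "visit": key[1], **model.to_dict()})
    return PathSpecificSurvival(a=a, astar=astar, times=t_grid, estimates=out, fit_log=log)
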