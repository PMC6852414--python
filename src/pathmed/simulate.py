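"""Synthetic two-arm trials from a longitudinal structural equation model,
with a ground-truth oracle for path-specific survival.

The generator follows the causal ordering of the estimator's assumed data
structure: baseline covariates ``L0``; randomised arm ``A``; then per visit
``k`` (in time order) survival through the preceding interval, the
confounder ``V_k`` (which may respond to treatment and to *earlier*
mediators, never to ``M_k``), and the mediator ``M_k``.  Two optional shared
normal frailties mimic unmeasured heterogeneity that the identification
assumptions permit: ``U_m`` enters only the mediator equations, ``U_l`` the
confounder equations and (log-linearly) the hazard.

Hazards are piecewise constant between visits, so interval survival is exact
inverse-CDF exponential sampling and the oracle carries no numerical
integration error.  An ``illegal_shared_frailty`` switch adds a common cause
of mediators *and* confounders -- deliberately violating the identification
assumptions -- for robustness experiments, and is labelled as such.

The oracle computes ``S_{a,a*}(t)`` by forward-simulating the structural
model under the edge intervention itself: every equation receives arm ``a``
except the mediator equations, which receive arm ``a*``.  Under the assumed
independent-errors structural model this coincides exactly with the nested
g-formula the estimator targets, and remains exact in the presence of the
permitted frailties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import LongitudinalMediationDataset, VisitSchedule
from .gcomp import PathSpecificSurvival
from .hazard import HazardFit, LogitFit


# ---------------------------------------------------------------------------
# Structural-equation configuration
# ---------------------------------------------------------------------------


@dataclass
class VisitModel:
    """Linear Gaussian structural equation for one visit variable.

    ``v`` holds coefficients on earlier confounders ``V_1..`` (for a mediator
    equation the current visit's confounder is included last); ``m`` holds
    coefficients on earlier mediators ``M_1..M_{k-1}``.  ``frailty`` is the
    loading on the relevant shared frailty."""

    intercept: float
    a: float = 0.0
    l0: float = 0.0
    v: tuple[float, ...] = ()
    m: tuple[float, ...] = ()
    frailty: float = 0.0
    sd: float = 1.0

    def linpred(self, arm, L0, V_hist, M_hist, U):
        out = self.intercept + self.a * arm + U * self.frailty
        if self.l0 and L0.shape[1]:
            out = out + self.l0 * L0[:, 0]
        for c, col in zip(self.v, V_hist):
            out = out + c * col
        for c, col in zip(self.m, M_hist):
            out = out + c * col
        return out


@dataclass
class IntervalHazard:
    """Constant hazard on one inter-visit interval as a function of history.

    ``form="loglinear"``: rate ``exp(intercept + a A + l0 L0 + v.V + m.M +
    frailty U_l)``.  ``form="additive"``: rate ``max(0, intercept + a A +
    l0 L0 + v.V + m.M)`` (no frailty), the dynamic-path-analysis form."""

    intercept: float
    a: float = 0.0
    l0: float = 0.0
    v: tuple[float, ...] = ()
    m: tuple[float, ...] = ()
    frailty: float = 0.0
    form: str = "loglinear"

    def rate(self, arm, L0, V_hist, M_hist, U_l):
        lin = self.intercept + self.a * arm
        if self.l0 and L0.shape[1]:
            lin = lin + self.l0 * L0[:, 0]
        for c, col in zip(self.v, V_hist):
            lin = lin + c * col
        for c, col in zip(self.m, M_hist):
            lin = lin + c * col
        if self.form == "loglinear":
            return np.exp(lin + self.frailty * U_l)
        if self.form == "additive":
            return np.maximum(lin, 0.0)
        raise ValueError(f"unknown hazard form {self.form!r}")


@dataclass
class SimConfig:
    """Full specification of one synthetic trial design."""

    n: int
    schedule: VisitSchedule
    end_of_study: float
    l0_mean: float | None          # None: no baseline covariate
    l0_sd: float
    v_models: list[VisitModel | None]   # one per visit (None: no confounder)
    m_models: list[VisitModel]          # one per visit
    hazards: list[IntervalHazard]       # K+1 intervals: (0,t1], ..., (tK,end]
    var_um: float = 0.0
    var_ul: float = 0.0
    censor_rate: float = 0.0            # exponential loss to follow-up (0: admin only)
    illegal_shared_frailty: float = 0.0  # SYNTHETIC assumption violation, see module doc

    def __post_init__(self) -> None:
        K = self.schedule.K
        if len(self.m_models) != K or len(self.v_models) != K:
            raise ValueError("need one mediator and one confounder slot per visit")
        if len(self.hazards) != K + 1:
            raise ValueError(f"need {K + 1} interval hazards")
        if self.end_of_study <= self.schedule.times[-1]:
            raise ValueError("end of study must exceed the last visit")
        if min(self.var_um, self.var_ul, self.censor_rate) < 0:
            raise ValueError("variances and rates must be nonnegative")

    @property
    def boundaries(self) -> list[float]:
        return [0.0, *self.schedule.times, self.end_of_study]


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def _forward(cfg: SimConfig, rng, arm_outcome, arm_mediator, n: int):
    """Simulate latent event times and visit variables.

    ``arm_outcome`` feeds the hazard and confounder equations, ``arm_mediator``
    the mediator equations; they coincide for an ordinary trial and differ
    under the oracle's edge intervention.  Returns ``(T_latent, V, M)`` where
    visit values are NaN for patients whose event precedes the visit.
    """
    L0 = (
        rng.normal(cfg.l0_mean, cfg.l0_sd, size=(n, 1))
        if cfg.l0_mean is not None
        else np.empty((n, 0))
    )
    U_m = rng.normal(0.0, math.sqrt(cfg.var_um), size=n) if cfg.var_um else np.zeros(n)
    U_l = rng.normal(0.0, math.sqrt(cfg.var_ul), size=n) if cfg.var_ul else np.zeros(n)
    if cfg.illegal_shared_frailty:
        shared = rng.normal(0.0, math.sqrt(cfg.illegal_shared_frailty), size=n)
        U_m, U_l = U_m + shared, U_l + shared
    T = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    # V_hist holds only the visits that actually have a confounder (the
    # coefficient tuples index these, in visit order); V_slots mirrors the
    # schedule with None where a visit has no confounder.
    V_hist: list[np.ndarray] = []
    V_slots: list[np.ndarray | None] = []
    M_hist: list[np.ndarray] = []
    bounds = cfg.boundaries
    for j, hz in enumerate(cfg.hazards):
        lo, hi = bounds[j], bounds[j + 1]
        with np.errstate(invalid="ignore"):
            rate = hz.rate(arm_outcome, L0, V_hist, M_hist, U_l)
            draw = rng.exponential(1.0, size=n)
            gap = np.where(rate > 0, draw / np.where(rate > 0, rate, 1.0), np.inf)
            newly = alive & (gap <= hi - lo)
        T[newly] = lo + gap[newly]
        alive = alive & ~newly
        if j < cfg.schedule.K:
            # visit j+1 happens at time hi for survivors: V first, then M
            vm, mm = cfg.v_models[j], cfg.m_models[j]
            if vm is not None:
                v = vm.linpred(arm_outcome, L0, V_hist, M_hist, U_l) + rng.normal(0, vm.sd, n)
                v = np.where(alive, v, np.nan)
                V_hist.append(v)
                V_slots.append(v)
            else:
                V_slots.append(None)
            m = mm.linpred(arm_mediator, L0, V_hist, M_hist, U_m)
            m = m + rng.normal(0, mm.sd, n)
            M_hist.append(np.where(alive, m, np.nan))
    return L0, T, V_slots, M_hist


def simulate_trial(cfg: SimConfig, seed: int | np.random.Generator = 0) -> LongitudinalMediationDataset:
    """Draw one trial: 1:1 randomisation, structural visit process, censoring.

    Mediator and confounder values are blanked (NaN) after the end of
    follow-up, exactly as a real trial stops recording them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = rng.integers(0, 2, size=cfg.n)
    L0, T_latent, V_hist, M_hist = _forward(cfg, rng, A, A, cfg.n)
    if cfg.censor_rate > 0:
        C = rng.exponential(1.0 / cfg.censor_rate, size=cfg.n)
    else:
        C = np.full(cfg.n, np.inf)
    C = np.minimum(C, cfg.end_of_study)
    T = np.minimum(T_latent, C)
    E = (T_latent <= C).astype(int)
    V: list[np.ndarray | None] = []
    M: list[np.ndarray] = []
    for k in range(1, cfg.schedule.K + 1):
        seen = T > cfg.schedule.tau(k)
        v = V_hist[k - 1]
        V.append(None if v is None else np.where(seen, v, np.nan)[:, None])
        M.append(np.where(seen, M_hist[k - 1], np.nan)[:, None])
    ds = LongitudinalMediationDataset(
        ids=np.arange(cfg.n), arm=A, L0=L0, V=V, M=M, T=T, E=E,
        schedule=cfg.schedule,
        l0_names=["l0"] if L0.shape[1] else [],
        v_names=[[] if v is None else [f"v{k+1}"] for k, v in enumerate(V)],
        m_names=[[f"m{k+1}"] for k in range(cfg.schedule.K)],
        end_of_study=cfg.end_of_study,
    )
    ds.validate(strict=True)
    return ds


@dataclass
class OracleSurvival(PathSpecificSurvival):
    """Monte-Carlo ground truth with its binomial standard error."""

    se: np.ndarray | None = None


def oracle_S(
    cfg: SimConfig,
    a: int,
    astar: int,
    t_grid,
    ndraws: int = 100_000,
    seed: int = 0,
    se_target: float | None = None,
) -> OracleSurvival:
    """Ground-truth ``S_{a,a*}(t)`` by structural forward simulation.

    All equations receive arm ``a`` except the mediator equations, which
    receive ``a*``; censoring is switched off (the estimand concerns the
    uncensored event time).  A patient failing before a visit simply keeps
    that event time -- no mediator is drawn for them, matching the estimand's
    handling of deaths before assessment.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    arm_out = np.full(ndraws, float(a))
    arm_med = np.full(ndraws, float(astar))
    _, T, _, _ = _forward(cfg, rng, arm_out, arm_med, ndraws)
    est = np.array([np.mean(T > t) for t in t_grid])
    se = np.sqrt(est * (1 - est) / ndraws)
    if se_target is not None and np.max(se) > se_target:
        import warnings

        warnings.warn(
            f"oracle SE up to {np.max(se):.2g} exceeds the requested {se_target:.2g}; "
            "increase ndraws"
        )
    return OracleSurvival(a=a, astar=astar, times=t_grid, estimates=est, se=se)


# ---------------------------------------------------------------------------
# Reference trial designs
# ---------------------------------------------------------------------------
#
# Scales mimic a glycaemic-control trial: baseline and visit covariates near
# 62 (an HbA1c-like scale), the treatment lowering the mediator by about 4
# units, hazards of a few events per hundred patient-months.


def two_visit_config(
    n: int = 5000,
    *,
    mediator_effect: float = -4.0,
    direct_effect: float = -0.10,
    confounder_effect: float = -1.5,
    var_um: float = 0.0,
    var_ul: float = 0.0,
    censor_rate: float = 0.0,
    illegal_shared_frailty: float = 0.0,
) -> SimConfig:
    """Two visits (months 3 and 9), 24-month study.

    Treatment acts directly on the hazard (``direct_effect`` log-rate), on
    the confounders (``confounder_effect``, a treatment-responsive pathway
    deliberately *excluded* from the mediated effect), and directly on both
    mediators (``mediator_effect``).  Set ``mediator_effect=0`` for the
    mediator-null design, and all three to 0 for the full null.
    """
    return SimConfig(
        n=n,
        schedule=VisitSchedule((3.0, 9.0)),
        end_of_study=24.0,
        l0_mean=62.0,
        l0_sd=6.0,
        v_models=[
            VisitModel(6.0, a=confounder_effect, l0=0.9, frailty=1.0, sd=3.0),
            VisitModel(5.0, a=confounder_effect / 1.5, l0=0.25, v=(0.5,), m=(0.2,),
                       frailty=1.0, sd=3.0),
        ],
        m_models=[
            VisitModel(2.0, a=mediator_effect, l0=0.55, v=(0.4,), frailty=1.0, sd=3.0),
            VisitModel(2.0, a=mediator_effect, l0=0.30, v=(0.0, 0.3), m=(0.4,),
                       frailty=1.0, sd=3.0),
        ],
        hazards=[
            IntervalHazard(-5.66, a=direct_effect, l0=0.02),
            IntervalHazard(-7.18, a=direct_effect, l0=0.01, v=(0.015,), m=(0.02,)),
            IntervalHazard(-8.08, a=direct_effect, l0=0.01, v=(0.01, 0.01),
                           m=(0.012, 0.018)),
        ],
        var_um=var_um,
        var_ul=var_ul,
        censor_rate=censor_rate,
        illegal_shared_frailty=illegal_shared_frailty,
    )


def mediator_null_config(n: int = 5000, **kw) -> SimConfig:
    """Treatment never enters a mediator equation: S_{1,0} == S_{1,1}."""
    return two_visit_config(n, mediator_effect=0.0, **kw)


def null_config(n: int = 1000, **kw) -> SimConfig:
    """No treatment effect anywhere (hazard, confounders, mediators)."""
    return two_visit_config(
        n, mediator_effect=0.0, direct_effect=0.0, confounder_effect=0.0, **kw
    )


def dpa_config(n: int = 10_000) -> SimConfig:
    """Single-visit additive-hazard + normal-mediator design.

    Matches the closed-form dynamic-path setting: constant additive hazard
    contributions ``0.08 - 0.03 A + 0.003 M1 I(t > 1)`` and mediator
    ``M1 | T>1, A ~ N(50 - 6 A, 4^2)``.  About 8%% of control patients fail
    before the first mediator assessment, so the early-event correction to
    the indirect effect is active.
    """
    return SimConfig(
        n=n,
        schedule=VisitSchedule((1.0,)),
        end_of_study=3.0,
        l0_mean=None,
        l0_sd=1.0,
        v_models=[None],
        m_models=[VisitModel(50.0, a=-6.0, sd=4.0)],
        hazards=[
            IntervalHazard(0.08, a=-0.03, form="additive"),
            IntervalHazard(0.08, a=-0.03, m=(0.003,), form="additive"),
        ],
    )


def dpa_params():
    """The :class:`~pathmed.dynpath.DPAParams` matching :func:`dpa_config`."""
    from .dynpath import CumulativeHazard, DPAParams

    return DPAParams(
        lambda0=CumulativeHazard.from_rate(0.08),
        lambda1=CumulativeHazard.from_rate(-0.03),
        lambda2=CumulativeHazard.from_rate(0.003),
        alpha0=50.0,
        alpha1=-6.0,
        sigma2=16.0,
        tau1=1.0,
    )


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

_WORKED_EXAMPLE_ROWS = [
    # id, A,  L0,    L1(=V1), M1,    E, T
    (1, 0, 62.79, 62.36, 63.36, 1, 5.57),
    (2, 0, 64.75, 65.96, 75.78, 1, 0.65),
    (3, 0, 57.13, 56.35, 74.80, 1, 11.44),
    (4, 1, 56.28, 55.27, 53.08, 1, 9.42),
    (5, 1, 72.55, 68.05, 59.07, 1, 13.68),
    (6, 1, 67.61, 61.02, 54.17, 1, 9.61),
    (7, 0, 52.84, 46.85, 65.93, 1, 6.70),
    (8, 1, 65.16, 58.16, 51.88, 0, 24.00),
    (9, 0, 62.69, 59.91, 66.51, 1, 5.61),
    (10, 1, 74.23, 65.88, 50.62, 0, 24.00),
]


def worked_example_fixture():
    """Ten-patient worked-example dataset with its frozen regression fits.

    One visit at month 3, 24-month study, baseline covariate ``l0``, visit
    confounder ``l1`` and mediator ``m1``.  Patient 2 failed at month 0.65,
    *before* the visit, yet carries recorded visit values: they are stored
    verbatim but excluded from every risk set (the at-risk indicator is
    derived from ``T``), so they never enter a fit or an at-risk prediction.
    (The patient-1 confounder is stored as the tabulated 62.36; a variant
    value 62.63 circulates for the same patient and shifts the mediator-
    integration prediction from 0.799 to 0.796 -- both round to 0.80.)

    Returns ``(dataset, models)`` where ``models`` maps recursion steps to
    frozen fits for replaying the estimate of ``S_{1,0}(5)``:

    * terminal hazard: log hazard ratios 0.05 (l0), -0.05 (l1), 0.02 (m1),
      cumulative baseline hazard 0.06 at month 5 (entry at month 3);
    * mediator integration: logit intercept 1.48, slopes 0.049 (l0),
      -0.051 (l1);
    * confounder integration: logit intercept 1.71, slope -0.003 (l0);
    * visit survival: log hazard ratio 0.003 (l0), cumulative baseline
      hazard 0.02 at month 3.
    """
    rows = np.array(_WORKED_EXAMPLE_ROWS)
    ds = LongitudinalMediationDataset(
        ids=rows[:, 0].astype(int),
        arm=rows[:, 1].astype(int),
        L0=rows[:, 2:3],
        V=[rows[:, 3:4]],
        M=[rows[:, 4:5]],
        T=rows[:, 6],
        E=rows[:, 5].astype(int),
        schedule=VisitSchedule((3.0,)),
        l0_names=["l0"],
        v_names=[["l1"]],
        m_names=[["m1"]],
        end_of_study=24.0,
    )
    models = {
        ("terminal", 1): HazardFit(
            coef=np.array([0.05, -0.05, 0.02]),
            names=["l0", "l1", "m1"],
            baseline_times=np.array([5.0]),
            baseline_cumhaz=np.array([0.06]),
            entry_time=3.0,
        ),
        ("med", 1): LogitFit(np.array([1.48, 0.049, -0.051]), ["l0", "l1"]),
        ("conf", 1): LogitFit(np.array([1.71, -0.003]), ["l0"]),
        ("visit", 1): HazardFit(
            coef=np.array([0.003]),
            names=["l0"],
            baseline_times=np.array([3.0]),
            baseline_cumhaz=np.array([0.02]),
            entry_time=0.0,
        ),
    }
    return ds, models
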