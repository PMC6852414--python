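"""Regression primitives: proportional-hazards fits with a Breslow baseline,
and quasi-binomial logistic regression for responses in [0, 1].

The sequential estimator alternates between exactly two kinds of model:

* a Cox proportional-hazards model fitted on a visit-specific risk set, whose
  predictions ``exp(-Lambda0(t) * exp(x'beta))`` give each patient's chance of
  remaining event free through time ``t``;
* a quasi-binomial logistic regression whose fractional responses are the
  survival predictions of the previous step.

The partial likelihood uses Breslow's tie convention so the fitted
coefficients are exactly congenial with the Breslow cumulative-baseline-hazard
estimator (jump ``d / sum_{j in risk set} exp(x_j'beta)`` at each event time).
Quasi-binomial fits are delegated to statsmodels' IRLS (GLM with binomial
variance and logit link), which accepts fractional responses; the dispersion
parameter is estimated but plays no role in prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

COX_TOL = 1e-8      # relative coefficient change declaring convergence
COX_MAX_ITER = 100
PROB_EPS = 1e-12    # clamp for fitted probabilities


class FitError(RuntimeError):
    """Raised when a regression fit cannot be completed (collinearity,
    separation, non-convergence)."""


# ---------------------------------------------------------------------------
# Cox proportional hazards with Breslow baseline
# ---------------------------------------------------------------------------


@dataclass
class HazardFit:
    """Fitted proportional-hazards model.

    ``baseline_times`` / ``baseline_cumhaz`` tabulate the right-continuous
    Breslow step function; ``cumhaz0`` evaluates it, with ``Lambda0`` anchored
    at zero at ``entry_time`` (the common left-truncation time of the fit).
    """

    coef: np.ndarray
    names: list[str]
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    entry_time: float = 0.0
    dropped: list[str] = field(default_factory=list)

    def cumhaz0(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.entry_time - 1e-12):
            raise ValueError("prediction time precedes the fit's entry time")
        if len(self.baseline_times) == 0:
            return np.zeros(t.shape)
        idx = np.searchsorted(self.baseline_times, t, side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]

    def to_dict(self) -> dict:
        return {
            "coef": dict(zip(self.names, np.round(self.coef, 6).tolist())),
            "entry_time": self.entry_time,
            "n_event_times": int(len(self.baseline_times)),
            "dropped": self.dropped,
        }


def fit_cox(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    entry_time: float = 0.0,
    names: list[str] | None = None,
) -> HazardFit:
    """Maximum partial-likelihood Cox fit with Breslow ties and baseline.

    All patients share ``entry_time`` (the risk set enters at the visit being
    conditioned on), so left truncation reduces to anchoring the baseline
    cumulative hazard at that time.  Columns with zero variance are dropped
    with a warning (their coefficient is unidentifiable); a rank-deficient
    design after that raises :class:`FitError`.  With no events the baseline
    hazard is identically zero (returned with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.any(times <= entry_time):
        raise ValueError("all event/censoring times must exceed entry_time")

    keep = np.flatnonzero(np.ptp(X, axis=0) > 0) if p else np.array([], int)
    dropped = [names[j] for j in range(p) if j not in keep]
    if dropped:
        warnings.warn(f"dropping constant covariate(s) {dropped}: coefficient unidentifiable")
    Xw = X[:, keep] - (X[:, keep].mean(axis=0) if keep.size else 0.0)
    full_coef = np.zeros(p)

    if not events.any():
        warnings.warn("no events in the fitting sample: baseline hazard is identically zero")
        return HazardFit(full_coef, names, np.array([]), np.array([]), entry_time, dropped)

    if keep.size and np.linalg.matrix_rank(Xw) < keep.size:
        raise FitError(f"collinear design (rank < {keep.size})")

    order = np.argsort(times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], Xw[order]
    # group patients by distinct time; the risk set at a group's time is the
    # tail of the sorted arrays, so risk-set sums are reverse cumulative sums
    _, first = np.unique(t_s, return_index=True)
    d_g = np.add.reduceat(e_s.astype(float), first)
    ev_mask = d_g > 0
    xx = np.einsum("ij,ik->ijk", X_s, X_s)  # (n, p, p) per-row outer products
    beta = np.zeros(keep.size)

    def negloglik_grad_hess(b):
        eta = X_s @ b
        eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1][first][ev_mask]
        S1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1][first][ev_mask]
        S2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1][first][ev_mask]
        d = d_g[ev_mask]
        ll = float(np.sum(eta * e_s) - np.sum(d * np.log(S0)))
        Z = S1 / S0[:, None]
        g = X_s[e_s].sum(axis=0) - d @ Z
        H = -(np.einsum("g,gjk->jk", d, S2 / S0[:, None, None])
              - np.einsum("g,gj,gk->jk", d, Z, Z))
        return -ll, -g, -H

    if keep.size:
        nll, g, H = negloglik_grad_hess(beta)
        for _ in range(COX_MAX_ITER):
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise FitError(f"singular information matrix: {exc}") from exc
            # Newton step with halving if the likelihood worsens
            for half in range(30):
                cand = beta - step / (2**half)
                nll_new, g_new, H_new = negloglik_grad_hess(cand)
                if nll_new <= nll + 1e-12:
                    break
            else:  # pragma: no cover
                raise FitError("Cox partial likelihood failed to improve")
            delta = np.max(np.abs(cand - beta)) / (np.max(np.abs(beta)) + 1.0)
            beta, nll, g, H = cand, nll_new, g_new, H_new
            if delta < COX_TOL:
                break
        else:
            raise FitError("Cox fit did not converge")
        full_coef[keep] = beta

    # Breslow baseline on the original (uncentred) covariate scale
    eta = X[order][:, keep] @ beta if keep.size else np.zeros(n)
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1][first]
    bt = t_s[first][ev_mask]
    bc = np.cumsum(d_g[ev_mask] / S0[ev_mask])
    return HazardFit(full_coef, names, bt, bc, entry_time, dropped)


def predict_interval_survival(fit: HazardFit, X: np.ndarray, t: float) -> np.ndarray:
    """``exp(-Lambda0(t) * exp(x'beta))`` for each row of ``X``; equals 1 at
    ``t = entry_time`` and is nonincreasing in ``t``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(fit.coef):
        raise ValueError(f"design has {X.shape[1]} columns, fit expects {len(fit.coef)}")
    lam = float(fit.cumhaz0(t))
    return np.exp(-lam * np.exp(X @ fit.coef))


# ---------------------------------------------------------------------------
# Quasi-binomial logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogitFit:
    """Quasi-binomial logit fit; ``params[0]`` is the intercept."""

    params: np.ndarray
    names: list[str]
    dispersion: float = 1.0

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(["(intercept)"] + self.names, np.round(self.params, 6).tolist())),
            "dispersion": round(float(self.dispersion), 6),
        }


def fit_quasibinomial_logit(
    X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> LogitFit:
    """Quasi-likelihood logit fit for fractional responses.

    The point estimates coincide with binomial IRLS; the dispersion (Pearson
    chi-square over residual degrees of freedom) is reported for completeness
    but never used in prediction.  Because the score equation includes an
    intercept, the mean of the fitted values equals the mean of the responses
    on the fitting sample -- the property the estimator's same-arm robustness
    rests on.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if np.ptp(y) < 1e-12:
        # constant response: intercept-only fit reproducing it everywhere
        c = float(np.clip(y.mean(), PROB_EPS, 1 - PROB_EPS))
        params = np.zeros(X.shape[1] + 1)
        params[0] = np.log(c / (1 - c))
        return LogitFit(params, names, 0.0)
    Xc = sm.add_constant(X, has_constant="add")
    yc = np.clip(y, PROB_EPS, 1 - PROB_EPS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(yc, Xc, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
        except Exception as exc:
            raise FitError(f"quasi-binomial fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e6:
        raise FitError(
            "quasi-binomial fit did not converge (possible perfect separation); "
            f"|params| max = {np.max(np.abs(res.params)):.3g}"
        )
    df = max(len(y) - Xc.shape[1], 1)
    mu = np.clip(res.fittedvalues, PROB_EPS, 1 - PROB_EPS)
    dispersion = float(np.sum((yc - mu) ** 2 / (mu * (1 - mu))) / df)
    return LogitFit(np.asarray(res.params), names, dispersion)


def predict_logit(fit: LogitFit, X: np.ndarray) -> np.ndarray:
    """``expit(intercept + x'coef)``, strictly inside (0, 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(fit.params) - 1:
        raise ValueError(f"design has {X.shape[1]} columns, fit expects {len(fit.params) - 1}")
    p = expit(fit.params[0] + X @ fit.params[1:])
    return np.clip(p, PROB_EPS, 1 - PROB_EPS)
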