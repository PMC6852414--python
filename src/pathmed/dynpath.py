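"""Closed-form path-specific effects in the additive-hazard special case.

With a single mediator wave at time ``tau_1``, an additive hazard

    lambda(t | A, M1) = lambda_0(t) + lambda_1(t) A + lambda_2(t) M1 I(t > tau_1)

and a homoscedastic normal linear mediator model

    M1 | T > tau_1, A  ~  N(alpha_0 + alpha_1 A, sigma^2),

the nested g-formula integrates in closed form: with ``t = -dL2`` the normal
moment generating function ``E exp(tM) = exp(t mu + t^2 s^2 / 2)`` gives

    S_{1,0}(t) = exp[-L0(t) - L1(t) - dL2(t) a0 + dL2(t)^2 s^2 / 2]
    S_{0,0}(t) = exp[-L0(t)         - dL2(t) a0 + dL2(t)^2 s^2 / 2]
    S_{1,1}(t) = S_{1,0}(t) exp[-dL2(t) a1]

(the variance term is positive -- mediator heterogeneity can only *raise*
the averaged survival above its value at the mean mediator, by Jensen)

with ``dL2(t) = Lambda_2(t) - Lambda_2(tau_1)`` (zero for ``t <= tau_1``),
whence the survival-ratio effects

    PDE(t) = S_{1,0}/S_{0,0} = exp{-Lambda_1(t)}
    PIE(t) = S_{1,1}/S_{1,0} = exp{-dL2(t) alpha_1}     (1 for t <= tau_1).

This is dynamic path analysis made exact for events occurring before the
first mediator assessment: an implementation that ignores that possibility
uses ``Lambda_2(t)`` in place of ``dL2(t)`` and its indirect effect differs
by the factor ``exp{Lambda_2(tau_1) alpha_1}`` exactly.

The module is an evaluator: cumulative-hazard coefficient functions are
supplied (constant-rate or piecewise linear), not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CumulativeHazard:
    """Nonnegative cumulative hazard coefficient function with ``L(0) = 0``.

    Either a constant rate (``L(t) = rate * t``) or a continuous piecewise
    linear interpolation through supplied knots (flat beyond the last knot).
    """

    def __init__(self, knot_times, knot_values):
        kt = np.asarray(knot_times, dtype=float)
        kv = np.asarray(knot_values, dtype=float)
        if kt[0] != 0 or kv[0] != 0:
            kt = np.concatenate([[0.0], kt])
            kv = np.concatenate([[0.0], kv])
        if np.any(np.diff(kt) <= 0):
            raise ValueError("knot times must be strictly increasing")
        self.kt, self.kv = kt, kv

    @classmethod
    def from_rate(cls, rate: float, horizon: float = 1e6) -> "CumulativeHazard":
        return cls([0.0, horizon], [0.0, rate * horizon])

    @classmethod
    def zero(cls) -> "CumulativeHazard":
        return cls.from_rate(0.0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.kt, self.kv)


@dataclass
class DPAParams:
    """Parameters of the additive-hazard + normal-mediator model."""

    lambda0: CumulativeHazard
    lambda1: CumulativeHazard
    lambda2: CumulativeHazard
    alpha0: float
    alpha1: float
    sigma2: float
    tau1: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")

    def dL2(self, t):
        """``Lambda_2(t) - Lambda_2(tau_1)``, clipped to 0 before ``tau_1``."""
        return np.maximum(self.lambda2(t) - self.lambda2(self.tau1), 0.0)


def closed_form_survival(a: int, astar: int, t, params: DPAParams):
    """Evaluate ``S_{a,a*}(t)`` analytically.

    ``a`` drives the direct hazard term and ``astar`` the mediator mean; the
    (0,1) pair follows from the same expressions with ``alpha_0 + alpha_1``
    as mediator mean and the arm-0 hazard.  For ``t <= tau_1`` the result is
    ``exp(-Lambda_0(t) - a Lambda_1(t))`` whatever ``a*``.
    """
    if a not in (0, 1) or astar not in (0, 1):
        raise ValueError("arms must be 0 or 1")
    t = np.asarray(t, dtype=float)
    d2 = params.dL2(t)
    mean_m = params.alpha0 + params.alpha1 * astar
    logS = -(params.lambda0(t) + a * params.lambda1(t) + d2 * mean_m) \
        + 0.5 * d2**2 * params.sigma2
    return np.exp(logS)


def closed_form_effects(t, params: DPAParams):
    """Survival-ratio direct and indirect effects ``(PDE, PIE)``.

    ``PDE(t) = exp{-Lambda_1(t)}``; ``PIE(t) = exp{-dL2(t) alpha_1}``, equal
    to 1 for ``t <= tau_1`` (no mediator has been assessed yet).
    """
    t = np.asarray(t, dtype=float)
    pde = np.exp(-params.lambda1(t))
    pie = np.exp(-params.dL2(t) * params.alpha1)
    return pde, pie


def naive_indirect_effect(t, params: DPAParams):
    """Indirect effect of classical dynamic path analysis, which ignores
    events before the first mediator assessment: ``exp{-Lambda_2(t) alpha_1}``
    for ``t > tau_1``.  It differs from :func:`closed_form_effects`'s PIE by
    the factor ``exp{Lambda_2(tau_1) alpha_1}`` exactly."""
    t = np.asarray(t, dtype=float)
    return np.where(t > params.tau1, np.exp(-params.lambda2(t) * params.alpha1), 1.0)
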