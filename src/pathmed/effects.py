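"""Effect contrasts and nonparametric bootstrap inference.

Given the three estimated curves ``S_{1,1}``, ``S_{1,0}`` and ``S_{0,0}``:

* the *indirect* (mediated) effect contrasts ``S_{1,1}`` with ``S_{1,0}``;
* the *direct* (non-mediated) effect contrasts ``S_{1,0}`` with ``S_{0,0}``;
* the *mediated proportion* is ``(S11 - S10) / (S11 - S00)``, reported only
  where the total effect ``|S11 - S00|`` is large enough to divide by.

Contrasts are available as survival ratios, survival differences, or failure
(risk) ratios.  Inference resamples whole patients with replacement -- each
patient's entire trajectory is the exchangeable unit -- reruns the full
sequential estimator per resample, and reports percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import LongitudinalMediationDataset
from .gcomp import EstimatorConfig, PathSpecificSurvival, estimate_S

SCALES = ("ratio", "difference", "failure_ratio")


def _contrast(num: np.ndarray, den: np.ndarray, scale: str) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == "ratio":
            return num / den
        if scale == "difference":
            return num - den
        if scale == "failure_ratio":
            return (1 - num) / (1 - den)
    raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")


@dataclass
class EffectCurves:
    """Point estimates (and optional percentile intervals) of the path-specific
    effects over the time grid.

    ``pie`` is the mediated (indirect) contrast, ``pde`` the non-mediated
    (direct) contrast, ``mp`` the mediated proportion (NaN where the total
    effect is below ``mp_threshold``).  ``lower``/``upper`` map curve name ->
    arrays when a bootstrap was run; ``n_failed`` counts resamples on which
    the estimator failed (skipped)."""

    times: np.ndarray
    scale: str
    pie: np.ndarray
    pde: np.ndarray
    mp: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    lower: dict[str, np.ndarray] = field(default_factory=dict)
    upper: dict[str, np.ndarray] = field(default_factory=dict)
    n_boot: int = 0
    n_failed: int = 0
    mp_threshold: float = 1e-3

    def to_frame(self):
        import pandas as pd

        rows = []
        for name in ("pie", "pde", "mp"):
            est = getattr(self, name)
            for i, t in enumerate(self.times):
                rows.append({
                    "t": t, "curve": name, "estimate": est[i],
                    "lo": self.lower.get(name, np.full_like(est, np.nan))[i],
                    "hi": self.upper.get(name, np.full_like(est, np.nan))[i],
                })
        return pd.DataFrame(rows)


def path_specific_contrasts(
    S11: PathSpecificSurvival,
    S10: PathSpecificSurvival,
    S00: PathSpecificSurvival,
    scale: str = "ratio",
    mp_threshold: float = 1e-3,
) -> EffectCurves:
    """Build the effect curves from three survival curves on a shared grid.

    At ``t = 0`` ratio contrasts are 1 and difference contrasts 0 by
    construction.  The mediated proportion is computed on the survival
    difference scale regardless of ``scale`` and flagged NaN wherever
    ``|S11 - S00| <= mp_threshold`` (no total effect to apportion).
    """
    if not (np.array_equal(S11.times, S10.times) and np.array_equal(S10.times, S00.times)):
        raise ValueError("survival curves must share a time grid")
    s11, s10, s00 = S11.estimates, S10.estimates, S00.estimates
    pie = _contrast(s11, s10, scale)
    pde = _contrast(s10, s00, scale)
    total = s11 - s00
    with np.errstate(divide="ignore", invalid="ignore"):
        mp = np.where(np.abs(total) > mp_threshold, (s11 - s10) / total, np.nan)
    return EffectCurves(
        times=np.asarray(S11.times, float), scale=scale, pie=pie, pde=pde, mp=mp,
        curves={"s11": s11, "s10": s10, "s00": s00}, mp_threshold=mp_threshold,
    )


def estimate_effects(
    ds: LongitudinalMediationDataset,
    t_grid,
    cfg: EstimatorConfig | None = None,
    scale: str = "ratio",
    mp_threshold: float = 1e-3,
) -> EffectCurves:
    """Convenience wrapper: estimate the three curves and contrast them."""
    s11 = estimate_S(ds, 1, 1, t_grid, cfg)
    s10 = estimate_S(ds, 1, 0, t_grid, cfg)
    s00 = estimate_S(ds, 0, 0, t_grid, cfg)
    return path_specific_contrasts(s11, s10, s00, scale, mp_threshold)


def bootstrap_cis(
    ds: LongitudinalMediationDataset,
    t_grid,
    B: int,
    seed: int,
    cfg: EstimatorConfig | None = None,
    scale: str = "ratio",
    level: float = 0.95,
    stratify_by_arm: bool = False,
    mp_threshold: float = 1e-3,
) -> EffectCurves:
    """Percentile bootstrap intervals for the effect curves.

    Patients are resampled with replacement (optionally within arm) and the
    full three-curve estimator is rerun per resample.  A resample on which
    any step fails is recorded and skipped; more than 10%% failures triggers
    a warning.  Results are reproducible given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    point = estimate_effects(ds, t_grid, cfg, scale, mp_threshold)
    names = ("pie", "pde", "mp", "s11", "s10", "s00")
    draws: dict[str, list[np.ndarray]] = {nm: [] for nm in names}
    n_failed = 0
    arms = [np.flatnonzero(ds.arm == 0), np.flatnonzero(ds.arm == 1)]
    for _ in range(B):
        if stratify_by_arm:
            idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in arms])
        else:
            idx = rng.integers(0, ds.n, size=ds.n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eff = estimate_effects(ds.subset(idx), t_grid, cfg, scale, mp_threshold)
        except Exception:
            n_failed += 1
            continue
        for nm in ("pie", "pde", "mp"):
            draws[nm].append(getattr(eff, nm))
        for nm in ("s11", "s10", "s00"):
            draws[nm].append(eff.curves[nm])
    if n_failed > 0.1 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap resamples failed and were skipped")
    alpha = (1 - level) / 2
    for nm in names:
        if not draws[nm]:
            continue
        mat = np.vstack(draws[nm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN grid points (flagged MP)
            point.lower[nm] = np.nanpercentile(mat, 100 * alpha, axis=0)
            point.upper[nm] = np.nanpercentile(mat, 100 * (1 - alpha), axis=0)
    point.n_boot = B - n_failed
    point.n_failed = n_failed
    return point
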