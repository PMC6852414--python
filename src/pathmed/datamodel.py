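"""Longitudinal trial data model for mediation analysis of time-to-event endpoints.

A trial records, per patient: a randomised arm ``A`` in {0, 1}, baseline
covariates ``L0``, and at each scheduled visit ``k`` (times ``tau_1 < ... <
tau_K``) a vector of time-varying confounders ``V_k`` and a vector of mediator
measurements ``M_k`` -- but only while the patient is still event free and
under observation.  Follow-up ends at time ``T`` with event indicator ``E``
(``E = 0`` means censoring, administrative or loss to follow-up).

Conventions (fixed throughout the package):

* visits live at absolute times; "event free at visit k" means ``T > tau_k``
  strictly, so an event or censoring exactly at ``tau_k`` does *not* survive
  visit ``k``;
* the at-risk indicator ``I(T > tau_k)`` is always derived from ``T``, never
  stored;
* patients are kept in a deterministic order (sorted by id) so that every
  downstream fit is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when a longitudinal dataset violates its structural invariants."""


# ---------------------------------------------------------------------------
# Visit schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitSchedule:
    """Common visit times ``tau_1 < ... < tau_K`` (months), shared by all patients."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) == 0:
            raise ValueError("schedule needs at least one visit")
        if times[0] <= 0:
            raise ValueError("first visit time must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def K(self) -> int:
        return len(self.times)

    def tau(self, k: int) -> float:
        """Absolute time of visit ``k`` (1-based); ``tau(0) == 0`` (baseline)."""
        if k == 0:
            return 0.0
        if not 1 <= k <= self.K:
            raise IndexError(f"visit {k} outside 1..{self.K}")
        return self.times[k - 1]

    def floor_visit(self, t: float) -> int:
        """Largest ``k`` with ``tau_k <= t`` (0 if ``t < tau_1``)."""
        return int(np.searchsorted(np.asarray(self.times), t, side="right"))


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalMediationDataset:
    """Wide, visit-indexed container for a two-arm trial with repeated mediators.

    ``V[k-1]`` and ``M[k-1]`` hold the visit-``k`` confounder / mediator
    matrices with one row per patient; rows of patients not at risk at
    ``tau_k`` are NaN.  ``V`` entries may be ``None`` when a visit has no
    measured confounders.
    """

    ids: np.ndarray              # (n,) patient identifiers, sorted
    arm: np.ndarray              # (n,) int in {0, 1}
    L0: np.ndarray               # (n, p0)
    V: list[np.ndarray | None]   # per visit: (n, pv_k) or None
    M: list[np.ndarray]          # per visit: (n, pm_k)
    T: np.ndarray                # (n,) follow-up time > 0
    E: np.ndarray                # (n,) int in {0, 1}
    schedule: VisitSchedule
    l0_names: list[str] = field(default_factory=list)
    v_names: list[list[str]] = field(default_factory=list)
    m_names: list[list[str]] = field(default_factory=list)
    end_of_study: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        order = np.argsort(self.ids, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            # deterministic patient ordering by id
            self.ids = self.ids[order]
            self.arm = np.asarray(self.arm)[order]
            self.L0 = np.atleast_2d(np.asarray(self.L0, dtype=float))[order]
            self.V = [None if v is None else np.asarray(v, float)[order] for v in self.V]
            self.M = [np.asarray(m, float)[order] for m in self.M]
            self.T = np.asarray(self.T, float)[order]
            self.E = np.asarray(self.E, int)[order]
        self.arm = np.asarray(self.arm, dtype=int)
        self.L0 = np.asarray(self.L0, dtype=float)
        if self.L0.ndim == 1:
            self.L0 = self.L0[:, None]
        self.V = [None if v is None else _as_matrix(v) for v in self.V]
        self.M = [_as_matrix(m) for m in self.M]
        self.T = np.asarray(self.T, dtype=float)
        self.E = np.asarray(self.E, dtype=int)
        if not self.l0_names:
            self.l0_names = [f"l0_{j}" for j in range(self.L0.shape[1])]
        if not self.v_names:
            self.v_names = [
                [] if v is None else [f"v{k+1}_{j}" for j in range(v.shape[1])]
                for k, v in enumerate(self.V)
            ]
        if not self.m_names:
            self.m_names = [
                [f"m{k+1}_{j}" for j in range(m.shape[1])] for k, m in enumerate(self.M)
            ]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return self.schedule.K

    def validate(self, strict: bool = True) -> None:
        """Check structural invariants; raise :class:`DataValidationError`.

        With ``strict=False``, values recorded after the end of follow-up are
        tolerated (they are never used: risk sets are derived from ``T``), and
        at-risk patients with missing visit values are reported via a warning
        instead of an error.
        """
        if self.n == 0:
            raise DataValidationError("no patients")
        if not np.all(np.isin(self.arm, [0, 1])):
            raise DataValidationError("non-binary arm")
        if np.any(self.T <= 0):
            raise DataValidationError("follow-up times must be positive")
        if not np.all(np.isin(self.E, [0, 1])):
            raise DataValidationError("event indicator must be 0/1")
        for k in range(1, self.K + 1):
            at_risk = self.T > self.schedule.tau(k)
            for block, label in ((self.V[k - 1], "confounder"), (self.M[k - 1], "mediator")):
                if block is None or block.shape[1] == 0:
                    continue
                has_value = ~np.isnan(block).any(axis=1)
                bad_extra = has_value & ~at_risk
                bad_missing = at_risk & ~has_value
                if bad_extra.any() and strict:
                    raise DataValidationError(
                        f"{label} value recorded at visit {k} for patients not at "
                        f"risk (ids {list(self.ids[bad_extra][:5])})"
                    )
                if bad_missing.any():
                    msg = (
                        f"at-risk patients missing {label} at visit {k}: "
                        f"ids {list(self.ids[bad_missing][:5])}"
                    )
                    if strict:
                        raise DataValidationError(msg)
                    warnings.warn(msg)

    def at_risk(self, k: int) -> np.ndarray:
        """Boolean mask of patients event free and under observation past ``tau_k``."""
        if k == 0:
            return np.ones(self.n, dtype=bool)
        return self.T > self.schedule.tau(k)

    def subset(self, index: np.ndarray) -> "LongitudinalMediationDataset":
        """New dataset holding rows ``index`` (positions); ids are relabelled
        ``0..len-1`` so that bootstrap resamples with repeats stay valid."""
        index = np.asarray(index)
        return LongitudinalMediationDataset(
            ids=np.arange(len(index)),
            arm=self.arm[index],
            L0=self.L0[index],
            V=[None if v is None else v[index] for v in self.V],
            M=[m[index] for m in self.M],
            T=self.T[index],
            E=self.E[index],
            schedule=self.schedule,
            l0_names=list(self.l0_names),
            v_names=[list(v) for v in self.v_names],
            m_names=[list(m) for m in self.m_names],
            end_of_study=self.end_of_study,
        )


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


# ---------------------------------------------------------------------------
# Risk sets and history designs
# ---------------------------------------------------------------------------


def risk_set(ds: LongitudinalMediationDataset, k: int, arm: int | str = "both") -> np.ndarray:
    """Positional indices of patients event free and uncensored past visit ``k``.

    ``arm`` selects one trial arm (0 or 1) or ``"both"``.  ``k = 0`` with
    ``arm="both"`` returns every patient.  Risk sets are nested: the set at
    ``k+1`` is a subset of the set at ``k``.
    """
    if not 0 <= k <= ds.K:
        raise ValueError(f"visit {k} outside 0..{ds.K}")
    mask = ds.at_risk(k)
    if arm != "both":
        mask = mask & (ds.arm == int(arm))
    return np.flatnonzero(mask)


@dataclass
class HistoryDesign:
    """Covariate matrix ``(L0, V_1..V_j, M_1..M_m)`` on a patient subset.

    Column order is deterministic (baseline, then confounders by visit, then
    mediators by visit) and identical across fit and predict calls.
    """

    k: int
    patients: np.ndarray   # positional indices into the dataset
    X: np.ndarray          # (len(patients), p)
    names: list[str]


def build_history(
    ds: LongitudinalMediationDataset,
    patients: np.ndarray,
    confounder_depth: int,
    mediator_depth: int,
) -> HistoryDesign:
    """Assemble ``(L0, V_1..V_j, M_1..M_m)`` for the given patients.

    ``confounder_depth = j`` and ``mediator_depth = m`` give the number of
    visits whose confounders / mediators enter; baseline ``L0`` is always
    included.  Raises if any requested value is missing for some patient.
    """
    if confounder_depth > ds.K or mediator_depth > ds.K:
        raise ValueError("requested history depth exceeds the visit schedule")
    patients = np.asarray(patients)
    cols: list[np.ndarray] = [ds.L0[patients]]
    names: list[str] = list(ds.l0_names)
    for k in range(1, confounder_depth + 1):
        v = ds.V[k - 1]
        if v is not None and v.shape[1] > 0:
            cols.append(v[patients])
            names.extend(ds.v_names[k - 1])
    for k in range(1, mediator_depth + 1):
        cols.append(ds.M[k - 1][patients])
        names.extend(ds.m_names[k - 1])
    X = np.hstack(cols) if cols else np.empty((len(patients), 0))
    if np.isnan(X).any():
        bad = patients[np.isnan(X).any(axis=1)]
        raise DataValidationError(
            f"incomplete history to depths (j={confounder_depth}, m={mediator_depth}) "
            f"for patient ids {list(ds.ids[bad][:5])}"
        )
    return HistoryDesign(k=max(confounder_depth, mediator_depth), patients=patients, X=X, names=names)


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------
#
# On disk the trial is a long CSV: one baseline row per patient (visit 0,
# carrying arm, baseline covariates, follow-up time and event indicator) plus
# one row per attended visit carrying that visit's confounders and mediators.
# A schema mapping declares which columns play which role.

DEFAULT_SCHEMA = {
    "id": "patient",
    "arm": "arm",
    "visit": "visit",
    "time": "time",
    "event": "event",
}


def _schema_lists(ds: LongitudinalMediationDataset) -> dict:
    return {
        **DEFAULT_SCHEMA,
        "baseline": list(ds.l0_names),
        "confounders": sorted({n for vs in ds.v_names for n in vs}),
        "mediators": sorted({n for ms in ds.m_names for n in ms}),
        "visit_times": list(ds.schedule.times),
    }


def write_longitudinal_table(
    ds: LongitudinalMediationDataset, path, header_comment: str | None = None
) -> dict:
    """Write the long-format CSV; returns the schema mapping describing it.

    ``header_comment``, if given, is written as ``# ...`` comment line(s)
    ahead of the data; :func:`read_longitudinal_table` skips such lines.
    """
    schema = _schema_lists(ds)
    rows = []
    for i in range(ds.n):
        base = {
            schema["id"]: ds.ids[i],
            schema["visit"]: 0,
            schema["arm"]: ds.arm[i],
            schema["time"]: ds.T[i],
            schema["event"]: ds.E[i],
        }
        for j, name in enumerate(ds.l0_names):
            base[name] = ds.L0[i, j]
        rows.append(base)
        for k in range(1, ds.K + 1):
            if not ds.at_risk(k)[i]:
                continue
            row = {schema["id"]: ds.ids[i], schema["visit"]: k}
            v = ds.V[k - 1]
            if v is not None:
                for j, name in enumerate(ds.v_names[k - 1]):
                    row[name] = v[i, j]
            for j, name in enumerate(ds.m_names[k - 1]):
                row[name] = ds.M[k - 1][i, j]
            rows.append(row)
    # %.17g round-trips float64 exactly
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.rstrip("\n").split("\n"):
                fh.write(line if line.startswith("#") else f"# {line}")
                fh.write("\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")
    return schema


def read_longitudinal_table(
    path, schema: dict, strict: bool = True
) -> LongitudinalMediationDataset:
    """Read a long-format CSV into a validated dataset.

    ``schema`` must declare the id / arm / visit / time / event columns, the
    ``baseline``, ``confounders`` and ``mediators`` variable lists, and the
    ``visit_times``.  A visit-level value recorded after the end of follow-up
    is a validation error in strict mode (spec of the at-risk invariant);
    ``strict=False`` drops such rows with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip", comment="#")
    for key in ("id", "arm", "visit", "time", "event"):
        if schema[key] not in df.columns:
            raise DataValidationError(f"missing mandatory column '{schema[key]}'")
    sched = VisitSchedule(tuple(schema["visit_times"]))
    base = df[df[schema["visit"]] == 0].sort_values(schema["id"])
    if len(base) == 0:
        raise DataValidationError("no patients")
    ids = base[schema["id"]].to_numpy()
    if base[schema["id"]].duplicated().any():
        raise DataValidationError("duplicated baseline rows")
    arm = base[schema["arm"]].to_numpy()
    if not np.all(np.isin(arm, [0, 1])):
        raise DataValidationError("non-binary arm")
    T = base[schema["time"]].to_numpy(float)
    E = base[schema["event"]].to_numpy(int)
    n = len(ids)
    pos = {pid: i for i, pid in enumerate(ids)}
    L0 = base[schema["baseline"]].to_numpy(float)

    conf_names, med_names = list(schema["confounders"]), list(schema["mediators"])
    V: list[np.ndarray | None] = []
    M: list[np.ndarray] = []
    v_names: list[list[str]] = []
    m_names: list[list[str]] = []
    for k in range(1, sched.K + 1):
        rows = df[df[schema["visit"]] == k]
        vk_names = [c for c in conf_names if c in rows.columns and rows[c].notna().any()]
        mk_names = [c for c in med_names if c in rows.columns and rows[c].notna().any()]
        vk = np.full((n, len(vk_names)), np.nan)
        mk = np.full((n, len(mk_names)), np.nan)
        for _, r in rows.iterrows():
            i = pos.get(r[schema["id"]])
            if i is None:
                raise DataValidationError(f"visit row for unknown patient {r[schema['id']]}")
            if T[i] <= sched.tau(k):
                msg = (
                    f"visit-{k} values recorded for patient {ids[i]} whose "
                    f"follow-up ended at T={T[i]:g} <= tau_{k}={sched.tau(k):g}"
                )
                if strict:
                    raise DataValidationError(msg)
                warnings.warn(msg + " -- row dropped")
                continue
            for j, c in enumerate(vk_names):
                vk[i, j] = r[c]
            for j, c in enumerate(mk_names):
                mk[i, j] = r[c]
        V.append(vk if vk_names else None)
        M.append(mk)
        v_names.append(vk_names)
        m_names.append(mk_names)

    ds = LongitudinalMediationDataset(
        ids=ids, arm=arm, L0=L0, V=V, M=M, T=T, E=E, schedule=sched,
        l0_names=list(schema["baseline"]), v_names=v_names, m_names=m_names,
    )
    ds.validate(strict=strict)
    return ds
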