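"""Domain types and table I/O for interval-censored competing-risk test data.

The central observational unit is a subject under periodic examination
(e.g., biopsies on an active-surveillance protocol).  The primary event
(progression) is interval-censored between the last negative examination
``t_neg`` and, when detected, the first positive examination ``t_pos``.
Early treatment is a competing event observed exactly at ``t_trt``;
right censoring occurs at ``t_cen``.  Exactly one of the three terminal
times is present, matching the event code ``delta`` (1 = progression
detected, 2 = early treatment, 0 = censored).

All times are decimal years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectOutcome",
    "Window",
    "LongitudinalRecord",
    "RiskTable",
    "read_outcomes",
    "write_outcomes",
    "read_longitudinal",
    "write_longitudinal",
    "read_risk_tables",
    "write_risk_tables",
]


class DataError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class Window:
    """Evaluation interval of interest [t, t + dt), in years."""

    t: float
    dt: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise DataError(f"window start must be >= 0, got {self.t}")
        if self.dt <= 0:
            raise DataError(f"window length must be > 0, got {self.dt}")

    @property
    def end(self) -> float:
        return self.t + self.dt


@dataclass(frozen=True)
class SubjectOutcome:
    """One test-set subject's observed event data.

    ``true_t_prg`` / ``true_t_trt`` are the latent event times, available
    only for simulated data (used by the no-censoring reference metrics);
    ``None`` means absent, ``inf`` means the latent event never occurs
    within the simulated horizon.
    """

    subject_id: str
    t_neg: float
    delta: int
    t_pos: float | None = None
    t_trt: float | None = None
    t_cen: float | None = None
    true_t_prg: float | None = None
    true_t_trt: float | None = None

    def __post_init__(self) -> None:
        if self.delta not in (0, 1, 2):
            raise DataError(f"delta must be in {{0,1,2}}, got {self.delta}")
        if not (self.t_neg >= 0):
            raise DataError(f"t_neg must be >= 0, got {self.t_neg}")
        expected = {1: "t_pos", 2: "t_trt", 0: "t_cen"}[self.delta]
        present = {
            "t_pos": self.t_pos,
            "t_trt": self.t_trt,
            "t_cen": self.t_cen,
        }
        for name, value in present.items():
            if name == expected and value is None:
                raise DataError(
                    f"subject {self.subject_id}: delta/time mismatch — "
                    f"delta={self.delta} requires {expected}"
                )
            if name != expected and value is not None:
                raise DataError(
                    f"subject {self.subject_id}: delta/time mismatch — "
                    f"delta={self.delta} forbids {name}"
                )
        if self.t_pos is not None and not (self.t_pos > self.t_neg):
            raise DataError(
                f"subject {self.subject_id}: t_pos must be > t_neg "
                f"({self.t_pos} <= {self.t_neg})"
            )
        if self.t_trt is not None and not (self.t_trt >= self.t_neg):
            raise DataError(
                f"subject {self.subject_id}: t_trt must be >= t_neg"
            )
        if self.t_cen is not None and not (self.t_cen >= self.t_neg):
            raise DataError(
                f"subject {self.subject_id}: t_cen must be >= t_neg"
            )
        if self.true_t_prg is not None and self.delta == 1:
            if not (self.t_neg < self.true_t_prg <= self.t_pos):
                raise DataError(
                    f"subject {self.subject_id}: true_t_prg must lie in "
                    f"(t_neg, t_pos] when delta=1"
                )

    @property
    def t2(self) -> float:
        """Observed follow-up end: whichever of t_pos / t_trt / t_cen occurred."""
        return {1: self.t_pos, 2: self.t_trt, 0: self.t_cen}[self.delta]


@dataclass(frozen=True)
class LongitudinalRecord:
    """One biomarker measurement (e.g., log-scale PSA) at a study time."""

    subject_id: str
    time: float
    value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"measurement time must be >= 0, got {self.time}")


_OUTCOME_COLS = [
    "subject_id", "t_neg", "t_pos", "t_trt", "t_cen", "delta",
    "true_t_prg", "true_t_trt",
]


def _cell(value: float | None) -> float | str:
    return "" if value is None else value


def write_outcomes(outcomes: Iterable[SubjectOutcome], path) -> None:
    rows = [
        {
            "subject_id": o.subject_id,
            "t_neg": o.t_neg,
            "t_pos": _cell(o.t_pos),
            "t_trt": _cell(o.t_trt),
            "t_cen": _cell(o.t_cen),
            "delta": o.delta,
            "true_t_prg": _cell(o.true_t_prg),
            "true_t_trt": _cell(o.true_t_trt),
        }
        for o in outcomes
    ]
    pd.DataFrame(rows, columns=_OUTCOME_COLS).to_csv(path, index=False, float_format="%.17g")


def read_outcomes(path) -> list[SubjectOutcome]:
    """Read a subject-outcome CSV; empty cells mean absent.

    Raises :class:`DataError` naming the offending row on any invariant
    violation or duplicated subject_id.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    required = {"subject_id", "t_neg", "delta"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"outcome file missing columns: {sorted(missing)}")
    outcomes: list[SubjectOutcome] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after header

        def opt(col: str) -> float | None:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        sid = str(row["subject_id"])
        if sid in seen:
            raise DataError(f"row {rownum}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            outcomes.append(
                SubjectOutcome(
                    subject_id=sid,
                    t_neg=float(row["t_neg"]),
                    delta=int(row["delta"]),
                    t_pos=opt("t_pos"),
                    t_trt=opt("t_trt"),
                    t_cen=opt("t_cen"),
                    true_t_prg=opt("true_t_prg"),
                    true_t_trt=opt("true_t_trt"),
                )
            )
        except DataError as err:
            raise DataError(f"row {rownum}: {err}") from err
    return outcomes


def write_longitudinal(records: Iterable[LongitudinalRecord], path) -> None:
    pd.DataFrame(
        [{"subject_id": r.subject_id, "time": r.time, "value": r.value} for r in records]
    ).to_csv(path, index=False, float_format="%.17g")


def read_longitudinal(path) -> list[LongitudinalRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return [
        LongitudinalRecord(str(r.subject_id), float(r.time), float(r.value))
        for r in df.itertuples(index=False)
    ]


@dataclass
class RiskTable:
    """A subject's tabulated risk predictions on a time grid.

    ``cif[i]`` is the predicted cause-specific cumulative incidence of the
    primary event by ``grid[i]`` conditional on being event-free at ``t0``;
    ``surv[i]`` the predicted overall survival.  Between grid points values
    are linearly interpolated (which preserves monotonicity); queries
    beyond the last grid point raise.
    """

    subject_id: str
    t0: float
    grid: np.ndarray
    cif: np.ndarray
    surv: np.ndarray
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.cif = np.asarray(self.cif, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if not (self.grid.shape == self.cif.shape == self.surv.shape):
            raise DataError(f"subject {self.subject_id}: ragged risk table")
        if self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise DataError(
                f"subject {self.subject_id}: grid must be strictly increasing "
                "with at least two points"
            )
        if not math.isclose(self.grid[0], self.t0, abs_tol=1e-12):
            raise DataError(
                f"subject {self.subject_id}: grid must start at t0={self.t0}"
            )
        if abs(self.cif[0]) > self._tol or abs(self.surv[0] - 1.0) > self._tol:
            raise DataError(
                f"subject {self.subject_id}: cif(t0) must be 0 and surv(t0) 1"
            )
        if np.any(np.diff(self.cif) < -self._tol):
            raise DataError(f"subject {self.subject_id}: cif must be non-decreasing")
        if np.any(np.diff(self.surv) > self._tol):
            raise DataError(f"subject {self.subject_id}: surv must be non-increasing")
        if np.any(self.cif < -self._tol) or np.any(self.cif > 1 + self._tol):
            raise DataError(f"subject {self.subject_id}: cif outside [0,1]")
        if np.any(self.surv < -self._tol) or np.any(self.surv > 1 + self._tol):
            raise DataError(f"subject {self.subject_id}: surv outside [0,1]")
        if np.any(self.cif > 1 - self.surv + 1e-6):
            raise DataError(
                f"subject {self.subject_id}: cif exceeds 1 - surv beyond tolerance"
            )

    def _interp(self, values: np.ndarray, s: float) -> float:
        if s < self.grid[0] - 1e-12 or s > self.grid[-1] + 1e-12:
            raise DataError(
                f"subject {self.subject_id}: query at s={s} outside tabulated "
                f"grid [{self.grid[0]}, {self.grid[-1]}]"
            )
        return float(np.interp(s, self.grid, values))

    def cif_at(self, s: float) -> float:
        return self._interp(self.cif, s)

    def surv_at(self, s: float) -> float:
        return self._interp(self.surv, s)


def write_risk_tables(tables: Mapping[str, RiskTable] | Sequence[RiskTable], path) -> None:
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    frames = []
    for tab in tables:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tab.subject_id,
                    "t0": tab.t0,
                    "s": tab.grid,
                    "cif": tab.cif,
                    "surv": tab.surv,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_risk_tables(path) -> dict[str, RiskTable]:
    """Read per-subject tabulated risk curves keyed by subject_id."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    out: dict[str, RiskTable] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        t0 = grp["t0"].to_numpy(dtype=float)
        if np.ptp(t0) > 1e-12:
            raise DataError(f"subject {sid}: inconsistent t0 across rows")
        out[str(sid)] = RiskTable(
            subject_id=str(sid),
            t0=float(t0[0]),
            grid=grp["s"].to_numpy(dtype=float),
            cif=grp["cif"].to_numpy(dtype=float),
            surv=grp["surv"].to_numpy(dtype=float),
        )
    return out
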