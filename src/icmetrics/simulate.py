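"""Joint longitudinal-survival simulator for interval-censored competing-risk
cohorts under active-surveillance-style examination schedules.

The data-generating process mirrors a prostate-cancer active-surveillance
cohort: each subject has a smooth latent biomarker trajectory (log2(PSA+1)
with subject-level random effects on a natural cubic spline of time and
heavy-tailed measurement error), and two cause-specific hazards —
progression and early treatment — that depend on the current trajectory
value, its one-year change, and a baseline covariate (PSA density) on top
of a spline log-baseline hazard.  Progression is only detected at scheduled
examinations (biopsies), so its time is interval-censored between the last
negative and first positive examination; treatment is observed exactly and
precludes further detection; independent exponential dropout plus an
administrative cutoff produce right censoring.

Latent event times are drawn by inverse-transform sampling of each
cause-specific cumulative hazard on a dense grid; the oracle risk
functions integrate the subject's true hazards, so the simulator doubles
as the correctly-specified predictor of the evaluation studies.  Two
deliberately misspecified predictors (linear trajectory; dropped baseline
covariate) are derived from the same latent state.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import BSpline

from .data import DataError, LongitudinalRecord, SubjectOutcome
from .risk import HazardSpec, RiskFunction, risk_from_hazards

__all__ = [
    "SimulationParams",
    "BiopsySchedule",
    "SubjectState",
    "Cohort",
    "simulate_cohort",
    "oracle_risk",
    "misspecified_risk",
    "params_to_yaml",
    "params_from_yaml",
]

_GRID_STEP = 0.005  # years; latent-time grid resolution


# ---------------------------------------------------------------------------
# Spline bases
# ---------------------------------------------------------------------------


def natural_cubic_basis(t: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form, no intercept).

    With K knots the basis has K - 1 columns: the identity and the K - 2
    natural-spline terms; it is linear beyond the boundary knots, so
    evaluation at negative times (needed for one-year-lag terms) is safe.
    Columns are normalized to unit maximum magnitude on [0, 1.4 * last
    knot] so that coefficients are on a common, interpretable scale.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    xi = np.asarray(knots, dtype=float)
    K = xi.size

    def raw(tt: np.ndarray) -> list[np.ndarray]:
        def d(k: int) -> np.ndarray:
            num = np.maximum(tt - xi[k], 0.0) ** 3 - np.maximum(tt - xi[K - 1], 0.0) ** 3
            return num / (xi[K - 1] - xi[k])

        return [tt] + [d(k) - d(K - 2) for k in range(K - 2)]

    return np.stack(raw(t), axis=-1) / _ns_scales(tuple(xi))


@lru_cache(maxsize=32)
def _ns_scales(knots: tuple[float, ...]) -> np.ndarray:
    xi = np.asarray(knots, dtype=float)
    K = xi.size
    ref = np.linspace(0.0, 1.4 * xi[-1], 200)

    def d(k: int) -> np.ndarray:
        num = np.maximum(ref - xi[k], 0.0) ** 3 - np.maximum(ref - xi[K - 1], 0.0) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [ref] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.array([np.max(np.abs(col)) or 1.0 for col in cols])


def _bspline_design(knots: Sequence[float], degree: int = 3):
    """Full clamped knot vector and coefficient count for a B-spline basis."""
    xi = np.asarray(knots, dtype=float)
    tv = np.concatenate([[xi[0]] * degree, xi, [xi[-1]] * degree])
    ncoef = len(tv) - degree - 1
    return tv, ncoef


def bspline_basis(t: np.ndarray, knots: Sequence[float], degree: int = 3) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tv, ncoef = _bspline_design(knots, degree)
    tc = np.clip(t, tv[0], tv[-1] - 1e-12)
    return BSpline.design_matrix(tc, tv, degree).toarray()


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _default_omega() -> np.ndarray:
    return np.array(
        [
            [0.50, 0.02, 0.02, 0.02],
            [0.02, 0.08, 0.01, 0.01],
            [0.02, 0.01, 0.08, 0.01],
            [0.02, 0.01, 0.01, 0.08],
        ]
    )


def _default_h0(intercept: float, ramp: float, ncoef: int) -> np.ndarray:
    # linear ramp in coefficient space ~ gently increasing log-baseline
    return intercept + ramp * np.linspace(0.0, 1.0, ncoef)


@dataclass
class SimulationParams:
    """Data-generating configuration.

    Units: times in years, biomarker on the log2(PSA + 1) scale.  The
    default values are the package's calibrated configuration: under the
    PASS examination schedule with 12-year administrative censoring and
    exponential dropout they yield roughly 22% of subjects observed with
    progression and 9% starting early treatment.
    """

    beta: np.ndarray = field(
        default_factory=lambda: np.array([2.36, 0.45, 0.35, -0.30, 0.012])
    )
    omega: np.ndarray = field(default_factory=_default_omega)
    error_df: float = 3.0
    error_scale: float = 0.18
    traj_knots: tuple[float, ...] = (1.5, 4.0, 7.0, 10.5)
    base_knots: tuple[float, ...] = tuple(np.linspace(0.0, 15.0, 11))
    h0_coef_prg: np.ndarray = field(
        default_factory=lambda: _default_h0(-5.62, 0.60, 13)
    )
    h0_coef_trt: np.ndarray = field(
        default_factory=lambda: _default_h0(-5.52, 0.30, 13)
    )
    gamma_prg: float = 3.5
    gamma_trt: float = 2.5
    alpha1_prg: float = 0.60
    alpha2_prg: float = 0.80
    alpha1_trt: float = 0.25
    alpha2_trt: float = 0.40
    admin_censor: float = 12.0
    dropout_rate: float = 0.04
    visit_spacing: float = 0.5
    age_mean: float = 62.0
    age_sd: float = 6.5
    psad_meanlog: float = -2.3
    psad_sdlog: float = 0.6

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.h0_coef_prg = np.asarray(self.h0_coef_prg, dtype=float)
        self.h0_coef_trt = np.asarray(self.h0_coef_trt, dtype=float)
        if not np.allclose(self.omega, self.omega.T):
            raise DataError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(self.omega) <= 0):
            raise DataError("omega must be positive definite")
        if self.error_df <= 0:
            raise DataError("error_df must be > 0")
        if self.admin_censor <= 0:
            raise DataError("admin_censor must be > 0")
        _, ncoef = _bspline_design(self.base_knots)
        for name, coef in (("h0_coef_prg", self.h0_coef_prg), ("h0_coef_trt", self.h0_coef_trt)):
            if coef.size != ncoef:
                raise DataError(
                    f"{name} must have {ncoef} coefficients for the given base_knots"
                )


@dataclass(frozen=True)
class BiopsySchedule:
    """Examination schedule: ``pass`` (exams at years 1, 2, then biennially)
    or ``uniform`` (random gaps drawn Uniform(lo, hi) years)."""

    kind: Literal["pass", "uniform"] = "pass"
    bounds: tuple[float, float] = (1.0, 2.0)
    max_follow: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("pass", "uniform"):
            raise DataError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "uniform":
            lo, hi = self.bounds
            if not (0 < lo <= hi):
                raise DataError("uniform schedule needs 0 < lo <= hi")

    def exam_times(self, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "pass":
            times = [1.0, 2.0]
            nxt = 4.0
            while nxt <= self.max_follow + 1e-9:
                times.append(nxt)
                nxt += 2.0
            return np.array([u for u in times if u <= self.max_follow + 1e-9])
        lo, hi = self.bounds
        n = int(np.ceil(self.max_follow / lo)) + 2
        times = np.cumsum(rng.uniform(lo, hi, size=n))
        return times[times <= self.max_follow]


@dataclass
class SubjectState:
    """A simulated subject's latent state: baseline covariates, random
    effects, and the latent event/censoring times (inf = never)."""

    subject_id: str
    age: float
    psad: float
    u: np.ndarray
    t_prg_latent: float
    t_trt_latent: float
    t_cen_latent: float


@dataclass
class Cohort:
    outcomes: list[SubjectOutcome]
    longitudinal: pd.DataFrame
    states: list[SubjectState]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.states],
                "true_t_prg": [s.t_prg_latent for s in self.states],
                "true_t_trt": [s.t_trt_latent for s in self.states],
                "t_cen_latent": [s.t_cen_latent for s in self.states],
            }
        )


# ---------------------------------------------------------------------------
# Trajectory and hazards
# ---------------------------------------------------------------------------


def trajectory(params: SimulationParams, state: SubjectState) -> Callable[[np.ndarray], np.ndarray]:
    """The subject's expected biomarker trajectory m(t)."""
    b0 = params.beta[0] + state.u[0] + params.beta[4] * (state.age - params.age_mean)
    slopes = params.beta[1:4] + state.u[1:4]

    def m(t: np.ndarray) -> np.ndarray:
        return b0 + natural_cubic_basis(t, params.traj_knots) @ slopes

    return m


def _hazards_from_trajectory(
    params: SimulationParams,
    m: Callable[[np.ndarray], np.ndarray],
    psad: float,
    gamma_scale: tuple[float, float] = (1.0, 1.0),
    gammas: tuple[float, float] | None = None,
) -> HazardSpec:
    g_prg, g_trt = gammas if gammas is not None else (params.gamma_prg, params.gamma_trt)
    tv, _ = _bspline_design(params.base_knots)

    def make(coef: np.ndarray, gamma: float, a1: float, a2: float, scale: float):
        def h(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(np.asarray(t, dtype=float))
            base = bspline_basis(t, params.base_knots) @ coef
            mt = m(t)
            dm = mt - m(t - 1.0)
            return scale * np.exp(base + gamma * psad + a1 * mt + a2 * dm)

        return h

    return HazardSpec(
        h_prg=make(params.h0_coef_prg, g_prg, params.alpha1_prg, params.alpha2_prg, gamma_scale[0]),
        h_trt=make(params.h0_coef_trt, g_trt, params.alpha1_trt, params.alpha2_trt, gamma_scale[1]),
    )


def subject_hazards(params: SimulationParams, state: SubjectState) -> HazardSpec:
    """The subject's true cause-specific hazards."""
    return _hazards_from_trajectory(params, trajectory(params, state), state.psad)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_latent_time(
    grid: np.ndarray, cumhaz: np.ndarray, rng: np.random.Generator
) -> float:
    """Inverse-transform sample: solve cumhaz(T) = -log(U) by inverse
    linear interpolation on the dense grid (the exact inverse of the
    piecewise-linear cumulative hazard used throughout the simulator)."""
    target = -np.log(rng.uniform())
    if target > cumhaz[-1]:
        return np.inf
    return float(np.interp(target, cumhaz, grid))


def simulate_cohort(
    params: SimulationParams,
    n: int,
    schedule: BiopsySchedule | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate ``n`` subjects under the given examination schedule.

    Reproducible under ``seed``; each subject uses an independent
    substream keyed by (seed, subject index), so cohorts are stable
    under subsetting.
    """
    if n < 1:
        raise DataError("need n >= 1 subjects")
    schedule = schedule or BiopsySchedule()
    horizon = max(params.admin_censor, schedule.max_follow)
    grid = np.arange(0.0, horizon + _GRID_STEP, _GRID_STEP)
    grid_lag = grid - 1.0
    traj_basis = natural_cubic_basis(grid, params.traj_knots)
    traj_basis_lag = natural_cubic_basis(grid_lag, params.traj_knots)
    base_prg = bspline_basis(grid, params.base_knots) @ params.h0_coef_prg
    base_trt = bspline_basis(grid, params.base_knots) @ params.h0_coef_trt
    chol = np.linalg.cholesky(params.omega)

    outcomes: list[SubjectOutcome] = []
    states: list[SubjectState] = []
    long_rows: list[LongitudinalRecord] = []

    for i in range(n):
        rng = np.random.default_rng([seed, i])
        sid = f"s{i:05d}"
        age = rng.normal(params.age_mean, params.age_sd)
        psad = float(np.exp(rng.normal(params.psad_meanlog, params.psad_sdlog)))
        u = chol @ rng.standard_normal(4)

        b0 = params.beta[0] + u[0] + params.beta[4] * (age - params.age_mean)
        slopes = params.beta[1:4] + u[1:4]
        m_grid = b0 + traj_basis @ slopes
        dm_grid = m_grid - (b0 + traj_basis_lag @ slopes)

        h_prg = np.exp(base_prg + params.gamma_prg * psad
                       + params.alpha1_prg * m_grid + params.alpha2_prg * dm_grid)
        h_trt = np.exp(base_trt + params.gamma_trt * psad
                       + params.alpha1_trt * m_grid + params.alpha2_trt * dm_grid)
        cum_prg = cumulative_trapezoid(h_prg, grid, initial=0.0)
        cum_trt = cumulative_trapezoid(h_trt, grid, initial=0.0)

        t_prg = _draw_latent_time(grid, cum_prg, rng)
        t_trt = _draw_latent_time(grid, cum_trt, rng)
        dropout = (
            rng.exponential(1.0 / params.dropout_rate)
            if params.dropout_rate > 0
            else np.inf
        )
        t_cen = min(dropout, params.admin_censor)

        exams = schedule.exam_times(rng)
        cand = exams[(exams >= t_prg)]
        t_pos_cand = float(cand[0]) if cand.size else np.inf

        if t_trt < min(t_cen, t_pos_cand):
            delta, terminal = 2, t_trt
        elif t_pos_cand < t_cen:
            delta, terminal = 1, t_pos_cand
        else:
            delta, terminal = 0, t_cen

        first_event = min(t_prg, t_trt, t_cen)
        before = exams[exams < first_event]
        t_neg = float(before[-1]) if before.size else 0.0

        outcomes.append(
            SubjectOutcome(
                subject_id=sid,
                t_neg=t_neg,
                delta=delta,
                t_pos=terminal if delta == 1 else None,
                t_trt=terminal if delta == 2 else None,
                t_cen=terminal if delta == 0 else None,
                true_t_prg=t_prg,
                true_t_trt=t_trt,
            )
        )
        states.append(
            SubjectState(
                subject_id=sid, age=float(age), psad=psad, u=u,
                t_prg_latent=t_prg, t_trt_latent=t_trt, t_cen_latent=t_cen,
            )
        )

        visit = np.arange(0.0, terminal + 1e-9, params.visit_spacing)
        noise = params.error_scale * rng.standard_t(params.error_df, size=visit.size)
        b_visit = b0 + natural_cubic_basis(visit, params.traj_knots) @ slopes
        for tt, vv in zip(visit, b_visit + noise):
            long_rows.append(LongitudinalRecord(sid, float(tt), float(vv)))

    longitudinal = pd.DataFrame(
        [{"subject_id": r.subject_id, "time": r.time, "value": r.value} for r in long_rows]
    )
    return Cohort(outcomes=outcomes, longitudinal=longitudinal, states=states)


# ---------------------------------------------------------------------------
# Oracle and misspecified risk functions
# ---------------------------------------------------------------------------


def oracle_risk(params: SimulationParams, state: SubjectState) -> RiskFunction:
    """The correctly specified predictor: risk curves integrated from the
    subject's true cause-specific hazards."""
    horizon = params.admin_censor + 4.0
    return risk_from_hazards(subject_hazards(params, state), horizon=horizon)


def _mean_exp_gamma_psad(params: SimulationParams, gamma: float) -> float:
    # population mean of exp(gamma * PSAD), fixed-seed Monte Carlo
    rng = np.random.default_rng(202_401)
    draws = np.exp(rng.normal(params.psad_meanlog, params.psad_sdlog, size=20_000))
    return float(np.mean(np.exp(gamma * draws)))


def misspecified_risk(
    params: SimulationParams,
    state: SubjectState,
    mode: Literal["linear_trajectory", "drop_baseline_covariate"],
) -> RiskFunction:
    """Deliberately misspecified predictors for the same subject.

    ``linear_trajectory`` replaces the spline trajectory with its
    least-squares linear fit over [0, admin_censor]; the one-year change
    becomes the constant slope.  ``drop_baseline_covariate`` removes the
    baseline covariate from both hazards and rescales each baseline by
    the population mean of exp(gamma * PSAD), preserving marginal
    incidence while losing between-subject discrimination.
    """
    horizon = params.admin_censor + 4.0
    m = trajectory(params, state)
    if mode == "linear_trajectory":
        tt = np.linspace(0.0, params.admin_censor, 121)
        slope, intercept = np.polyfit(tt, m(tt), 1)

        def m_lin(t: np.ndarray) -> np.ndarray:
            return intercept + slope * np.asarray(t, dtype=float)

        spec = _hazards_from_trajectory(params, m_lin, state.psad)
    elif mode == "drop_baseline_covariate":
        scale = (
            _mean_exp_gamma_psad(params, params.gamma_prg),
            _mean_exp_gamma_psad(params, params.gamma_trt),
        )
        spec = _hazards_from_trajectory(
            params, m, state.psad, gamma_scale=scale, gammas=(0.0, 0.0)
        )
    else:
        raise DataError(f"unknown misspecification mode {mode!r}")
    return risk_from_hazards(spec, horizon=horizon)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def params_to_yaml(params: SimulationParams, path=None) -> str:
    payload = {
        "beta": [float(v) for v in params.beta],
        "omega": [[float(v) for v in row] for row in params.omega],
        "error_df": params.error_df,
        "error_scale": params.error_scale,
        "traj_knots": [float(v) for v in params.traj_knots],
        "base_knots": [float(v) for v in params.base_knots],
        "h0_coef_prg": [float(v) for v in params.h0_coef_prg],
        "h0_coef_trt": [float(v) for v in params.h0_coef_trt],
        "gamma_prg": params.gamma_prg,
        "gamma_trt": params.gamma_trt,
        "alpha1_prg": params.alpha1_prg,
        "alpha2_prg": params.alpha2_prg,
        "alpha1_trt": params.alpha1_trt,
        "alpha2_trt": params.alpha2_trt,
        "admin_censor": params.admin_censor,
        "dropout_rate": params.dropout_rate,
        "visit_spacing": params.visit_spacing,
        "age_mean": params.age_mean,
        "age_sd": params.age_sd,
        "psad_meanlog": params.psad_meanlog,
        "psad_sdlog": params.psad_sdlog,
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_yaml(source) -> SimulationParams:
    if isinstance(source, (str, io.TextIOBase)) and "\n" in str(source):
        payload = yaml.safe_load(source)
    else:
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    payload["traj_knots"] = tuple(payload["traj_knots"])
    payload["base_knots"] = tuple(payload["base_knots"])
    return SimulationParams(**payload)
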