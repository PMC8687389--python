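"""Closed-loop simulation of the observer-based glucose controller.

The loop couples three pieces:

* the true plant — Bergman dynamics in deviated coordinates with
  time-varying (sinusoidally modulated) rate constants and a meal
  disturbance state that is reset impulsively at meal times and decays
  with first-order kinetics in between;
* a Luenberger-type observer running the nominal model plus the
  bilinear term evaluated at the estimate, corrected by output
  injection on the measured glucose deviation; and
* the output-feedback law ``u = max(0, K @ xhat)`` — insulin can only
  be infused, never withdrawn, so the raw feedback is clamped at zero.

Integration is segment-wise between meal events with a stiff-capable
adaptive method and dense output sampled on a regular reporting grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    NOMINAL_PATIENT,
    ModelMatrices,
    PatientParams,
    build_matrices,
    from_deviated,
    phi,
)

__all__ = [
    "MealEvent",
    "ParamModulation",
    "SimConfig",
    "Trajectory",
    "modulated_params",
    "control_law",
    "observer_rhs",
    "run_closed_loop",
    "run_scenario_1",
    "run_scenario_2",
    "scenario_2_meals",
    "MEAL_WINDOWS",
]

#: Daily meal windows (min within the day) and the admissible initial
#: disturbance magnitude range, mg/dl/min.
MEAL_WINDOWS = {
    "breakfast": (420.0, 540.0),
    "lunch": (660.0, 780.0),
    "dinner": (1140.0, 1260.0),
}
MEAL_MAGNITUDE = (5.0, 10.0)

MODULATED = ("c2", "c3", "c4", "c5")


@dataclass(frozen=True)
class MealEvent:
    """Impulsive meal: at ``time`` the disturbance state jumps to ``magnitude``."""

    time: float  # min
    magnitude: float  # mg/dl/min

    def __post_init__(self) -> None:
        if self.time < 0 or self.magnitude < 0:
            raise ValueError("meal time and magnitude must be non-negative")


@dataclass(frozen=True)
class ParamModulation:
    """Sinusoidal intra-patient variation of the rate constants.

    ``ci(t) = ci * (1 + amplitude * sin(2*pi*t/period + phase_i))`` for
    the parameters named in ``which``.  ``amplitude`` is a fraction of
    the patient's base value; per-parameter phases decorrelate the
    physiological rhythms (and make the insulin sensitivity ``c3/c2``
    genuinely time-varying).  ``amplitudes`` overrides the common
    fraction per parameter, which the cohort driver uses to keep every
    modulated value inside its population range.
    """

    amplitude: float = 0.30
    period: float = 1440.0  # circadian
    phases: dict = field(default_factory=dict)
    which: tuple = MODULATED
    amplitudes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("amplitude fraction must be in [0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @staticmethod
    def none() -> "ParamModulation":
        return ParamModulation(amplitude=0.0)


def modulated_params(t: float, base: PatientParams, mod: ParamModulation) -> PatientParams:
    """Instantaneous parameter set at time ``t`` under sinusoidal modulation."""
    if mod.amplitude == 0.0 and not mod.amplitudes:
        return base
    w = 2.0 * math.pi / mod.period
    kw = {}
    for name in mod.which:
        a = mod.amplitudes.get(name, mod.amplitude * getattr(base, name))
        ph = mod.phases.get(name, 0.0)
        kw[name] = getattr(base, name) + a * math.sin(w * t + ph)
    return base.replace(**kw)


def control_law(xhat_d: np.ndarray, K: np.ndarray, clamp: bool = True) -> float:
    """Output-feedback insulin rate ``u = K @ xhat``, clamped at zero."""
    u = float(np.dot(K, xhat_d))
    if clamp and u < 0.0:
        return 0.0
    return u


def observer_rhs(
    t: float,
    xhat_d: np.ndarray,
    u: float,
    y_dev: float,
    mats: ModelMatrices,
    L: np.ndarray,
) -> np.ndarray:
    """Observer derivative: nominal model + output injection on ``y - xhat1``."""
    return mats.A @ xhat_d + mats.B * u + phi(xhat_d) + L * (y_dev - xhat_d[0])


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one closed-loop run.

    The plant initial state is given in absolute coordinates
    ``(x1, x2, x3)``; the observer starts from the measured glucose
    deviation with zero estimates for the unmeasured coordinates.
    """

    K: np.ndarray
    L: np.ndarray
    t_end: float = 800.0
    dt_out: float = 1.0
    x0_abs: tuple = (200.0, 0.001, 7.0)
    d0: float = 0.0
    clamp: bool = True
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt_out <= 0:
            raise ValueError("t_end and dt_out must be positive")


@dataclass
class Trajectory:
    """Time-gridded result of a closed-loop run (absolute coordinates)."""

    t: np.ndarray
    x: np.ndarray  # (n, 3) plasma glucose, remote action, plasma insulin
    d: np.ndarray
    xhat: np.ndarray  # (n, 3) observer estimates, absolute coordinates
    dhat: np.ndarray
    u: np.ndarray
    params_t: pd.DataFrame  # instantaneous c2..c5
    meals: list = field(default_factory=list)
    saturation_count: int = 0

    @property
    def glucose(self) -> np.ndarray:
        return self.x[:, 0]

    def deviated(self, params: PatientParams = NOMINAL_PATIENT) -> np.ndarray:
        out = np.column_stack([self.x, self.d]).copy()
        out[:, 0] -= params.Gb
        out[:, 2] -= params.Ib
        return out

    def deviated_estimates(self, params: PatientParams = NOMINAL_PATIENT) -> np.ndarray:
        out = np.column_stack([self.xhat, self.dhat]).copy()
        out[:, 0] -= params.Gb
        out[:, 2] -= params.Ib
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "x1": self.x[:, 0],
                "x2": self.x[:, 1],
                "x3": self.x[:, 2],
                "d": self.d,
                "xhat1": self.xhat[:, 0],
                "xhat2": self.xhat[:, 1],
                "xhat3": self.xhat[:, 2],
                "dhat": self.dhat,
                "u": self.u,
            }
        )
        return pd.concat([df, self.params_t.reset_index(drop=True)], axis=1)


def run_closed_loop(
    cfg: SimConfig,
    params: PatientParams = NOMINAL_PATIENT,
    mod: ParamModulation | None = None,
    meals: list | None = None,
) -> Trajectory:
    """Integrate plant + observer jointly over ``[0, t_end]``.

    Meals are impulsive resets of the disturbance state, handled by
    splitting the integration at each event time; between events the
    joint 8-state system is integrated with dense output and sampled on
    the reporting grid.  The observer always runs the *nominal* model
    matrices; the plant uses the instantaneous (modulated) parameters.
    """
    mod = mod or ParamModulation.none()
    meals = sorted(meals or [], key=lambda m: m.time)
    if any(m.time > cfg.t_end for m in meals):
        raise ValueError("meal scheduled after t_end")
    nominal_mats = build_matrices(params)
    K = np.asarray(cfg.K, dtype=float)
    L = np.asarray(cfg.L, dtype=float)
    Gb, Ib = params.Gb, params.Ib

    def rhs(t, z):
        xd, xh = z[:4], z[4:]
        p = modulated_params(t, params, mod)
        u = control_law(xh, K, cfg.clamp)
        dxd = np.array(
            [
                -p.c1 * xd[0] - (xd[0] + Gb) * xd[1] + xd[3],
                -p.c2 * xd[1] + p.c3 * xd[2],
                -p.c4 * xd[2] + u,
                -p.c5 * xd[3],
            ]
        )
        dxh = observer_rhs(t, xh, u, xd[0], nominal_mats, L)
        return np.concatenate([dxd, dxh])

    x1, x2, x3 = cfg.x0_abs
    xd0 = np.array([x1 - Gb, x2, x3 - Ib, cfg.d0])
    xh0 = np.array([x1 - Gb, 0.0, 0.0, 0.0])  # observer: measured glucose, zero rest
    z = np.concatenate([xd0, xh0])

    t_grid = np.arange(0.0, cfg.t_end + 0.5 * cfg.dt_out, cfg.dt_out)
    t_grid = t_grid[t_grid <= cfg.t_end]
    Z = np.empty((len(t_grid), 8))
    filled = np.zeros(len(t_grid), dtype=bool)

    events = [m for m in meals if m.time > 0.0]
    d0_extra = sum(m.magnitude for m in meals if m.time == 0.0)
    z[3] += d0_extra
    breakpoints = [m.time for m in events] + [cfg.t_end]
    mags = [m.magnitude for m in events] + [None]
    t_prev = 0.0
    for t_next, mag in zip(breakpoints, mags):
        if t_next > t_prev:
            sol = solve_ivp(
                rhs,
                (t_prev, t_next),
                z,
                method=cfg.method,
                rtol=cfg.rtol,
                atol=cfg.atol,
                dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed at t in [{t_prev}, {t_next}]: {sol.message}; "
                    f"state {z}"
                )
            sel = (t_grid >= t_prev - 1e-9) & (t_grid <= t_next + 1e-9) & ~filled
            if sel.any():
                Z[sel] = sol.sol(t_grid[sel]).T
                filled[sel] = True
            z = sol.y[:, -1].copy()
        if mag is not None:
            z[3] = mag  # impulsive reset of the meal state
        t_prev = t_next

    xd, xh = Z[:, :4], Z[:, 4:]
    u = np.array([control_law(row, K, cfg.clamp) for row in xh])
    raw = xh @ K
    sat = int(np.sum(raw < 0)) if cfg.clamp else 0
    ptab = pd.DataFrame(
        [
            {n: getattr(modulated_params(t, params, mod), n) for n in MODULATED}
            for t in t_grid
        ]
    )
    return Trajectory(
        t=t_grid,
        x=np.column_stack([xd[:, 0] + Gb, xd[:, 1], xd[:, 2] + Ib]),
        d=xd[:, 3],
        xhat=np.column_stack([xh[:, 0] + Gb, xh[:, 1], xh[:, 2] + Ib]),
        dhat=xh[:, 3],
        u=u,
        params_t=ptab,
        meals=meals,
        saturation_count=sat,
    )


def run_scenario_1(
    params: PatientParams = NOMINAL_PATIENT,
    K: np.ndarray | None = None,
    L: np.ndarray | None = None,
    t_end: float = 800.0,
    mod: ParamModulation | None = None,
    **cfg_kw,
) -> Trajectory:
    """Single-meal hyperglycemic recovery scenario.

    Starts from the post-prandial hyperglycemic state
    ``(x1, x2, x3) = (200, 0.001, 7)`` with an initial meal disturbance
    of 8 mg/dl/min and runs 800 min, enough to cover settling at basal
    glucose with margin.
    """
    from .design import REFERENCE_K, REFERENCE_L

    cfg = SimConfig(
        K=REFERENCE_K if K is None else K,
        L=REFERENCE_L if L is None else L,
        t_end=t_end,
        x0_abs=(200.0, 0.001, 7.0),
        d0=8.0,
        **cfg_kw,
    )
    return run_closed_loop(cfg, params=params, mod=mod)


def scenario_2_meals(rng: np.random.Generator, days: int = 3) -> list:
    """Sample the uncertain 3-meals-per-day protocol.

    Per day, one meal per window with timing uniform over the window
    and magnitude uniform over the protocol range; windows repeat with
    a 1440-min offset on subsequent days.
    """
    meals = []
    for day in range(days):
        for lo, hi in MEAL_WINDOWS.values():
            t = rng.uniform(lo + 1440.0 * day, hi + 1440.0 * day)
            mag = rng.uniform(*MEAL_MAGNITUDE)
            meals.append(MealEvent(time=float(t), magnitude=float(mag)))
    return sorted(meals, key=lambda m: m.time)


def run_scenario_2(
    params: PatientParams = NOMINAL_PATIENT,
    K: np.ndarray | None = None,
    L: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    mod: ParamModulation | None = None,
    days: int = 3,
    **cfg_kw,
) -> Trajectory:
    """Three-day free-living scenario: random meals + sinusoidal variability.

    Starts at the basal equilibrium (the scenario probes meal response
    under intra-patient variability, not recovery from an extreme
    initial state).  With the default ``mod=None`` the modulation
    amplitude is 30% with phases drawn once from ``seed``'s stream.
    """
    from .design import REFERENCE_K, REFERENCE_L

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mod is None:
        phases = {n: float(rng.uniform(0.0, 2.0 * math.pi)) for n in MODULATED}
        mod = ParamModulation(amplitude=0.30, phases=phases)
    meals = scenario_2_meals(rng, days=days)
    cfg = SimConfig(
        K=REFERENCE_K if K is None else K,
        L=REFERENCE_L if L is None else L,
        t_end=1440.0 * days,
        x0_abs=(params.Gb, 0.0, params.Ib),
        d0=0.0,
        **cfg_kw,
    )
    return run_closed_loop(cfg, params=params, mod=mod, meals=meals)
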