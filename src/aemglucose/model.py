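"""Bergman minimal model of glucose-insulin dynamics in type 1 diabetes.

The intravenous Bergman minimal model describes three coupled states:
plasma glucose concentration ``x1`` (mg/dl), delayed (remote) insulin
action ``x2`` (1/min), and plasma insulin concentration ``x3`` (mU/l).
Exogenous insulin is infused through the input ``u`` (mU/l/min) and a
meal appears as a disturbance ``d`` (mg/dl/min) that decays with first
order kinetics.  Written about the basal equilibrium ``(Gb, 0, Ib)``
the model splits into a linear part, a single bilinear residual
``-x1d * x2d`` (glucose removal proportional to glucose times insulin
action), and the disturbance channel.

For controller and observer synthesis the meal state is appended to the
deviated state, giving the augmented four-state system

    xd = (x1d, x2d, x3d, d),   d/dt xd = A xd + B u + phi(xd)

with ``B = (0, 0, 1, 0)^T``, measured output ``y = x1d`` and
``phi(xd) = (-x1d*x2d, 0, 0, 0)^T``.  This matches the dimension of the
four-entry observer and feedback gains used throughout the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatientParams",
    "ParamRanges",
    "StateBox",
    "ModelMatrices",
    "UncertaintyBounds",
    "NOMINAL_PATIENT",
    "TABLE_RANGES",
    "DEFAULT_STATE_BOX",
    "build_matrices",
    "rhs",
    "phi",
    "to_deviated",
    "from_deviated",
    "lipschitz_constant",
    "delta_bound",
    "default_bounds",
]

_PARAM_NAMES = ("c1", "c2", "c3", "c4", "c5")


@dataclass(frozen=True)
class PatientParams:
    """Rate constants and basal values defining one virtual subject.

    c1 : insulin-independent glucose effectiveness, 1/min (0 in T1D)
    c2 : decay rate of remote insulin action, 1/min
    c3 : insulin action gain, L/(min*mU); c3/c2 is the insulin sensitivity
    c4 : plasma insulin degradation rate, 1/min
    c5 : meal disturbance decay rate, 1/min
    Gb : basal plasma glucose, mg/dl
    Ib : basal plasma insulin, mU/l
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    Gb: float = 80.0
    Ib: float = 7.0

    def __post_init__(self) -> None:
        if self.c1 < 0:
            raise ValueError(f"c1 must be >= 0, got {self.c1}")
        for name in ("c2", "c3", "c4", "c5"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not (self.Gb > 0 and self.Ib > 0):
            raise ValueError("basal values Gb, Ib must be positive")

    def replace(self, **kw) -> "PatientParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (*_PARAM_NAMES, "Gb", "Ib")}


#: Nominal T1D subject (c1 = 0: negligible glucose effectiveness).
NOMINAL_PATIENT = PatientParams(c1=0.0, c2=0.015, c3=2e-6, c4=0.2, c5=0.05)


@dataclass(frozen=True)
class ParamRanges:
    """Closed per-parameter intervals of plausible physiological variation.

    Intervals are ``(lo, hi)`` tuples in the same units as
    :class:`PatientParams`.  A degenerate interval (``lo == hi``) pins a
    parameter, as for c1 in T1D.
    """

    c1: tuple = (0.0, 0.0)
    c2: tuple = (0.0105, 0.0195)
    c3: tuple = (1.4e-6, 2.6e-6)
    c4: tuple = (0.14, 0.26)
    c5: tuple = (0.045, 0.055)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range for {name} has lo > hi: ({lo}, {hi})")

    def validate_nominal(self, params: PatientParams) -> None:
        """Raise if any nominal parameter lies outside its interval."""
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            v = getattr(params, name)
            if not (lo <= v <= hi):
                raise ValueError(f"nominal {name}={v} outside range [{lo}, {hi}]")

    def as_dict(self) -> dict:
        return {k: tuple(getattr(self, k)) for k in _PARAM_NAMES}


#: +/-30% physiological variability around the nominal subject.
TABLE_RANGES = ParamRanges()


@dataclass(frozen=True)
class StateBox:
    """Axis-aligned operating box for the augmented deviated state.

    Lower corners of the first three coordinates follow from
    non-negativity of the physical variables: glucose and insulin cannot
    fall below zero, so ``x1d >= -Gb`` and ``x3d >= -Ib``, and the remote
    insulin action stays non-negative.  Upper corners bound the
    physiologically plausible excursions (glucose up to 400 mg/dl,
    plasma insulin up to 100 mU/l, meal disturbance up to the largest
    protocol value).
    """

    x1d: tuple = (-80.0, 320.0)
    x2d: tuple = (0.0, 0.05)
    x3d: tuple = (-7.0, 93.0)
    d: tuple = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("x1d", "x2d", "x3d", "d"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"state box interval {name} must be bounded")
            if lo > hi:
                raise ValueError(f"state box interval {name} has lo > hi")

    @property
    def intervals(self) -> list:
        return [self.x1d, self.x2d, self.x3d, self.d]

    def farthest_corner_norm(self) -> float:
        """Euclidean norm of the box corner farthest from the origin."""
        return float(
            np.sqrt(sum(max(lo**2, hi**2) for lo, hi in self.intervals))
        )


DEFAULT_STATE_BOX = StateBox()


@dataclass(frozen=True)
class ModelMatrices:
    """Augmented deviated-state system ``xd' = A xd + B u + phi(xd)``."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    params: PatientParams = field(default=NOMINAL_PATIENT)

    @property
    def n(self) -> int:
        return self.A.shape[0]


def build_matrices(params: PatientParams) -> ModelMatrices:
    """Assemble the augmented 4-state matrices for a patient.

    The linear part of the deviated glucose equation carries ``-Gb`` on
    the insulin-action column (the bilinear residual ``-x1d*x2d`` is kept
    in ``phi`` so that ``phi(0) = 0``), and the meal state enters the
    glucose row with unit coefficient while decaying at rate ``c5``.
    """
    p = params
    A = np.array(
        [
            [-p.c1, -p.Gb, 0.0, 1.0],
            [0.0, -p.c2, p.c3, 0.0],
            [0.0, 0.0, -p.c4, 0.0],
            [0.0, 0.0, 0.0, -p.c5],
        ]
    )
    B = np.array([0.0, 0.0, 1.0, 0.0])
    C = np.array([1.0, 0.0, 0.0, 0.0])
    return ModelMatrices(A=A, B=B, C=C, params=params)


def phi(xd: np.ndarray) -> np.ndarray:
    """Bilinear residual of the deviated dynamics, ``(-x1d*x2d, 0, 0, 0)``."""
    out = np.zeros(4)
    out[0] = -xd[0] * xd[1]
    return out


def rhs(t: float, state: np.ndarray, u: float, params: PatientParams) -> np.ndarray:
    """Time derivative of the absolute-coordinate state ``(x1, x2, x3, d)``.

    ``u`` must be non-negative; clamping a raw control signal is the
    simulator's responsibility, so a negative value here is a contract
    violation rather than something to silently repair.
    """
    if u < 0:
        raise ValueError(f"insulin infusion rate must be >= 0, got {u}")
    x1, x2, x3, d = state
    p = params
    return np.array(
        [
            -p.c1 * (x1 - p.Gb) - x1 * x2 + d,
            -p.c2 * x2 + p.c3 * (x3 - p.Ib),
            -p.c4 * (x3 - p.Ib) + u,
            -p.c5 * d,
        ]
    )


def to_deviated(state: np.ndarray, params: PatientParams = NOMINAL_PATIENT) -> np.ndarray:
    """Absolute ``(x1, x2, x3, d)`` -> deviated ``(x1d, x2d, x3d, d)``."""
    s = np.asarray(state, dtype=float).copy()
    s[..., 0] -= params.Gb
    s[..., 2] -= params.Ib
    return s


def from_deviated(xd: np.ndarray, params: PatientParams = NOMINAL_PATIENT) -> np.ndarray:
    """Inverse of :func:`to_deviated`."""
    s = np.asarray(xd, dtype=float).copy()
    s[..., 0] += params.Gb
    s[..., 2] += params.Ib
    return s


def lipschitz_constant(box: StateBox, weights: np.ndarray | None = None) -> float:
    """Lipschitz constant of ``phi`` over the operating box.

    The Jacobian of ``phi`` is ``(-x2d, -x1d, 0, 0)`` in the first row,
    so its operator norm is ``sqrt(x1d**2 + x2d**2)``, maximised at a box
    corner.

    With ``weights`` ``w`` the constant refers to the diagonally scaled
    coordinates ``z = x / w`` used by the synthesis routines: the scaled
    nonlinearity is ``-w2 * z1 * z2`` in the glucose row, whose Jacobian
    norm over the scaled box is ``w2 * sqrt(z1**2 + z2**2)``.
    """
    if weights is None:
        weights = np.ones(4)
    w1, w2 = float(weights[0]), float(weights[1])
    best = 0.0
    for x1d in box.x1d:
        for x2d in box.x2d:
            best = max(best, w2 * float(np.hypot(x1d / w1, x2d / w2)))
    return best


def delta_bound(
    ranges: ParamRanges,
    params: PatientParams = NOMINAL_PATIENT,
    weights: np.ndarray | None = None,
) -> float:
    """Worst-case spectral norm of ``A(theta) - A(nominal)`` over range corners.

    The augmented ``A`` is affine in each rate constant, so the maximum
    over the parameter hyper-rectangle is attained at a corner; all
    ``2**k`` corner combinations of the non-degenerate intervals are
    enumerated.  ``weights`` evaluates the norm in the diagonally scaled
    coordinates ``z = x / w`` (``T (A - A0) T^{-1}`` with ``T = diag(1/w)``).
    """
    ranges.validate_nominal(params)
    A0 = build_matrices(params).A
    if weights is None:
        S = np.ones((4, 4))
    else:
        w = np.asarray(weights, dtype=float)
        S = w[None, :] / w[:, None]
    names = [n for n in _PARAM_NAMES if getattr(ranges, n)[0] != getattr(ranges, n)[1]]
    best = 0.0
    for corner in itertools.product(*(getattr(ranges, n) for n in names)):
        A = build_matrices(params.replace(**dict(zip(names, corner)))).A
        best = max(best, float(np.linalg.norm((A - A0) * S, 2)))
    return best


@dataclass(frozen=True)
class UncertaintyBounds:
    """Worst-case bounds feeding the robust synthesis.

    X_plus : bound on the deviated-state norm, mg/dl-dominated mixed units
    D_plus : bound on the disturbance magnitude, mg/dl/min
    delta  : bound on the spectral norm of the time-varying model error
    L_phi  : Lipschitz constant of the nonlinearity over ``state_box``
    """

    X_plus: float
    D_plus: float
    delta: float
    L_phi: float
    state_box: StateBox = field(default=DEFAULT_STATE_BOX)
    #: parameter ranges behind ``delta``; kept so that synthesis can
    #: re-evaluate the model-error norm in scaled coordinates
    ranges: "ParamRanges | None" = None

    def __post_init__(self) -> None:
        for name in ("X_plus", "D_plus", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.L_phi < 0:
            raise ValueError("L_phi must be >= 0")

    def replace(self, **kw) -> "UncertaintyBounds":
        return replace(self, **kw)


def default_bounds(
    params: PatientParams = NOMINAL_PATIENT,
    ranges: ParamRanges = TABLE_RANGES,
    box: StateBox = DEFAULT_STATE_BOX,
) -> UncertaintyBounds:
    """Bounds implied by the parameter table and the default operating box."""
    return UncertaintyBounds(
        X_plus=box.farthest_corner_norm(),
        D_plus=box.d[1],
        delta=delta_bound(ranges, params),
        L_phi=lipschitz_constant(box),
        state_box=box,
        ranges=ranges,
    )
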