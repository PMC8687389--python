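"""Dense interior-point solver for small semidefinite programs.

Solves problems of the form

    minimize    c^T theta
    subject to  F_k(theta) = F_k0 + sum_i theta_i F_ki  >  0   for all k

with symmetric coefficient matrices, via a standard logarithmic-barrier
path-following method with exact Newton steps.  The linear matrix
inequalities arising in attractive-ellipsoid synthesis involve a few
dozen scalar unknowns and blocks of size at most eight, for which a
dense barrier method is accurate and fast; no external conic solver is
required.

Strict feasibility ("< 0" constraints) is the caller's responsibility:
shift the constant term by the desired margin before calling.  A large
box ``|theta_i| < bound_radius`` (handled analytically, not as matrix
blocks) keeps the analytic center finite when the feasible cone is
unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["AffineLMI", "SDPResult", "solve_sdp", "lmi_from_assembler"]


@dataclass
class AffineLMI:
    """Affine matrix-valued map ``theta -> F0 + sum_i theta_i Fs[i]``, constrained PD."""

    F0: np.ndarray
    Fs: list

    def __post_init__(self) -> None:
        self._stack = np.stack(self.Fs) if self.Fs else None

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        F = self.F0 + np.tensordot(theta, self._stack, axes=(0, 0))
        return 0.5 * (F + F.T)


def lmi_from_assembler(fn: Callable[[np.ndarray], np.ndarray], m: int) -> AffineLMI:
    """Build an :class:`AffineLMI` by probing an affine assembler on unit vectors.

    ``fn`` maps a length-``m`` parameter vector to a symmetric matrix and
    must be affine; non-affine assemblers are rejected by a spot check.
    """
    F0 = np.asarray(fn(np.zeros(m)), dtype=float)
    Fs = []
    for i in range(m):
        e = np.zeros(m)
        e[i] = 1.0
        Fs.append(np.asarray(fn(e), dtype=float) - F0)
    rng = np.random.default_rng(0)
    th = rng.standard_normal(m)
    rebuilt = F0 + sum(t * Fi for t, Fi in zip(th, Fs))
    if not np.allclose(rebuilt, fn(th), rtol=1e-9, atol=1e-9 * (1 + np.abs(F0).max())):
        raise ValueError("assembler is not affine in theta")
    return AffineLMI(F0=F0, Fs=Fs)


@dataclass
class SDPResult:
    status: str  # "optimal", "infeasible", "failed"
    theta: np.ndarray | None
    objective: float | None
    gap: float | None = None
    phase1_slack: float | None = None


def _chol_ok(F: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(F)
        return True
    except np.linalg.LinAlgError:
        return False


def _barrier_value(blocks, theta: np.ndarray, R: float) -> float:
    if np.any(np.abs(theta) >= R):
        return np.inf
    val = -float(np.sum(np.log(R - theta)) + np.sum(np.log(R + theta)))
    for blk in blocks:
        F = blk(theta)
        try:
            Lc = np.linalg.cholesky(F)
        except np.linalg.LinAlgError:
            return np.inf
        val -= 2.0 * np.sum(np.log(np.diag(Lc)))
    return val


def _newton_minimize(
    blocks,
    c: np.ndarray,
    t: float,
    theta: np.ndarray,
    R: float,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> np.ndarray:
    """Minimize ``t*c@theta + barrier(theta)`` from a strictly feasible point."""
    m = len(theta)
    for _ in range(max_iter):
        grad = t * c + 1.0 / (R - theta) - 1.0 / (R + theta)
        H = np.zeros((m, m))
        H[np.diag_indices_from(H)] = 1.0 / (R - theta) ** 2 + 1.0 / (R + theta) ** 2
        try:
            finvs = [np.linalg.inv(blk(theta)) for blk in blocks]
        except np.linalg.LinAlgError:
            break  # boundary reached to numerical precision; stop this stage
        for blk, Finv in zip(blocks, finvs):
            W = Finv @ blk._stack  # (m, n, n)
            grad -= np.trace(W, axis1=1, axis2=2)
            H += np.einsum("iab,jba->ij", W, W, optimize=True)
        H[np.diag_indices_from(H)] += 1e-12 * (1.0 + np.abs(np.diag(H)))
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(H, grad, rcond=None)[0]
        decrement = float(-grad @ step)
        if decrement < 0:
            step = -grad / (1.0 + np.linalg.norm(grad))
            decrement = float(-grad @ step)
        if decrement / 2.0 <= tol:
            break
        f0 = t * float(c @ theta) + _barrier_value(blocks, theta, R)
        alpha = 1.0
        for _ in range(50):
            cand = theta + alpha * step
            f1 = t * float(c @ cand) + _barrier_value(blocks, cand, R)
            if np.isfinite(f1) and f1 <= f0 - 1e-4 * alpha * decrement:
                theta = cand
                break
            alpha *= 0.5
        else:
            break
    return theta


def solve_sdp(
    blocks: Sequence[AffineLMI],
    c: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    gap_tol: float = 1e-7,
    feas_tol: float = 1e-9,
    t_init: float = 1.0,
    mu: float = 30.0,
    bound_radius: float = 1e9,
) -> SDPResult:
    """Solve ``min c@theta s.t. F_k(theta) > 0`` (all blocks).

    A phase-I problem (minimizing the uniform slack ``s`` with
    ``F_k + s I > 0``) finds a strictly feasible start or certifies that
    none exists: once the barrier duality gap drops below the positive
    slack, no feasible point can exist and the search stops early.
    ``c=None`` solves feasibility only.
    """
    blocks = list(blocks)
    m = len(blocks[0].Fs)
    R = bound_radius
    if theta0 is None:
        theta0 = np.zeros(m)

    # ---- phase I: min s  s.t.  F_k(theta) + s I > 0
    aug = []
    for blk in blocks:
        eye = np.eye(blk.F0.shape[0])
        aug.append(AffineLMI(F0=blk.F0, Fs=blk.Fs + [eye]))
    s0 = 0.0
    for blk in blocks:
        lam = np.linalg.eigvalsh(blk(theta0)).min()
        s0 = max(s0, -lam)
    scale0 = max(1.0, s0)
    th = np.concatenate([theta0, [s0 + scale0]])
    c1 = np.zeros(m + 1)
    c1[-1] = 1.0
    N = sum(blk.F0.shape[0] for blk in blocks) + 2 * (m + 1)
    t = t_init
    slack = th[-1]
    while True:
        th = _newton_minimize(aug, c1, t, th, R)
        slack = th[-1]
        gap = N / t
        if slack < -10 * feas_tol:
            break  # strictly feasible
        if slack - gap > 0:
            break  # certified infeasible: optimal slack >= slack - gap > 0
        if gap < feas_tol * scale0 + feas_tol:
            break
        t *= mu
        if t > 1e14:
            break
    if slack >= -10 * feas_tol:
        return SDPResult(
            status="infeasible", theta=None, objective=None, phase1_slack=float(slack)
        )
    theta = th[:m]
    if not all(_chol_ok(blk(theta)) for blk in blocks):
        return SDPResult(status="failed", theta=None, objective=None)

    if c is None:
        return SDPResult(
            status="optimal",
            theta=theta,
            objective=0.0,
            gap=0.0,
            phase1_slack=float(slack),
        )

    # ---- phase II: barrier path following on the true objective
    c = np.asarray(c, dtype=float)
    N2 = sum(blk.F0.shape[0] for blk in blocks) + 2 * m
    t = t_init
    while True:
        theta = _newton_minimize(blocks, c, t, theta, R)
        gap = N2 / t
        if gap <= gap_tol * (1.0 + abs(float(c @ theta))):
            break
        t *= mu
        if t > 1e16:
            break
    return SDPResult(
        status="optimal",
        theta=theta,
        objective=float(c @ theta),
        gap=float(N2 / t),
        phase1_slack=float(slack),
    )
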