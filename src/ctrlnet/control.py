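"""Finite-horizon optimal control of linear dynamics on a connectome.

Solves, for strictly stable ``A`` and input matrix ``B`` (identity by
default, i.e. every region is an independent controller),

    min  integral_0^T  x(t)'x(t) + rho * u(t)'u(t)  dt
    s.t. dx/dt = A x + B u,   x(0) = x0,   x(T) = xT

via the Hamiltonian first-order conditions. The stationarity condition
``u* = -B'p / (2 rho)`` reduces the problem to a linear two-point boundary
value problem on the augmented state ``z = (x, p)`` with

    dz/dt = M z,   M = [[A, -BB'/(2 rho)], [-2 I, -A']]

solved by a matrix exponential and one dense solve for the initial
costate ``p(0)``. Per-node control energy is the time integral of the
squared control input (composite trapezoid on the solver grid).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .connectome import SystemMatrix

log = logging.getLogger(__name__)

__all__ = [
    "TransitionSpec",
    "TransitionResult",
    "StabilityResult",
    "ImpactResult",
    "ControlSolveError",
    "optimal_control",
    "state_stability",
    "control_impact",
    "top_impact_nodes",
]


class ControlSolveError(RuntimeError):
    """Boundary-value solve failed or missed the target state."""


@dataclass(frozen=True)
class TransitionSpec:
    """Source/target states plus solver parameters for one transition.

    ``control_set`` selects which nodes carry a control input (columns of
    ``B``); ``None`` means all nodes (``B = I``). ``nsteps`` is the number
    of uniform grid points used for trajectory propagation and quadrature.
    """

    x0: np.ndarray
    xT: np.ndarray
    horizon: float = 1.0
    rho: float = 1.0
    control_set: tuple[int, ...] | None = None
    nsteps: int = 1001
    boundary_tol: float = 1e-4

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0, dtype=float).ravel()
        xT = np.asarray(self.xT, dtype=float).ravel()
        if x0.shape != xT.shape:
            raise ValueError("x0 and xT must have the same length")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.nsteps < 2:
            raise ValueError("nsteps must be at least 2")
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "xT", xT)
        if self.control_set is not None:
            cs = tuple(int(i) for i in self.control_set)
            if len(cs) == 0 or len(set(cs)) != len(cs):
                raise ValueError("control_set must be non-empty and unique")
            object.__setattr__(self, "control_set", cs)


@dataclass(frozen=True)
class TransitionResult:
    """Optimal trajectories and energies for one state transition."""

    times: np.ndarray            # (nsteps,)
    u_traj: np.ndarray           # (m, nsteps) optimal control u*(t)
    x_traj: np.ndarray           # (n, nsteps) state trajectory
    costate_traj: np.ndarray     # (n, nsteps) costate p(t)
    nodal_energy: np.ndarray     # (m,) integral of u_k(t)^2
    total_energy: float
    log_energy: float
    cost: float                  # integral of x'x + rho u'u
    boundary_error: float
    condition_number: float
    control_set: tuple[int, ...]


@dataclass(frozen=True)
class StabilityResult:
    """Inverse log-energy of maintaining a state against its own dynamics.

    ``valid`` is False when the maintenance energy is <= 1, where the
    inverse-log definition diverges or flips sign; such values are flagged
    rather than propagated into cohort statistics.
    """

    maintain_energy: float
    stability: float
    valid: bool


@dataclass(frozen=True)
class ImpactResult:
    """Per-node change in total transition energy upon node removal.

    ``impact[i] = E(network without node i) - E(full network)``: positive
    values mean the node's presence lowers the energetic demand of the
    transition. Unsolvable reduced problems yield NaN with a log entry.
    """

    impact: np.ndarray
    baseline_energy: float


def _input_matrix(n: int, control_set: tuple[int, ...] | None) -> tuple[np.ndarray, tuple[int, ...]]:
    if control_set is None:
        return np.eye(n), tuple(range(n))
    idx = control_set
    if any(i < 0 or i >= n for i in idx):
        raise ValueError("control_set index out of range")
    return np.eye(n)[:, list(idx)], idx


def optimal_control(system: SystemMatrix, spec: TransitionSpec) -> TransitionResult:
    """Solve the two-point boundary problem and integrate energies.

    Raises
    ------
    ControlSolveError
        If the boundary solve is singular/non-finite or the propagated
        endpoint misses ``xT`` by more than ``spec.boundary_tol``
        (relative to ``max(||xT||, 1)``).
    """
    A = system.A
    n = system.n
    if spec.x0.size != n:
        raise ValueError(f"state length {spec.x0.size} != system size {n}")
    B, control_idx = _input_matrix(n, spec.control_set)
    rho, T, nsteps = spec.rho, spec.horizon, spec.nsteps

    M = np.block([
        [A, -B @ B.T / (2.0 * rho)],
        [-2.0 * np.eye(n), -A.T],
    ])
    ET = expm(M * T)
    E11, E12 = ET[:n, :n], ET[:n, n:]
    cond = float(np.linalg.cond(E12))
    if not np.isfinite(cond) or cond > 1e12:
        raise ControlSolveError(
            f"ill-conditioned boundary solve (cond(E12) = {cond:.3e})"
        )
    rhs = spec.xT - E11 @ spec.x0
    try:
        p0 = np.linalg.solve(E12, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by cond
        raise ControlSolveError(f"singular boundary solve: {exc}") from exc

    dt = T / (nsteps - 1)
    Phi = expm(M * dt)
    z = np.empty((2 * n, nsteps))
    z[:, 0] = np.concatenate([spec.x0, p0])
    for k in range(1, nsteps):
        z[:, k] = Phi @ z[:, k - 1]
    x_traj = z[:n]
    p_traj = z[n:]
    u_traj = -(B.T @ p_traj) / (2.0 * rho)

    times = np.linspace(0.0, T, nsteps)
    nodal_energy = np.trapezoid(u_traj**2, dx=dt, axis=1)
    total_energy = float(nodal_energy.sum())
    cost = float(np.trapezoid(
        (x_traj**2).sum(axis=0) + rho * (u_traj**2).sum(axis=0), dx=dt
    ))
    boundary_error = float(
        np.linalg.norm(x_traj[:, -1] - spec.xT)
        / max(np.linalg.norm(spec.xT), 1.0)
    )
    if boundary_error > spec.boundary_tol:
        raise ControlSolveError(
            f"endpoint missed target: relative boundary error "
            f"{boundary_error:.3e} > {spec.boundary_tol:g} "
            f"(cond(E12) = {cond:.3e}, horizon = {T:g}, n = {n})"
        )
    with np.errstate(divide="ignore"):
        log_energy = float(np.log10(total_energy)) if total_energy > 0 else -math.inf
    return TransitionResult(
        times=times,
        u_traj=u_traj,
        x_traj=x_traj,
        costate_traj=p_traj,
        nodal_energy=nodal_energy,
        total_energy=total_energy,
        log_energy=log_energy,
        cost=cost,
        boundary_error=boundary_error,
        condition_number=cond,
        control_set=control_idx,
    )


def state_stability(
    system: SystemMatrix,
    x: np.ndarray,
    horizon: float = 1.0,
    rho: float = 1.0,
    nsteps: int = 1001,
) -> StabilityResult:
    """Maintenance energy of the ``x -> x`` transition and its inverse log.

    Stability is ``1 / log10(E_maintain)``; when ``E_maintain <= 1`` the
    quantity diverges or changes sign, so the result is flagged invalid
    (``stability = nan``) instead.
    """
    spec = TransitionSpec(x0=x, xT=x, horizon=horizon, rho=rho, nsteps=nsteps)
    res = optimal_control(system, spec)
    E = res.total_energy
    if E > 1.0:
        return StabilityResult(maintain_energy=E, stability=1.0 / math.log10(E), valid=True)
    log.info("maintenance energy %.3g <= 1; stability flagged invalid", E)
    return StabilityResult(maintain_energy=E, stability=math.nan, valid=False)


def _remove_node(spec: TransitionSpec, i: int, n: int) -> TransitionSpec:
    keep = [j for j in range(n) if j != i]
    if spec.control_set is None:
        cs = None
    else:
        cs = tuple(j - (j > i) for j in spec.control_set if j != i)
        if not cs:
            raise ValueError(f"removing node {i} empties the control set")
    return TransitionSpec(
        x0=spec.x0[keep],
        xT=spec.xT[keep],
        horizon=spec.horizon,
        rho=spec.rho,
        control_set=cs,
        nsteps=spec.nsteps,
        boundary_tol=spec.boundary_tol,
    )


def control_impact(system: SystemMatrix, spec: TransitionSpec) -> ImpactResult:
    """Leave-one-node-out change in total transition energy.

    Each node is removed from the state, the dynamics matrix, and the
    control channels (with ``B = I`` a removed region can neither be
    steered nor steer), the transition is re-solved, and the signed
    energy difference to the full-network baseline recorded.
    """
    n = system.n
    if n < 3:
        raise ValueError("control impact needs at least 3 nodes")
    baseline = optimal_control(system, spec)
    impact = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        A_sub = system.A[np.ix_(keep, keep)]
        bound = float(np.linalg.eigvals(A_sub).real.max())
        try:
            sub_system = SystemMatrix(
                A=A_sub, spectral_bound=bound, normalization=system.normalization
            )
            res = optimal_control(system=sub_system, spec=_remove_node(spec, i, n))
            impact[i] = res.total_energy - baseline.total_energy
        except (ControlSolveError, ValueError) as exc:
            log.warning("impact of node %d not solvable: %s", i, exc)
            impact[i] = np.nan
    return ImpactResult(impact=impact, baseline_energy=baseline.total_energy)


def top_impact_nodes(result: ImpactResult, fraction: float) -> np.ndarray:
    """Indices of the ``ceil(fraction * n)`` nodes with largest |impact|.

    Sorted by impact magnitude descending; ties broken by node index
    ascending. ``fraction`` must lie in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    mag = np.abs(result.impact)
    n = mag.size
    order = sorted(range(n), key=lambda i: (-mag[i], i))
    k = math.ceil(fraction * n)
    return np.array(order[:k], dtype=int)
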