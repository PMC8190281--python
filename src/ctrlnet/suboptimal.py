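"""Discrete-time suboptimal-trajectory perturbation analysis.

The continuous system is discretized with a zero-order hold at a sampling
time set to one tenth of the rise time of its fastest mode. Gaussian
perturbations are added to the (resampled) optimal control inputs, the
perturbed trajectories are rolled forward through the discrete dynamics,
and the spread of the resulting state cloud around the reference
trajectory is summarized per timestep by projection onto the first
principal component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .connectome import SystemMatrix
from .control import TransitionResult

log = logging.getLogger(__name__)

__all__ = [
    "DiscreteSystem",
    "SuboptimalEnsemble",
    "DeviationSummary",
    "RepeatResult",
    "discretize",
    "perturb_trajectories",
    "deviation_summary",
    "repeat_analysis",
]


@dataclass(frozen=True)
class DiscreteSystem:
    """Zero-order-hold discretization of a stable continuous system.

    ``Abar = exp(A * Ts)``, ``Bbar = (int_0^Ts exp(A s) ds) B``, with
    ``Ts = rise_time / 10`` and ``rise_time = ln(9) / max_i |Re lambda_i|``
    (the 10-to-90% step-response time of the fastest first-order mode).
    """

    Abar: np.ndarray
    Bbar: np.ndarray
    Ts: float
    rise_time: float

    @property
    def n(self) -> int:
        return self.Abar.shape[0]

    @property
    def m(self) -> int:
        return self.Bbar.shape[1]


@dataclass
class SuboptimalEnsemble:
    """Reference discrete trajectory plus a cloud of perturbed ones.

    ``optimal_discrete`` has shape ``(n, K+1)`` and ``perturbed`` shape
    ``(J, n, K+1)`` for ``J`` perturbation iterations over ``K`` control
    samples. The summary fields are filled by :func:`deviation_summary`.
    """

    optimal_discrete: np.ndarray
    perturbed: np.ndarray
    sigma: float
    u_discrete: np.ndarray
    pc1_variance_fraction: np.ndarray | None = None
    deviation_percent: float | None = None


@dataclass(frozen=True)
class DeviationSummary:
    deviation_percent: float
    pc1_variance_fraction: np.ndarray   # per timestep, in [0, 1]
    per_timestep_deviation: np.ndarray  # max PC1 distance / ||x*(t)||, per t


@dataclass(frozen=True)
class RepeatResult:
    deviations: np.ndarray
    mean_deviation: float
    mean_pc1_variance_fraction: np.ndarray  # per repeat


def discretize(system: SystemMatrix, B: np.ndarray | None = None) -> DiscreteSystem:
    """Discretize a strictly stable system at a tenth of its fastest rise time.

    ``Bbar`` is computed from the augmented exponential block
    ``expm([[A, B], [0, 0]] * Ts)``, which is exact regardless of the
    invertibility of ``A``.
    """
    A = system.A
    n = system.n
    if B is None:
        B = np.eye(n)
    B = np.asarray(B, dtype=float)
    eig = np.linalg.eigvals(A)
    if eig.real.max() >= 0:
        raise ValueError("discretize requires a strictly stable system")
    rate = float(np.abs(eig.real).max())
    rise_time = math.log(9.0) / rate
    Ts = rise_time / 10.0
    m = B.shape[1]
    aug = np.zeros((n + m, n + m))
    aug[:n, :n] = A
    aug[:n, n:] = B
    Eaug = expm(aug * Ts)
    return DiscreteSystem(Abar=Eaug[:n, :n], Bbar=Eaug[:n, n:], Ts=Ts, rise_time=rise_time)


def _zoh_resample(transition: TransitionResult, Ts: float) -> np.ndarray:
    """Resample the continuous-grid optimal control at the Ts grid (ZOH)."""
    times = transition.times
    T = float(times[-1])
    K = max(1, int(math.floor(T / Ts + 1e-12)))
    sample_t = np.arange(K) * Ts
    idx = np.searchsorted(times, sample_t, side="right") - 1
    return transition.u_traj[:, idx]  # (m, K)


def _rollout(dsys: DiscreteSystem, x0: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Roll x(t+1) = Abar x(t) + Bbar u(t) forward; U is (m, K)."""
    K = U.shape[1]
    X = np.empty((dsys.n, K + 1))
    X[:, 0] = x0
    for k in range(K):
        X[:, k + 1] = dsys.Abar @ X[:, k] + dsys.Bbar @ U[:, k]
    return X


def perturb_trajectories(
    dsys: DiscreteSystem,
    transition: TransitionResult,
    sigma: float,
    n_iter: int = 200,
    seed=None,
) -> SuboptimalEnsemble:
    """Generate ``n_iter`` dynamics-consistent perturbed trajectories.

    Each control sample receives i.i.d. Gaussian noise with standard
    deviation ``sigma * RMS(u*) * sqrt((rise_time/10) / Ts)``; states then
    evolve lawfully through the discrete dynamics from the transition's
    initial state. At the nominal sampling time ``Ts = rise_time / 10``
    the scale is exactly ``sigma * RMS(u*)``; the square-root factor keeps
    the injected disturbance intensity consistent across refinements of
    the sampling grid (constant-intensity white noise, so the deviation
    summary is insensitive to halving ``Ts``). Fully seeded.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if transition.u_traj.shape[0] != dsys.m:
        raise ValueError(
            f"control dimension mismatch: transition has "
            f"{transition.u_traj.shape[0]} channels, discrete system {dsys.m}"
        )
    U = _zoh_resample(transition, dsys.Ts)
    x0 = transition.x_traj[:, 0]
    reference = _rollout(dsys, x0, U)
    rms = float(np.sqrt(np.mean(U**2)))
    scale = sigma * rms * math.sqrt((dsys.rise_time / 10.0) / dsys.Ts)
    rng = np.random.default_rng(seed)
    J, (m, K) = n_iter, U.shape
    noise = rng.normal(0.0, 1.0, size=(J, m, K)) * scale
    perturbed = np.empty((J, dsys.n, K + 1))
    for j in range(J):
        perturbed[j] = _rollout(dsys, x0, U + noise[j])
    return SuboptimalEnsemble(
        optimal_discrete=reference, perturbed=perturbed, sigma=sigma, u_discrete=U
    )


def deviation_summary(ensemble: SuboptimalEnsemble) -> DeviationSummary:
    """Per-timestep PC1 projection distance of the cloud from the reference.

    At each timestep a PCA of the J perturbed state points gives the first
    principal axis; the deviation is the maximum absolute difference
    between the projected perturbed points and the projected reference
    point, normalized by ``||x*(t)||`` and expressed as a percentage
    (averaged over timesteps with nonzero reference norm). A degenerate
    cloud (all points identical) contributes zero deviation and a PC1
    variance fraction of 1 by convention.
    """
    J = ensemble.perturbed.shape[0]
    if J < 2:
        raise ValueError("need at least 2 perturbed trajectories")
    ref = ensemble.optimal_discrete
    n_t = ref.shape[1]
    frac = np.empty(n_t)
    dev = np.full(n_t, np.nan)
    for t in range(n_t):
        cloud = ensemble.perturbed[:, :, t]
        center = cloud.mean(axis=0)
        Xc = cloud - center
        total_var = float((Xc**2).sum())
        ref_norm = float(np.linalg.norm(ref[:, t]))
        scale = float(np.abs(cloud).max())
        degenerate = math.sqrt(total_var / J) <= 1e-13 * (1.0 + scale)
        if degenerate:
            # no cloud spread at this timestep (e.g. the shared initial
            # state, or sigma = 0): excluded from the average
            frac[t] = 1.0
            continue
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        frac[t] = float(s[0] ** 2 / (s**2).sum())
        v = Vt[0]
        proj = Xc @ v
        proj_ref = float((ref[:, t] - center) @ v)
        d = float(np.abs(proj - proj_ref).max())
        dev[t] = d / ref_norm if ref_norm > 0 else np.nan
    usable = np.isfinite(dev)
    if not usable.any():
        log.info("all timesteps degenerate; deviation is 0")
        deviation_percent = 0.0
    else:
        deviation_percent = float(100.0 * dev[usable].mean())
    ensemble.pc1_variance_fraction = frac
    ensemble.deviation_percent = deviation_percent
    return DeviationSummary(
        deviation_percent=deviation_percent,
        pc1_variance_fraction=frac,
        per_timestep_deviation=dev,
    )


def repeat_analysis(
    dsys: DiscreteSystem,
    transition: TransitionResult,
    sigma: float,
    n_iter: int = 200,
    n_repeat: int = 10,
    seed=None,
) -> RepeatResult:
    """Repeat the perturbation analysis with independent seeded substreams."""
    if n_repeat < 1:
        raise ValueError("n_repeat must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_repeat)
    devs = np.empty(n_repeat)
    fracs = np.empty(n_repeat)
    for r, child in enumerate(children):
        ens = perturb_trajectories(dsys, transition, sigma, n_iter=n_iter, seed=child)
        summary = deviation_summary(ens)
        devs[r] = summary.deviation_percent
        fracs[r] = float(np.nanmean(summary.pc1_variance_fraction))
    return RepeatResult(
        deviations=devs,
        mean_deviation=float(devs.mean()),
        mean_pc1_variance_fraction=fracs,
    )
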