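"""Independent reference computations used to check the package.

Everything here deliberately avoids the code paths under test: the
quadratic program solves the discretized transition problem directly over
all control samples; the Gramian energy uses the minimum-energy closed
form with a quadrature-built controllability Gramian; the scalar case
uses the closed-form Euler-Lagrange boundary solution; discrete
simulations are checked against a plain RK4 integrator.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, sparse
from scipy.linalg import expm
from scipy.sparse.linalg import spsolve


def zoh_discretize(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization via the augmented exponential."""
    n, m = A.shape[0], B.shape[1]
    aug = np.zeros((n + m, n + m))
    aug[:n, :n] = A
    aug[:n, n:] = B
    E = expm(aug * dt)
    return E[:n, :n], E[:n, n:]


def qp_optimal(A, B, x0, xT, T, rho, N):
    """Discrete-time quadratic program for the optimal transition.

    Decision variables are all states x_0..x_N and all control samples
    u_0..u_{N-1}; equality constraints are the ZOH dynamics plus both
    endpoints. Solved exactly through the sparse KKT system. Returns a
    dict with the trajectory cost, total/nodal control energy, and the
    optimizing control samples.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    x0 = np.asarray(x0, float).ravel()
    xT = np.asarray(xT, float).ravel()
    n, m = A.shape[0], B.shape[1]
    dt = T / N
    Ad, Bd = zoh_discretize(A, B, dt)

    nx = (N + 1) * n
    nu = N * m
    cx = np.full(N + 1, dt)
    cx[0] = cx[-1] = dt / 2.0  # trapezoid weights for the state cost
    cu = rho * dt              # ZOH rectangle weights for the control cost
    Q = sparse.diags(
        np.concatenate([np.repeat(2.0 * cx, n), np.full(nu, 2.0 * cu)])
    )

    In = sparse.identity(n)
    D_x = sparse.kron(sparse.eye(N, N + 1), Ad) + sparse.kron(
        sparse.eye(N, N + 1, k=1), -In
    )
    D_u = sparse.kron(sparse.identity(N), Bd)
    E0 = sparse.eye(n, nx)
    EN = sparse.eye(n, nx, k=N * n)
    C = sparse.bmat([
        [E0, None],
        [D_x, D_u],
        [EN, None],
    ])
    KKT = sparse.bmat([[Q, C.T], [C, None]]).tocsc()
    rhs = np.concatenate([np.zeros(nx + nu), x0, np.zeros(N * n), xT])
    sol = spsolve(KKT, rhs)
    z = sol[: nx + nu]
    X = z[:nx].reshape(N + 1, n).T
    U = z[nx:].reshape(N, m).T
    cost = float(cx @ (X**2).sum(axis=0) + cu * (U**2).sum())
    nodal_energy = dt * (U**2).sum(axis=1)
    return {
        "cost": cost,
        "energy": float(nodal_energy.sum()),
        "nodal_energy": nodal_energy,
        "u": U,
        "x": X,
        "Ad": Ad,
        "Bd": Bd,
        "dt": dt,
    }


def qp_rollout_cost(oracle: dict, U: np.ndarray, x0, rho: float) -> float:
    """Cost of an arbitrary control sequence under the QP discretization."""
    Ad, Bd, dt = oracle["Ad"], oracle["Bd"], oracle["dt"]
    N = U.shape[1]
    n = Ad.shape[0]
    X = np.empty((n, N + 1))
    X[:, 0] = x0
    for k in range(N):
        X[:, k + 1] = Ad @ X[:, k] + Bd @ U[:, k]
    cx = np.full(N + 1, dt)
    cx[0] = cx[-1] = dt / 2.0
    return float(cx @ (X**2).sum(axis=0) + rho * dt * (U**2).sum())


def qp_endpoint_projection(oracle: dict, delta: np.ndarray) -> np.ndarray:
    """Project a control perturbation onto the endpoint-preserving set.

    Removes the component of ``delta`` that changes x_N, using the
    reachability map G with G_k = Ad^{N-1-k} Bd.
    """
    Ad, Bd = oracle["Ad"], oracle["Bd"]
    N = delta.shape[1]
    n, m = Bd.shape
    G = np.empty((n, m * N))
    P = np.eye(n)
    for k in range(N - 1, -1, -1):
        G[:, k * m:(k + 1) * m] = P @ Bd
        P = Ad @ P
    d = delta.T.ravel()
    lam = np.linalg.solve(G @ G.T, G @ d)
    d_proj = d - G.T @ lam
    return d_proj.reshape(N, m).T


def gramian_energy(A, B, x0, xT, T, npts=2001):
    """Minimum-energy transition cost from the controllability Gramian.

    ``Wc = int_0^T exp(At) B B' exp(A't) dt`` by composite trapezoid on a
    fine grid; the energy is the inverse quadratic form applied to
    ``xT - exp(AT) x0``.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = A.shape[0]
    dt = T / (npts - 1)
    step = expm(A * dt)
    P = np.eye(n)
    BBt = B @ B.T
    acc = np.zeros((n, n))
    for k in range(npts):
        w = 0.5 if k in (0, npts - 1) else 1.0
        acc += w * (P @ BBt @ P.T)
        P = step @ P
    Wc = acc * dt
    v = np.asarray(xT, float) - expm(A * T) @ np.asarray(x0, float)
    return float(v @ np.linalg.solve(Wc, v))


def scalar_solution(a, rho, x0, xT, T):
    """Closed-form 1-D Euler-Lagrange boundary solution.

    For dynamics ``xdot = -a x + u`` and cost ``int x^2 + rho u^2``, the
    stationarity conditions give ``xddot = (a^2 + 1/rho) x``; the
    hyperbolic boundary solution and ``u = xdot + a x`` follow. Returns
    (x(t) callable, u(t) callable, exact control energy via quadrature).
    """
    mu = math.sqrt(a * a + 1.0 / rho)
    beta = (xT - x0 * math.cosh(mu * T)) / math.sinh(mu * T)

    def x(t):
        return x0 * np.cosh(mu * t) + beta * np.sinh(mu * t)

    def u(t):
        xdot = x0 * mu * np.sinh(mu * t) + beta * mu * np.cosh(mu * t)
        return xdot + a * x(t)

    energy, _ = integrate.quad(lambda t: u(t) ** 2, 0.0, T, limit=200)
    return x, u, float(energy)


def rk4_zoh(A, B, x0, U, Ts, substeps=100):
    """Fine-grid RK4 integration of xdot = Ax + Bu with piecewise-constant u.

    Returns the state at every sample boundary, shape (n, K+1) for K
    control samples held over intervals of length Ts.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    K = U.shape[1]
    h = Ts / substeps
    X = np.empty((A.shape[0], K + 1))
    x = np.asarray(x0, float).copy()
    X[:, 0] = x
    for k in range(K):
        bu = B @ U[:, k]

        def f(y):
            return A @ y + bu

        for _ in range(substeps):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        X[:, k + 1] = x
    return X
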