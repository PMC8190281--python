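"""Structural connectome handling.

Reads, validates, averages, and stabilizes weighted symmetric adjacency
matrices (FA-like edge weights) into strictly stable continuous-time
dynamics matrices suitable for the optimal-control solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: asymmetries below this are treated as file-precision noise and symmetrized
ASYMMETRY_TOL = 1e-8
#: strict symmetry requirement on a validated Connectome
SYMMETRY_TOL = 1e-10

__all__ = [
    "Connectome",
    "SystemMatrix",
    "ConnectomeError",
    "load_connectome",
    "write_connectome",
    "average_connectomes",
    "stabilize",
]


class ConnectomeError(ValueError):
    """Raised for invalid connectome data or incompatible operations."""


def _default_labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"R{i:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class Connectome:
    """A weighted, symmetric, hollow (zero-diagonal) structural brain graph.

    Parameters
    ----------
    weights
        ``(n, n)`` array of nonnegative edge weights.
    labels
        ``n`` unique region identifiers. Auto-generated when omitted.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {W.shape}")
        n = W.shape[0]
        if n < 2:
            raise ConnectomeError("connectome needs at least 2 regions")
        if np.isnan(W).any():
            raise ConnectomeError("NaN entries in weights")
        if (W < 0).any():
            raise ConnectomeError("negative weight encountered")
        if np.abs(W - W.T).max() > SYMMETRY_TOL:
            raise ConnectomeError(
                f"weights not symmetric within {SYMMETRY_TOL:g}"
            )
        if np.abs(np.diag(W)).max() > 0:
            raise ConnectomeError("diagonal must be zero (no self-loops)")
        labels = tuple(self.labels) if self.labels else _default_labels(n)
        if len(labels) != n:
            raise ConnectomeError(
                f"{len(labels)} labels for {n} regions"
            )
        if len(set(labels)) != n:
            raise ConnectomeError("labels must be unique")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SystemMatrix:
    """Strictly stable continuous-time dynamics matrix (units 1/time).

    ``spectral_bound`` is the largest real part over the eigenvalues of
    ``A``; it must be negative. ``normalization`` records the stabilization
    scheme that produced ``A`` from raw connectome weights.
    """

    A: np.ndarray
    spectral_bound: float
    normalization: str

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ConnectomeError(f"A must be square, got shape {A.shape}")
        if not self.spectral_bound < 0:
            raise ConnectomeError(
                f"system matrix is not strictly stable "
                f"(spectral bound {self.spectral_bound:g} >= 0)"
            )
        object.__setattr__(self, "A", A)

    @property
    def n(self) -> int:
        return self.A.shape[0]


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_connectome(path, delimiter: str = ",") -> Connectome:
    """Load a dense connectivity matrix from CSV/TSV.

    An optional header row and/or first label column is detected by whether
    the corner tokens parse as numbers. Asymmetries below
    :data:`ASYMMETRY_TOL` are symmetrized as ``(W + W.T) / 2``; larger ones
    are an error. A nonzero diagonal is zeroed with a logged warning.
    """
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.rstrip("\n").split(delimiter)]
    has_header = not all(_looks_numeric(t) for t in tokens if t != "")

    if has_header:
        df = pd.read_csv(path, delimiter=delimiter, header=0, index_col=0)
        labels = tuple(str(c) for c in df.columns)
        W = df.to_numpy(dtype=float)
    else:
        W = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        labels = ()

    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ConnectomeError(
            f"{path}: matrix is not square (shape {W.shape})"
        )
    if np.isnan(W).any():
        raise ConnectomeError(f"{path}: NaN entries")
    if (W < 0).any():
        raise ConnectomeError(f"{path}: negative weight")
    asym = np.abs(W - W.T).max()
    if asym > ASYMMETRY_TOL:
        raise ConnectomeError(
            f"{path}: asymmetry {asym:g} exceeds tolerance {ASYMMETRY_TOL:g}"
        )
    W = (W + W.T) / 2.0
    if np.abs(np.diag(W)).max() > 0:
        log.warning("%s: nonzero diagonal zeroed (self-loops removed)", path)
        np.fill_diagonal(W, 0.0)
    return Connectome(W, labels)


def write_connectome(conn: Connectome, path, delimiter: str = ",") -> None:
    """Write a connectome as a labeled dense matrix at full double precision."""
    df = pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def average_connectomes(connectomes: list[Connectome]) -> Connectome:
    """Link-wise arithmetic mean of a set of connectomes sharing layout."""
    if not connectomes:
        raise ConnectomeError("cannot average an empty list of connectomes")
    ref = connectomes[0]
    for c in connectomes[1:]:
        if c.n != ref.n:
            raise ConnectomeError(
                f"dimension mismatch: {c.n} vs {ref.n}"
            )
        if c.labels != ref.labels:
            raise ConnectomeError("label mismatch between connectomes")
    mean = np.mean([c.weights for c in connectomes], axis=0)
    # exact symmetry can drift by rounding; re-symmetrize
    mean = (mean + mean.T) / 2.0
    return Connectome(mean, ref.labels)


def stabilize(conn: Connectome, scheme: str = "spectral", c: float = 1.0) -> SystemMatrix:
    """Turn nonnegative weights into a strictly stable dynamics matrix.

    scheme "spectral" (default)
        ``A = W / (lam_max + 1) - I`` where ``lam_max`` is the largest
        eigenvalue of the symmetric ``W``. Always strictly stable for
        nonnegative symmetric weights (largest eigenvalue of A is
        ``-1 / (lam_max + 1)``).
    scheme "scaled"
        ``A = W / (lam_max + 1) - c * I`` with configurable shift ``c``;
        errors if the choice of ``c`` does not yield a stable matrix.
    """
    W = conn.weights
    lam = np.linalg.eigvalsh(W)
    lam_max = float(lam[-1])
    if scheme == "spectral":
        A = W / (lam_max + 1.0) - np.eye(conn.n)
        tag = "spectral"
    elif scheme == "scaled":
        A = W / (lam_max + 1.0) - c * np.eye(conn.n)
        tag = f"scaled(c={c:g})"
    else:
        raise ConnectomeError(f"unknown stabilization scheme {scheme!r}")
    bound = float(np.linalg.eigvalsh((A + A.T) / 2.0)[-1])
    if not bound < 0:
        raise ConnectomeError(
            f"scheme {scheme!r} did not stabilize (spectral bound {bound:g})"
        )
    return SystemMatrix(A=A, spectral_bound=bound, normalization=tag)
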