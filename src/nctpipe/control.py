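"""Linear network dynamics and per-node modal controllability.

The dynamics model is the noise-free, discrete-time, time-invariant linear
system x(t+1) = A x(t) + B u(t) on a symmetric weighted adjacency A with zero
diagonal. Modal controllability of node i,

    phi_i = sum_j (1 - lambda_j^2) v_ij^2,

sums, over the eigenmodes (lambda_j, v_j) of A, the squared participation of
node i in each mode, downweighted for slowly-decaying modes. Nodes with high
phi can steer the system toward hard-to-reach (high-energy) states.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .networks import ControlSystem

__all__ = [
    "ModalResult",
    "Trajectory",
    "ModalControllability",
    "modal_controllability",
    "evolve_state",
    "controllability_gramian",
    "is_controllable",
    "node_metrics_table",
]

_SYM_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class ModalResult:
    """Eigen-decomposition of the system matrix plus per-node phi.

    Eigenvalues are sorted in descending order; ``eigenvectors[:, j]`` is the
    orthonormal eigenvector of ``eigenvalues[j]``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    phi: np.ndarray


@dataclasses.dataclass(frozen=True)
class Trajectory:
    states: np.ndarray   # (T+1, N)
    inputs: np.ndarray   # (T, m)


class ModalControllability(TransformerMixin, BaseEstimator):
    """Per-node modal controllability of a symmetric system matrix.

    scikit-learn style estimator: ``fit`` takes the (stabilized) N x N
    symmetric adjacency and exposes ``eigenvalues_``, ``eigenvectors_`` and
    ``phi_``; ``transform`` returns phi for the fitted matrix.

    Parameters
    ----------
    check_symmetry : bool, default True
        Reject matrices asymmetric beyond 1e-10.
    """

    def __init__(self, check_symmetry: bool = True):
        self.check_symmetry = check_symmetry

    def fit(self, X, y=None):
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {A.shape}")
        if self.check_symmetry and np.max(np.abs(A - A.T)) > _SYM_TOL:
            raise ValueError("system matrix must be symmetric")
        lam, V = np.linalg.eigh((A + A.T) / 2.0)
        order = np.argsort(lam)[::-1]          # descending eigenvalues
        lam, V = lam[order], V[:, order]
        self.eigenvalues_ = lam
        self.eigenvectors_ = V
        self.phi_ = (V ** 2) @ (1.0 - lam ** 2)
        self.n_features_in_ = A.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "phi_")
        return self.phi_

    def result_(self) -> ModalResult:
        check_is_fitted(self, "phi_")
        return ModalResult(self.eigenvalues_, self.eigenvectors_, self.phi_)


def modal_controllability(A: np.ndarray) -> ModalResult:
    """Functional wrapper around :class:`ModalControllability`."""
    return ModalControllability().fit(A).result_()


def evolve_state(system: ControlSystem, x0: Sequence[float],
                 inputs: Sequence[Sequence[float]]) -> Trajectory:
    """Iterate x(t+1) = A x(t) + B u(t) over a given input sequence."""
    A, B = system.A, system.B
    x = np.asarray(x0, dtype=float)
    if x.shape != (A.shape[0],):
        raise ValueError(f"x0 has shape {x.shape}, expected ({A.shape[0]},)")
    U = np.atleast_2d(np.asarray(inputs, dtype=float))
    if U.size and U.shape[1] != B.shape[1]:
        raise ValueError(
            f"inputs have {U.shape[1]} channels, input matrix has {B.shape[1]}"
        )
    states = [x]
    for u in U:
        x = A @ x + B @ u
        states.append(x)
    return Trajectory(states=np.array(states), inputs=U)


def controllability_gramian(system: ControlSystem, horizon: int | None = None) -> np.ndarray:
    """Finite-horizon controllability Gramian W = sum_t A^t B B' (A')^t.

    The default horizon is N: by Cayley-Hamilton, longer horizons add no rank.
    """
    A, B = system.A, system.B
    n = A.shape[0]
    if horizon is None:
        horizon = n
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    W = np.zeros((n, n))
    M = B.copy()
    for _ in range(horizon):
        W += M @ M.T
        M = A @ M
    return (W + W.T) / 2.0


def is_controllable(system: ControlSystem, tol: float | None = None):
    """Decide controllability from the numerical rank of the horizon-N Gramian.

    Returns ``(controllable, report)`` where the report carries the rank, the
    dimension, the smallest retained singular value and the tolerance used
    (default: N * eps * largest singular value).
    """
    n = system.A.shape[0]
    W = controllability_gramian(system, horizon=n)
    s = np.linalg.svd(W, compute_uv=False)
    if tol is None:
        tol = n * np.finfo(float).eps * (s[0] if s.size else 0.0)
    elif tol <= 0:
        raise ValueError("tol must be positive")
    rank = int(np.sum(s > tol))
    report = {
        "rank": rank,
        "n": n,
        "smallest_retained_sv": float(s[rank - 1]) if rank else 0.0,
        "tol": float(tol),
    }
    return rank == n, report


def node_metrics_table(labels, weights, phi):
    """Per-node metrics table: label, weighted_degree, phi."""
    import pandas as pd

    w = np.asarray(weights, dtype=float)
    return pd.DataFrame(
        {"label": list(labels), "weighted_degree": w.sum(axis=1), "phi": np.asarray(phi)}
    )
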