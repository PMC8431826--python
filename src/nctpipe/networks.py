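"""Weighted anatomical networks: loading, validation, normalization, stabilization.

A connectome here is an undirected, weighted, zero-diagonal adjacency matrix
over a fixed parcellation (one node per brain region), with edge weights
proportional to streamline counts between region pairs, optionally divided by
the summed volumes of the two regions. One node is designated the analysis
target (the stimulation site, an LIFG-pars-triangularis analog).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Connectome",
    "ControlSystem",
    "load_connectome",
    "write_connectome",
    "normalize_by_volume",
    "stabilize",
    "build_input_matrix",
    "make_control_system",
]

_SYMMETRY_TOL = 1e-9
_DIAG_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class Connectome:
    """A validated region-by-region weighted network.

    Parameters
    ----------
    labels : tuple of str
        Ordered region identifiers, one per node.
    weights : ndarray of shape (N, N)
        Symmetric, nonnegative, zero-diagonal adjacency (streamline density).
    volumes : ndarray of shape (N,), optional
        Per-region volumes (positive), if volume normalization is in play.
    target_index : int
        Index of the analysis target node.
    """

    labels: tuple
    weights: np.ndarray
    volumes: np.ndarray | None = None
    target_index: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {w.shape}")
        if w.shape[0] != n:
            raise ValueError(
                f"label count ({n}) does not match adjacency size ({w.shape[0]})"
            )
        if n < 2:
            raise ValueError("a connectome needs at least 2 nodes")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("adjacency contains negative weights")
        asym = np.max(np.abs(w - w.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"adjacency asymmetric beyond tolerance ({asym:g})")
        if np.max(np.abs(np.diag(w))) > _DIAG_TOL:
            raise ValueError("adjacency has nonzero diagonal entries")
        # symmetrize numeric noise and freeze
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if self.volumes is not None:
            v = np.asarray(self.volumes, dtype=float)
            if v.shape != (n,):
                raise ValueError("volumes length does not match node count")
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError("volumes must be finite and strictly positive")
            v.setflags(write=False)
            object.__setattr__(self, "volumes", v)
        if not (0 <= self.target_index < n):
            raise ValueError(f"target_index {self.target_index} out of range [0, {n})")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def strength(self) -> np.ndarray:
        """Weighted degree (node strength) of every node."""
        return self.weights.sum(axis=1)

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return Connectome(self.labels, weights, self.volumes, self.target_index)


@dataclasses.dataclass(frozen=True)
class ControlSystem:
    """Stabilized linear system x(t+1) = A x(t) + B u(t) with control set K.

    ``B`` has one column per control node, each a canonical basis vector.
    """

    A: np.ndarray
    control_set: tuple
    B: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None  # whitespace


def load_connectome(
    adjacency_path,
    labels_path,
    volumes_path=None,
    target_label: str | None = None,
) -> Connectome:
    """Read a connectome from delimited text.

    The adjacency file is an N x N numeric grid (tab, comma or whitespace
    delimited, no header); the labels file has one region identifier per line;
    the optional volumes file has one positive number per line. Asymmetry up
    to 1e-9 is treated as numeric noise and symmetrized by averaging.
    """
    adjacency_path = Path(adjacency_path)
    delim = _sniff_delimiter(adjacency_path)
    w = np.loadtxt(adjacency_path, delimiter=delim, ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(
            f"adjacency grid is {w.shape[0]}x{w.shape[1]}, expected square"
        )
    labels = [ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()]
    if len(labels) != w.shape[0]:
        raise ValueError(
            f"labels file has {len(labels)} entries for a {w.shape[0]}-node adjacency"
        )
    volumes = None
    if volumes_path is not None:
        volumes = np.loadtxt(volumes_path, ndmin=1)
    target_index = 0
    if target_label is not None:
        try:
            target_index = labels.index(target_label)
        except ValueError:
            raise ValueError(f"target label {target_label!r} not in labels file") from None
    return Connectome(tuple(labels), w, volumes, target_index)


def write_connectome(conn: Connectome, adjacency_path, labels_path, volumes_path=None,
                     delimiter: str = "\t") -> None:
    """Write adjacency/labels (and volumes if present) as delimited text.

    Floats are written with repr-faithful precision so load -> write -> load
    round-trips bit-identically.
    """
    np.savetxt(adjacency_path, conn.weights, fmt="%.17g", delimiter=delimiter)
    Path(labels_path).write_text("".join(f"{l}\n" for l in conn.labels))
    if volumes_path is not None:
        if conn.volumes is None:
            raise ValueError("connectome has no volumes to write")
        np.savetxt(volumes_path, conn.volumes, fmt="%.17g")


def normalize_by_volume(counts: np.ndarray, volumes: Sequence[float]) -> np.ndarray:
    """Divide each streamline count by the summed volumes of its two regions.

    out[i, j] = counts[i, j] / (volumes[i] + volumes[j]); the diagonal stays
    zero and symmetry is preserved.
    """
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(~np.isfinite(volumes)) or np.any(volumes <= 0):
        raise ValueError("volumes must be finite and strictly positive")
    denom = volumes[:, None] + volumes[None, :]
    out = counts / denom
    np.fill_diagonal(out, 0.0)
    return out


def stabilize(conn: Connectome | np.ndarray, mode: str = "mean-edge") -> np.ndarray:
    """Rescale the adjacency for use as the system matrix of the dynamics.

    mode="mean-edge" (default): divide every entry by the mean weight over
    nonzero off-diagonal entries, each undirected edge counted once. After
    rescaling the mean nonzero edge weight is exactly 1. This follows the
    convention of dividing the streamline matrix by its mean edge weight; it
    does not bound the spectral radius.

    mode="spectral": divide by (1 + |lambda_max|), which guarantees spectral
    radius < 1 so every modal factor (1 - lambda_j^2) is positive.
    """
    w = conn.weights if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    edges = w[iu]
    nz = edges[edges != 0]
    if nz.size == 0:
        raise ValueError("cannot stabilize an all-zero network")
    if mode == "mean-edge":
        return w / nz.mean()
    if mode == "spectral":
        lam = np.linalg.eigvalsh(w)
        rho = np.max(np.abs(lam))
        return w / (1.0 + rho)
    raise ValueError(f"unknown stabilization mode {mode!r}")


def build_input_matrix(control_set: Sequence[int], n_nodes: int) -> np.ndarray:
    """Input map B whose i-th column is the canonical vector e_{k_i}."""
    ks = list(control_set)
    if len(set(ks)) != len(ks):
        raise ValueError("control set contains duplicate indices")
    B = np.zeros((n_nodes, len(ks)))
    for col, k in enumerate(ks):
        if not (0 <= k < n_nodes):
            raise ValueError(f"control node {k} out of range [0, {n_nodes})")
        B[k, col] = 1.0
    return B


def make_control_system(conn: Connectome, control_set: Sequence[int],
                        mode: str = "mean-edge") -> ControlSystem:
    """Stabilize a connectome and attach the input map for a control set."""
    A = stabilize(conn, mode=mode)
    B = build_input_matrix(control_set, conn.n_nodes)
    return ControlSystem(A=A, control_set=tuple(control_set), B=B)
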