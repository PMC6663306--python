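"""Linear network control metrics on a structural connectome.

The connectome is a symmetric, weighted, nonnegative adjacency matrix S with
zero diagonal.  Dynamics are the noise-free discrete-time linear model

    x(t+1) = A x(t) + B u(t),

with A = S / (1 + xi0(S)), where xi0 is the largest singular value of S, so
the spectral radius is below one and the free system is stable.  Modal
controllability of node i is

    phi_i = sum_j (1 - lambda_j^2) * v_ij^2,

computed from the symmetric eigendecomposition of the normalized A
(orthonormal eigenvectors V = [v_ij], real eigenvalues lambda_j).  High
phi_i marks nodes positioned to steer the fast, difficult-to-reach modes;
such nodes tend to be weak structural hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, InvalidConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralNetwork",
    "LinearSystem",
    "ControllabilityProfile",
    "normalize_structural",
    "modal_controllability",
    "structural_strength",
    "controllability_profile",
    "simulate_linear",
    "map_electrodes",
]


@dataclass
class StructuralNetwork:
    """Weighted structural connectome with ROI metadata."""

    S: np.ndarray
    roi_labels: list[str]
    hemisphere: list[str]  # "L" / "R" per ROI
    centroids: np.ndarray  # [N, 3] millimetres

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        _validate_structural(self.S)
        n = self.S.shape[0]
        if not (len(self.roi_labels) == len(self.hemisphere) == n):
            raise InvalidConfigError("ROI metadata length mismatch")
        if self.centroids.shape != (n, 3):
            raise InvalidConfigError("centroids must be [N, 3]")

    @property
    def n_rois(self) -> int:
        return self.S.shape[0]


@dataclass
class LinearSystem:
    """Normalized dynamics matrix plus canonical-vector input matrix."""

    A: np.ndarray
    control_nodes: tuple[int, ...]
    xi0: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)

    @property
    def B(self) -> np.ndarray:
        n = self.A.shape[0]
        B = np.zeros((n, len(self.control_nodes)))
        for col, node in enumerate(self.control_nodes):
            B[node, col] = 1.0
        return B


@dataclass
class ControllabilityProfile:
    """Per-ROI modal controllability, eigenpairs, and structural strength."""

    phi: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are modes, sorted by descending lambda
    structural_strength: np.ndarray


def _validate_structural(S: np.ndarray) -> None:
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidConfigError(f"structural matrix must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise InvalidConfigError("structural matrix must be symmetric")
    if not np.allclose(np.diag(S), 0.0):
        raise InvalidConfigError("structural matrix must have zero diagonal")
    if np.any(S < 0):
        raise InvalidConfigError("structural weights must be nonnegative")


def normalize_structural(
    S: np.ndarray, control_nodes: tuple[int, ...] = ()
) -> LinearSystem:
    """Scale S by 1 + xi0(S) so the linear dynamics are stable.

    xi0 is the largest singular value of the *unnormalized* S.
    """
    S = np.asarray(S, dtype=float)
    _validate_structural(S)
    xi0 = float(np.linalg.norm(S, 2)) if S.size else 0.0
    A = S / (1.0 + xi0)
    return LinearSystem(A=A, control_nodes=tuple(control_nodes), xi0=xi0)


def modal_controllability(A: np.ndarray | LinearSystem) -> np.ndarray:
    """phi_i = sum_j (1 - lambda_j^2) v_ij^2 on the normalized matrix.

    Eigenvector orthonormality (rows of V**2 summing to one) is asserted
    before use, which also guarantees 1 - max_j lambda_j^2 <= phi_i <= 1.
    """
    if isinstance(A, LinearSystem):
        A = A.A
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise InvalidConfigError("modal controllability requires symmetric A")
    lam, V = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]  # descending for reproducible reporting
    lam, V = lam[order], V[:, order]
    row_norms = np.sum(V**2, axis=1)
    if not np.allclose(row_norms, 1.0, atol=1e-8):
        raise FloatingPointError(
            "eigenvector matrix not orthonormal; "
            f"max row-norm deviation {np.max(np.abs(row_norms - 1)):.2e}"
        )
    return (1.0 - lam**2) @ (V**2).T


def structural_strength(S: np.ndarray) -> np.ndarray:
    """k_i = (1/(N-1)) sum_j S_ij."""
    S = np.asarray(S, dtype=float)
    _validate_structural(S)
    n = S.shape[0]
    if n < 2:
        raise InvalidConfigError("strength needs >= 2 nodes")
    return S.sum(axis=1) / (n - 1)


def controllability_profile(net: StructuralNetwork) -> ControllabilityProfile:
    """Convenience: normalize, eigendecompose, and compute phi + strength."""
    sys = normalize_structural(net.S)
    lam, V = np.linalg.eigh(sys.A)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    phi = (1.0 - lam**2) @ (V**2).T
    return ControllabilityProfile(
        phi=phi,
        eigenvalues=lam,
        eigenvectors=V,
        structural_strength=structural_strength(net.S),
    )


def simulate_linear(
    sys: LinearSystem,
    x0: np.ndarray,
    u: np.ndarray | None,
    T: int,
) -> np.ndarray:
    """Iterate x(t+1) = A x(t) + B u(t) for T steps; returns [T+1, N]."""
    A = sys.A
    n = A.shape[0]
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != n:
        raise AlignmentError(f"x0 has length {x0.size}, expected {n}")
    B = sys.B
    m = B.shape[1]
    if u is None:
        u = np.zeros((T, m))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape != (T, m):
        raise AlignmentError(f"u must have shape ({T}, {m}), got {u.shape}")
    traj = np.empty((T + 1, n))
    traj[0] = x0
    for t in range(T):
        traj[t + 1] = A @ traj[t] + B @ u[t]
    return traj


def map_electrodes(
    electrode_coords: np.ndarray,
    structural: StructuralNetwork,
) -> np.ndarray:
    """Assign each electrode to the ROI with the nearest centroid.

    Ties in Euclidean distance go to the lowest ROI index (and are logged).
    Returns an integer array of ROI indices, one per electrode.
    """
    coords = np.atleast_2d(np.asarray(electrode_coords, dtype=float))
    if structural.n_rois == 0:
        raise InvalidConfigError("cannot map electrodes onto an empty ROI set")
    if coords.shape[1] != 3:
        raise AlignmentError("electrode coordinates must be [n, 3]")
    d = cdist(coords, structural.centroids)
    assignment = np.argmin(d, axis=1)
    for ei in range(coords.shape[0]):
        ties = np.flatnonzero(np.isclose(d[ei], d[ei, assignment[ei]]))
        if ties.size > 1:
            logger.info(
                "electrode %d equidistant to ROIs %s; assigned lowest index %d",
                ei,
                ties.tolist(),
                assignment[ei],
            )
    return assignment
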