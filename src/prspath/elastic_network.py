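"""Anisotropic network model (ANM) Hessians and positional covariance.

The ANM represents a protein as its CA beads joined by identical harmonic
springs for every pair within a distance cutoff.  The pseudo-inverse of the
resulting 3N x 3N Hessian (with the six rigid-body modes removed)
approximates the positional covariance C that linear response theory
consumes; alternatively C can be estimated directly from a superposed
coordinate ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from ._geometry import kabsch
from .structure_io import CoordinateEnsemble, StructureModel

#: Default CA-CA spring cutoff (Angstrom), standard ANM practice.
DEFAULT_CUTOFF = 13.0
#: Number of rigid-body (zero-frequency) modes of a connected 3-D network.
N_RIGID_MODES = 6


@dataclass
class ElasticNetwork:
    """CA positions plus the assembled ANM Hessian."""

    positions: np.ndarray  # (N, 3), Angstrom
    cutoff_rc: float
    gamma_spring: float
    hessian: np.ndarray  # (3N, 3N)

    @property
    def n_residues(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class CovarianceModel:
    """3N x 3N positional covariance with provenance."""

    matrix: np.ndarray
    kT: float = 1.0
    source: str = "anm"  # "anm" | "ensemble"
    n_zero_modes_removed: int = 0

    @property
    def n_residues(self) -> int:
        return int(self.matrix.shape[0] // 3)

    def block(self, i: int, j: int) -> np.ndarray:
        """3x3 covariance sub-block coupling residues i and j (0-based)."""
        return self.matrix[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]


def _contact_matrix(positions: np.ndarray, cutoff: float) -> np.ndarray:
    dist = squareform(pdist(positions))
    contacts = (dist <= cutoff) & ~np.eye(len(positions), dtype=bool)
    return contacts


def build_anm_hessian(
    ca_model: StructureModel | np.ndarray,
    cutoff_rc: float = DEFAULT_CUTOFF,
    gamma_spring: float = 1.0,
) -> ElasticNetwork:
    """Assemble the ANM Hessian from CA coordinates.

    For a contacting pair (i, j) the off-diagonal 3x3 super-element is
    ``-gamma * d d^T / |d|^2`` with ``d = r_j - r_i``; diagonal super-elements
    enforce zero row sums (translational invariance).

    Raises
    ------
    ValueError
        For fewer than 3 residues, collinear coordinates, or a contact graph
        that is disconnected at the given cutoff.
    """
    if cutoff_rc <= 0:
        raise ValueError(f"cutoff_rc must be positive, got {cutoff_rc}")
    positions = (
        ca_model.coords if isinstance(ca_model, StructureModel) else np.asarray(ca_model, float)
    )
    n = positions.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 residues to build an ANM, got {n}")
    centered = positions - positions.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("collinear CA coordinates: ANM would be degenerate")
    contacts = _contact_matrix(positions, cutoff_rc)
    n_comp, _ = connected_components(contacts, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"contact graph is disconnected at cutoff {cutoff_rc} A "
            f"({n_comp} components)"
        )

    hessian = np.zeros((3 * n, 3 * n))
    idx_i, idx_j = np.nonzero(np.triu(contacts, k=1))
    for i, j in zip(idx_i, idx_j):
        d = positions[j] - positions[i]
        block = -gamma_spring * np.outer(d, d) / (d @ d)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return ElasticNetwork(
        positions=positions.copy(),
        cutoff_rc=float(cutoff_rc),
        gamma_spring=float(gamma_spring),
        hessian=hessian,
    )


def anm_covariance(
    network: ElasticNetwork, kT: float = 1.0, zero_mode_tol: float = 1e-8
) -> CovarianceModel:
    """Pseudo-inverse covariance ``C = kT * sum_k v_k v_k^T / lambda_k``.

    Eigendecomposes the Hessian, removes exactly the six smallest-magnitude
    (rigid-body) modes, and inverts the rest.  A connected, non-degenerate
    network has exactly six eigenvalues below ``zero_mode_tol * lambda_max``;
    any other count raises, which catches disconnected or collinear input.
    """
    evals, evecs = np.linalg.eigh(network.hessian)
    lam_max = float(np.max(np.abs(evals)))
    n_zero = int(np.sum(np.abs(evals) < zero_mode_tol * lam_max))
    if n_zero != N_RIGID_MODES:
        raise ValueError(
            f"expected exactly {N_RIGID_MODES} zero modes, found {n_zero}: "
            "network is disconnected or geometrically degenerate"
        )
    order = np.argsort(np.abs(evals))
    keep = order[N_RIGID_MODES:]
    inv = evecs[:, keep] / evals[keep]
    matrix = kT * (inv @ evecs[:, keep].T)
    matrix = 0.5 * (matrix + matrix.T)
    return CovarianceModel(
        matrix=matrix, kT=float(kT), source="anm", n_zero_modes_removed=N_RIGID_MODES
    )


def superpose_frames(
    frames: np.ndarray, n_passes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto an iteratively refined mean structure.

    Returns (superposed frames, final mean).  Two passes (mean -> superpose ->
    re-mean -> superpose) remove the dependence on frame order.
    """
    frames = np.array(frames, dtype=float)
    mean = frames.mean(axis=0)
    for _ in range(n_passes):
        for f in range(frames.shape[0]):
            rot, trans, _ = kabsch(frames[f], mean)
            frames[f] = frames[f] @ rot.T + trans
        mean = frames.mean(axis=0)
    return frames, mean


def ensemble_covariance(ensemble: CoordinateEnsemble) -> CovarianceModel:
    """Positional covariance of a coordinate ensemble after superposition.

    Every frame is superposed onto the (twice-iterated) mean structure, then
    ``C = (1/F) * sum_f (x_f - xbar)(x_f - xbar)^T`` over flattened 3N
    coordinates.
    """
    if ensemble.n_frames < 2:
        raise ValueError("ensemble covariance needs at least 2 frames")
    frames, mean = superpose_frames(ensemble.frames)
    flat = frames.reshape(ensemble.n_frames, -1)
    dev = flat - mean.reshape(1, -1)
    matrix = dev.T @ dev / ensemble.n_frames
    matrix = 0.5 * (matrix + matrix.T)
    return CovarianceModel(matrix=matrix, kT=1.0, source="ensemble", n_zero_modes_removed=0)


def export_matrix_tsv(matrix: np.ndarray, path, header: str = "") -> None:
    """Write a matrix as row-major TSV with an optional ``#`` header comment."""
    np.savetxt(path, matrix, delimiter="\t", fmt="%.6g", header=header)
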