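"""Perturbation response scanning (PRS) via linear response theory.

PRS probes allosteric communication by applying external forces at each
residue in turn and reading off the displacement everywhere else through the
linear response relation ``dR = (1/kT) C F``, where C is the positional
covariance (from an ANM or an ensemble).  Perturbations are made isotropic
by averaging over a quasi-uniform set of unit force directions generated
with the Fibonacci sphere algorithm (M = 100 by default); the exact
isotropic limit ``<|A u|^2> = tr(A^T A) / 3`` is available as the
"analytic" scheme and doubles as an internal consistency oracle.

Rows of the response matrix index the perturbed residue (effector), columns
the responding residue (sensor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import fibonacci_sphere
from .elastic_network import CovarianceModel

DEFAULT_N_FORCES = 100


@dataclass
class ForceSet:
    """A set of unit force directions applied at every perturbed residue."""

    directions: np.ndarray  # (M, 3); empty for scheme="analytic"
    scheme: str = "fibonacci"  # "fibonacci" | "analytic"

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if self.scheme not in ("fibonacci", "analytic"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme != "analytic":
            norms = np.linalg.norm(self.directions, axis=1)
            if self.directions.shape[0] < 1:
                raise ValueError("force set must contain at least one direction")
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise ValueError("force directions must be unit vectors")

    @property
    def n_forces(self) -> int:
        return int(self.directions.shape[0])


def fibonacci_force_set(n_forces: int = DEFAULT_N_FORCES) -> ForceSet:
    """Quasi-uniform unit forces from the Fibonacci sphere algorithm."""
    return ForceSet(directions=fibonacci_sphere(n_forces), scheme="fibonacci")


def analytic_force_set() -> ForceSet:
    """Sentinel force set selecting the exact isotropic-average response."""
    return ForceSet(directions=np.empty((0, 3)), scheme="analytic")


@dataclass
class PRSResult:
    """Response matrices and effector/sensor profiles of one PRS scan.

    ``response[i, j]`` is the mean squared displacement magnitude at residue j
    when residue i is perturbed; ``normalized`` divides each row by its
    self-response so the diagonal is exactly 1.
    """

    response: np.ndarray
    normalized: np.ndarray
    effector_profile: np.ndarray
    sensor_profile: np.ndarray
    n_forces: int

    @property
    def n_residues(self) -> int:
        return int(self.response.shape[0])


def lrt_response(cov: CovarianceModel, residue: int, force: np.ndarray) -> np.ndarray:
    """Displacement field ``dR = (1/kT) C F`` for a point force at one residue.

    Parameters
    ----------
    cov : CovarianceModel
    residue : int
        1-based residue index of the perturbation site.
    force : 3-vector

    Returns
    -------
    (N, 3) displacement field, same length units as the covariance.
    """
    n = cov.n_residues
    if not 1 <= residue <= n:
        raise IndexError(f"residue {residue} outside 1..{n}")
    force = np.asarray(force, dtype=float).reshape(3)
    if not np.all(np.isfinite(force)):
        raise ValueError("force must be finite")
    i = residue - 1
    field = cov.matrix[:, 3 * i : 3 * i + 3] @ force / cov.kT
    return field.reshape(n, 3)


def prs_scan(cov: CovarianceModel, forces: ForceSet | None = None) -> PRSResult:
    """Scan every residue with the given force set and collect responses.

    For the sampled schemes, ``response[i, j] = (1/M) sum_m |C_block(j,i) u_m|^2
    / kT^2``; the "analytic" scheme computes the exact spherical average
    ``tr(A^T A) / 3`` with ``A = C_block(j, i)`` instead.

    Raises
    ------
    ValueError
        If some residue has zero self-response (degenerate covariance), with
        the residue named.
    """
    if forces is None:
        forces = fibonacci_force_set()
    n = cov.n_residues
    c = cov.matrix
    response = np.empty((n, n))
    if forces.scheme == "analytic":
        # <|A u|^2> over the unit sphere equals tr(A^T A)/3; with C symmetric
        # the Frobenius norms of C_block(j,i) for all j are read off column
        # blocks of C.
        for i in range(n):
            cols = c[:, 3 * i : 3 * i + 3]  # (3N, 3); row block j is C_block(j, i)
            sq = cols**2
            response[i, :] = sq.reshape(n, 3, 3).sum(axis=(1, 2)) / 3.0
        n_forces = 0
    else:
        u = forces.directions.T  # (3, M)
        for i in range(n):
            cols = c[:, 3 * i : 3 * i + 3]  # (3N, 3)
            disp = cols @ u  # (3N, M)
            sq = (disp**2).reshape(n, 3, -1).sum(axis=1)  # (N, M)
            response[i, :] = sq.mean(axis=1)
        n_forces = forces.n_forces
    response /= cov.kT**2

    diag = np.diag(response).copy()
    bad = np.nonzero(diag <= 0)[0]
    if bad.size:
        raise ValueError(
            f"zero self-response at residue {bad[0] + 1}: covariance is degenerate"
        )
    normalized = response / diag[:, None]
    np.fill_diagonal(normalized, 1.0)

    off = ~np.eye(n, dtype=bool)
    effector = np.array([normalized[i, off[i]].mean() for i in range(n)])
    sensor = np.array([normalized[off[:, j], j].mean() for j in range(n)])
    return PRSResult(
        response=response,
        normalized=normalized,
        effector_profile=effector,
        sensor_profile=sensor,
        n_forces=n_forces,
    )


def key_residues(
    result: PRSResult, z_threshold: float = 1.0
) -> list[tuple[int, float]]:
    """Residues whose effector z-score exceeds ``z_threshold``.

    Returns (1-based residue index, z-score) pairs sorted by descending score,
    ties broken by ascending residue index.  A constant profile (zero spread)
    yields an empty list with a warning.
    """
    profile = result.effector_profile
    std = profile.std()
    if std == 0 or not np.isfinite(std):
        warnings.warn("effector profile is constant; no key residues identified")
        return []
    z = (profile - profile.mean()) / std
    hits = [(int(i) + 1, float(z[i])) for i in np.nonzero(z > z_threshold)[0]]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def export_profiles_tsv(result: PRSResult, path) -> None:
    """Write effector and sensor profiles as TSV (residue, effector, sensor)."""
    n = result.n_residues
    with open(path, "w") as fh:
        fh.write("residue_index\teffector\tsensor\n")
        for i in range(n):
            fh.write(
                f"{i + 1}\t{result.effector_profile[i]:.6g}\t{result.sensor_profile[i]:.6g}\n"
            )
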