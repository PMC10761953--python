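"""Shared geometric primitives: Fibonacci sphere sampling and Kabsch superposition."""

from __future__ import annotations

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere via the golden-angle spiral.

    For k = 0..n-1: z_k = 1 - 2(k+0.5)/n, azimuth phi_k = k * pi * (3 - sqrt 5);
    the point is (sqrt(1-z^2) cos phi, sqrt(1-z^2) sin phi, z).

    Parameters
    ----------
    n_points : int
        Number of directions, >= 1.

    Returns
    -------
    (n_points, 3) array of unit vectors.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    k = np.arange(n_points, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    # renormalize to kill the last few ulps of rounding
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that mobile @ rotation.T +
    translation best matches reference in least squares. The rotation is
    proper (determinant +1): the SVD sign is corrected so reflections are
    never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be n x 3 with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    x = mobile - mob_c
    y = reference - ref_c
    # collinear sets leave the rotation about the line undetermined
    if min(np.linalg.matrix_rank(x, tol=1e-8), np.linalg.matrix_rank(y, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) point set: superposition is ill-posed")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    moved = x @ rot.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(translation, float)
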