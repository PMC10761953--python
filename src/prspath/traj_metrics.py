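"""Trajectory stability metrics.

Kabsch superposition, RMSD/RMSF/radius-of-gyration series, Shrake-Rupley
solvent-accessible surface area, geometric hydrogen-bond counting,
relative-frequency histograms, and k-means clustering of frames with
representative-structure selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from ._geometry import fibonacci_sphere, kabsch
from .elastic_network import superpose_frames
from .structure_io import CoordinateEnsemble, StructureModel

DEFAULT_N_BINS = 50
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960
#: Heavy-atom/hydrogen covalent bond length ceiling used by the donor heuristic.
_DH_BOND_MAX = 1.25


@dataclass
class MetricSeries:
    """A per-frame scalar series plus its relative-frequency histogram."""

    name: str  # "rmsd" | "rg" | "sasa" | "hbond_count"
    values: np.ndarray
    bin_edges: np.ndarray = field(default=None)
    frequencies: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_edges is None:
            self.bin_edges, self.frequencies = histogram(self.values)


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_da_distance`` bounds the donor-heavy to acceptor-heavy distance
    (inclusive); ``min_dha_angle`` is the minimum donor-hydrogen-acceptor
    angle in degrees (inclusive).
    """

    max_da_distance: float = 3.0
    min_dha_angle: float = 135.0

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass
class ClusterResult:
    """Frame labels and one representative frame index per cluster."""

    labels: np.ndarray
    representatives: list[int]
    k: int


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition; returns (rotation, translation, rmsd).

    The rotation is always proper (no reflection); fewer than 3 points or a
    collinear point set raises.
    """
    return kabsch(mobile, reference)


def rmsd_series(
    ensemble: CoordinateEnsemble,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
) -> MetricSeries:
    """Per-frame Kabsch RMSD against a reference frame (default: the first)."""
    if not 0 <= reference_frame < ensemble.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    mask = _resolve_selection(ensemble.n_atoms, selection)
    ref = ensemble.frames[reference_frame][mask]
    values = np.array(
        [kabsch(ensemble.frames[f][mask], ref)[2] for f in range(ensemble.n_frames)]
    )
    return MetricSeries(name="rmsd", values=values)


def rmsf(
    ensemble: CoordinateEnsemble, selection: np.ndarray | None = None
) -> np.ndarray:
    """Root-mean-square fluctuation per atom after superposition to the mean.

    All frames are superposed onto the iteratively refined mean structure,
    then ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)`` over frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mask = _resolve_selection(ensemble.n_atoms, selection)
    frames, mean = superpose_frames(ensemble.frames[:, mask, :])
    dev = frames - mean[None, :, :]
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def _resolve_selection(n_atoms: int, selection) -> np.ndarray:
    if selection is None:
        return np.ones(n_atoms, dtype=bool)
    mask = np.asarray(selection)
    if mask.dtype == bool:
        if mask.shape != (n_atoms,):
            raise ValueError("boolean selection must match atom count")
    else:
        idx = mask.astype(int)
        mask = np.zeros(n_atoms, dtype=bool)
        mask[idx] = True
    if not mask.any():
        raise ValueError("empty selection")
    return mask


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the center of mass, Angstrom."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one atom")
    m = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((coords - com) ** 2, axis=1)).sum() / m.sum()))


def rg_series(ensemble: CoordinateEnsemble, masses: np.ndarray | None = None) -> MetricSeries:
    values = np.array(
        [radius_of_gyration(ensemble.frames[f], masses) for f in range(ensemble.n_frames)]
    )
    return MetricSeries(name="rg", values=values)


def sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's accessible sphere (radius ``r_vdw + probe``) is tiled with
    Fibonacci test points; a point is exposed iff it lies outside every
    neighboring atom's expanded sphere.  Per-atom area is the exposed
    fraction of ``4 pi (r_vdw + probe)^2``.

    Returns
    -------
    (total area, per-atom areas) in square Angstrom.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = model.coords
    radii = np.array([a.vdw_radius for a in model.atoms]) + probe_radius
    n = len(radii)
    sphere = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return float(per_atom.sum()), per_atom


def sasa_series(
    ensemble: CoordinateEnsemble,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> MetricSeries:
    values = np.array(
        [
            sasa(ensemble.topology.with_coords(f), probe_radius, n_sphere_points)[0]
            for f in ensemble.frames
        ]
    )
    return MetricSeries(name="sasa", values=values)


def find_donor_hydrogens(
    model: StructureModel, donor_indices: list[int]
) -> list[tuple[int, int]]:
    """Pair each donor heavy atom with its covalently attached hydrogens.

    A hydrogen belongs to a donor if it is within 1.25 A (bonding heuristic)
    or, failing any such hydrogen, if its name marks it as attached
    (e.g. H/HA following the heavy-atom name).
    """
    coords = model.coords
    h_idx = [i for i, a in enumerate(model.atoms) if a.element == "H"]
    pairs = []
    for d in donor_indices:
        for h in h_idx:
            if np.linalg.norm(coords[h] - coords[d]) <= _DH_BOND_MAX:
                pairs.append((d, h))
    return pairs


def count_hbonds(
    model: StructureModel,
    donors: list[int],
    acceptors: list[int],
    criteria: HBondCriteria | None = None,
) -> int:
    """Count hydrogen bonds in one frame under geometric criteria.

    ``donors`` and ``acceptors`` are 0-based atom indices of heavy atoms.
    A (D, A) pair is counted at most once per frame even if several attached
    hydrogens satisfy the angle criterion; both cutoffs are inclusive.
    """
    if criteria is None:
        criteria = HBondCriteria()
    if not donors or not acceptors:
        raise ValueError("donor and acceptor selections must be non-empty")
    coords = model.coords
    dh_pairs = find_donor_hydrogens(model, donors)
    bonded: set[tuple[int, int]] = set()
    cos_max = np.cos(np.deg2rad(criteria.min_dha_angle))
    for d, h in dh_pairs:
        for a in acceptors:
            if a == d or (d, a) in bonded:
                continue
            da = np.linalg.norm(coords[a] - coords[d])
            if da > criteria.max_da_distance:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            # angle >= min_dha_angle  <=>  cos(angle) <= cos(min_dha_angle)
            if (v1 @ v2) / denom <= cos_max + 1e-12:
                bonded.add((d, a))
    return len(bonded)


def hbond_series(
    ensemble: CoordinateEnsemble,
    donors: list[int],
    acceptors: list[int],
    criteria: HBondCriteria | None = None,
) -> MetricSeries:
    """Per-frame hydrogen-bond counts between donor and acceptor selections."""
    values = np.array(
        [
            count_hbonds(ensemble.topology.with_coords(f), donors, acceptors, criteria)
            for f in ensemble.frames
        ],
        dtype=float,
    )
    return MetricSeries(name="hbond_count", values=values)


def histogram(values: np.ndarray, n_bins: int = DEFAULT_N_BINS):
    """Equal-width relative-frequency histogram spanning [min, max].

    Frequencies sum to 1; the right-most bin is inclusive of the maximum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts / values.size


def cluster_frames(
    ensemble: CoordinateEnsemble, k: int = 10, seed: int = 0
) -> ClusterResult:
    """k-means clustering of superposed frames with representative selection.

    Frames are superposed to the iterated mean, flattened, and clustered with
    k-means++ seeding from the fixed seed (at most 500 iterations, centroid
    shift tolerance 1e-6).  The representative of each cluster is the member
    frame nearest its centroid.  Euclidean distance on superposed flattened
    coordinates approximates pairwise-RMSD clustering.
    """
    if not 1 <= k <= ensemble.n_frames:
        raise ValueError(f"k must lie in 1..{ensemble.n_frames}, got {k}")
    frames, _ = superpose_frames(ensemble.frames)
    flat = frames.reshape(ensemble.n_frames, -1)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=500, tol=1e-6,
        random_state=seed,
    ).fit(flat)
    labels = km.labels_
    reps = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        if members.size == 0:
            continue
        d = np.linalg.norm(flat[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(members[np.argmin(d)]))
    return ClusterResult(labels=labels, representatives=reps, k=k)


def export_series_tsv(series: MetricSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"frame\t{series.name}\n")
        for f, v in enumerate(series.values):
            fh.write(f"{f}\t{v:.6g}\n")


def export_histogram_tsv(series: MetricSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_left\tbin_right\trelative_frequency\n")
        for lo, hi, fr in zip(series.bin_edges[:-1], series.bin_edges[1:], series.frequencies):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{fr:.6g}\n")
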