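"""Synthetic structures and ensembles with known ground truth.

Every other module is exercised against these generators: ideal CA helices
and bead chains with analytic geometry, two-domain "dumbbell" structures
whose only inter-domain connection is a planted channel of residues (so the
true allosteric route is known by construction), normal-mode-sampled
ensembles whose population covariance is the generating ANM covariance,
and small hand-built all-atom fragments for surface-area and hydrogen-bond
geometry.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .elastic_network import ElasticNetwork
from .structure_io import AtomRecord, CoordinateEnsemble, StructureModel, VDW_RADII

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_RADIUS = 2.3  # Angstrom
HELIX_TWIST_DEG = 100.0  # degrees per residue
_MIN_BEAD_SEPARATION = 3.5  # Angstrom, CA excluded-volume floor
_MAX_RETRIES = 500


def _ca_model(coords: np.ndarray, title: str) -> StructureModel:
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            residue_name="ALA",
            residue_index=i + 1,
            chain_id="A",
            position=c,
            vdw_radius=VDW_RADII["C"],
        )
        for i, c in enumerate(np.asarray(coords, float))
    ]
    return StructureModel(atoms=atoms, title=title)


def make_helix(n_residues: int) -> StructureModel:
    """CA trace of an ideal alpha-helix (rise 1.5 A, radius 2.3 A, 100 deg/residue)."""
    if n_residues < 3:
        raise ValueError(f"helix needs at least 3 residues, got {n_residues}")
    k = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * k
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * k]
    )
    return _ca_model(coords, f"ideal helix n={n_residues}")


def make_chain(n_residues: int, spacing: float = 3.8) -> StructureModel:
    """Straight CA bead chain along x with uniform spacing (default 3.8 A).

    Collinear by construction: useful for subsampling and contact-graph
    tests, deliberately degenerate for ANM building.
    """
    if n_residues < 1:
        raise ValueError("chain needs at least 1 residue")
    coords = np.column_stack(
        [spacing * np.arange(n_residues), np.zeros(n_residues), np.zeros(n_residues)]
    )
    return _ca_model(coords, f"bead chain n={n_residues}")


def _sample_domain(
    rng: np.random.Generator, n_points: int, radius: float
) -> np.ndarray:
    """Compact random bead cluster inside a sphere with excluded volume."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_points:
        if attempts > _MAX_RETRIES * n_points:
            raise RuntimeError(
                "geometric placement failure: could not pack domain beads "
                f"(n={n_points}, radius={radius:.1f})"
            )
        attempts += 1
        cand = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(cand) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) < _MIN_BEAD_SEPARATION:
            continue
        pts.append(cand)
    return np.asarray(pts)


def _graph_connected(coords: np.ndarray, cutoff: float, exclude: set[int] = frozenset()):
    keep = [i for i in range(len(coords)) if i not in exclude]
    sub = coords[keep]
    if len(sub) == 0:
        return True
    dist = squareform(pdist(sub)) if len(sub) > 1 else np.zeros((1, 1))
    adj = (dist <= cutoff) & ~np.eye(len(sub), dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1


def _six_zero_modes(coords: np.ndarray, cutoff: float) -> bool:
    from .elastic_network import build_anm_hessian

    try:
        net = build_anm_hessian(coords, cutoff_rc=cutoff)
    except ValueError:
        return False
    evals = np.linalg.eigvalsh(net.hessian)
    return int(np.sum(np.abs(evals) < 1e-8 * np.max(np.abs(evals)))) == 6


def make_dumbbell(
    n_per_domain: int,
    channel_residues: int = 3,
    seed: int = 0,
    cutoff: float = 10.0,
    anm_cutoff: float = 16.0,
) -> tuple[StructureModel, list[int]]:
    """Two compact random domains bridged only by a planted channel of beads.

    At the contact cutoff the ONLY inter-domain contacts run through the
    channel, whose middle ("waist") bead is a graph cut vertex: every
    inter-domain path must cross it.  Direct domain-domain bead distances
    all exceed the cutoff, which is asserted at generation time along with
    full-graph connectivity and channel-removal disconnection.  The moat
    around the waist keeps an elastic network built at the contact cutoff
    constraint-starved (hinge mechanisms), so the spectral guarantee —
    exactly six rigid-body zero modes, asserted at generation — is made at
    the larger ``anm_cutoff`` (default 1.6x the contact cutoff), where
    enough springs bridge the waist to pin the articulation.  Build ANMs of
    dumbbells at ``anm_cutoff``.  Residues are numbered domain A (1..n),
    channel (n+1..n+c), domain B (n+c+1..2n+c).

    Returns
    -------
    (StructureModel, channel residue indices) — the ground-truth channel.
    """
    if n_per_domain < 5:
        raise ValueError("n_per_domain must be >= 5")
    if channel_residues < 1:
        raise ValueError("channel_residues must be >= 1")
    rng = np.random.default_rng(seed)
    # sphere sized for the excluded-volume packing, with slack for rejection
    radius = max(4.5, (20.0 * n_per_domain) ** (1.0 / 3.0))
    # Channel layout: an arc of beads hugs each domain's channel-facing
    # surface cap (each arc bead sits `gap` above the sphere, so all arc
    # beads touch many cap beads and their arc neighbors), and the two arcs
    # meet at a single "waist" bead that is a graph cut vertex — everything
    # on the A side sits farther than the contact cutoff from everything on
    # the B side, so every inter-domain path must cross the waist.  A
    # single-point articulation would leave rigid pivot modes in an elastic
    # network built at the same cutoff, which is why the spectral guarantee
    # is made at the larger anm_cutoff where the arc ends bridge the waist.
    gap = 0.35 * cutoff  # domain surface to arc shell
    waist_gap = 0.55 * cutoff  # arc end to waist; 2*waist_gap > cutoff
    wobble = 0.08 * cutoff  # out-of-plane jitter so spring directions span 3-D
    shell = radius + gap
    arc_step = 2.0 * np.arcsin(0.2 * cutoff / shell)  # ~4 A chords: arc stays dense
    n_arc_a = channel_residues // 2  # beads before the waist
    n_arc_b = channel_residues - 1 - n_arc_a

    def _arc(n_beads: int) -> np.ndarray:
        # ordered from the far end of the arc down to the axial bead (k=0)
        k = np.arange(n_beads)[::-1]
        theta = arc_step * k
        return np.column_stack([
            shell * np.cos(theta),
            shell * np.sin(theta),
            wobble * np.where(k % 2, 1.0, -1.0),
        ])

    for attempt in range(_MAX_RETRIES):
        dom_a = _sample_domain(rng, n_per_domain, radius)
        dom_b_local = _sample_domain(rng, n_per_domain, radius)
        arc_a = _arc(n_arc_a)
        waist_x = (arc_a[-1, 0] + waist_gap) if n_arc_a else (radius + waist_gap)
        waist = np.array([[waist_x, 0.0, 0.0]])
        arc_b_local = _arc(n_arc_b)[::-1] * np.array([-1.0, 1.0, 1.0])
        # domain B sits so its axial arc bead (or its pole, for an empty
        # B arc) lies waist_gap beyond the waist
        b_center = waist_x + waist_gap + (shell if n_arc_b else radius)
        arc_b = arc_b_local + np.array([b_center, 0.0, 0.0])
        channel = np.vstack([arc_a, waist, arc_b])
        # generic off-plane jitter: coplanar channel beads would leave the
        # two halves an exact torsion mechanism about the dumbbell axis
        channel[:, 1:] += rng.uniform(-0.6, 0.6, size=(len(channel), 2))
        dom_b = dom_b_local + np.array([b_center, 0.0, 0.0])

        coords = np.vstack([dom_a, channel, dom_b])
        n = n_per_domain
        c = channel_residues
        channel_idx = list(range(n + 1, n + c + 1))  # 1-based
        # direct A-B contacts must not exist
        cross = np.linalg.norm(dom_a[:, None, :] - dom_b[None, :, :], axis=2)
        if cross.min() <= cutoff:
            continue
        if not _graph_connected(coords, cutoff):
            continue
        if _graph_connected(coords, cutoff, exclude={i - 1 for i in channel_idx}):
            continue  # channel removal must disconnect the graph
        if not _six_zero_modes(coords, anm_cutoff):
            continue  # sparse junction contacts can leave spurious soft modes
        model = _ca_model(coords, f"dumbbell n={n} channel={c} seed={seed}")
        return model, channel_idx
    raise RuntimeError("geometric placement failure: dumbbell construction did not converge")


def sample_anm_ensemble(
    network: ElasticNetwork,
    n_frames: int,
    kT: float = 1.0,
    seed: int = 0,
    topology: StructureModel | None = None,
) -> CoordinateEnsemble:
    """Draw frames from the Gaussian equilibrium distribution of an ANM.

    Frames are ``mean + sum_k sqrt(kT / lambda_k) z_k v_k`` over the non-zero
    modes with ``z_k`` iid standard normal, so the population covariance of
    the frames is exactly the ANM pseudo-inverse covariance at temperature kT.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    evals, evecs = np.linalg.eigh(network.hessian)
    lam_max = float(np.max(np.abs(evals)))
    nonzero = np.abs(evals) > 1e-8 * lam_max
    if np.sum(~nonzero) != 6:
        raise ValueError("degenerate network: expected exactly 6 zero modes")
    lam = evals[nonzero]
    modes = evecs[:, nonzero]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, lam.size))
    amps = z * np.sqrt(kT / lam)[None, :]
    flat = network.positions.reshape(-1)[None, :] + amps @ modes.T
    frames = flat.reshape(n_frames, -1, 3)
    if topology is None:
        topology = _ca_model(network.positions, "ANM-sampled ensemble")
    return CoordinateEnsemble(topology=topology, frames=frames)


def make_water_dimer(
    oo_distance: float = 2.8, dha_angle_deg: float = 180.0
) -> StructureModel:
    """Two waters with a controllable O-H...O hydrogen-bond geometry.

    The donor O sits at the origin with one H at 0.96 A along +x; the
    acceptor O is placed at ``oo_distance`` so that the D-H...A angle equals
    ``dha_angle_deg``.  The second donor H and the acceptor's hydrogens
    point away from the bond axis.
    """
    oh = 0.96
    d = np.array([0.0, 0.0, 0.0])
    h1 = np.array([oh, 0.0, 0.0])
    # acceptor direction from H1 making the requested D-H...A angle with H1->D,
    # then the H->A length t solves |h1 + t*u| = oo_distance (positive root)
    u = np.array([np.cos(np.pi - np.deg2rad(dha_angle_deg)),
                  np.sin(np.pi - np.deg2rad(dha_angle_deg)), 0.0])
    b = 2 * h1 @ u
    cc = h1 @ h1 - oo_distance**2
    t = (-b + np.sqrt(b * b - 4 * cc)) / 2.0
    a = h1 + t * u
    h2 = d + np.array([-0.32, 0.90, 0.0])  # second donor H, away from the bond
    ha1 = a + np.array([0.0, 0.0, 0.96])
    ha2 = a + np.array([0.0, 0.90, -0.32])
    specs = [
        ("O", "O", d), ("H1", "H", h1), ("H2", "H", h2),
        ("O", "O", a), ("H1", "H", ha1), ("H2", "H", ha2),
    ]
    atoms = [
        AtomRecord(
            serial=i + 1, name=nm, element=el, residue_name="HOH",
            residue_index=1 + i // 3, chain_id="W", position=pos,
            vdw_radius=VDW_RADII[el],
        )
        for i, (nm, el, pos) in enumerate(specs)
    ]
    return StructureModel(atoms=atoms, title="water dimer")
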