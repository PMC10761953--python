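"""Structure and ensemble I/O.

Reads and writes PDB coordinate files (fixed-column ATOM/HETATM dialect,
MODEL/ENDMDL blocks) and plain multi-frame XYZ files, selects CA subsets,
and performs the stride-based residue subsampling used to compress large
chains before network analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Default van der Waals radii (Angstrom) for the elements that occur in
#: protein heavy atoms plus hydrogen.  Unknown elements raise unless the
#: caller supplies an explicit radius table.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

#: Three-letter codes accepted as amino-acid residues by :func:`select_ca`.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/disulfide variants produced by modelling tools
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}


@dataclass
class AtomRecord:
    """One atom: identity, position (Angstrom) and van der Waals radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass
class StructureModel:
    """An ordered collection of atoms from one conformer."""

    atoms: list[AtomRecord]
    title: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms=atoms, title=self.title)


@dataclass
class CoordinateEnsemble:
    """A topology plus an ordered stack of coordinate frames."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (used when columns 77-78 are blank).

    Strips digits and primes, then takes the leading character; names beginning
    with a digit (e.g. ``1HB``) or with H are hydrogens.
    """
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


def _resolve_radius(element: str, radius_table: dict[str, float]) -> float:
    try:
        return radius_table[element]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {element!r}; "
            "supply a radius via radius_table"
        ) from None


def _parse_pdb_atom(line: str, radius_table: dict[str, float]) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        residue_index = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparseable ATOM/HETATM record: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name)
    element = element.upper()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_index=residue_index,
        chain_id=chain_id,
        position=np.array([x, y, z]),
        vdw_radius=_resolve_radius(element, radius_table),
    )


def read_structure(
    path, model_index: int = 1, radius_table: dict[str, float] | None = None
) -> StructureModel:
    """Read one MODEL of a PDB file.

    Parameters
    ----------
    path : path-like
        PDB file with ATOM/HETATM records; MODEL/ENDMDL blocks optional.
    model_index : int
        1-based model to extract; files without MODEL records are model 1.
    radius_table : dict, optional
        Element -> van der Waals radius (Angstrom) overriding the defaults.

    Raises
    ------
    FileNotFoundError, ValueError, IndexError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if model_index < 1:
        raise ValueError(f"model_index must be >= 1, got {model_index}")
    table = dict(VDW_RADII)
    if radius_table:
        table.update(radius_table)

    title = ""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    saw_model_record = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                saw_model_record = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_atom(line, table))
            # ANISOU, TER, REMARK etc. intentionally ignored
    if current or not models:
        if current:
            models.append(current)
    if not saw_model_record:
        models = [sum(models, [])] if len(models) > 1 else models
    if not models or not any(models):
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    if model_index > len(models):
        raise IndexError(
            f"{path}: model {model_index} requested but file has {len(models)} model(s)"
        )
    atoms = models[model_index - 1]
    if not atoms:
        raise ValueError(f"{path}: model {model_index} contains no atoms")
    return StructureModel(atoms=atoms, title=title)


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    with open(path, "w") as fh:
        if model.title:
            fh.write(f"TITLE     {model.title}\n")
        _write_atom_block(fh, model)
        fh.write("END\n")


def _write_atom_block(fh, model: StructureModel) -> None:
    for atom in model.atoms:
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        fh.write(
            "ATOM  {serial:>5d} {name:<4s} {res:<3s} {chain:1s}{resi:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                serial=atom.serial % 100000,
                name=name,
                res=atom.residue_name,
                chain=atom.chain_id,
                resi=atom.residue_index % 10000,
                x=atom.position[0],
                y=atom.position[1],
                z=atom.position[2],
                occ=1.0,
                b=0.0,
                el=atom.element,
            )
        )


def select_ca(model: StructureModel) -> StructureModel:
    """Keep one CA atom per amino-acid residue, in file order.

    The first CA record of a residue wins when altloc duplicates are present.

    Raises
    ------
    ValueError : if the model is empty or contains no CA atoms.
    """
    if model.n_atoms == 0:
        raise ValueError("empty model")
    seen: set[tuple[str, int]] = set()
    kept: list[AtomRecord] = []
    for atom in model.atoms:
        if atom.name != "CA" or atom.residue_name not in AMINO_ACIDS:
            continue
        key = (atom.chain_id, atom.residue_index)
        if key in seen:
            continue
        seen.add(key)
        kept.append(atom)
    if not kept:
        raise ValueError("no CA atoms found in model")
    return StructureModel(atoms=kept, title=model.title)


def subsample_residues(model: StructureModel, stride: int) -> StructureModel:
    """Keep residues at ordinal positions 1, 1+stride, 1+2*stride, ...

    On a CA-only model of N residues this returns floor((N-1)/stride) + 1
    residues; e.g. a 1332-residue chain at stride 10 compresses to 134.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if any(a.name != "CA" for a in model.atoms):
        raise ValueError("subsample_residues expects a CA-only model")
    return StructureModel(atoms=model.atoms[::stride], title=model.title)


# ---------------------------------------------------------------------------
# Ensembles


def read_ensemble(
    path, radius_table: dict[str, float] | None = None, frame_interval: float = 1.0
) -> CoordinateEnsemble:
    """Read a coordinate ensemble from a multi-model PDB or a multi-frame XYZ file.

    The topology is taken from the first frame; every subsequent frame must
    have the same atom count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        head = fh.read(2048)
    if re.search(r"^(ATOM  |HETATM|MODEL )", head, flags=re.M):
        return _read_pdb_ensemble(path, radius_table, frame_interval)
    return _read_xyz_ensemble(path, radius_table, frame_interval)


def _read_pdb_ensemble(path, radius_table, frame_interval) -> CoordinateEnsemble:
    topology = read_structure(path, model_index=1, radius_table=radius_table)
    frames = [topology.coords]
    idx = 2
    while True:
        try:
            model = read_structure(path, model_index=idx, radius_table=radius_table)
        except IndexError:
            break
        if model.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: frame {idx} has {model.n_atoms} atoms, expected {topology.n_atoms}"
            )
        frames.append(model.coords)
        idx += 1
    return CoordinateEnsemble(
        topology=topology, frames=np.stack(frames), frame_interval=frame_interval
    )


def _read_xyz_ensemble(path, radius_table, frame_interval) -> CoordinateEnsemble:
    table = dict(VDW_RADII)
    if radius_table:
        table.update(radius_table)
    frames: list[np.ndarray] = []
    first_atoms: list[AtomRecord] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n_atoms = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from exc
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise ValueError(
                f"{path}: inconsistent atom counts across frames ({count} vs {n_atoms})"
            )
        i += 2  # skip the comment line
        coords = np.empty((count, 3))
        atoms: list[AtomRecord] = []
        for j in range(count):
            parts = lines[i + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed XYZ atom line {i + j + 1}")
            el = parts[0].upper()
            coords[j] = [float(p) for p in parts[1:4]]
            if first_atoms is None:
                atoms.append(
                    AtomRecord(
                        serial=j + 1,
                        name=el,
                        element=el,
                        residue_name="UNK",
                        residue_index=j + 1,
                        chain_id="A",
                        position=coords[j],
                        vdw_radius=_resolve_radius(el, table),
                    )
                )
        if first_atoms is None:
            first_atoms = atoms
        frames.append(coords)
        i += count
    if not frames:
        raise ValueError(f"{path}: zero frames")
    topology = StructureModel(atoms=first_atoms, title="")
    return CoordinateEnsemble(
        topology=topology, frames=np.stack(frames), frame_interval=frame_interval
    )


def write_ensemble(ensemble: CoordinateEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    with open(path, "w") as fh:
        if ensemble.topology.title:
            fh.write(f"TITLE     {ensemble.topology.title}\n")
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            _write_atom_block(fh, ensemble.topology.with_coords(ensemble.frames[f]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Residue selections


def parse_selection(spec: str | Iterable[int]) -> list[int]:
    """Parse a residue selection like ``"804,907-914,1261"`` into a sorted list.

    Accepts an iterable of ints unchanged (deduplicated and sorted).
    """
    if not isinstance(spec, str):
        return sorted(set(int(i) for i in spec))
    out: set[int] = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token[1:]:  # allow a leading minus to fail loudly below
            lo, hi = token.split("-", 1)
            lo_i, hi_i = int(lo), int(hi)
            if hi_i < lo_i:
                raise ValueError(f"descending range {token!r}")
            out.update(range(lo_i, hi_i + 1))
        else:
            out.add(int(token))
    if not out:
        raise ValueError(f"empty selection {spec!r}")
    return sorted(out)
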