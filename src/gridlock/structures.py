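"""PDB structure I/O and docking preprocessing.

A molecule entering the docking engine is an ordered list of atom records
carrying, besides the usual PDB fields, two flags the engine consumes:

* ``is_surface`` — whether the atom lies on the molecular surface.  Surface
  atoms carry the favorable shape-complementarity score during
  discretization; buried (core) atoms carry the clash penalty.
* ``blocked`` — user-requested suppression of favorable scoring for this
  atom's residue (e.g. antibody framework regions, so that predictions are
  steered toward the CDR loops).  A blocked atom is discretized with the
  core value regardless of its surface flag.

Surface detection here is a neighbor-count proxy: an atom is a surface atom
iff the number of other atoms within ``neighbor_radius`` is at most
``neighbor_max``.  The proxy is deterministic, parameter-explicit and
dependency-free; it is not claimed to match any particular solvent
accessibility definition, and both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

RECEPTOR = "receptor"
LIGAND = "ligand"

__all__ = [
    "AtomRecord",
    "Molecule",
    "RECEPTOR",
    "LIGAND",
    "read_pdb",
    "write_pdb",
    "write_complex_pdb",
    "mark_surface",
    "interface_residues",
    "block_residues",
    "read_block_list",
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record with docking annotations."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # (3,) Å
    is_surface: bool = False
    blocked: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=np.float64)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be finite")
        object.__setattr__(self, "position", pos)
        if self.serial < 1:
            raise ValueError(f"atom serial must be >= 1, got {self.serial}")

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Molecule:
    """Ordered atom list with a label and a docking role.

    Atom order is preserved from the source file; every operation that
    returns a new molecule keeps the order.
    """

    atoms: list[AtomRecord]
    label: str = ""
    role: str = RECEPTOR

    def __post_init__(self) -> None:
        if self.role not in (RECEPTOR, LIGAND):
            raise ValueError(f"role must be '{RECEPTOR}' or '{LIGAND}', got {self.role!r}")
        self.atoms = list(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom coordinates as an (n, 3) float64 array (Å)."""
        if not self.atoms:
            return np.empty((0, 3), dtype=np.float64)
        return np.stack([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of the molecule with replaced coordinates, flags preserved."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Molecule(atoms, label=self.label, role=self.role)

    def with_role(self, role: str) -> "Molecule":
        return Molecule(self.atoms, label=self.label, role=role)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Residue identifiers (chain, number) in first-occurrence order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)


def _require_nonempty(molecule: Molecule, op: str) -> None:
    if len(molecule) == 0:
        raise ValueError(f"{op} requires a non-empty molecule")


def read_pdb(
    path: str | Path,
    *,
    role: str = RECEPTOR,
    label: str | None = None,
    include_hetatm: bool = False,
) -> Molecule:
    """Read a PDB file into a :class:`Molecule`.

    The first model of a multi-model file is used; alternate locations keep
    the first occurrence.  HETATM records are skipped unless
    ``include_hetatm`` is set, so toy and real inputs behave alike.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pdb_file = pdb.PDBFile.read(str(path))
    structure = pdb_file.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    if not include_hetatm:
        structure = structure[~structure.hetero]
    n = structure.array_length()
    if n == 0:
        raise ValueError(f"no ATOM records found in {path}")
    atoms = []
    for i in range(n):
        serial = int(structure.atom_id[i])
        atoms.append(
            AtomRecord(
                serial=serial if serial >= 1 else i + 1,
                name=str(structure.atom_name[i]),
                residue_name=str(structure.res_name[i]),
                chain_id=str(structure.chain_id[i]),
                residue_number=int(structure.res_id[i]),
                position=np.asarray(structure.coord[i], dtype=np.float64),
            )
        )
    return Molecule(atoms, label=label if label is not None else path.stem, role=role)


def _element_guess(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


def _to_atom_array(molecule: Molecule, chain_override: str | None = None) -> struc.AtomArray:
    n = len(molecule)
    arr = struc.AtomArray(n)
    arr.coord = molecule.coords.astype(np.float32)
    arr.chain_id = np.array(
        [chain_override or a.chain_id for a in molecule.atoms], dtype="U4"
    )
    arr.res_id = np.array([a.residue_number for a in molecule.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in molecule.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in molecule.atoms], dtype="U6")
    arr.element = np.array([_element_guess(a.name) for a in molecule.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(molecule: Molecule, path: str | Path) -> None:
    """Write a molecule as fixed-column PDB ATOM records (coordinates %8.3f)."""
    _require_nonempty(molecule, "write_pdb")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_to_atom_array(molecule))
    pdb_file.write(str(path))


def write_complex_pdb(receptor: Molecule, ligand: Molecule, path: str | Path) -> None:
    """Write a two-molecule complex as a single multi-chain PDB file."""
    _require_nonempty(receptor, "write_complex_pdb")
    _require_nonempty(ligand, "write_complex_pdb")
    arr = _to_atom_array(receptor) + _to_atom_array(ligand)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def mark_surface(
    molecule: Molecule,
    neighbor_radius: float = 6.0,
    neighbor_max: int = 24,
) -> Molecule:
    """Flag surface atoms by the neighbor-count criterion.

    An atom is a surface atom iff the number of *other* atoms within
    ``neighbor_radius`` Å is at most ``neighbor_max``.  Permutation of atom
    order does not change the flags.
    """
    _require_nonempty(molecule, "mark_surface")
    if neighbor_radius <= 0:
        raise ValueError("neighbor_radius must be positive")
    tree = cKDTree(molecule.coords)
    counts = tree.query_ball_point(
        molecule.coords, r=neighbor_radius, return_length=True
    ) - 1  # exclude self
    atoms = [
        replace(a, is_surface=bool(c <= neighbor_max))
        for a, c in zip(molecule.atoms, counts)
    ]
    return Molecule(atoms, label=molecule.label, role=molecule.role)


def interface_residues(
    receptor: Molecule,
    ligand: Molecule,
    cutoff: float = 10.0,
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Residues of each molecule with any atom within ``cutoff`` of the partner.

    Returns two sets of ``(chain_id, residue_number)`` identifiers, one per
    molecule.  Symmetric under exchanging the molecules (sets swap).
    """
    _require_nonempty(receptor, "interface_residues")
    _require_nonempty(ligand, "interface_residues")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree_r = cKDTree(receptor.coords)
    tree_l = cKDTree(ligand.coords)
    pairs = tree_r.query_ball_tree(tree_l, cutoff)
    rec_set: set[tuple[str, int]] = set()
    lig_set: set[tuple[str, int]] = set()
    for i, js in enumerate(pairs):
        if js:
            rec_set.add(receptor.atoms[i].residue_id)
            for j in js:
                lig_set.add(ligand.atoms[j].residue_id)
    return rec_set, lig_set


def block_residues(
    molecule: Molecule,
    residues: Iterable[tuple[str, int] | int],
) -> Molecule:
    """Set the ``blocked`` flag on the listed residues.

    Entries are ``(chain_id, residue_number)`` pairs, or bare residue
    numbers which match any chain.
    """
    _require_nonempty(molecule, "block_residues")
    pairs: set[tuple[str, int]] = set()
    numbers: set[int] = set()
    for r in residues:
        if isinstance(r, tuple):
            pairs.add((str(r[0]), int(r[1])))
        else:
            numbers.add(int(r))
    atoms = [
        replace(
            a,
            blocked=a.blocked
            or a.residue_id in pairs
            or a.residue_number in numbers,
        )
        for a in molecule.atoms
    ]
    return Molecule(atoms, label=molecule.label, role=molecule.role)


def read_block_list(path: str | Path) -> list[tuple[str, int] | int]:
    """Parse a per-residue blocking list.

    One residue per line: either ``<chain> <resnum>`` or a bare ``<resnum>``.
    Blank lines and ``#`` comments are ignored.
    """
    entries: list[tuple[str, int] | int] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        try:
            if len(parts) == 1:
                entries.append(int(parts[0]))
            elif len(parts) == 2:
                entries.append((parts[0], int(parts[1])))
            else:
                raise ValueError
        except ValueError:
            raise ValueError(f"malformed block-list line {lineno}: {raw!r}") from None
    return entries
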