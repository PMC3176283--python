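"""Deterministic synthetic molecules and planted complexes.

Real docking benchmarks require curated structure downloads; every stage of
this engine is instead testable against synthetic molecules built here.
Molecules are jittered cubic-lattice atom clouds (2 Å sites, ±0.3 Å
jitter) shaped as:

* ``globular`` — a ball,
* ``rod``      — a 3:1:1 ellipsoid, echoing elongated receptors for which
  a rotated rectangular grid is much smaller than a cubic one,
* ``ell``      — two rod arms meeting at a corner,
* ``knob``     — three unequal lobes (a 5 Å head, a 3 Å inner lobe along
  the burial axis and a 3 Å lateral bump), the default ligand: the shape
  has no rotational symmetry about any axis, so no flip, spin or slide
  superimposes it on itself and a recovered pose is unambiguous.

Every atom is a generic pseudo-atom *named* ``CA`` in its own one-atom
residue, so interface detection and Cα-RMSD evaluation operate unchanged.
Surface flags use the neighbor-count criterion with parameters matched to
the lattice (radius between the second and third neighbor shells, count
cut between a face atom and an interior one), which marks exactly the
outermost atom layer as surface and leaves a solid core — the
protein-like regime the shape-complementarity channel assumes, in which
pressing into the partner is stopped by its interior.

:func:`make_planted_complex` builds a bound complex with a genuinely
shape-complementary interface: the knob ligand is planted head-out at the
receptor's +x surface apex, inner lobe enclosed, and the receptor is
carved around it with a clearance just under the lattice spacing, leaving
a socket the knob uniquely fills; atoms exposed by carving are flagged
surface explicitly, since a concave lining keeps too many neighbors for
the count criterion to see it.  The input-frame ligand is the bound
ligand de-rotated by a recorded *planted pose*, so search-and-reconstruct
tests can verify that docking with the planted rotation in its sampling
set recovers the bound coordinates.

All generators are pure functions of their spec: the same seed yields
bit-identical molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import EulerAngles, euler_from_matrix, rotation_matrix
from .structures import LIGAND, RECEPTOR, AtomRecord, Molecule, mark_surface

LATTICE_SPACING = 2.0  # Å between atom sites
JITTER = 0.1  # Å uniform jitter per coordinate; small enough to keep neighbor shells separated
# radius between the 2nd (3.46 Å) and 3rd (4.0 Å) lattice neighbor shells, and a
# count cut between a boundary atom (17 in-molecule neighbors) and an interior
# one (26): marks exactly the outermost atom layer as surface.
SURFACE_RADIUS = 3.7
SURFACE_MAX_NEIGHBORS = 21
# carve clearance just under the lattice spacing: sites coincident with the
# ligand are removed but lattice-adjacent ones (2 Å) survive, so the bound
# interface is a packed lattice continuation and the score optimum
CARVE_CLEARANCE = 1.9

__all__ = [
    "ToyComplexSpec",
    "PlantedComplex",
    "make_molecule",
    "make_planted_complex",
]

_SHAPE_AXES = {
    # ellipsoid semi-axis ratios per shape class
    "globular": ((1.0, 1.0, 1.0),),
    "rod": ((3.0, 1.0, 1.0),),
    "ell": ((3.0, 1.0, 1.0), (1.0, 3.0, 1.0)),
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a planted toy complex."""

    seed: int = 0
    receptor_shape: str = "globular"
    ligand_shape: str = "knob"
    receptor_atoms: int = 700
    ligand_atoms: int = 80
    planted_pose: tuple[EulerAngles, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.receptor_atoms < 4 or self.ligand_atoms < 4:
            raise ValueError("each molecule needs at least 4 atoms")
        if self.receptor_shape not in ("globular", "rod", "ell"):
            raise ValueError(f"unknown receptor shape {self.receptor_shape!r}")
        if self.ligand_shape not in ("globular", "knob"):
            raise ValueError(f"unknown ligand shape {self.ligand_shape!r}")


def _lattice_sites(half_extent: int = 12) -> np.ndarray:
    r = np.arange(-half_extent, half_extent + 1)
    x, y, z = np.meshgrid(r, r, r, indexing="ij")
    return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1) * LATTICE_SPACING


def _shape_norm(shape: str, sites: np.ndarray) -> np.ndarray:
    if shape == "knob":
        # three unequal lobes: a 5 Å head ball, a 3 Å inner ball along the
        # burial axis (x) and a 3 Å lateral bump (+y).  Bound with the
        # inner lobe enclosed in a carved socket, the shape has no
        # rotational symmetry — continuous or discrete — about any axis,
        # so the planted orientation is the unique snug fit.
        n1 = np.linalg.norm(sites, axis=1) / 5.0
        n2 = np.linalg.norm(sites - np.array([-6.0, 0.0, 0.0]), axis=1) / 3.0
        n3 = np.linalg.norm(sites - np.array([0.0, 5.5, 0.0]), axis=1) / 3.0
        return np.minimum(np.minimum(n1, n2), n3)
    if shape not in _SHAPE_AXES:
        raise ValueError(f"unknown shape label {shape!r}")
    norm = np.full(len(sites), np.inf)
    for axes in _SHAPE_AXES[shape]:
        a = np.asarray(axes, dtype=np.float64)
        # second arm of the "ell" is offset so the arms meet near the origin
        offset = np.zeros(3)
        if len(_SHAPE_AXES[shape]) > 1:
            offset = (a != a.min()) * LATTICE_SPACING * 2.0
        scaled = (sites - offset) / a
        norm = np.minimum(norm, np.linalg.norm(scaled, axis=1))
    return norm


def _select_sites(shape: str, n_atoms: int) -> np.ndarray:
    """The n lattice sites of smallest shape-norm, in deterministic order."""
    sites = _lattice_sites()
    norm = _shape_norm(shape, sites)
    if n_atoms > len(sites):
        raise ValueError(f"atom count {n_atoms} exceeds lattice capacity {len(sites)}")
    order = np.argsort(norm, kind="stable")
    return sites[order[:n_atoms]]


def _as_molecule(coords: np.ndarray, label: str, role: str) -> Molecule:
    chain = "A" if role == RECEPTOR else "B"
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="GLY",
            chain_id=chain,
            residue_number=i + 1,
            position=c,
        )
        for i, c in enumerate(coords)
    ]
    return mark_surface(
        Molecule(atoms, label=label, role=role), SURFACE_RADIUS, SURFACE_MAX_NEIGHBORS
    )


def make_molecule(
    shape: str,
    n_atoms: int,
    seed: int,
    label: str = "toy",
    role: str = RECEPTOR,
) -> Molecule:
    """A seeded pseudo-random atom cloud of the requested shape class."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    coords = _select_sites(shape, n_atoms) + rng.uniform(-JITTER, JITTER, (n_atoms, 3))
    return _as_molecule(coords, label, role)


@dataclass(frozen=True)
class PlantedComplex:
    """A toy complex with its bound reference and the planted pose."""

    receptor: Molecule  # docking input (identical to ref_receptor)
    ligand: Molecule  # docking input, de-rotated/displaced by the planted pose
    ref_receptor: Molecule  # bound reference
    ref_ligand: Molecule  # bound reference
    planted_pose: tuple[EulerAngles, np.ndarray]


def _bound_ligand_coords(
    spec: ToyComplexSpec, pocket_site: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bound-frame ligand at the receptor's +x apex.

    A ``knob`` ligand is half-buried at the apex (the receptor gets carved
    around it); a ``globular`` one rests outside, touching the surface.
    """
    body = _select_sites(spec.ligand_shape, spec.ligand_atoms)
    if spec.ligand_shape == "globular":
        r_body = np.linalg.norm(body, axis=1).max() if len(body) > 1 else 0.0
        center = pocket_site + np.array([r_body + 1.0, 0.0, 0.0])
    else:
        # knob head half-buried, inner lobe fully enclosed in its tube
        center = pocket_site + np.array([-2.0, 0.0, 0.0])
    out = body + center
    return out + rng.uniform(-JITTER, JITTER, out.shape)


def make_planted_complex(spec: ToyComplexSpec) -> PlantedComplex:
    """Build a shape-complementary bound complex and its displaced input."""
    rng = np.random.default_rng(spec.seed)
    receptor_coords = _select_sites(spec.receptor_shape, spec.receptor_atoms)
    receptor_coords = receptor_coords + rng.uniform(-JITTER, JITTER, receptor_coords.shape)

    # pocket site: the receptor's +x surface apex
    pocket_site = receptor_coords[int(np.argmax(receptor_coords[:, 0]))].copy()
    lig_bound = _bound_ligand_coords(spec, pocket_site, rng)

    # carve the pocket: drop receptor atoms clashing with the bound ligand
    d2 = ((receptor_coords[:, None, :] - lig_bound[None, :, :]) ** 2).sum(axis=2)
    keep = d2.min(axis=1) > CARVE_CLEARANCE**2
    removed = receptor_coords[~keep]
    receptor_coords = receptor_coords[keep]
    if len(receptor_coords) < 4:
        raise ValueError("carving removed too much of the receptor; enlarge it")

    receptor = _as_molecule(receptor_coords, f"receptor-{spec.seed}", RECEPTOR)
    if len(removed):
        # carving exposes the pocket lining; the neighbor-count criterion
        # cannot see that (concave sites keep many neighbors), so atoms
        # adjacent to a removed site are surface by construction
        d2x = ((receptor_coords[:, None, :] - removed[None, :, :]) ** 2).sum(axis=2)
        exposed = d2x.min(axis=1) <= (LATTICE_SPACING * 1.15) ** 2
        receptor = Molecule(
            [
                replace(a, is_surface=a.is_surface or bool(e))
                for a, e in zip(receptor.atoms, exposed)
            ],
            label=receptor.label,
            role=receptor.role,
        )
    ref_ligand = _as_molecule(lig_bound, f"ligand-{spec.seed}", LIGAND)

    if spec.planted_pose is None:
        rot = euler_from_matrix(Rotation.random(random_state=rng).as_matrix())
        displacement = rng.uniform(-12.0, 12.0, 3) + np.array([30.0, 0.0, 0.0])
        pose = (rot, displacement)
    else:
        pose = (spec.planted_pose[0], np.asarray(spec.planted_pose[1], dtype=np.float64))

    # input ligand: bound coordinates de-rotated about their mean and displaced,
    # so that re-rotating by the planted angles restores the bound orientation
    r_p = rotation_matrix(pose[0])
    com = lig_bound.mean(axis=0)
    lig_input = (lig_bound - com) @ r_p + com + pose[1]  # rows: R_p^T (x - com)
    ligand = ref_ligand.with_coords(lig_input)

    return PlantedComplex(
        receptor=receptor,
        ligand=ligand,
        ref_receptor=receptor,
        ref_ligand=ref_ligand,
        planted_pose=pose,
    )
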