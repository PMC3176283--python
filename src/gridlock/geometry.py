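"""Molecular centering, rotations, and grid-minimizing orientation search.

Three pieces of machinery keep the correlation grids small:

1. **Centering.**  The fixed molecule is centered on the halfway points of
   its per-axis extents (bounding-box center), which fits a rectangular
   grid more tightly than the center of mass when the mass distribution is
   uneven.  The rotating molecule is centered on the origin of an enclosing
   sphere — Ritter's two-pass heuristic sphere or the center of mass,
   whichever gives the smaller radius — so that a single cubic grid holds
   it in every orientation.

2. **Receptor rotation.**  Before the search, the engine scans the full
   rotational sampling set and re-orients the fixed molecule to the Euler
   angles whose rotated bounding box needs the fewest grid cells (an
   elongated molecule aligned with a grid axis needs a much smaller
   rectangular grid than the same molecule along a diagonal).

3. **Switching.**  The roles of the two molecules may be swapped when
   fixing the other molecule yields a smaller combined correlation grid;
   the comparison metric is the product of the combined per-dimension
   transform sizes.

Euler angles use the intrinsic z–x–z convention in degrees throughout
(rotation matrix ``Rz(phi) · Rx(theta) · Rz(psi)``).  Any self-consistent
convention yields identical poses; this one is declared so that output
files are unambiguous.

The rotational sampling sets are deterministic near-uniform constructions:
``n_psi`` equal spin steps about z crossed with a golden-angle spiral of
``n_sphere`` axis directions on the unit sphere, with the first element
pinned to the identity rotation.  The 15° set has 150 × 24 = 3,600
rotations and the 6° set has 900 × 60 = 54,000.  A user-supplied angle file
(three whitespace-separated degrees per line) overrides the built-in sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .gridding import (
    DEFAULT_MARGIN_CELLS,
    DEFAULT_SPACING,
    GridShape,
    combined_grid_shape,
    cubic_edge_for,
    fft_friendly_size,
    grid_cells,
)
from .structures import Molecule

__all__ = [
    "EulerAngles",
    "IDENTITY_ROTATION",
    "RotationSet",
    "CenteringResult",
    "SwitchDecision",
    "rotation_matrix",
    "euler_from_matrix",
    "load_rotation_set",
    "center_of_mass",
    "bbox_center",
    "fixed_grid_center",
    "ritter_bounding_sphere",
    "choose_ligand_center",
    "minimal_grid_shape",
    "select_receptor_rotation",
    "decide_switch",
]


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic z–x–z Euler angles in degrees."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        for v in (self.phi, self.theta, self.psi):
            if not math.isfinite(v):
                raise ValueError("Euler angles must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)

    def normalized(self) -> "EulerAngles":
        """Canonical ranges: phi, psi in [0, 360), theta in [0, 180]."""
        phi, theta, psi = self.phi % 360.0, self.theta % 360.0, self.psi % 360.0
        if theta > 180.0:
            # (phi, theta, psi) and (phi+180, 360-theta, psi+180) are the same rotation
            theta = 360.0 - theta
            phi = (phi + 180.0) % 360.0
            psi = (psi + 180.0) % 360.0
        return EulerAngles(phi, theta, psi)


IDENTITY_ROTATION = EulerAngles(0.0, 0.0, 0.0)


def rotation_matrix(angles: EulerAngles) -> np.ndarray:
    """Proper rotation matrix (det +1) for intrinsic z–x–z angles."""
    return Rotation.from_euler(
        "ZXZ", [angles.phi, angles.theta, angles.psi], degrees=True
    ).as_matrix()


def euler_from_matrix(matrix: np.ndarray) -> EulerAngles:
    """Inverse of :func:`rotation_matrix`, normalized to canonical ranges."""
    phi, theta, psi = Rotation.from_matrix(np.asarray(matrix)).as_euler(
        "ZXZ", degrees=True
    )
    return EulerAngles(phi, theta, psi).normalized()


def _matrices(angles: Sequence[EulerAngles]) -> np.ndarray:
    arr = np.array([[a.phi, a.theta, a.psi] for a in angles], dtype=np.float64)
    return Rotation.from_euler("ZXZ", arr, degrees=True).as_matrix()


@dataclass(frozen=True)
class RotationSet:
    """An ordered, index-stable set of Euler angles."""

    angles: tuple[EulerAngles, ...]
    sampling_label: str  # "deg15" | "deg6" | "user"

    def __len__(self) -> int:
        return len(self.angles)

    def __iter__(self) -> Iterator[EulerAngles]:
        return iter(self.angles)

    def __getitem__(self, i: int) -> EulerAngles:
        return self.angles[i]


_GOLDEN_ANGLE = 180.0 * (3.0 - math.sqrt(5.0))  # ≈ 137.50776°


def _spiral_sphere(n: int) -> list[tuple[float, float]]:
    """(phi, theta) of n near-uniform axis directions; index 0 is the pole."""
    out = []
    for i in range(n):
        if n == 1:
            cos_t = 1.0
        else:
            cos_t = 1.0 - 2.0 * i / (n - 1)
        theta = math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))
        phi = (i * _GOLDEN_ANGLE) % 360.0
        out.append((phi, theta))
    return out


def _uniform_rotation_set(n_sphere: int, n_psi: int, delta_psi: float) -> tuple[EulerAngles, ...]:
    angles = []
    for phi, theta in _spiral_sphere(n_sphere):
        for j in range(n_psi):
            angles.append(EulerAngles(phi, theta, j * delta_psi))
    return tuple(angles)


_BUILTIN_SETS = {
    "deg15": (150, 24, 15.0),  # 3,600 rotations
    "deg6": (900, 60, 6.0),  # 54,000 rotations
}


def load_rotation_set(sampling: str | Path) -> RotationSet:
    """Load a rotation set by label ("deg15", "deg6") or from an angle file.

    The built-in sets are generated deterministically (see module
    docstring) with the identity rotation at index 0.  An angle file holds
    three whitespace-separated degrees (phi theta psi) per line; ``#``
    comments and blank lines are ignored and file order is preserved.
    """
    key = str(sampling)
    if key in _BUILTIN_SETS:
        n_sphere, n_psi, delta = _BUILTIN_SETS[key]
        return RotationSet(_uniform_rotation_set(n_sphere, n_psi, delta), key)
    path = Path(sampling)
    if not path.exists():
        raise ValueError(
            f"unknown rotation sampling {sampling!r}: not a built-in label "
            f"({', '.join(_BUILTIN_SETS)}) and not a readable file"
        )
    angles = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed angle line {lineno} in {path}: {raw!r}")
        try:
            phi, theta, psi = (float(p) for p in parts)
        except ValueError:
            raise ValueError(f"malformed angle line {lineno} in {path}: {raw!r}") from None
        angles.append(EulerAngles(phi, theta, psi).normalized())
    if not angles:
        raise ValueError(f"rotation file {path} contains no angles")
    return RotationSet(tuple(angles), "user")


# ---------------------------------------------------------------------------
# Centering


def _require_nonempty(molecule: Molecule, op: str) -> None:
    if len(molecule) == 0:
        raise ValueError(f"{op} requires a non-empty molecule")


def center_of_mass(molecule: Molecule) -> np.ndarray:
    """Unweighted mean of atom positions (unit atom masses)."""
    _require_nonempty(molecule, "center_of_mass")
    return molecule.coords.mean(axis=0)


def bbox_center(molecule: Molecule) -> np.ndarray:
    """Per-axis halfway point of the molecule's extents."""
    _require_nonempty(molecule, "bbox_center")
    c = molecule.coords
    return (c.min(axis=0) + c.max(axis=0)) / 2.0


def fixed_grid_center(molecule: Molecule, rotation: EulerAngles | np.ndarray) -> np.ndarray:
    """Input-frame point that maps to the rotated molecule's bbox center.

    Discretizing the fixed molecule about this point places its rotated
    bounding box symmetrically in the grid, so the minimal rectangular grid
    shape computed for that rotation is actually sufficient.
    """
    _require_nonempty(molecule, "fixed_grid_center")
    rot = rotation_matrix(rotation) if isinstance(rotation, EulerAngles) else np.asarray(rotation)
    q = molecule.coords @ rot.T
    mid = (q.min(axis=0) + q.max(axis=0)) / 2.0
    return rot.T @ mid


def ritter_bounding_sphere(points: Sequence[np.ndarray] | np.ndarray) -> tuple[np.ndarray, float]:
    """Ritter's two-pass enclosing-sphere heuristic.

    First pass picks an approximate diameter by a farthest-point chain:
    from the minimum-x point, find the farthest point Q, then the point R
    farthest from Q, and initialize the sphere on the QR diameter.  Second
    pass grows the sphere once per point left outside.  The returned
    sphere contains every input point; it is near-minimal but not
    guaranteed minimal.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 3:
        raise ValueError("ritter_bounding_sphere needs a non-empty (n, 3) point set")
    p = pts[int(np.argmin(pts[:, 0]))]
    q = pts[int(np.argmax(((pts - p) ** 2).sum(axis=1)))]
    r = pts[int(np.argmax(((pts - q) ** 2).sum(axis=1)))]
    center = (q + r) / 2.0
    radius = float(np.linalg.norm(q - r)) / 2.0
    for p in pts:
        d = float(np.linalg.norm(p - center))
        if d > radius + 1e-12:
            new_radius = (radius + d) / 2.0
            center = center + (p - center) * ((d - new_radius) / d)
            radius = new_radius
    return center, radius


@dataclass(frozen=True)
class CenteringResult:
    """Chosen rotation center for the rotating molecule.

    ``translation`` is the vector that brings the chosen center to the
    origin (i.e. ``-center``); ``radius`` is the enclosing-sphere radius
    about the chosen center, which sizes the cubic grid.
    """

    center: np.ndarray
    translation: np.ndarray
    method: str  # "center_of_mass" | "bounding_sphere"
    radius: float


def choose_ligand_center(molecule: Molecule) -> CenteringResult:
    """Pick the enclosing-sphere center with the smaller radius.

    Compares Ritter's bounding sphere against the center of mass (whose
    radius is the greatest atom distance from it); ties keep the center of
    mass.
    """
    _require_nonempty(molecule, "choose_ligand_center")
    coords = molecule.coords
    com = coords.mean(axis=0)
    r_com = float(np.linalg.norm(coords - com, axis=1).max())
    c_rit, r_rit = ritter_bounding_sphere(coords)
    if r_rit < r_com:
        return CenteringResult(
            center=c_rit, translation=-c_rit, method="bounding_sphere", radius=r_rit
        )
    return CenteringResult(center=com, translation=-com, method="center_of_mass", radius=r_com)


# ---------------------------------------------------------------------------
# Minimal grids, receptor rotation, switching


def minimal_grid_shape(
    molecule: Molecule,
    rotation: EulerAngles | np.ndarray,
    spacing: float = DEFAULT_SPACING,
    margin_cells: int = DEFAULT_MARGIN_CELLS,
) -> GridShape:
    """Smallest FFT-friendly rectangular grid holding the rotated molecule.

    Per axis: ``fft_friendly_size(ceil(extent / spacing) + 2 * margin)``
    where the extent is measured on the rotated coordinates.  Invariant to
    translation of the input.
    """
    _require_nonempty(molecule, "minimal_grid_shape")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rot = rotation_matrix(rotation) if isinstance(rotation, EulerAngles) else np.asarray(rotation)
    q = molecule.coords @ rot.T
    extents = q.max(axis=0) - q.min(axis=0)
    dims = [
        fft_friendly_size(max(1, _ceil_cells(e, spacing) + 2 * margin_cells))
        for e in extents
    ]
    return GridShape(*dims)


def _ceil_cells(extent: float, spacing: float) -> int:
    return int(math.ceil(extent / spacing - 1e-9))


def select_receptor_rotation(
    molecule: Molecule,
    rotations: RotationSet,
    spacing: float = DEFAULT_SPACING,
    margin_cells: int = DEFAULT_MARGIN_CELLS,
) -> tuple[EulerAngles, GridShape]:
    """Rotation from the set minimizing the molecule's grid cell count.

    Exhaustive scan over the rotation set; ties are broken by the lowest
    index, so the result is deterministic for a given set.
    """
    _require_nonempty(molecule, "select_receptor_rotation")
    if len(rotations) == 0:
        raise ValueError("select_receptor_rotation requires a non-empty rotation set")
    coords = molecule.coords - bbox_center(molecule)
    best_cells = None
    best_idx = 0
    best_shape: GridShape | None = None
    chunk = 1024
    for start in range(0, len(rotations), chunk):
        mats = _matrices(rotations.angles[start : start + chunk])  # (m, 3, 3)
        pts = np.einsum("rij,nj->rni", mats, coords)  # (m, n, 3)
        extents = pts.max(axis=1) - pts.min(axis=1)  # (m, 3)
        n_cells = np.ceil(extents / spacing - 1e-9).astype(np.int64) + 2 * margin_cells
        n_cells = np.maximum(n_cells, 1)
        friendly = np.vectorize(fft_friendly_size, otypes=[np.int64])(n_cells)
        totals = friendly.prod(axis=1)
        i = int(np.argmin(totals))  # argmin keeps the lowest index on ties
        if best_cells is None or totals[i] < best_cells:
            best_cells = int(totals[i])
            best_idx = start + i
            best_shape = GridShape(*friendly[i])
    assert best_shape is not None
    return rotations[best_idx], best_shape


@dataclass(frozen=True)
class SwitchDecision:
    """Outcome of the receptor/ligand switch evaluation.

    ``fixed``/``rotating`` are the molecules in the roles actually used by
    the search; ``switched`` records whether they were exchanged relative
    to the input receptor/ligand assignment.  ``metric_original`` and
    ``metric_switched`` are the combined-grid cell counts of the two
    evaluated configurations; the chosen one is their exact minimum (ties
    keep the original roles).
    """

    switched: bool
    fixed: Molecule
    rotating: Molecule
    fixed_rotation: EulerAngles
    fixed_shape: GridShape
    rotating_edge: int
    combined: GridShape
    metric_original: int
    metric_switched: int


def _combined_metric(
    fixed: Molecule,
    rotating: Molecule,
    rotations: RotationSet,
    spacing: float,
    margin_cells: int,
) -> tuple[int, EulerAngles, GridShape, int, GridShape]:
    rot, shape = select_receptor_rotation(fixed, rotations, spacing, margin_cells)
    edge = cubic_edge_for(rotating, spacing, margin_cells)
    combined = combined_grid_shape(shape, edge)
    return grid_cells(combined), rot, shape, edge, combined


def decide_switch(
    receptor: Molecule,
    ligand: Molecule,
    rotations: RotationSet,
    spacing: float = DEFAULT_SPACING,
    margin_cells: int = DEFAULT_MARGIN_CELLS,
) -> SwitchDecision:
    """Keep or switch the receptor/ligand roles to minimize the combined grid.

    Evaluates the combined correlation grid (fixed molecule at its best
    rotation plus the rotating molecule's cubic edge) for the original and
    the switched role assignment, and returns whichever is smaller; ties
    keep the original roles.
    """
    _require_nonempty(receptor, "decide_switch")
    _require_nonempty(ligand, "decide_switch")
    m_orig, rot_o, shape_o, edge_o, comb_o = _combined_metric(
        receptor, ligand, rotations, spacing, margin_cells
    )
    m_sw, rot_s, shape_s, edge_s, comb_s = _combined_metric(
        ligand, receptor, rotations, spacing, margin_cells
    )
    if m_sw < m_orig:
        return SwitchDecision(
            switched=True,
            fixed=ligand,
            rotating=receptor,
            fixed_rotation=rot_s,
            fixed_shape=shape_s,
            rotating_edge=edge_s,
            combined=comb_s,
            metric_original=m_orig,
            metric_switched=m_sw,
        )
    return SwitchDecision(
        switched=False,
        fixed=receptor,
        rotating=ligand,
        fixed_rotation=rot_o,
        fixed_shape=shape_o,
        rotating_edge=edge_o,
        combined=comb_o,
        metric_original=m_orig,
        metric_switched=m_sw,
    )
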