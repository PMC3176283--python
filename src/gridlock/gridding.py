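"""FFT-friendly grid sizing and molecule discretization.

The docking engine correlates two complex-valued score lattices: a
*rectangular* grid tightly fitted to the fixed molecule and a *cubic* grid
for the rotating molecule (cubic so its size is constant through the whole
rotational sweep).  Transform dimensions are rounded up to "FFT-friendly"
sizes, i.e. integers whose prime factors are all in {2, 3, 5, 7}, for which
the FFT has efficient codelets.

Scoring channel
---------------
One reference shape-complementarity channel in the Katchalski-Katzir
tradition is parameterized:

* fixed molecule:    surface cells ``1+0j``, core cells ``0+9j``
* rotating molecule: surface cells ``1+2j``, core cells ``0+3j``

The translational score is the real part of the complex correlation
``Re(F·L)``, so a surface–surface cell pair contributes ``+1`` while any
rotating-molecule cell overlapping the fixed molecule's core is heavily
penalized (``Re(9j·(1+2j)) = -18`` per surface cell, ``Re(9j·3j) = -27``
per core cell).  Treating the fixed molecule's interior as forbidden
volume for the whole partner — not merely for the partner's own core — is
the classic grid shape-complementarity design: without it, a molecule
whose discretized body is mostly surface cells could bury itself in the
partner's interior at a profit.  The channel interface is pluggable — a
search may sum any number of weighted channel pairs — but only this shape
channel ships with values; pairwise-potential and electrostatic channels
are interface only.

Default cell size is 1.2 Å and the default atom stamp radius is 1.8 Å
(≈ heavy-atom van der Waals); both are configurable.  A margin of 2 empty
cells is kept around the molecular extent inside each grid so atom stamps
never touch the grid border, the smallest safe margin for stamp radii up to
two cell widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

DEFAULT_SPACING = 1.2  # Å per cell
DEFAULT_MARGIN_CELLS = 2
DEFAULT_ATOM_RADIUS = 1.8  # Å

__all__ = [
    "GridShape",
    "ScoreGrid",
    "ChannelSpec",
    "ChannelPair",
    "DEFAULT_SPACING",
    "DEFAULT_MARGIN_CELLS",
    "DEFAULT_ATOM_RADIUS",
    "default_channels",
    "load_channel_config",
    "fft_friendly_size",
    "grid_cells",
    "combined_grid_shape",
    "cubic_edge_for",
    "discretize",
]


class GridShape(NamedTuple):
    """Cells per dimension.

    The sizing operations (:func:`fft_friendly_size` rounding inside
    :func:`combined_grid_shape`, ``minimal_grid_shape`` and
    :func:`cubic_edge_for`) always produce FFT-friendly dimensions; the
    tuple itself also admits arbitrary positive sizes so that printed grid
    arithmetic for historical cubic grids (whose dimensions may contain
    larger prime factors) can be expressed.
    """

    n_x: int
    n_y: int
    n_z: int


def grid_cells(shape: GridShape | Sequence[int]) -> int:
    """Total cell count: the product of the per-dimension point counts."""
    n_x, n_y, n_z = shape
    return int(n_x) * int(n_y) * int(n_z)


def _is_smooth(n: int) -> bool:
    for p in (2, 3, 5, 7):
        while n % p == 0:
            n //= p
    return n == 1


@lru_cache(maxsize=None)
def fft_friendly_size(n_min: int) -> int:
    """Smallest integer >= ``n_min`` whose prime factors are all <= 7."""
    n_min = int(n_min)
    if n_min < 1:
        raise ValueError(f"n_min must be >= 1, got {n_min}")
    n = n_min
    while not _is_smooth(n):
        n += 1
    return n


def combined_grid_shape(
    fixed_shape: GridShape | Sequence[int], rotating_edge: int
) -> GridShape:
    """Correlation transform size: fixed dims plus the cubic rotating edge.

    Each dimension is the fixed grid's point count plus the rotating grid's
    edge, rounded up to an FFT-friendly size.  This is both the transform
    shape used by the search and the grid-size metric reported for a run.
    """
    if rotating_edge < 0:
        raise ValueError("rotating_edge must be non-negative")
    dims = [fft_friendly_size(max(1, int(d) + int(rotating_edge))) for d in fixed_shape]
    return GridShape(*dims)


def _ceil_cells(extent: float, spacing: float) -> int:
    # guard against 12/1.2 -> 10.000000000000002 -> ceil 11
    return int(math.ceil(extent / spacing - 1e-9))


def cubic_edge_for(
    molecule,
    spacing: float = DEFAULT_SPACING,
    margin_cells: int = DEFAULT_MARGIN_CELLS,
) -> int:
    """Edge of the cubic grid for the rotating molecule.

    Sized from the enclosing-sphere radius about the chosen rotation center
    (bounding sphere or center of mass, whichever is smaller), so the edge
    is invariant under any rotation of the molecule:
    ``fft_friendly_size(ceil(2R / spacing) + 2 * margin_cells)``.
    """
    from .geometry import choose_ligand_center

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    centering = choose_ligand_center(molecule)
    n = _ceil_cells(2.0 * centering.radius, spacing) + 2 * margin_cells
    return fft_friendly_size(max(1, n))


@dataclass(frozen=True)
class ChannelSpec:
    """Per-molecule discretization values for one scoring channel."""

    name: str
    surface_value: complex
    core_value: complex
    atom_radius: float = DEFAULT_ATOM_RADIUS

    def __post_init__(self) -> None:
        if self.atom_radius <= 0:
            raise ValueError("atom_radius must be positive")


@dataclass(frozen=True)
class ChannelPair:
    """A (fixed, rotating) channel specification with a merge weight."""

    fixed: ChannelSpec
    rotating: ChannelSpec
    weight: float = 1.0

    @property
    def name(self) -> str:
        return self.fixed.name


def default_channels() -> list[ChannelPair]:
    """The reference shape-complementarity channel (see module docstring)."""
    return [
        ChannelPair(
            fixed=ChannelSpec("shape", surface_value=1 + 0j, core_value=9j),
            rotating=ChannelSpec("shape", surface_value=1 + 2j, core_value=3j),
        )
    ]


def _parse_value(v) -> complex:
    if isinstance(v, (int, float)):
        return complex(v)
    if isinstance(v, str):
        return complex(v.replace(" ", ""))
    if isinstance(v, (list, tuple)) and len(v) == 2:
        return complex(float(v[0]), float(v[1]))
    raise ValueError(f"cannot interpret channel value {v!r}")


def _parse_side(name: str, node: dict) -> ChannelSpec:
    return ChannelSpec(
        name=name,
        surface_value=_parse_value(node["surface"]),
        core_value=_parse_value(node["core"]),
        atom_radius=float(node.get("radius", DEFAULT_ATOM_RADIUS)),
    )


def load_channel_config(path: str | Path) -> list[ChannelPair]:
    """Load scoring channels from a YAML config.

    Layout::

        channels:
          - name: shape
            weight: 1.0
            fixed:    {surface: [1, 0], core: [0, 9], radius: 1.8}
            rotating: {surface: [1, 0], core: [0, 1], radius: 1.8}

    Complex values may be given as ``[real, imag]`` pairs, numbers, or
    strings such as ``"1+0j"``.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "channels" not in data:
        raise ValueError("channel config must contain a 'channels' list")
    pairs = []
    for node in data["channels"]:
        name = str(node.get("name", "channel"))
        pairs.append(
            ChannelPair(
                fixed=_parse_side(name, node["fixed"]),
                rotating=_parse_side(name, node["rotating"]),
                weight=float(node.get("weight", 1.0)),
            )
        )
    if not pairs:
        raise ValueError("channel config lists no channels")
    return pairs


@dataclass
class ScoreGrid:
    """A complex-valued score lattice with its geometry.

    ``origin_offset`` is the coordinate, in the molecule's internal
    (rotated, centered) frame, of the center of cell ``(0, 0, 0)``; the
    grid center cell ``shape // 2`` sits at the frame origin.  Values are
    stored in single precision.
    """

    shape: GridShape
    spacing: float
    origin_offset: np.ndarray  # (3,) Å
    values: np.ndarray  # complex64, shape == shape


def discretize(
    molecule,
    shape: GridShape | Sequence[int],
    spacing: float,
    channel: ChannelSpec,
    rotation,
    center: np.ndarray,
) -> ScoreGrid:
    """Stamp a rotated, centered molecule onto a complex score grid.

    Each atom writes ``channel.surface_value`` or ``channel.core_value``
    into every cell whose center lies within ``channel.atom_radius`` of the
    atom's transformed position ``R (p - center)``.  Core stamps are applied
    after surface stamps, so core overrides surface where they overlap.
    Blocked atoms always stamp the core value (blocking suppresses
    favorable scoring).

    Raises ``ValueError`` if the molecule (plus stamp radius) does not fit
    inside the grid, or if it is empty.
    """
    from .geometry import EulerAngles, rotation_matrix

    if len(molecule) == 0:
        raise ValueError("cannot discretize an empty molecule")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    shape = GridShape(*(int(d) for d in shape))
    if min(shape) < 1:
        raise ValueError(f"invalid grid shape {shape}")

    if isinstance(rotation, EulerAngles):
        rot = rotation_matrix(rotation)
    else:
        rot = np.asarray(rotation, dtype=np.float64)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be EulerAngles or a 3x3 matrix")

    center = np.asarray(center, dtype=np.float64)
    center_idx = np.array(shape, dtype=np.int64) // 2
    # continuous cell coordinates of each atom
    g = ((molecule.coords - center) @ rot.T) / spacing + center_idx

    r_cells = channel.atom_radius / spacing
    reach = int(math.ceil(r_cells))
    # exact range of cells any atom can stamp
    lo = np.ceil(g - r_cells).astype(np.int64)
    hi = np.floor(g + r_cells).astype(np.int64)
    if np.any(lo < 0) or np.any(hi > np.array(shape) - 1):
        raise ValueError("molecule exceeds grid bounds")

    offs = np.arange(-reach, reach + 2)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (K, 3)

    values = np.zeros(shape, dtype=np.complex64)
    flat = values.reshape(-1)
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    r2 = (channel.atom_radius / spacing) ** 2

    is_core = np.array(
        [(not a.is_surface) or a.blocked for a in molecule.atoms], dtype=bool
    )

    def _stamp(sel: np.ndarray, value: complex) -> None:
        if not np.any(sel):
            return
        base = np.floor(g[sel]).astype(np.int64)  # (m, 3)
        cand = base[:, None, :] + offsets[None, :, :]  # (m, K, 3)
        d2 = ((cand - g[sel][:, None, :]) ** 2).sum(axis=2)
        ok = d2 <= r2 * (1 + 1e-12)
        ok &= np.all(cand >= 0, axis=2) & np.all(cand < np.array(shape), axis=2)
        idx = (cand * strides).sum(axis=2)[ok]
        flat[idx] = np.complex64(value)

    _stamp(~is_core, channel.surface_value)
    _stamp(is_core, channel.core_value)

    origin_offset = -center_idx.astype(np.float64) * spacing
    return ScoreGrid(shape=shape, spacing=spacing, origin_offset=origin_offset, values=values)
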