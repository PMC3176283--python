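"""Translational FFT correlation and the full rotational docking search.

For each rotation of the rotating molecule, every relative translation of
the two score grids is evaluated at once through the Fourier convolution
theorem: with the fixed grid ``F`` and rotating grid ``L`` zero-embedded in
a common transform array, the circular correlation

    C(t) = sum_x F(x) · L(x - t)

is ``ifftn(fftn(F) * fftn(L_rev))`` where ``L_rev`` is the circular index
reversal of ``L``.  The translational score is ``Re C(t)``, which realizes
the shape-complementarity channel encoding (surface–surface ``+1``,
core–core clash penalty).  The transform dimensions are at least the sum
of the two grids' dimensions, so no translation with grid overlap is
aliased and the circular correlation equals the linear one.

Transform sizes are fixed once per run — the fixed molecule's rectangular
shape plus the rotating molecule's constant cubic edge, rounded to
FFT-friendly sizes — so the per-rotation cost is constant across the
sweep.  All grids and transforms are single precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.spatial.transform import Rotation

from .geometry import (
    EulerAngles,
    IDENTITY_ROTATION,
    RotationSet,
    SwitchDecision,
    choose_ligand_center,
    decide_switch,
    euler_from_matrix,
    fixed_grid_center,
    minimal_grid_shape,
    rotation_matrix,
)
from .gridding import (
    ChannelPair,
    DEFAULT_MARGIN_CELLS,
    DEFAULT_SPACING,
    GridShape,
    ScoreGrid,
    combined_grid_shape,
    cubic_edge_for,
    default_channels,
    discretize,
    grid_cells,
)
from .output import DockOutput, DockPrediction
from .structures import Molecule, mark_surface

__all__ = ["TranslationScore", "SearchConfig", "correlate", "top_translations", "run_search"]


@dataclass(frozen=True)
class TranslationScore:
    """A grid translation (signed cells) and its correlation score."""

    translation: np.ndarray  # (3,) int, each in [-N_d/2, N_d/2)
    score: float


@dataclass
class SearchConfig:
    """Parameters of a docking run.

    ``fixed_receptor`` reproduces the "-F" behaviour: the input receptor is
    neither rotated nor switched, so the output header carries an identity
    receptor rotation and a zero switch flag.  ``random_ligand_seed``, when
    given, applies a seeded uniform random pre-rotation to the rotating
    molecule before the sweep.
    """

    rotations: RotationSet
    spacing: float = DEFAULT_SPACING
    keep_per_rotation: int = 1
    total_keep: int = 2000
    fixed_receptor: bool = False
    random_ligand_seed: int | None = None
    channels: list[ChannelPair] = field(default_factory=default_channels)
    margin_cells: int = DEFAULT_MARGIN_CELLS
    surface_radius: float = 6.0
    surface_max_neighbors: int = 24

    def __post_init__(self) -> None:
        if self.keep_per_rotation < 1:
            raise ValueError("keep_per_rotation must be >= 1")
        if self.keep_per_rotation > self.total_keep:
            raise ValueError("keep_per_rotation must not exceed total_keep")


def _embed(values: np.ndarray, shape: GridShape) -> np.ndarray:
    out = np.zeros(tuple(shape), dtype=np.complex64)
    out[: values.shape[0], : values.shape[1], : values.shape[2]] = values
    return out


def _circular_reverse(arr: np.ndarray) -> np.ndarray:
    # G[i] = arr[(-i) mod N] along every axis
    return np.roll(arr[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))


def _correlate_with_fixed_fft(
    fixed_fft: np.ndarray, rotating_values: np.ndarray, shape: GridShape
) -> np.ndarray:
    rev = _circular_reverse(_embed(rotating_values, shape))
    c = sp_fft.ifftn(fixed_fft * sp_fft.fftn(rev))
    return np.ascontiguousarray(c.real)


def correlate(
    fixed: ScoreGrid, rotating: ScoreGrid, transform_shape: GridShape | None = None
) -> np.ndarray:
    """Real score lattice over all cyclic translations of the two grids.

    ``transform_shape`` defaults to the combined shape of the inputs; it
    must be at least ``fixed + rotating - 1`` per dimension so that the
    cyclic correlation is alias-free wherever the grids overlap.
    """
    if transform_shape is None:
        transform_shape = combined_grid_shape(fixed.shape, max(rotating.shape))
    for t, f, r in zip(transform_shape, fixed.shape, rotating.shape):
        if t < f + r - 1:
            raise ValueError(
                f"transform shape {tuple(transform_shape)} too small for grids "
                f"{tuple(fixed.shape)} + {tuple(rotating.shape)}"
            )
    fixed_fft = sp_fft.fftn(_embed(fixed.values, transform_shape))
    return _correlate_with_fixed_fft(fixed_fft, rotating.values, transform_shape)


def _unwrap(indices: np.ndarray, shape: GridShape) -> np.ndarray:
    dims = np.array(shape, dtype=np.int64)
    return ((indices + dims // 2) % dims) - dims // 2


def top_translations(lattice: np.ndarray, k: int) -> list[TranslationScore]:
    """The k best translations, unwrapped to signed cell offsets.

    Ties are broken by flat (row-major) lattice index, so the result is
    deterministic; on a constant lattice the first pick is ``(0, 0, 0)``.
    """
    flat = lattice.ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > flat.size:
        raise ValueError(f"k={k} exceeds lattice size {flat.size}")
    if k == 1:
        picks = np.array([np.argmax(flat)])
    else:
        threshold = np.partition(flat, flat.size - k)[flat.size - k]
        cand = np.flatnonzero(flat >= threshold)
        order = np.lexsort((cand, -flat[cand].astype(np.float64)))
        picks = cand[order[:k]]
    shape = GridShape(*lattice.shape)
    raw = np.stack(np.unravel_index(picks, tuple(shape)), axis=1)
    signed = _unwrap(raw, shape)
    return [
        TranslationScore(translation=t, score=float(s))
        for t, s in zip(signed, flat[picks])
    ]


def _ensure_surface(molecule: Molecule, config: SearchConfig) -> Molecule:
    if any(a.is_surface for a in molecule.atoms):
        return molecule
    return mark_surface(molecule, config.surface_radius, config.surface_max_neighbors)


def run_search(receptor: Molecule, ligand: Molecule, config: SearchConfig) -> DockOutput:
    """Full rigid-body docking sweep.

    Pipeline: optional seeded pre-rotation of the rotating molecule →
    centering (rotated-bbox halfway points for the fixed molecule,
    minimum-radius sphere center for the rotating one) → unless
    ``fixed_receptor``, receptor-rotation selection and receptor/ligand
    switching over the run's rotation set → one discretization of the
    fixed molecule → per rotation: discretize the rotating molecule,
    correlate, keep the best translations → merge, sort by score
    descending (stable; rotation index breaks ties), truncate.
    """
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("both molecules must be non-empty")
    if len(config.rotations) == 0:
        raise ValueError("rotation set must be non-empty")

    receptor = _ensure_surface(receptor, config)
    ligand = _ensure_surface(ligand, config)
    spacing = config.spacing
    margin = config.margin_cells

    if config.fixed_receptor:
        switched = False
        fixed_mol, rotating_mol = receptor, ligand
        fixed_rotation = IDENTITY_ROTATION
        fixed_shape = minimal_grid_shape(fixed_mol, fixed_rotation, spacing, margin)
        rotating_edge = cubic_edge_for(rotating_mol, spacing, margin)
        transform = combined_grid_shape(fixed_shape, rotating_edge)
    else:
        decision: SwitchDecision = decide_switch(
            receptor, ligand, config.rotations, spacing, margin
        )
        switched = decision.switched
        fixed_mol, rotating_mol = decision.fixed, decision.rotating
        fixed_rotation = decision.fixed_rotation
        fixed_shape = decision.fixed_shape
        rotating_edge = decision.rotating_edge
        transform = decision.combined

    if config.random_ligand_seed is not None:
        rng = np.random.default_rng(config.random_ligand_seed)
        pre = euler_from_matrix(Rotation.random(random_state=rng).as_matrix())
    else:
        pre = IDENTITY_ROTATION
    pre_matrix = rotation_matrix(pre)

    c_fix = fixed_grid_center(fixed_mol, fixed_rotation)
    c_rot = choose_ligand_center(rotating_mol).center
    edge_shape = GridShape(rotating_edge, rotating_edge, rotating_edge)

    fixed_ffts = []
    for pair in config.channels:
        grid = discretize(
            fixed_mol, fixed_shape, spacing, pair.fixed, fixed_rotation, c_fix
        )
        fixed_ffts.append(sp_fft.fftn(_embed(grid.values, transform)))

    # stored translation = rotating-center displacement from the fixed grid
    # center, in cells: FFT offset plus the difference of the grid centers
    center_offset = np.array(edge_shape, dtype=np.int64) // 2 - np.array(
        fixed_shape, dtype=np.int64
    ) // 2

    records: list[DockPrediction] = []
    for angles in config.rotations:
        total_rotation = rotation_matrix(angles) @ pre_matrix
        lattice: np.ndarray | None = None
        for pair, f_fft in zip(config.channels, fixed_ffts):
            grid = discretize(
                rotating_mol, edge_shape, spacing, pair.rotating, total_rotation, c_rot
            )
            part = _correlate_with_fixed_fft(f_fft, grid.values, transform)
            lattice = pair.weight * part if lattice is None else lattice + pair.weight * part
        assert lattice is not None
        for ts in top_translations(lattice, config.keep_per_rotation):
            records.append(
                DockPrediction(
                    angles=angles,
                    translation=ts.translation + center_offset,
                    score=ts.score,
                )
            )

    records.sort(key=lambda p: -p.score)  # stable: rotation order breaks ties
    records = records[: config.total_keep]

    return DockOutput(
        spacing=spacing,
        combined_shape=transform,
        switched=switched,
        receptor_rotation=fixed_rotation,
        receptor_center=c_fix,
        ligand_center=c_rot,
        ligand_prerotation=pre,
        receptor_path=fixed_mol.label,
        ligand_path=rotating_mol.label,
        predictions=records,
    )
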