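"""Docking output serialization and complex reconstruction.

File dialect (version tag ``#gridlock v1``)::

    #gridlock v1
    n_x n_y n_z spacing switched(0|1)
    phi theta psi          <- rotation applied to the fixed molecule
    phi theta psi          <- pre-rotation applied to the rotating molecule
    fixed_path cx cy cz    <- fixed-molecule source and grid center (Å)
    rotating_path cx cy cz <- rotating-molecule source and sphere center (Å)
    phi theta psi tx ty tz score   <- one line per prediction

Header lines two through five describe the *internal* roles: when the
``switched`` flag is 1 the fixed molecule is the input ligand.  Angles are
degrees (intrinsic z–x–z, two decimals); ``tx ty tz`` is the displacement,
in integer grid cells, of the rotating molecule's center from the fixed
molecule's grid center in the internal (rotated receptor) frame.  Storing
the displacement in that form makes the header self-sufficient: no grid
bookkeeping beyond the spacing is needed to rebuild a pose.

Reconstruction (:func:`create_complex`) inverts every internal transform —
centering, receptor rotation, switching, pre-rotation, per-prediction
rotation and translation — so that the returned receptor coordinates are
bit-identical to the input receptor file and the ligand is posed
accordingly.  The internal grid optimizations are thus invisible to the
end user.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import EulerAngles, rotation_matrix
from .gridding import GridShape
from .structures import Molecule

__all__ = ["DockPrediction", "DockOutput", "write_output", "read_output", "create_complex"]

_VERSION_TAG = "#gridlock v1"


@dataclass(frozen=True)
class DockPrediction:
    """One pose: rotating-molecule Euler angles, cell translation, score."""

    angles: EulerAngles
    translation: np.ndarray  # (3,) integer cells
    score: float

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=np.int64)
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector of cells")
        object.__setattr__(self, "translation", t)


@dataclass
class DockOutput:
    """A full docking result: reconstruction header plus ranked poses."""

    spacing: float
    combined_shape: GridShape
    switched: bool
    receptor_rotation: EulerAngles  # applied to the fixed molecule
    receptor_center: np.ndarray  # fixed-molecule grid center (input frame, Å)
    ligand_center: np.ndarray  # rotating-molecule sphere center (input frame, Å)
    ligand_prerotation: EulerAngles  # applied to the rotating molecule
    receptor_path: str
    ligand_path: str
    predictions: list[DockPrediction]

    def __post_init__(self) -> None:
        self.receptor_center = np.asarray(self.receptor_center, dtype=np.float64)
        self.ligand_center = np.asarray(self.ligand_center, dtype=np.float64)
        scores = [p.score for p in self.predictions]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("predictions must be sorted by score, descending")


def _fmt_angles(a: EulerAngles) -> str:
    return f"{a.phi:.2f} {a.theta:.2f} {a.psi:.2f}"


def write_output(result: DockOutput, path: str | Path) -> None:
    """Serialize a :class:`DockOutput` in the v1 text dialect."""
    shape = result.combined_shape
    lines = [
        _VERSION_TAG,
        f"{shape.n_x} {shape.n_y} {shape.n_z} {result.spacing:.4f} {int(result.switched)}",
        _fmt_angles(result.receptor_rotation),
        _fmt_angles(result.ligand_prerotation),
        "{} {:.4f} {:.4f} {:.4f}".format(
            result.receptor_path or "-", *result.receptor_center
        ),
        "{} {:.4f} {:.4f} {:.4f}".format(result.ligand_path or "-", *result.ligand_center),
    ]
    for p in result.predictions:
        tx, ty, tz = (int(v) for v in p.translation)
        lines.append(f"{_fmt_angles(p.angles)} {tx} {ty} {tz} {p.score:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_angles(line: str, what: str) -> EulerAngles:
    parts = line.split()
    if len(parts) != 3:
        raise ValueError(f"malformed {what} line: {line!r}")
    return EulerAngles(*(float(p) for p in parts))


def _parse_path_center(line: str, what: str) -> tuple[str, np.ndarray]:
    parts = line.split()
    if len(parts) < 4:
        raise ValueError(f"malformed {what} line: {line!r}")
    center = np.array([float(v) for v in parts[-3:]])
    return " ".join(parts[:-3]), center


def read_output(path: str | Path) -> DockOutput:
    """Parse a v1 docking output file; record order is preserved."""
    raw = Path(path).read_text().splitlines()
    lines = [l for l in raw if l.strip() and not l.lstrip().startswith("#")]
    if len(lines) < 5:
        raise ValueError(f"truncated docking output header in {path}")
    head = lines[0].split()
    if len(head) != 5:
        raise ValueError(f"malformed shape line: {lines[0]!r}")
    shape = GridShape(int(head[0]), int(head[1]), int(head[2]))
    spacing = float(head[3])
    switched = bool(int(head[4]))
    receptor_rotation = _parse_angles(lines[1], "receptor rotation")
    prerotation = _parse_angles(lines[2], "pre-rotation")
    receptor_path, receptor_center = _parse_path_center(lines[3], "receptor center")
    ligand_path, ligand_center = _parse_path_center(lines[4], "ligand center")
    predictions = []
    for line in lines[5:]:
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed prediction record: {line!r}")
        angles = EulerAngles(float(parts[0]), float(parts[1]), float(parts[2]))
        translation = np.array([int(parts[3]), int(parts[4]), int(parts[5])])
        predictions.append(DockPrediction(angles, translation, float(parts[6])))
    return DockOutput(
        spacing=spacing,
        combined_shape=shape,
        switched=switched,
        receptor_rotation=receptor_rotation,
        receptor_center=receptor_center,
        ligand_center=ligand_center,
        ligand_prerotation=prerotation,
        receptor_path=receptor_path,
        ligand_path=ligand_path,
        predictions=predictions,
    )


def create_complex(
    output: DockOutput,
    index: int,
    receptor: Molecule,
    ligand: Molecule,
) -> tuple[Molecule, Molecule]:
    """Rebuild a predicted complex in the input receptor's coordinate frame.

    ``receptor`` and ``ligand`` are the molecules in their *input* roles
    (matching the files the search was run on); the ``switched`` flag in
    the header determines which of them was fixed internally.  The returned
    receptor carries exactly the input coordinates; the ligand is posed by
    applying the internal transforms and mapping everything back through
    the inverse of the receptor's internal placement.
    """
    if index < 0 or index >= len(output.predictions):
        raise IndexError(
            f"prediction index {index} out of range [0, {len(output.predictions)})"
        )
    pred = output.predictions[index]
    r_fix = rotation_matrix(output.receptor_rotation)
    a = rotation_matrix(pred.angles) @ rotation_matrix(output.ligand_prerotation)
    d = pred.translation.astype(np.float64) * output.spacing
    c_fix = output.receptor_center
    c_rot = output.ligand_center

    if not output.switched:
        # internal fixed = receptor; ligand internal pose: A (p - c_rot) + d
        w = (ligand.coords - c_rot) @ a.T + d
        lig_coords = w @ r_fix + c_fix  # p = R_fix^T w + c_fix
    else:
        # internal fixed = ligand at R_fix (p - c_fix); receptor rotates.
        # Map internal frame -> input receptor frame: p = A^T (w - d) + c_rot
        w = (ligand.coords - c_fix) @ r_fix.T  # R_fix (p - c_fix)
        lig_coords = (w - d) @ a + c_rot
    receptor_out = receptor.with_coords(receptor.coords)
    return receptor_out, ligand.with_coords(lig_coords)
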