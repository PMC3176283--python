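"""Shared fixtures and oracles for the docking engine test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import correlate as _direct_correlate

from gridlock.structures import AtomRecord, Molecule, RECEPTOR


def molecule_from_coords(
    coords,
    label: str = "test",
    role: str = RECEPTOR,
    chain: str = "A",
    surface: bool | list[bool] = True,
) -> Molecule:
    """Build a one-atom-per-residue Cα molecule from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    if isinstance(surface, bool):
        surface = [surface] * len(coords)
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="GLY",
            chain_id=chain,
            residue_number=i + 1,
            position=c,
            is_surface=s,
        )
        for i, (c, s) in enumerate(zip(coords, surface))
    ]
    return Molecule(atoms, label=label, role=role)


def linear_correlation_oracle(fixed_values: np.ndarray, rotating_values: np.ndarray):
    """Direct-summation complex correlation C(t) = sum_y F(y+t) L(y).

    Returns ``(lattice, offset)`` where ``lattice[t + offset]`` is C(t) for
    every linear translation t in [-(nL-1), nF-1] per dimension.  Uses
    scipy's direct (non-FFT) correlation as an independent path.
    """
    z = _direct_correlate(
        fixed_values, np.conj(rotating_values), mode="full", method="direct"
    )
    offset = np.array(rotating_values.shape) - 1
    return z, offset


@pytest.fixture(scope="session")
def psi_subgroup():
    """The 24-element cyclic group of 15-degree spins about z."""
    from gridlock.geometry import EulerAngles, RotationSet

    return RotationSet(
        tuple(EulerAngles(0.0, 0.0, 15.0 * j) for j in range(24)), "user"
    )


def planted_case(seed: int):
    """A planted complex whose pose rotation lies in the psi subgroup."""
    from gridlock.fixtures import ToyComplexSpec, make_planted_complex
    from gridlock.geometry import EulerAngles

    rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 24))
    pose = (
        EulerAngles(0.0, 0.0, 15.0 * k),
        rng.uniform(-12.0, 12.0, 3) + np.array([30.0, 0.0, 0.0]),
    )
    return make_planted_complex(ToyComplexSpec(seed=seed, planted_pose=pose))
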