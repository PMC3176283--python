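"""Centering, rotations, rotation sets, minimal grids, switching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridlock.geometry import (
    EulerAngles,
    IDENTITY_ROTATION,
    RotationSet,
    bbox_center,
    center_of_mass,
    choose_ligand_center,
    decide_switch,
    euler_from_matrix,
    load_rotation_set,
    minimal_grid_shape,
    ritter_bounding_sphere,
    rotation_matrix,
    select_receptor_rotation,
)
from gridlock.gridding import cubic_edge_for, combined_grid_shape, grid_cells
from gridlock.fixtures import make_molecule

from conftest import molecule_from_coords


class TestCentering:
    def test_center_of_mass_examples(self):
        assert np.allclose(
            center_of_mass(molecule_from_coords([[0, 0, 0], [2, 0, 0]])), [1, 0, 0]
        )
        p = [3.2, -1.5, 7.0]
        assert np.allclose(center_of_mass(molecule_from_coords([p])), p)

    def test_center_of_mass_equals_direct_mean(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 3)) * 5
        assert np.allclose(
            center_of_mass(molecule_from_coords(coords)), coords.sum(axis=0) / 100
        )

    def test_bbox_center_examples(self):
        assert np.allclose(
            bbox_center(molecule_from_coords([[0, 0, 0], [4, 2, 6]])), [2, 1, 3]
        )
        p = [1.0, 2.0, 3.0]
        assert np.allclose(bbox_center(molecule_from_coords([p])), p)

    def test_bbox_center_vs_mass_center_on_skewed_cluster(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.uniform(-0.2, 0.2, (99, 3)), [[10.0, 0.0, 0.0]]])
        mol = molecule_from_coords(coords)
        assert bbox_center(mol)[0] == pytest.approx(
            (coords[:, 0].min() + coords[:, 0].max()) / 2
        )
        assert abs(bbox_center(mol)[0] - 5.0) < 0.3
        assert abs(center_of_mass(mol)[0] - 0.1) < 0.1

    def test_empty_molecule_rejected(self):
        empty = molecule_from_coords(np.empty((0, 3)))
        for fn in (center_of_mass, bbox_center, choose_ligand_center):
            with pytest.raises(ValueError):
                fn(empty)


def _minimal_sphere_oracle(points):
    """Exhaustive minimal enclosing sphere over point-subset candidates."""
    pts = np.asarray(points, dtype=float)
    best = None

    def consider(center, radius):
        nonlocal best
        if np.all(np.linalg.norm(pts - center, axis=1) <= radius + 1e-9):
            if best is None or radius < best[1]:
                best = (center, radius)

    for i, j in itertools.combinations(range(len(pts)), 2):
        c = (pts[i] + pts[j]) / 2
        consider(c, np.linalg.norm(pts[i] - c))
    for sub in itertools.combinations(range(len(pts)), 4):
        a, b, c, d = (pts[k] for k in sub)
        m = 2 * np.array([b - a, c - a, d - a])
        rhs = np.array(
            [b @ b - a @ a, c @ c - a @ a, d @ d - a @ a]
        )
        if abs(np.linalg.det(m)) < 1e-9:
            continue
        center = np.linalg.solve(m, rhs)
        consider(center, np.linalg.norm(a - center))
    return best


class TestRitterSphere:
    def test_single_point(self):
        c, r = ritter_bounding_sphere([[2.0, 3.0, 4.0]])
        assert np.allclose(c, [2, 3, 4]) and r == 0.0

    def test_two_points_diameter_initialization(self):
        c, r = ritter_bounding_sphere([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(c, [1, 0, 0]) and r == pytest.approx(1.0)

    def test_unit_cube_contained_and_near_minimal(self):
        cube = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        c, r = ritter_bounding_sphere(cube)
        assert np.all(np.linalg.norm(cube - c, axis=1) <= r + 1e-9)
        _, r_min = _minimal_sphere_oracle(cube)
        assert r_min == pytest.approx(np.sqrt(3) / 2, abs=1e-9)
        assert r <= 1.2 * r_min

    def test_random_sets_contained(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            pts = rng.normal(size=(rng.integers(1, 40), 3)) * rng.uniform(0.1, 20)
            c, r = ritter_bounding_sphere(pts)
            assert np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-6)


class TestChooseLigandCenter:
    def test_single_atom_ties_to_center_of_mass(self):
        res = choose_ligand_center(molecule_from_coords([[1.0, 1.0, 1.0]]))
        assert res.method == "center_of_mass"
        assert res.radius == 0.0
        assert np.allclose(res.translation, -res.center)

    def test_unbalanced_dumbbell_prefers_bounding_sphere(self):
        coords = np.vstack(
            [np.random.default_rng(2).normal(0, 0.3, (50, 3)), [[20.0, 0, 0]]]
        )
        mol = molecule_from_coords(coords)
        res = choose_ligand_center(mol)
        com = coords.mean(axis=0)
        r_com = np.linalg.norm(coords - com, axis=1).max()
        assert res.method == "bounding_sphere"
        assert res.radius < r_com

    def test_radius_never_exceeds_center_of_mass_radius(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            coords = rng.normal(size=(rng.integers(2, 30), 3)) * 4
            mol = molecule_from_coords(coords)
            res = choose_ligand_center(mol)
            com = coords.mean(axis=0)
            r_com = np.linalg.norm(coords - com, axis=1).max()
            assert res.radius <= r_com + 1e-9
            # contract: all atoms inside the chosen sphere
            assert np.all(
                np.linalg.norm(coords - res.center, axis=1) <= res.radius + 1e-6
            )


class TestRotations:
    def test_identity_angles_give_identity_matrix(self):
        assert np.allclose(rotation_matrix(IDENTITY_ROTATION), np.eye(3), atol=1e-12)

    def test_quarter_turn_about_z(self):
        m = rotation_matrix(EulerAngles(90, 0, 0))
        assert np.allclose(m @ [1, 0, 0], [0, 1, 0], atol=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.floats(-720, 720),
        st.floats(-720, 720),
        st.floats(-720, 720),
    )
    def test_matrices_are_proper_rotations(self, phi, theta, psi):
        m = rotation_matrix(EulerAngles(phi, theta, psi))
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-9)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-9)

    def test_euler_round_trip(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            ang = EulerAngles(*rng.uniform(0, 360, 3)).normalized()
            back = euler_from_matrix(rotation_matrix(ang))
            assert np.allclose(
                rotation_matrix(back), rotation_matrix(ang), atol=1e-9
            )


class TestRotationSets:
    def test_builtin_cardinalities(self):
        assert len(load_rotation_set("deg15")) == 3600
        assert len(load_rotation_set("deg6")) == 54000

    def test_identity_is_first_element(self):
        for label in ("deg15", "deg6"):
            first = load_rotation_set(label)[0]
            assert np.allclose(rotation_matrix(first), np.eye(3), atol=1e-12)

    def test_deterministic_across_builds(self):
        a = load_rotation_set("deg15")
        b = load_rotation_set("deg15")
        assert a.angles == b.angles

    def test_file_set_preserves_order_and_comments(self, tmp_path):
        path = tmp_path / "angles.txt"
        path.write_text("# comment\n0 0 0\n90 45 10\n\n10 20 30  # trailing\n")
        rs = load_rotation_set(path)
        assert rs.sampling_label == "user"
        assert len(rs) == 3
        assert rs[0] == EulerAngles(0, 0, 0)
        assert rs[1].psi == pytest.approx(10.0)

    def test_unknown_label_and_malformed_file(self, tmp_path):
        with pytest.raises(ValueError):
            load_rotation_set("deg30")
        bad = tmp_path / "bad.txt"
        bad.write_text("1 2\n")
        with pytest.raises(ValueError):
            load_rotation_set(bad)


class TestMinimalGridShape:
    def test_single_atom_shape_is_rotation_invariant(self):
        mol = molecule_from_coords([[5.0, -3.0, 1.0]])
        shapes = {
            minimal_grid_shape(mol, EulerAngles(*a))
            for a in [(0, 0, 0), (45, 30, 10), (120, 90, 270)]
        }
        assert len(shapes) == 1

    def test_axis_aligned_rod_beats_rotated_rod(self):
        xs = np.linspace(0, 36, 30)
        rod = molecule_from_coords(
            [[x, y, z] for x in xs for y in (0, 12) for z in (0, 12)]
        )
        s_id = minimal_grid_shape(rod, IDENTITY_ROTATION)
        s_45 = minimal_grid_shape(rod, EulerAngles(45, 0, 0))
        assert grid_cells(s_id) <= grid_cells(s_45)

    def test_exact_extent_arithmetic_zero_margin(self):
        mol = molecule_from_coords([[0, 0, 0], [12.0, 24.0, 36.0]])
        shape = minimal_grid_shape(mol, IDENTITY_ROTATION, spacing=1.2, margin_cells=0)
        assert tuple(shape) == (10, 20, 30)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-5, 5, (40, 3))
        rot = EulerAngles(33, 51, 77)
        s0 = minimal_grid_shape(molecule_from_coords(coords), rot)
        s1 = minimal_grid_shape(molecule_from_coords(coords + [103.7, -55.1, 9.9]), rot)
        assert s0 == s1


class TestSelectReceptorRotation:
    def test_tie_breaks_to_lowest_index(self, psi_subgroup):
        mol = molecule_from_coords([[0.0, 0.0, 0.0]])  # rotation-invariant point
        ang, _ = select_receptor_rotation(mol, psi_subgroup)
        assert ang == psi_subgroup[0]

    def test_never_worse_than_identity_with_builtin_set(self):
        rotations = load_rotation_set("deg15")
        rng = np.random.default_rng(7)
        for seed in range(5):
            mol = make_molecule("rod", 120, seed=seed)
            ang, shape = select_receptor_rotation(mol, rotations)
            assert grid_cells(shape) <= grid_cells(
                minimal_grid_shape(mol, IDENTITY_ROTATION)
            )

    def test_equals_exhaustive_scan_on_small_set(self, psi_subgroup):
        mol = make_molecule("ell", 90, seed=2)
        ang, shape = select_receptor_rotation(mol, psi_subgroup)
        best = min(
            range(len(psi_subgroup)),
            key=lambda i: grid_cells(minimal_grid_shape(mol, psi_subgroup[i])),
        )
        assert grid_cells(shape) == grid_cells(
            minimal_grid_shape(mol, psi_subgroup[best])
        )


class TestDecideSwitch:
    def test_identical_molecules_keep_original_roles(self, psi_subgroup):
        mol = make_molecule("globular", 80, seed=1)
        decision = decide_switch(mol, mol, psi_subgroup)
        assert not decision.switched
        assert decision.metric_original == decision.metric_switched

    def test_elongated_ligand_triggers_switch(self, psi_subgroup):
        rec = make_molecule("globular", 80, seed=1)
        lig = make_molecule("rod", 200, seed=2)
        assert decide_switch(rec, lig, psi_subgroup).switched

    def test_elongated_receptor_stays_fixed(self, psi_subgroup):
        rec = make_molecule("rod", 200, seed=2)
        lig = make_molecule("globular", 80, seed=1)
        assert not decide_switch(rec, lig, psi_subgroup).switched

    def test_chosen_metric_is_exact_min_of_both(self, psi_subgroup):
        for seed in range(5):
            rec = make_molecule("globular", 100, seed=seed)
            lig = make_molecule("rod", 60, seed=seed + 50)
            d = decide_switch(rec, lig, psi_subgroup)
            chosen = grid_cells(d.combined)
            assert chosen == min(d.metric_original, d.metric_switched)
            # independently recompute both metrics
            for fixed, rotating, metric in (
                (rec, lig, d.metric_original),
                (lig, rec, d.metric_switched),
            ):
                _, shape = select_receptor_rotation(fixed, psi_subgroup)
                edge = cubic_edge_for(rotating)
                assert grid_cells(combined_grid_shape(shape, edge)) == metric
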