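import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molcloud import (
    RigidTransform,
    Selection,
    Structure,
    apply_transform,
    center_of_mass,
    distance_matrix,
    rmsd,
    rmsf,
    select,
    superpose,
)
from molcloud.core import centroid, kabsch, rotation_about_axis
from molcloud.errors import (
    MassError,
    SelectionError,
    SizeMismatchError,
    TransformError,
)

from conftest import random_rotation


# ---------------------------------------------------------------------------
# Structure invariants
# ---------------------------------------------------------------------------

class TestStructure:
    def test_2d_promoted_to_single_conformation(self):
        s = Structure(np.zeros((4, 3)))
        assert s.n_conformations == 1
        assert s.n_points == 4

    def test_metadata_row_count_enforced(self):
        with pytest.raises(ValueError, match="metadata"):
            Structure(np.zeros((2, 3)), pd.DataFrame({"atom_name": ["CA"]}))

    def test_current_out_of_range(self):
        with pytest.raises(ValueError):
            Structure(np.zeros((1, 2, 3)), current=1)

    def test_nonfinite_rejected(self):
        coords = np.zeros((2, 3))
        coords[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Structure(coords)

    def test_default_metadata_has_masses_and_radii(self):
        s = Structure(np.zeros((3, 3)))
        assert (s.metadata["vdw_radius"] > 0).all()
        assert (s.metadata["mass"] >= 0).all()


# ---------------------------------------------------------------------------
# select
# ---------------------------------------------------------------------------

class TestSelect:
    def test_atom_name_filter(self, three_atom_structure):
        out = select(three_atom_structure, "atom_name == 'CA'")
        assert out.n_points == 2
        assert list(out.metadata["atom_name"]) == ["CA", "CA"]

    def test_no_match_returns_empty(self, three_atom_structure):
        out = select(three_atom_structure, "chain_id == 'Z'")
        assert out.n_points == 0

    def test_residue_id_membership(self, toy_polymer):
        # brute-force row scan oracle
        expected = [
            i for i in range(toy_polymer.n_points)
            if toy_polymer.metadata.iloc[i]["residue_id"] in (1, 2)
        ]
        out = select(toy_polymer, "residue_id in [1, 2]")
        assert out.n_points == len(expected) == 2
        assert sorted(out.metadata["residue_id"]) == [1, 2]

    def test_unknown_column_raises(self, three_atom_structure):
        with pytest.raises(SelectionError):
            select(three_atom_structure, "no_such_column == 1")

    def test_original_untouched(self, three_atom_structure):
        before = three_atom_structure.coordinates.copy()
        out = select(three_atom_structure, "atom_name == 'CA'")
        out.coordinates[:] = 99.0
        np.testing.assert_array_equal(three_atom_structure.coordinates, before)

    def test_all_conformations_preserved(self, random_cloud):
        s = random_cloud(n=6, m=4)
        out = select(s, Selection(indices=[0, 2, 4]))
        assert out.n_conformations == 4
        np.testing.assert_array_equal(out.coordinates, s.coordinates[:, [0, 2, 4]])

    def test_explicit_indices_out_of_range(self, three_atom_structure):
        with pytest.raises(SelectionError):
            select(three_atom_structure, Selection(indices=[5]))

    def test_complementary_predicates_partition(self, toy_polymer):
        a = select(toy_polymer, "residue_id <= 5")
        b = select(toy_polymer, "residue_id > 5")
        assert a.n_points + b.n_points == toy_polymer.n_points


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

class TestApplyTransform:
    def test_identity(self, random_cloud):
        s = random_cloud()
        out = apply_transform(s, RigidTransform.identity())
        np.testing.assert_allclose(out.coordinates, s.coordinates)

    def test_rotation_90_about_z(self):
        s = Structure(np.array([[1.0, 0, 0]]))
        t = RigidTransform(rotation_about_axis((0, 0, 1), 90.0), np.zeros(3))
        out = apply_transform(s, t)
        np.testing.assert_allclose(out.xyz[0], [0, 1, 0], atol=1e-12)

    def test_isometry_distance_matrix_oracle(self, rng):
        s = Structure(rng.normal(scale=5, size=(5, 3)))
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        before = distance_matrix(s, s)
        out = apply_transform(s, t)
        after = distance_matrix(out, out)
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(TransformError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(TransformError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_single_conformation_only(self, random_cloud):
        s = random_cloud(n=4, m=3)
        t = RigidTransform(np.eye(3), np.array([1.0, 0, 0]))
        out = apply_transform(s, t, conformation=1)
        np.testing.assert_array_equal(out.coordinates[0], s.coordinates[0])
        np.testing.assert_allclose(
            out.coordinates[1], s.coordinates[1] + [1, 0, 0])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_isometry_property(self, seed):
        r = np.random.default_rng(seed)
        s = Structure(r.normal(scale=10, size=(6, 3)))
        t = RigidTransform(random_rotation(r), r.normal(size=3))
        d0 = distance_matrix(s, s)
        d1_s = apply_transform(s, t)
        np.testing.assert_allclose(distance_matrix(d1_s, d1_s), d0, atol=1e-9)


# ---------------------------------------------------------------------------
# superpose
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_self_superposition(self, random_cloud):
        s = random_cloud(n=10)
        t, rms = superpose(s, s)
        assert rms <= 1e-9
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)

    def test_parameter_recovery(self, rng):
        s = Structure(rng.normal(scale=8, size=(12, 3)))
        R = random_rotation(rng)
        T = rng.normal(size=3)
        moved = apply_transform(s, RigidTransform(R, T))
        t, rms = superpose(s, moved)
        assert rms <= 1e-9
        np.testing.assert_allclose(t.rotation, R, atol=1e-6)
        np.testing.assert_allclose(t.translation, T, atol=1e-6)

    def test_mirror_images_do_not_fit(self, rng):
        # chiral 4-point cloud vs its reflection: no proper rotation fits.
        # Oracle: brute force over many sampled proper rotations.
        P = rng.normal(scale=5, size=(4, 3))
        P -= P.mean(axis=0)
        Q = P * np.array([1.0, 1.0, -1.0])  # mirror
        best = np.inf
        r2 = np.random.default_rng(7)
        for _ in range(2000):
            R = random_rotation(r2)
            best = min(best, float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))))
        _, rms = superpose(Structure(P), Structure(Q))
        assert rms > 1e-6
        # Kabsch must be at least as good as any sampled rotation
        assert rms <= best + 1e-9

    def test_too_few_points(self):
        a = Structure(np.zeros((2, 3)))
        with pytest.raises(SizeMismatchError):
            superpose(a, a)

    def test_mismatched_counts(self, random_cloud):
        with pytest.raises(SizeMismatchError):
            superpose(random_cloud(n=5), random_cloud(n=6))

    def test_idempotent(self, rng):
        a = Structure(rng.normal(scale=5, size=(8, 3)))
        b = Structure(rng.normal(scale=5, size=(8, 3)))
        t, rms1 = superpose(a, b)
        fitted = apply_transform(a, t)
        t2, rms2 = superpose(fitted, b)
        assert abs(rms2 - rms1) < 1e-9


# ---------------------------------------------------------------------------
# rmsd / rmsf
# ---------------------------------------------------------------------------

class TestRmsd:
    def test_identical_is_zero(self, random_cloud):
        s = random_cloud()
        assert rmsd(s, s) == 0.0

    def test_single_point_distance(self):
        a = Structure(np.array([[0.0, 0, 0]]))
        b = Structure(np.array([[3.0, 4, 0]]))
        assert rmsd(a, b) == pytest.approx(5.0)

    def test_one_displaced_point(self, rng):
        # 10 points, one displaced by 1 A -> sqrt(1/10)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[3] += [1.0, 0, 0]
        assert rmsd(Structure(P), Structure(Q)) == pytest.approx(np.sqrt(0.1))

    def test_symmetric(self, random_cloud):
        a, b = random_cloud(n=7), random_cloud(n=7)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-12)

    def test_count_mismatch(self, random_cloud):
        with pytest.raises(SizeMismatchError):
            rmsd(random_cloud(n=3), random_cloud(n=4))

    def test_superpose_first_removes_rigid_motion(self, rng):
        s = Structure(rng.normal(scale=5, size=(6, 3)))
        moved = apply_transform(
            s, RigidTransform(random_rotation(rng), rng.normal(size=3)))
        assert rmsd(s, moved, superpose_first=True) < 1e-9

    def test_mass_weighted(self):
        meta = pd.DataFrame({"element": ["C", "O"], "atom_name": ["C", "O"]})
        a = Structure(np.zeros((2, 3)), meta)
        b = Structure(np.array([[1.0, 0, 0], [0.0, 0, 0]]), meta)
        mc, mo = 12.011, 15.999
        expected = np.sqrt(mc * 1.0 / (mc + mo))
        assert rmsd(a, b, mass_weighted=True) == pytest.approx(expected)


class TestRmsf:
    def test_single_conformation_zero(self, random_cloud):
        np.testing.assert_array_equal(rmsf(random_cloud(n=5, m=1)), 0.0)

    def test_two_conformations_half_distance(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        assert rmsf(Structure(coords))[0] == pytest.approx(1.0)

    def test_three_z_positions(self):
        # z in {-1, 0, 1} -> sqrt(2/3)
        coords = np.zeros((3, 1, 3))
        coords[:, 0, 2] = [-1.0, 0.0, 1.0]
        assert rmsf(Structure(coords))[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_invariant_under_global_rigid_transform(self, rng):
        s = Structure(rng.normal(size=(4, 6, 3)))
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        moved = apply_transform(s, t, conformation="all")
        np.testing.assert_allclose(rmsf(moved), rmsf(s), atol=1e-9)


# ---------------------------------------------------------------------------
# center of mass / distance matrix
# ---------------------------------------------------------------------------

class TestCenterOfMass:
    def test_equal_masses(self):
        s = Structure(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        np.testing.assert_allclose(center_of_mass(s), [1, 0, 0])

    def test_weighted(self):
        meta = pd.DataFrame({"mass": [1.0, 3.0], "element": ["C", "C"]})
        s = Structure(np.array([[0.0, 0, 0], [4.0, 0, 0]]), meta)
        np.testing.assert_allclose(center_of_mass(s), [3, 0, 0])

    def test_equal_masses_match_centroid(self, rng):
        s = Structure(rng.normal(size=(20, 3)))
        np.testing.assert_allclose(
            center_of_mass(s), centroid(s), atol=1e-12)

    def test_zero_mass_raises(self):
        meta = pd.DataFrame({"mass": [0.0], "element": ["X"]})
        s = Structure(np.zeros((1, 3)), meta)
        with pytest.raises(MassError):
            center_of_mass(s)


class TestDistanceMatrix:
    def test_self_single_point(self):
        s = Structure(np.zeros((1, 3)))
        np.testing.assert_array_equal(distance_matrix(s, s), [[0.0]])

    def test_two_points(self):
        a = Structure(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        d = distance_matrix(a, a)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)

    def test_matches_double_loop(self, rng):
        a = Structure(rng.normal(size=(4, 3)))
        b = Structure(rng.normal(size=(3, 3)))
        expected = np.array([
            [np.linalg.norm(a.xyz[i] - b.xyz[j]) for j in range(3)]
            for i in range(4)
        ])
        np.testing.assert_allclose(distance_matrix(a, b), expected, atol=1e-12)


class TestKabschHelper:
    def test_kabsch_equals_sampled_best(self, rng):
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        t = kabsch(P, Q)
        ours = np.sqrt(np.mean(np.sum((t.apply(P) - Q) ** 2, axis=1)))
        r2 = np.random.default_rng(11)
        for _ in range(500):
            R = random_rotation(r2)
            Pc = P - P.mean(axis=0)
            fit = Pc @ R.T + Q.mean(axis=0)
            assert ours <= np.sqrt(np.mean(np.sum((fit - Q) ** 2, axis=1))) + 1e-9
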