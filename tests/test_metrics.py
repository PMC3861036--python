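import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ureamd.metrics import (MetricSeries, assign_ss, kabsch_superpose,
                            radius_of_gyration, rg_series, rmsd_series,
                            s2_index, sasa, sasa_normalize, sasa_partition,
                            structure_index, tm_score)
from ureamd.system import Trajectory
from ureamd.synthetic import build_extended_protein, build_toy_protein


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.normal(0, 3, (10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(0, 3, (10, 3))
        R, t = random_rigid(rng)
        Rout, tout, rmsd = kabsch_superpose(pts, pts @ R.T + t)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(Rout) == pytest.approx(1.0)

    def test_two_point_stretch(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0]])
        mob = np.array([[0.0, 0, 0], [3, 0, 0]])
        _, _, rmsd = kabsch_superpose(ref, mob)
        assert rmsd == pytest.approx(1.0)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((1, 3)), np.zeros((1, 3)))


class TestRmsdSeries:
    def test_repeated_reference_is_zero(self, helix16):
        system, native = helix16
        traj = Trajectory(np.tile(native, (5, 1, 1)), np.arange(5) * 0.1)
        s = rmsd_series(traj, native, system.protein_heavy_indices())
        assert np.allclose(s.values, 0.0, atol=1e-9)

    def test_rigid_tumbling_is_zero(self, helix16, rng):
        system, native = helix16
        frames = []
        for _ in range(5):
            R, t = random_rigid(rng)
            frames.append(native @ R.T + t)
        traj = Trajectory(np.stack(frames), np.arange(5) * 0.1)
        s = rmsd_series(traj, native, system.protein_heavy_indices())
        assert np.allclose(s.values, 0.0, atol=1e-8)

    def test_interpolation_monotone(self, helix16):
        system, native = helix16
        _, extended = build_extended_protein(16)
        fr = np.linspace(0, 1, 20)
        coords = native[None] * (1 - fr)[:, None, None] + extended[None] * fr[:, None, None]
        traj = Trajectory(coords, np.arange(20) * 0.1)
        s = rmsd_series(traj, native, system.protein_heavy_indices())
        assert np.all(np.diff(s.values) >= -1e-9)

    def test_empty_selection(self, helix16):
        system, native = helix16
        traj = Trajectory(native[None], [0.0])
        with pytest.raises(ValueError):
            rmsd_series(traj, native, [])


class TestRadiusOfGyration:
    def test_two_points(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [2, 0, 0]])) == pytest.approx(1.0)

    def test_cube_corners(self):
        pts = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                        for z in (-1, 1)], dtype=float)
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(3))

    def test_single_point(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_rigid_invariance(self, helix16, rng):
        system, native = helix16
        R, t = random_rigid(rng)
        sel = system.protein_heavy_indices()
        assert radius_of_gyration(native, sel) == pytest.approx(
            radius_of_gyration(native @ R.T + t, sel))


class TestSasa:
    def test_lone_sphere_closed_form(self, helix16):
        from ureamd.system import MolecularSystem, Atom, Residue, classify_system
        atoms = [Atom(1, "CX", "C", True, 0, "ALA", "A")]
        res = Residue(0, "ALA", atom_indices=[0])
        s = classify_system(MolecularSystem(atoms, [res]))
        a = sasa(np.zeros((1, 3)), s, n_points=960)
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert a[0] == pytest.approx(exact, rel=0.02)

    def test_distant_atoms_additive(self):
        from ureamd.system import MolecularSystem, Atom, Residue, classify_system
        atoms = [Atom(i + 1, "CX", "C", True, 0, "ALA", "A") for i in range(2)]
        res = Residue(0, "ALA", atom_indices=[0, 1])
        s = classify_system(MolecularSystem(atoms, [res]))
        a = sasa(np.array([[0.0, 0, 0], [100.0, 0, 0]]), s, n_points=960)
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert np.allclose(a, exact, rtol=1e-6)

    def test_caged_atom_zero(self):
        from ureamd.system import MolecularSystem, Atom, Residue, classify_system
        # octahedral cage of 6 large neighbors around a central atom
        cage = np.array([[3, 0, 0], [-3, 0, 0], [0, 3, 0], [0, -3, 0],
                         [0, 0, 3], [0, 0, -3]], dtype=float) * 0.8
        pts = np.vstack([[0, 0, 0], cage])
        atoms = [Atom(i + 1, "SX", "S", True, 0, "ALA", "A")
                 for i in range(len(pts))]
        res = Residue(0, "ALA", atom_indices=list(range(len(pts))))
        s = classify_system(MolecularSystem(atoms, [res]))
        a = sasa(pts, s, n_points=960)
        assert a[0] == 0.0

    def test_convergence_960_vs_4000(self, rng):
        from ureamd.system import MolecularSystem, Atom, Residue, classify_system
        pts = rng.uniform(0, 8, (12, 3))
        atoms = [Atom(i + 1, "CX", "C", True, 0, "ALA", "A") for i in range(12)]
        res = Residue(0, "ALA", atom_indices=list(range(12)))
        s = classify_system(MolecularSystem(atoms, [res]))
        a = sasa(pts, s, n_points=960).sum()
        b = sasa(pts, s, n_points=4000).sum()
        assert a == pytest.approx(b, rel=0.02)

    def test_missing_radius(self, helix16):
        system, native = helix16
        with pytest.raises(KeyError):
            sasa(native, system, radii={"N": 1.55, "O": 1.52})

    def test_partition_conservation(self, rng):
        from ureamd.synthetic import build_toy_protein
        seq = ["LEU", "SER", "LYS", "ALA"] * 4
        system, native = build_toy_protein("helix", 16, sequence=seq)
        areas = sasa(native, system)
        total, polar, apolar, per_res = sasa_partition(areas, system)
        assert polar + apolar == pytest.approx(total)
        assert sum(per_res.values()) == pytest.approx(total)
        assert polar > 0 and apolar > 0

    def test_rigid_invariance(self, helix16, rng):
        system, native = helix16
        R, t = random_rigid(rng)
        a = sasa(native, system, n_points=960)
        b = sasa(native @ R.T + t, system, n_points=960)
        assert np.abs(a - b).sum() / a.sum() < 0.02
        assert a.sum() == pytest.approx(b.sum(), rel=0.01)


class TestSasaNormalize:
    def test_scaling(self):
        s = MetricSeries("SASA", [6000.0], [0.0], "A2")
        ref = MetricSeries("SASA", [5000.0, 5000.0], [0.0, 1.0], "A2")
        assert sasa_normalize(s, ref).values[0] == pytest.approx(1.2)

    def test_self_normalization_unit_mean(self, rng):
        v = rng.uniform(4000, 6000, 50)
        s = MetricSeries("SASA", v, np.arange(50.0), "A2")
        assert np.mean(sasa_normalize(s, s).values) == pytest.approx(1.0)

    def test_zero_reference(self):
        s = MetricSeries("SASA", [1.0], [0.0], "A2")
        ref = MetricSeries("SASA", [0.0], [0.0], "A2")
        with pytest.raises(ValueError):
            sasa_normalize(s, ref)


class TestTmScore:
    def test_self_is_one(self, rng):
        pts = rng.normal(0, 5, (30, 3))
        assert tm_score(pts, pts) == pytest.approx(1.0)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(0, 5, (30, 3))
        R, t = random_rigid(rng)
        assert tm_score(pts, pts @ R.T + t) == pytest.approx(1.0)

    def test_all_residues_at_d0(self, rng):
        pts = rng.normal(0, 5, (20, 3))
        d0 = 1.24 * 5 ** (1 / 3) - 1.8
        mod = pts.copy()
        mod[:, 2] += d0 * np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        assert tm_score(pts, mod, superpose=False) == pytest.approx(0.5)

    def test_refine_never_worse(self, rng):
        for _ in range(5):
            pts = rng.normal(0, 5, (25, 3))
            mod = pts + rng.normal(0, 2.0, pts.shape)
            assert tm_score(pts, mod, refine=True) >= tm_score(
                pts, mod, refine=False) - 1e-12

    def test_bounded(self, rng):
        pts = rng.normal(0, 5, (20, 3))
        mod = rng.normal(0, 5, (20, 3))
        assert 0.0 < tm_score(pts, mod) <= 1.0

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            tm_score(np.zeros((10, 3)), np.zeros((10, 3)))


class TestSecondaryStructure:
    def test_ideal_helix_interior_H(self):
        system, native = build_toy_protein("helix", 12)
        labels = assign_ss(native, system)
        assert all(l == "H" for l in labels[2:-2])

    def test_extended_chain_all_coil(self):
        system, native = build_extended_protein(12)
        assert all(l == "C" for l in assign_ss(native, system))

    def test_hairpin_strands_E(self):
        system, native = build_toy_protein("hairpin", 14)
        labels = assign_ss(native, system)
        # strands are residues 0-4 and 9-13; interior must be E
        assert all(l == "E" for l in labels[1:4])
        assert all(l == "E" for l in labels[10:13])
        assert all(l == "C" for l in labels[5:9])

    def test_missing_backbone_warns_coil(self):
        system, native = build_toy_protein("beads", 8)
        with pytest.warns(UserWarning):
            labels = assign_ss(native, system)
        assert all(l == "C" for l in labels)


class TestS2AndStructureIndex:
    def test_native_is_one(self):
        native = np.array(list("HHHHEECC"))
        assert s2_index(native, native) == 1.0

    def test_half_retained(self):
        native = np.array(list("HHHHCC"))
        current = np.array(list("HHCCCC"))
        assert s2_index(current, native) == pytest.approx(0.5)

    def test_all_coil_zero(self):
        native = np.array(list("HHHH"))
        assert s2_index(np.array(list("CCCC")), native) == 0.0

    def test_degenerate_warns_one(self):
        native = np.array(list("CCCC"))
        with pytest.warns(UserWarning):
            assert s2_index(native, native) == 1.0

    @pytest.mark.parametrize("s2,s3,mode,expected", [
        (1.0, 1.0, "mean", 1.0),
        (0.8, 0.6, "mean", 0.7),
        (0.8, 0.6, "s3_only", 0.6),
    ])
    def test_structure_index(self, s2, s3, mode, expected):
        assert structure_index(s2, s3, mode) == pytest.approx(expected)

    def test_structure_index_range_check(self):
        with pytest.raises(ValueError):
            structure_index(1.2, 0.5)
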