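import numpy as np
import pytest

from ureamd.solvation import (FSS, BULK, INTERMEDIATE, NonbondedParams,
                              cc_uw, long_residence_report, nonbonded_energy,
                              residence_events, shell_assign,
                              shell_assign_series, shell_ratio_series)
from ureamd.synthetic import (SolventSpec, StickySpec, SyntheticSpec,
                              synthesize_trajectory)
from ureamd.system import (Atom, MolecularSystem, Residue, Trajectory,
                           classify_system)


def solvated_system(water_pos, urea_pos, protein_pos=((0.0, 0.0, 0.0),)):
    """Single-heavy-atom protein beads + point water/urea molecules."""
    atoms, residues, coords = [], [], []

    def add(resname, names_elems, xyz_list):
        ridx = len(residues)
        res = Residue(index=ridx, name=resname, chain="A")
        for (name, elem), xyz in zip(names_elems, xyz_list):
            atoms.append(Atom(len(atoms) + 1, name, elem,
                              elem.upper() != "H", ridx, resname, "A"))
            res.atom_indices.append(len(coords))
            coords.append(np.asarray(xyz, dtype=float))
        residues.append(res)

    for p in protein_pos:
        add("ALA", [("CA", "C")], [p])
    for w in water_pos:
        add("HOH", [("O", "O")], [w])
    for u in urea_pos:
        add("URE", [("C", "C")], [u])
    system = classify_system(MolecularSystem(atoms, residues))
    return system, np.stack(coords)


class TestShellAssign:
    def test_three_band_geometry(self):
        system, frame = solvated_system(
            water_pos=[(7.0, 0, 0)], urea_pos=[(4.0, 0, 0), (5.5, 0, 0)])
        asn = shell_assign(frame, system)
        by_res = dict(zip(asn.molecule_residues, asn.labels[0]))
        assert by_res[2] == FSS          # urea at 4.0
        assert by_res[3] == INTERMEDIATE  # urea at 5.5
        assert by_res[1] == BULK         # water at 7.0

    def test_labels_partition_molecules(self, sticky_bundle):
        asn = shell_assign(sticky_bundle.trajectory.coordinates[0],
                           sticky_bundle.system,
                           box=sticky_bundle.trajectory.box[0])
        n_solvent = len(sticky_bundle.system.solvent_molecules())
        assert asn.labels.shape == (1, n_solvent)
        assert set(np.unique(asn.labels)) <= {FSS, INTERMEDIATE, BULK}

    def test_inverted_cutoffs_raise(self):
        system, frame = solvated_system([(7.0, 0, 0)], [(4.0, 0, 0)])
        with pytest.raises(ValueError):
            shell_assign(frame, system, fss_cutoff=6.0, bulk_cutoff=5.0)


class TestShellRatios:
    def test_simple_counts(self):
        waters = [(4.0, y, 0) for y in np.linspace(-2, 2, 30)]
        ureas = [(0, 4.0, z) for z in np.linspace(-2, 2, 10)]
        system, frame = solvated_system(waters, ureas)
        asn = shell_assign(frame, system)
        ratios = shell_ratio_series(asn)
        assert ratios.fss_mean == pytest.approx(3.0)

    def test_zero_urea_frames_excluded(self):
        system, frame = solvated_system([(4.0, 0, 0)], [(20.0, 0, 0)])
        asn = shell_assign(frame, system)
        ratios = shell_ratio_series(asn)
        assert np.isnan(ratios.fss_ratio[0])
        assert ratios.n_excluded_fss == 1

    def test_uniform_mixture_null_calibration(self):
        spec = SyntheticSpec(seed=4, dt_ns=0.1, n_frames=150, protein="helix",
                             n_residues=16, box=(40.0, 40.0, 40.0),
                             solvent=SolventSpec(n_water=900, n_urea=150,
                                                 mode="resample"))
        res = synthesize_trajectory(spec)
        asn = shell_assign_series(res.trajectory, res.system)
        ratios = shell_ratio_series(asn, res.trajectory.times)
        se_f = np.nanstd(ratios.fss_ratio) / np.sqrt(150)
        se_b = np.nanstd(ratios.bulk_ratio) / np.sqrt(150)
        se = np.hypot(se_f, se_b)
        assert abs(ratios.fss_pooled - ratios.bulk_pooled) < 3 * se

    def test_enrichment_factor_recovered(self):
        spec = SyntheticSpec(seed=3, dt_ns=0.1, n_frames=150, protein="helix",
                             n_residues=16, box=(40.0, 40.0, 40.0),
                             solvent=SolventSpec(n_water=900, n_urea=150,
                                                 mode="resample",
                                                 fss_enrichment=2.0))
        res = synthesize_trajectory(spec)
        asn = shell_assign_series(res.trajectory, res.system)
        ratios = shell_ratio_series(asn, res.trajectory.times)
        assert ratios.fss_pooled == pytest.approx(
            res.ground_truth.expected_fss_ratio, rel=0.10)
        assert ratios.bulk_pooled == pytest.approx(
            res.ground_truth.expected_bulk_ratio, rel=0.10)


class TestCcUw:
    def test_simple_ratio(self):
        # one protein bead, 6 urea and 12 water atoms in contact every frame
        waters = [(2.0 * np.cos(a), 2.0 * np.sin(a), 0)
                  for a in np.linspace(0, 2 * np.pi, 12, endpoint=False)]
        ureas = [(2.0 * np.cos(a), 0, 2.0 * np.sin(a))
                 for a in np.linspace(0.3, 2 * np.pi + 0.3, 6, endpoint=False)]
        system, frame = solvated_system(waters, ureas)
        traj = Trajectory(np.tile(frame, (3, 1, 1)), np.arange(3) * 0.1)
        coeffs, flagged = cc_uw(traj, system, group_by="polarity_class")
        assert coeffs["hydrophobic"] == pytest.approx(0.5)
        assert not flagged

    def test_zero_urea_contacts(self):
        system, frame = solvated_system([(2.0, 0, 0)], [(30.0, 0, 0)])
        traj = Trajectory(frame[None], [0.0])
        coeffs, _ = cc_uw(traj, system)
        assert coeffs["hydrophobic"] == 0.0

    def test_sticky_core_preference(self):
        spec = SyntheticSpec(seed=23, dt_ns=0.05, n_frames=1500,
                             protein="helix", n_residues=16,
                             box=(32.0, 32.0, 32.0),
                             solvent=SolventSpec(n_water=80, n_urea=30),
                             sticky=StickySpec(k_off=0.25,
                                               target_residues=[6, 7, 8, 9]))
        res = synthesize_trajectory(spec)
        for r in res.system.residues:
            if r.species == "protein":
                r.is_core = r.index in (6, 7, 8, 9)
        coeffs, _ = cc_uw(res.trajectory, res.system, group_by="core")
        assert coeffs["core"] > coeffs["non_core"]


class TestResidenceEvents:
    def _one_molecule_traj(self, contact_frames, n_frames=12, dt=0.1):
        """Urea bead hopping between 2.0 (contact) and 10.0 (no contact)."""
        system, frame = solvated_system([], [(10.0, 0, 0)])
        coords = np.tile(frame, (n_frames, 1, 1))
        for f in contact_frames:
            coords[f, 1] = [2.0, 0, 0]
        return system, Trajectory(coords, np.arange(n_frames) * dt)

    def test_duration_arithmetic(self):
        system, traj = self._one_molecule_traj(range(2, 6))
        events = residence_events(traj, system, species="urea")
        assert len(events) == 1
        assert events[0].duration_ns == pytest.approx(0.4)

    def test_gap_tolerance_merging(self):
        frames = list(range(1, 6)) + list(range(7, 10))
        system, traj = self._one_molecule_traj(frames)
        ev0 = residence_events(traj, system, species="urea",
                               gap_tolerance_frames=0)
        assert [pytest.approx(e.duration_ns) for e in ev0] == [0.5, 0.3]
        ev1 = residence_events(traj, system, species="urea",
                               gap_tolerance_frames=1)
        assert len(ev1) == 1
        assert ev1[0].duration_ns == pytest.approx(0.9)

    def test_sticky_ground_truth_events_exact(self, sticky_bundle):
        events = residence_events(sticky_bundle.trajectory,
                                  sticky_bundle.system, species="urea")
        measured = sorted((e.molecule_residue, e.start_frame,
                           e.start_frame + e.n_frames - 1) for e in events)
        assert measured == sorted(sticky_bundle.ground_truth.residence_events)

    def test_durations_bounded_by_trajectory(self, sticky_bundle):
        events = residence_events(sticky_bundle.trajectory,
                                  sticky_bundle.system, species="urea")
        total = {}
        for e in events:
            total[e.molecule_residue] = total.get(e.molecule_residue, 0) \
                + e.duration_ns
        duration = sticky_bundle.trajectory.n_frames \
            * sticky_bundle.trajectory.dt_ns
        assert all(v <= duration + 1e-9 for v in total.values())

    def test_water_unsticky_is_shorter(self, sticky_bundle):
        ev_u = residence_events(sticky_bundle.trajectory,
                                sticky_bundle.system, species="urea")
        ev_w = residence_events(sticky_bundle.trajectory,
                                sticky_bundle.system, species="water")
        mean_u = np.mean([e.duration_ns for e in ev_u
                          if e.molecule_residue != 16])
        mean_w = np.mean([e.duration_ns for e in ev_w])
        assert mean_u > mean_w


class TestLongResidenceReport:
    def test_scripted_long_binder_top_ranked(self, sticky_bundle):
        events = residence_events(sticky_bundle.trajectory,
                                  sticky_bundle.system, species="urea")
        report = long_residence_report(sticky_bundle.trajectory,
                                       sticky_bundle.system, events,
                                       min_duration_ns=20.0)
        assert len(report) == 1
        # molecule 0 is the first solvent residue (index 16)
        assert report[0]["molecule_residue"] == 16
        assert report[0]["dots"]  # dot map is non-empty

    def test_no_event_above_threshold(self, sticky_bundle):
        events = residence_events(sticky_bundle.trajectory,
                                  sticky_bundle.system, species="urea")
        assert long_residence_report(sticky_bundle.trajectory,
                                     sticky_bundle.system, events,
                                     min_duration_ns=1e6) == []


class TestNonbondedEnergy:
    def test_coulomb_pair(self):
        p = NonbondedParams([1.0, -1.0], [1.0, 1.0], [0.0, 0.0])
        frame = np.array([[0.0, 0, 0], [3.3206, 0, 0]])
        elec, vdw = nonbonded_energy(frame, p, [0], [1])
        assert elec == pytest.approx(-332.0636 / 3.3206)
        assert vdw == 0.0

    def test_lj_zero_at_sigma(self):
        p = NonbondedParams([0.0, 0.0], [3.0, 3.0], [0.2, 0.2])
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        _, vdw = nonbonded_energy(frame, p, [0], [1])
        assert vdw == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum(self):
        p = NonbondedParams([0.0, 0.0], [3.0, 3.0], [0.2, 0.2])
        frame = np.array([[0.0, 0, 0], [3.0 * 2 ** (1 / 6), 0, 0]])
        _, vdw = nonbonded_energy(frame, p, [0], [1])
        assert vdw == pytest.approx(-0.2)

    def test_symmetric_in_group_order(self, rng):
        n = 10
        p = NonbondedParams(rng.uniform(-0.5, 0.5, n),
                            rng.uniform(2.5, 3.5, n),
                            rng.uniform(0.05, 0.3, n))
        frame = rng.uniform(0, 8, (n, 3))
        e1 = nonbonded_energy(frame, p, range(5), range(5, 10))
        e2 = nonbonded_energy(frame, p, range(5, 10), range(5))
        assert e1[0] == pytest.approx(e2[0])
        assert e1[1] == pytest.approx(e2[1])

    def test_linear_in_charge_product(self):
        frame = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        p1 = NonbondedParams([1.0, -1.0], [1.0, 1.0], [0.0, 0.0])
        p2 = NonbondedParams([2.0, -1.0], [1.0, 1.0], [0.0, 0.0])
        e1, _ = nonbonded_energy(frame, p1, [0], [1])
        e2, _ = nonbonded_energy(frame, p2, [0], [1])
        assert e2 == pytest.approx(2 * e1)

    def test_overlapping_groups_raise(self):
        p = NonbondedParams([0.0, 0.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            nonbonded_energy(np.zeros((2, 3)), p, [0, 1], [1])

    def test_clash_raises(self):
        p = NonbondedParams([1.0, 1.0], [1.0, 1.0], [0.0, 0.0])
        frame = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ValueError, match="clash"):
            nonbonded_energy(frame, p, [0], [1])
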