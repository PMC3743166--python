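"""Superposition, displacement, H-bond detection and axis descriptors."""

import math

import numpy as np
import pytest

from groovebind import builder
from groovebind.energetics import EnergyParams, hbond_energy
from groovebind.geometry import (
    DegenerateSelectionError,
    HBondGeometryCriteria,
    SelectionSpec,
    average_displacement,
    detect_hbonds,
    helix_ligand_angle,
    ring_geometry,
    superpose,
)
from groovebind.linalg import rotation_about_axis
from groovebind.model import AtomRecord, ComplexModel, Role


FIT_3_6 = SelectionSpec(3, 6, "heavy")


def _rigid_copy(model, axis=(1.0, 0.5, -0.2), angle=25.0, shift=(3.0, -1.0, 2.0)):
    R = rotation_about_axis(np.array(axis), angle)
    return model.with_coordinates(model.coordinates @ R.T + np.array(shift))


class TestSuperpose:
    def test_self_superposition_is_identity(self, complex_model):
        transform, rmsd = superpose(complex_model, complex_model, FIT_3_6)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self, complex_model):
        moved = _rigid_copy(complex_model)
        _, rmsd = superpose(moved, complex_model, FIT_3_6)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_symmetric(self, complex_model, small_ensemble):
        other = small_ensemble.snapshots[3]
        _, r_ab = superpose(complex_model, other, FIT_3_6)
        _, r_ba = superpose(other, complex_model, FIT_3_6)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_toy_set_matches_rotation_grid_oracle(self):
        """Optimal RMSD of two 4-point sets agrees with a brute-force scan
        over single-axis rotation angles for a constructed z-rotation."""
        rng = np.random.default_rng(5)
        # planar sets with in-plane noise: the optimal proper rotation is
        # about z, so a fine scan over that single angle is a true oracle
        x = rng.normal(size=(4, 3))
        x[:, 2] = 0.0
        true = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 73.0)
        noise = rng.normal(scale=0.05, size=(4, 3))
        noise[:, 2] = 0.0
        y = x @ true.T + noise

        def as_model(coords):
            atoms = [
                AtomRecord(f"C{k}", "C", "LIG", 1, "L", c, Role.LIGAND)
                for k, c in enumerate(coords)
            ]
            return ComplexModel(atoms, 0, None, "L")

        _, rmsd = superpose(as_model(x), as_model(y), np.arange(4))
        best = np.inf
        xc, yc = x - x.mean(0), y - y.mean(0)
        for ang in np.arange(0.0, 360.0, 0.01):
            R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), ang)
            best = min(best, float(np.sqrt(((xc @ R.T - yc) ** 2).sum(1).mean())))
        # the free rotation can only do at least as well as the grid
        assert rmsd <= best + 1e-3
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_collinear_selection_rejected(self):
        atoms = [
            AtomRecord(f"C{k}", "C", "LIG", 1, "L", np.array([k, 0.0, 0.0]),
                       Role.LIGAND)
            for k in range(4)
        ]
        line = ComplexModel(atoms, 0, None, "L")
        with pytest.raises(DegenerateSelectionError):
            superpose(line, line, np.arange(4))


class TestDisplacement:
    LIG = SelectionSpec(atom_class="ligand_heavy")

    def test_identical_copies_give_zero(self, complex_model):
        mean, sd = average_displacement(
            [complex_model, complex_model, complex_model], FIT_3_6, self.LIG
        )
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_ligand_shift_measured(self, complex_model):
        shifted_coords = complex_model.coordinates.copy()
        shifted_coords[complex_model.ligand_indices] += np.array([1.0, 0.0, 0.0])
        shifted = complex_model.with_coordinates(shifted_coords)
        mean, sd = average_displacement([complex_model, shifted], FIT_3_6, self.LIG)
        # both structures sit 0.5 A from the mean structure
        assert mean == pytest.approx(0.5, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_jitter_statistics(self, complex_model):
        """Pure rigid translation jitter: per-snapshot ligand displacement
        from the mean follows the 3-D Gaussian mean sigma*sqrt(8/pi)."""
        sigma = 0.4
        ens = builder.generate_ensemble(
            complex_model, 200, 0.0, (sigma, 0.0), seed=12
        )
        mean, _ = average_displacement(ens.snapshots, FIT_3_6, self.LIG)
        assert mean == pytest.approx(sigma * math.sqrt(8 / math.pi), rel=0.10)

    def test_topology_mismatch_rejected(self, complex_model, duplex):
        with pytest.raises(ValueError):
            average_displacement([complex_model, duplex], FIT_3_6, self.LIG)


def _hbond_toy(length, deviation_deg):
    """D-H...A triple with given H...A length and linearity deviation."""
    t = math.radians(deviation_deg)
    acceptor = np.array([1.01 + length * math.cos(t), length * math.sin(t), 0.0])
    atoms = [
        AtomRecord("N2", "N", "DG", 1, "A", np.zeros(3), Role.DNA_BASE),
        AtomRecord("H21", "H", "DG", 1, "A", np.array([1.01, 0, 0]), Role.DNA_BASE),
        AtomRecord("NP1A", "N", "LIG", 1, "L", acceptor, Role.LIGAND),
    ]
    return ComplexModel(atoms, 0, None, "L")


class TestHBondDetection:
    def test_inside_both_thresholds_detected(self):
        bonds = detect_hbonds(_hbond_toy(2.5, 10.0))
        assert len(bonds) == 1
        assert bonds[0].length == pytest.approx(2.5, abs=1e-6)
        assert bonds[0].angle == pytest.approx(10.0, abs=1e-6)

    def test_angle_failure_rejected(self):
        assert detect_hbonds(_hbond_toy(2.5, 30.0)) == []

    def test_length_failure_rejected(self):
        assert detect_hbonds(_hbond_toy(2.7, 10.0)) == []

    def test_matches_brute_force_on_fixture(self, complex_model):
        criteria = HBondGeometryCriteria(max_length=3.5, max_angle=45.0)
        fast = {
            (b.donor, b.hydrogen, b.acceptor)
            for b in detect_hbonds(complex_model, criteria)
        }
        coords = complex_model.coordinates
        atoms = complex_model.atoms
        is_dna = np.zeros(complex_model.n_atoms, bool)
        is_dna[complex_model.dna_indices] = True
        slow = set()
        no = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
        for h, ah in enumerate(atoms):
            if not ah.is_hydrogen:
                continue
            cov = [(np.linalg.norm(coords[i] - coords[h]), i) for i in no]
            cov = [c for c in cov if c[0] < 1.25]
            if not cov:
                continue
            donor = min(cov)[1]
            for acc in no:
                if acc == donor or is_dna[acc] == is_dna[h]:
                    continue
                length = np.linalg.norm(coords[acc] - coords[h])
                if not 1.25 <= length < criteria.max_length:
                    continue
                v1 = coords[h] - coords[donor]
                v2 = coords[acc] - coords[h]
                dev = math.degrees(
                    math.acos(
                        np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                                -1, 1)
                    )
                )
                if dev < criteria.max_angle:
                    slow.add((donor, h, acc))
        assert fast == slow

    def test_strict_list_subset_of_energy_3A_list(self, complex_model):
        """Geometric bonds (<2.6 A, <25 deg) are a subset of the 3 A
        distance-only contacts used by the enthalpy estimator."""
        strict = detect_hbonds(complex_model, HBondGeometryCriteria())
        _, ledger = hbond_energy(complex_model, EnergyParams())
        loose_pairs = {(t.i, t.j) for t in ledger}
        for b in strict:
            assert (b.hydrogen, b.acceptor) in loose_pairs


class TestRingGeometry:
    def _ring_model(self, proton_pos):
        atoms = []
        for k in range(6):
            a = math.radians(60 * k)
            atoms.append(
                AtomRecord(f"C{k}", "C", "LIG", 1, "L",
                           np.array([1.39 * math.cos(a), 1.39 * math.sin(a), 0.0]),
                           Role.LIGAND)
            )
        atoms.append(
            AtomRecord("H1'", "H", "DA", 1, "A", np.asarray(proton_pos, float),
                       Role.DNA_SUGAR)
        )
        return ComplexModel(atoms, 0, None, "L")

    def test_proton_on_normal(self):
        model = self._ring_model([0, 0, 3.0])
        dist, elev = ring_geometry(model, 6, range(6))
        assert dist == pytest.approx(3.0, abs=1e-9)
        assert elev == pytest.approx(90.0, abs=1e-9)

    def test_proton_in_plane(self):
        model = self._ring_model([5.0, 0, 0])
        dist, elev = ring_geometry(model, 6, range(6))
        assert dist == pytest.approx(5.0, abs=1e-9)
        assert elev == pytest.approx(0.0, abs=1e-9)

    def test_arbitrary_point_matches_vector_algebra(self):
        p = np.array([2.0, -1.0, 2.5])
        model = self._ring_model(p)
        dist, elev = ring_geometry(model, 6, range(6))
        # ring centroid is the origin, plane normal is z
        assert dist == pytest.approx(float(np.linalg.norm(p)), abs=1e-6)
        expected = math.degrees(math.asin(abs(p[2]) / np.linalg.norm(p)))
        assert elev == pytest.approx(expected, abs=1e-6)


class TestHelixLigandAngle:
    def _with_metals(self, duplex, direction):
        """Duplex plus a two-metal dummy dimer along ``direction``."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        centre = np.array([12.0, 0.0, 18.0])
        atoms = list(duplex.atoms) + [
            AtomRecord("RUA", "Ru", "LIG", 1, "L", centre - 6 * d, Role.METAL),
            AtomRecord("RUB", "Ru", "LIG", 1, "L", centre + 6 * d, Role.METAL),
        ]
        return ComplexModel(atoms, duplex.duplex_length, duplex.strand_chains, "L")

    def test_parallel_axis_zero(self, duplex):
        # the centroid-fitted axis deviates from the exact helix axis by a
        # fraction of a degree on a 12-mer
        assert helix_ligand_angle(self._with_metals(duplex, [0, 0, 1])) == (
            pytest.approx(0.0, abs=1.0)
        )

    def test_perpendicular_axis_ninety(self, duplex):
        assert helix_ligand_angle(self._with_metals(duplex, [1, 0, 0])) == (
            pytest.approx(90.0, abs=1.0)
        )

    def test_constructed_65_degrees_recovered(self, duplex, ligand):
        model = builder.place_in_minor_groove(
            duplex, ligand, builder.PoseSpec(tilt=65.0)
        )
        assert helix_ligand_angle(model) == pytest.approx(65.0, abs=3.0)

    def test_missing_metals_rejected(self, duplex):
        with pytest.raises(ValueError):
            helix_ligand_angle(duplex)


class TestRigidInvariance:
    def test_descriptors_invariant_under_global_motion(self, complex_model):
        moved = _rigid_copy(complex_model, axis=(0.3, 1.0, 0.7), angle=61.0)
        a_angle = helix_ligand_angle(complex_model)
        b_angle = helix_ligand_angle(moved)
        assert b_angle == pytest.approx(a_angle, abs=1e-6)
        crit = HBondGeometryCriteria(max_length=3.5, max_angle=45.0)
        a_bonds = {(b.hydrogen, b.acceptor) for b in detect_hbonds(complex_model, crit)}
        b_bonds = {(b.hydrogen, b.acceptor) for b in detect_hbonds(moved, crit)}
        assert a_bonds == b_bonds
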