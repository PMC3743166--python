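"""r^-6 averaging, violation logic and assignment enumeration/selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groovebind import builder
from groovebind.model import ComplexModel, Ensemble
from groovebind.pipeline import (
    TRUE_ASSIGNMENT,
    default_resonance_restraints,
    monomer_swap_map,
    score_assignment_classes,
)
from groovebind.restraints import (
    AssignmentCombination,
    AtomSelector,
    NOERestraint,
    ResonanceRestraint,
    check_violations,
    enumerate_assignments,
    noe_average_distance,
    read_restraints_tsv,
    score_assignment,
    select_assignment,
    write_restraints_tsv,
)
from tests.conftest import REFERENCE_DNOE_LIMITS, REFERENCE_DNOE_RUNS


def _two_atom_ensemble(distances):
    """Ensemble of a DNA proton and a ligand proton at given separations."""
    from groovebind.model import AtomRecord, Role

    snaps = []
    for d in distances:
        atoms = [
            AtomRecord("H1'", "H", "DA", 1, "A", np.zeros(3), Role.DNA_SUGAR),
            AtomRecord("HC1A", "H", "LIG", 1, "L", np.array([d, 0.0, 0.0]),
                       Role.LIGAND),
        ]
        snaps.append(ComplexModel(atoms, 0, None, "L"))
    return Ensemble(snaps)


RESTRAINT = NOERestraint(
    AtomSelector("A", 1, "H1'"), AtomSelector("L", 1, "HC1A"), 5.0, "weak"
)


class TestR6Average:
    def test_constant_ensemble_identity(self):
        ens = _two_atom_ensemble([3.1] * 7)
        assert noe_average_distance(ens, RESTRAINT) == pytest.approx(3.1, abs=1e-12)

    def test_two_snapshot_worked_example(self):
        # independent arithmetic: ((2^-6 + 4^-6)/2)^(-1/6) = 2.2390...
        expected = ((2.0 ** -6 + 4.0 ** -6) / 2.0) ** (-1.0 / 6.0)
        assert expected == pytest.approx(2.239, abs=0.001)
        ens = _two_atom_ensemble([2.0, 4.0])
        assert noe_average_distance(ens, RESTRAINT) == pytest.approx(expected, abs=1e-12)

    def test_single_snapshot(self):
        ens = _two_atom_ensemble([3.2])
        assert noe_average_distance(ens, RESTRAINT) == pytest.approx(3.2)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.5, 50.0), min_size=1, max_size=12))
    def test_power_mean_inequality_and_bounds(self, distances):
        ens = _two_atom_ensemble(distances)
        d_noe = noe_average_distance(ens, RESTRAINT)
        assert min(distances) - 1e-9 <= d_noe <= max(distances) + 1e-9
        assert d_noe <= np.mean(distances) + 1e-9

    def test_monotone_decreasing_in_each_distance(self):
        base = [3.0, 4.0, 5.0]
        d0 = noe_average_distance(_two_atom_ensemble(base), RESTRAINT)
        for k in range(3):
            shorter = list(base)
            shorter[k] -= 0.5
            dk = noe_average_distance(_two_atom_ensemble(shorter), RESTRAINT)
            assert dk < d0

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            noe_average_distance(_two_atom_ensemble([0.0]), RESTRAINT)


class TestViolations:
    def test_published_run_classification(self):
        """Applying the check to the published per-run d_NOE table reproduces
        the reported classification of the ten MD runs."""
        restraints = [
            NOERestraint(AtomSelector("B", 16, "H1'"), AtomSelector("L", 1, "HC1A"), l)
            for l in REFERENCE_DNOE_LIMITS
        ]
        consistent, only_weak_violated = [], []
        max_excess = {}
        for run in range(10):
            excess = check_violations(REFERENCE_DNOE_RUNS[:, run], restraints)
            max_excess[run + 1] = excess.max()
            if np.all(excess == 0):
                consistent.append(run + 1)
            elif excess[0] > 0 and np.all(excess[1:] == 0):
                only_weak_violated.append(run + 1)
        assert consistent == [4, 5, 6, 7, 10]
        assert max_excess[2] == pytest.approx(0.1, abs=1e-9)
        assert only_weak_violated == [1, 3, 8, 9]

    def test_single_excess_examples(self):
        r_weak = NOERestraint(
            AtomSelector("B", 16, "H1'"), AtomSelector("L", 1, "HC1A"), 5.0, "weak"
        )
        r_strong = NOERestraint(
            AtomSelector("B", 17, "H1'"), AtomSelector("L", 1, "HC1A"), 3.5, "strong"
        )
        assert check_violations([5.4], [r_weak])[0] == pytest.approx(0.4)
        assert check_violations([2.7], [r_strong])[0] == 0.0
        # boundary counts as satisfied
        assert check_violations([5.0, 3.5], [r_weak, r_strong]).max() == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            check_violations([1.0], [])

    def test_strength_limit_consistency_enforced(self):
        with pytest.raises(ValueError):
            NOERestraint(
                AtomSelector("B", 16, "H1'"), AtomSelector("L", 1, "HC1A"),
                4.0, "strong",
            )


def _brute_force_classes(protons, resonances, symmetry):
    injective = list(itertools.permutations(protons, len(resonances)))
    classes = set()
    for combo in injective:
        mapping = tuple(zip(resonances, combo))
        swapped = tuple((r, symmetry.get(p, p)) for r, p in mapping)
        classes.add(min(mapping, swapped))
    return len(injective), len(classes)


class TestEnumeration:
    def test_published_counts_p4_r2(self):
        protons = ["HC1A", "HC2A", "HC1B", "HC2B"]
        enum = enumerate_assignments(protons, ["r1", "r2"], monomer_swap_map(protons))
        assert enum.raw_count == 16
        assert enum.injective_count == 12
        assert enum.class_count == 6

    def test_identity_symmetry_keeps_all_injective(self):
        enum = enumerate_assignments(list("abcd"), ["r1", "r2"], {})
        assert enum.class_count == 12

    def test_single_candidate_single_resonance(self):
        enum = enumerate_assignments(["p"], ["r"], {})
        assert enum.raw_count == enum.injective_count == enum.class_count == 1

    @pytest.mark.parametrize("P,R", [(p, r) for p in range(1, 7) for r in range(1, 4) if p >= r])
    def test_counts_match_brute_force(self, P, R):
        protons = [f"p{k}" for k in range(P)]
        # pair protons (p0,p1), (p2,p3), ... as a fixed-point-free-as-possible
        # involution; an odd leftover maps to itself
        symmetry = {}
        for a, b in zip(protons[0::2], protons[1::2]):
            symmetry[a], symmetry[b] = b, a
        resonances = [f"r{k}" for k in range(R)]
        enum = enumerate_assignments(protons, resonances, symmetry)
        n_inj, n_cls = _brute_force_classes(protons, resonances, symmetry)
        assert enum.raw_count == P ** R
        assert enum.injective_count == n_inj == math.perm(P, R)
        assert enum.class_count == n_cls

    def test_non_involutive_symmetry_rejected(self):
        with pytest.raises(ValueError):
            enumerate_assignments(list("abc"), ["r"], {"a": "b", "b": "c", "c": "a"})


class TestScoring:
    def test_satisfied_restraints_score_zero(self, complex_model):
        combo = AssignmentCombination(tuple(sorted(TRUE_ASSIGNMENT.items())))
        score = score_assignment(combo, complex_model, default_resonance_restraints())
        assert score.restraint_term == 0.0
        assert score.total == score.steric_weight * score.steric_term

    def test_squared_excess_arithmetic(self):
        # a single restraint exceeded by 0.5 A contributes 0.25 A^2
        ens = _two_atom_ensemble([5.5])
        rr = ResonanceRestraint("r1", AtomSelector("A", 1, "H1'"), 5.0, "weak")
        combo = AssignmentCombination((("r1", "HC1A"),))
        score = score_assignment(combo, ens, [rr])
        assert score.restraint_term == pytest.approx(0.25)
        assert score.max_violation == pytest.approx(0.5)

    def test_adding_satisfied_restraint_keeps_score(self, complex_model):
        combo = AssignmentCombination(tuple(sorted(TRUE_ASSIGNMENT.items())))
        base = score_assignment(combo, complex_model, default_resonance_restraints())
        extra = default_resonance_restraints() + [
            ResonanceRestraint("r1", AtomSelector("B", 17, "H1'"), 5.0, "weak")
        ]
        more = score_assignment(combo, complex_model, extra)
        assert more.total == pytest.approx(base.total)

    def test_score_symmetric_on_symmetric_pose(self):
        """On the free (unplaced) symmetric dumbbell, a combination and its
        monomer-swap image give identical restraint terms against a probe
        equidistant from the swapped protons."""
        lig = builder.build_ligand(builder.LigandSpec(pivot_torsion=0.0))
        from groovebind.model import AtomRecord, Role

        pos = {a.atom_name: a.position for a in lig.atoms}
        mid = 0.5 * (pos["HC1A"] + pos["HC1B"]) + np.array([0.0, 0.0, 6.0])
        probe = AtomRecord("H1'", "H", "DA", 1, "A", mid, Role.DNA_SUGAR)
        model = ComplexModel(lig.atoms + [probe], 0, None, "L")
        rr = ResonanceRestraint("r1", AtomSelector("A", 1, "H1'"), 5.0, "weak")
        combo = AssignmentCombination((("r1", "HC1A"),))
        swapped = combo.apply_symmetry(monomer_swap_map())
        s1 = score_assignment(combo, model, [rr])
        s2 = score_assignment(swapped, model, [rr])
        assert s1.restraint_term == pytest.approx(s2.restraint_term, abs=1e-9)


class TestSelection:
    def _score(self, total, viol):
        combo = AssignmentCombination((("r1", "p"),))
        from groovebind.restraints import TargetFunctionScore

        return TargetFunctionScore(combo, total, 0.0, 1.0, viol)

    def test_clear_winner_accepted(self):
        scores = [self._score(0.13, 0.08)] + [
            self._score(0.43 + k, 0.35 + 0.1 * k) for k in range(5)
        ]
        report = select_assignment(scores, violation_tolerance=0.1)
        assert report.accepted
        assert report.winner.total == pytest.approx(0.13)

    def test_exact_tie_is_ambiguous(self):
        report = select_assignment([self._score(0.2, 0.0), self._score(0.2, 0.0)])
        assert report.status == "ambiguous"

    def test_winner_over_tolerance_is_ambiguous(self):
        report = select_assignment(
            [self._score(0.1, 0.3), self._score(0.5, 0.4)], violation_tolerance=0.1
        )
        assert report.status == "ambiguous"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_assignment([])

    def test_planted_assignment_recovered_on_ensembles(self, complex_model):
        rng_seeds = range(300, 310)
        symmetry = monomer_swap_map()
        true_keys = {
            tuple(sorted(TRUE_ASSIGNMENT.items())),
            tuple(sorted((r, symmetry[p]) for r, p in TRUE_ASSIGNMENT.items())),
        }
        for seed in rng_seeds:
            ens = builder.generate_ensemble(complex_model, 15, 0.3, (0.0, 0.0), seed)
            report = select_assignment(
                score_assignment_classes(ens, default_resonance_restraints())
            )
            assert report.accepted
            assert tuple(sorted(report.winner.combination.as_dict.items())) in true_keys


class TestTSV:
    def test_round_trip(self, complex_model, tmp_path):
        restraints = [
            NOERestraint.from_strength(
                AtomSelector("B", 16, "H1'"), AtomSelector("L", 1, "HC1A"), "weak"
            ),
            NOERestraint.from_strength(
                AtomSelector("B", 17, "H1'"), AtomSelector("L", 1, "HC2B"), "strong"
            ),
        ]
        path = tmp_path / "noe.tsv"
        write_restraints_tsv(restraints, str(path), complex_model)
        back = read_restraints_tsv(str(path))
        assert len(back) == 2
        assert back[0].upper_limit == 5.0 and back[0].strength == "weak"
        assert back[1].dna_proton == AtomSelector("B", 17, "H1'")
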