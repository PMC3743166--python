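"""NOE distance restraints: r^-6 averaging, violations, assignment selection.

An observed NOE between a DNA proton and a ligand proton is represented as
an upper distance limit (3.5 A for strong, 5.0 A for weak cross peaks).
Against a snapshot ensemble the relevant quantity is the r^-6 ensemble
average

    d_NOE = [ (1/N) * sum_i d_i^-6 ]^(-1/6),

a power mean dominated by the shortest sampled distances; a restraint is
satisfied when d_NOE does not exceed its limit (equality counts as
satisfied).

When the ligand resonances cannot be assigned uniquely, every assignment
combination (an injective mapping resonance -> candidate proton) is
enumerated, reduced to symmetry classes under the dumbbell's monomer-swap
involution, scored with a target function (squared restraint excesses plus
weighted squared van der Waals overlaps), and the combination with the
lowest score is accepted only if its violations stay within tolerance and
it wins by a clear margin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ComplexModel, Ensemble

__all__ = [
    "AtomSelector",
    "NOERestraint",
    "ResonanceRestraint",
    "AssignmentCombination",
    "AssignmentEnumeration",
    "TargetFunctionScore",
    "SelectionReport",
    "STRENGTH_LIMITS",
    "noe_average_distance",
    "check_violations",
    "enumerate_assignments",
    "score_assignment",
    "select_assignment",
    "read_restraints_tsv",
    "write_restraints_tsv",
    "DEFAULT_VDW_RADII",
]

#: Upper distance limits (A) implied by NOE strength classes.
STRENGTH_LIMITS = {"strong": 3.5, "weak": 5.0}

#: Per-element hard-sphere *lower-limit* radii (A) for the steric term of
#: the target function.  These are contact lower bounds in the spirit of
#: NMR structure-calculation van der Waals limits, not equilibrium radii:
#: a pair counts as violating only when it penetrates the summed limits.
DEFAULT_VDW_RADII = {
    "H": 0.8,
    "C": 1.15,
    "N": 1.05,
    "O": 1.0,
    "P": 1.2,
    "S": 1.2,
    "Ru": 1.2,
}


@dataclass(frozen=True)
class AtomSelector:
    """(chain, residue index, atom name) selector resolving to one atom."""

    chain_id: str
    residue_index: int
    atom_name: str

    def resolve(self, model: ComplexModel) -> int:
        return model.find_atom(self.chain_id, self.residue_index, self.atom_name)


@dataclass
class NOERestraint:
    """One NOE upper-limit restraint between a DNA and a ligand proton."""

    dna_proton: AtomSelector
    ligand_proton: AtomSelector
    upper_limit: float
    strength: str | None = None

    def __post_init__(self) -> None:
        if self.strength is not None:
            if self.strength not in STRENGTH_LIMITS:
                raise ValueError(f"unknown NOE strength {self.strength!r}")
            expected = STRENGTH_LIMITS[self.strength]
            if abs(self.upper_limit - expected) > 1e-9:
                raise ValueError(
                    f"{self.strength} NOE implies a {expected} A limit, "
                    f"got {self.upper_limit}"
                )
        if self.upper_limit <= 0:
            raise ValueError("upper_limit must be positive")

    @classmethod
    def from_strength(
        cls, dna_proton: AtomSelector, ligand_proton: AtomSelector, strength: str
    ) -> "NOERestraint":
        return cls(dna_proton, ligand_proton, STRENGTH_LIMITS[strength], strength)


@dataclass
class ResonanceRestraint:
    """A restraint anchored to an unassigned ligand resonance.

    The ligand partner is a resonance label; an AssignmentCombination maps
    it to a concrete candidate proton, turning this into an NOERestraint.
    """

    resonance: str
    dna_proton: AtomSelector
    upper_limit: float
    strength: str | None = None

    def resolve(self, proton: AtomSelector) -> NOERestraint:
        return NOERestraint(self.dna_proton, proton, self.upper_limit, self.strength)


def noe_average_distance(ensemble: Ensemble, restraint: NOERestraint) -> float:
    """r^-6 ensemble-averaged distance (A) between the restraint's protons.

    Uniform snapshot weights; raises on coincident atoms (zero distance).
    """
    top = ensemble.topology
    i = restraint.dna_proton.resolve(top)
    j = restraint.ligand_proton.resolve(top)
    d = ensemble.atom_distances(i, j)
    if np.any(d <= 0):
        raise ValueError("coincident atoms give a non-positive NOE distance")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def check_violations(
    d_noe_values: Sequence[float], restraints: Sequence[NOERestraint]
) -> np.ndarray:
    """Per-restraint upper-limit excesses max(0, d_NOE - limit).

    A run is consistent with the restraints iff every excess is zero;
    a distance exactly at its limit is satisfied.
    """
    if len(d_noe_values) != len(restraints):
        raise ValueError(
            f"{len(d_noe_values)} distances vs {len(restraints)} restraints"
        )
    excess = [max(0.0, d - r.upper_limit) for d, r in zip(d_noe_values, restraints)]
    return np.asarray(excess, dtype=float)


# ---------------------------------------------------------------------------
# assignment combinatorics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssignmentCombination:
    """One injective mapping resonance -> candidate proton."""

    mapping: tuple[tuple[str, str], ...]  # ordered (resonance, proton) pairs
    symmetry_class: tuple[tuple[str, str], ...] = ()

    @property
    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    def apply_symmetry(self, symmetry: Mapping[str, str]) -> "AssignmentCombination":
        swapped = tuple((res, symmetry.get(p, p)) for res, p in self.mapping)
        return AssignmentCombination(swapped, self.symmetry_class)


@dataclass
class AssignmentEnumeration:
    """Result of enumerating assignment combinations.

    ``raw_count`` counts all P^R mappings, ``injective_count`` those with no
    proton serving two resonances, and ``classes`` holds one representative
    per orbit of the symmetry involution applied jointly to all mapped
    protons.
    """

    raw_count: int
    injective_count: int
    classes: list[AssignmentCombination]

    @property
    def class_count(self) -> int:
        return len(self.classes)


def _validate_involution(symmetry: Mapping[str, str], protons: Iterable[str]) -> None:
    for p in protons:
        q = symmetry.get(p, p)
        if symmetry.get(q, q) != p:
            raise ValueError(f"symmetry map is not an involution at {p!r} -> {q!r}")


def enumerate_assignments(
    candidate_protons: Sequence[str],
    resonances: Sequence[str],
    symmetry: Mapping[str, str] | None = None,
) -> AssignmentEnumeration:
    """Enumerate injective resonance->proton assignments up to symmetry.

    ``symmetry`` is a self-inverse permutation of the candidate protons
    (e.g. the dumbbell monomer swap); orbits under applying it jointly to
    every mapped proton are collapsed to their lexicographically smallest
    representative.  With P candidates and R resonances the raw count is
    P^R; excluding repeated protons leaves P!/(P-R)! mappings.
    """
    P, R = len(candidate_protons), len(resonances)
    if R < 1 or P < R:
        raise ValueError("need at least one resonance and P >= R candidate protons")
    if len(set(candidate_protons)) != P:
        raise ValueError("candidate protons must be unique")
    symmetry = dict(symmetry or {})
    _validate_involution(symmetry, candidate_protons)

    raw_count = P ** R
    injective = [
        tuple(zip(resonances, combo))
        for combo in itertools.permutations(candidate_protons, R)
    ]
    seen: dict[tuple, AssignmentCombination] = {}
    for mapping in injective:
        swapped = tuple((res, symmetry.get(p, p)) for res, p in mapping)
        canonical = min(mapping, swapped)
        if canonical not in seen:
            seen[canonical] = AssignmentCombination(mapping, symmetry_class=canonical)
    return AssignmentEnumeration(
        raw_count=raw_count,
        injective_count=len(injective),
        classes=list(seen.values()),
    )


# ---------------------------------------------------------------------------
# scoring and selection
# ---------------------------------------------------------------------------


@dataclass
class TargetFunctionScore:
    """Simplified target function for one assignment combination."""

    combination: AssignmentCombination
    restraint_term: float  # A^2, sum of squared upper-limit excesses
    steric_term: float     # A^2, sum of squared van der Waals overlaps
    steric_weight: float
    max_violation: float   # A, worst restraint excess or steric overlap
    d_noe: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.restraint_term + self.steric_weight * self.steric_term


def _steric_overlaps(
    model: ComplexModel, vdw_radii: Mapping[str, float]
) -> np.ndarray:
    """Intermolecular heavy-atom vdW overlaps max(0, r_i + r_j - d_ij)."""
    dna = [i for i in model.dna_indices if not model.atoms[i].is_hydrogen]
    lig = [i for i in model.ligand_indices if not model.atoms[i].is_hydrogen]
    if not dna or not lig:
        return np.zeros(0)
    coords = model.coordinates
    try:
        r_dna = np.array([vdw_radii[model.atoms[i].element] for i in dna])
        r_lig = np.array([vdw_radii[model.atoms[j].element] for j in lig])
    except KeyError as exc:
        raise KeyError(f"element {exc} missing from the vdW radii table") from exc
    d = np.linalg.norm(coords[dna][:, None, :] - coords[lig][None, :, :], axis=2)
    overlap = np.maximum(0.0, (r_dna[:, None] + r_lig[None, :]) - d)
    return overlap[overlap > 0]


def score_assignment(
    combination: AssignmentCombination,
    structure: ComplexModel | Ensemble,
    restraints: Sequence[ResonanceRestraint],
    vdw_radii: Mapping[str, float] | None = None,
    steric_weight: float = 1.0,
    ligand_chain: str = "L",
    ligand_residue: int = 1,
) -> TargetFunctionScore:
    """Score one assignment combination on a model or ensemble.

    The restraint term sums squared upper-limit excesses of d_NOE (ensemble
    input) or of the instantaneous distance (single model); the steric term
    sums squared intermolecular heavy-atom vdW overlaps and is identical
    across combinations on a rigid structure.
    """
    vdw_radii = dict(vdw_radii or DEFAULT_VDW_RADII)
    mapping = combination.as_dict
    if isinstance(structure, Ensemble):
        ensemble = structure
        # sterics are judged on the ensemble-average structure, as for
        # trajectory-averaged models
        model = ensemble.topology.with_coordinates(
            ensemble.coordinates.mean(axis=0)
        )
    else:
        ensemble = Ensemble([structure])
        model = structure

    restraint_term = 0.0
    max_violation = 0.0
    d_noe: dict[str, float] = {}
    for k, rr in enumerate(restraints):
        if rr.resonance not in mapping:
            raise KeyError(f"combination does not assign resonance {rr.resonance!r}")
        proton = AtomSelector(ligand_chain, ligand_residue, mapping[rr.resonance])
        resolved = rr.resolve(proton)
        d = noe_average_distance(ensemble, resolved)
        d_noe[f"{rr.resonance}:{rr.dna_proton.chain_id}"
              f"{rr.dna_proton.residue_index}:{rr.dna_proton.atom_name}"] = d
        excess = max(0.0, d - rr.upper_limit)
        restraint_term += excess ** 2
        max_violation = max(max_violation, excess)

    overlaps = _steric_overlaps(model, vdw_radii)
    steric_term = float(np.sum(overlaps ** 2))
    if overlaps.size:
        max_violation = max(max_violation, float(overlaps.max()))
    return TargetFunctionScore(
        combination=combination,
        restraint_term=restraint_term,
        steric_term=steric_term,
        steric_weight=steric_weight,
        max_violation=max_violation,
        d_noe=d_noe,
    )


@dataclass
class SelectionReport:
    """Outcome of the lowest-target-function assignment selection."""

    status: str  # "accepted" or "ambiguous"
    winner: TargetFunctionScore | None
    ranked: list[TargetFunctionScore]
    violation_tolerance: float
    margin: float

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def select_assignment(
    scores: Sequence[TargetFunctionScore],
    violation_tolerance: float = 0.1,
    margin: float = 1e-6,
) -> SelectionReport:
    """Pick the combination with the lowest total target function.

    The minimum is flagged "accepted" only when its worst violation stays
    within ``violation_tolerance`` and it beats the runner-up total by more
    than ``margin``; otherwise the report is "ambiguous" with the ranking
    preserved.
    """
    if not scores:
        raise ValueError("no scores to select from")
    ranked = sorted(scores, key=lambda s: s.total)
    winner = ranked[0]
    unique = len(ranked) == 1 or (ranked[1].total - winner.total) > margin
    if unique and winner.max_violation <= violation_tolerance:
        return SelectionReport("accepted", winner, ranked, violation_tolerance, margin)
    return SelectionReport("ambiguous", None, ranked, violation_tolerance, margin)


# ---------------------------------------------------------------------------
# restraint list I/O (tab-delimited)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "dna_chain",
    "dna_residue",
    "dna_residue_name",
    "dna_atom",
    "ligand_chain",
    "ligand_residue",
    "ligand_residue_name",
    "ligand_atom",
    "upper_limit",
    "strength",
]


def read_restraints_tsv(path: str) -> list[NOERestraint]:
    """Read NOE restraints from tab-delimited text (one restraint per row)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"restraint file {path} lacks columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        strength = row["strength"] if row["strength"] in STRENGTH_LIMITS else None
        out.append(
            NOERestraint(
                dna_proton=AtomSelector(
                    row["dna_chain"], int(row["dna_residue"]), row["dna_atom"]
                ),
                ligand_proton=AtomSelector(
                    row["ligand_chain"], int(row["ligand_residue"]), row["ligand_atom"]
                ),
                upper_limit=float(row["upper_limit"]),
                strength=strength,
            )
        )
    return out


def write_restraints_tsv(
    restraints: Sequence[NOERestraint], path: str, model: ComplexModel | None = None
) -> None:
    """Write restraints as tab-delimited text (residue names from ``model``)."""

    def resname(sel: AtomSelector) -> str:
        if model is None:
            return "."
        idx = sel.resolve(model)
        return model.atoms[idx].residue_name

    rows = []
    for r in restraints:
        rows.append(
            {
                "dna_chain": r.dna_proton.chain_id,
                "dna_residue": r.dna_proton.residue_index,
                "dna_residue_name": resname(r.dna_proton),
                "dna_atom": r.dna_proton.atom_name,
                "ligand_chain": r.ligand_proton.chain_id,
                "ligand_residue": r.ligand_proton.residue_index,
                "ligand_residue_name": resname(r.ligand_proton),
                "ligand_atom": r.ligand_proton.atom_name,
                "upper_limit": r.upper_limit,
                "strength": r.strength or ".",
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
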