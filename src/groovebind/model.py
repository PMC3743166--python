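"""Domain types for DNA-ligand complexes.

The package works on three in-memory containers:

``AtomRecord``
    One atom with its PDB-style identity (name, element, residue, chain),
    Cartesian position in Angstrom, and a structural *role* label
    (base / sugar / phosphate / ligand / metal) that every downstream
    selector relies on.

``ComplexModel``
    An ordered atom list describing one B-DNA duplex, optionally combined
    with one bound ligand on its own chain.  Residues are numbered with a
    single running index: 1..L on the first strand and L+1..2L on the
    second, so base pair *i* is formed by residues (i, 2L+1-i).

``Ensemble``
    An ordered list of snapshots of one ComplexModel topology, the stand-in
    for a molecular-dynamics trajectory: every snapshot shares atom
    identities and ordering and differs only in coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Role",
    "AtomRecord",
    "ComplexModel",
    "Ensemble",
    "TopologyError",
    "infer_role",
]


class TopologyError(ValueError):
    """Raised when structures that must share a topology do not."""


class Role(str, Enum):
    DNA_BASE = "dna_base"
    DNA_SUGAR = "dna_sugar"
    DNA_PHOSPHATE = "dna_phosphate"
    LIGAND = "ligand"
    METAL = "metal"

    @property
    def is_dna(self) -> bool:
        return self in (Role.DNA_BASE, Role.DNA_SUGAR, Role.DNA_PHOSPHATE)


#: Atom names forming the phosphate group of a nucleotide.
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3"}

#: Element symbols treated as coordinated metal centres.
METAL_ELEMENTS = {"RU", "FE", "OS", "ZN", "PT"}


def infer_role(chain_kind: str, atom_name: str, element: str) -> Role:
    """Assign the structural role of one atom.

    ``chain_kind`` is ``"dna"`` or ``"ligand"`` (from the chain-role
    mapping).  DNA atoms partition by name: phosphate group by name table,
    primed names (sugar ring and its protons) as sugar, everything else as
    base.  On the ligand chain, metal elements get the metal role.
    """
    kind = chain_kind.lower()
    if kind == "ligand":
        return Role.METAL if element.upper() in METAL_ELEMENTS else Role.LIGAND
    if kind != "dna":
        raise ValueError(f"unknown chain kind {chain_kind!r} (expected 'dna' or 'ligand')")
    if atom_name in PHOSPHATE_ATOMS:
        return Role.DNA_PHOSPHATE
    if "'" in atom_name:
        return Role.DNA_SUGAR
    return Role.DNA_BASE


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    role: Role

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        self.role = Role(self.role)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def same_identity(self, other: "AtomRecord") -> bool:
        return (
            self.atom_name == other.atom_name
            and self.element == other.element
            and self.residue_name == other.residue_name
            and self.residue_index == other.residue_index
            and self.chain_id == other.chain_id
            and self.role == other.role
        )


@dataclass
class ComplexModel:
    """A DNA duplex, optionally with one ligand, as an ordered atom list."""

    atoms: list[AtomRecord]
    duplex_length: int = 0
    strand_chains: tuple[str, str] | None = None
    ligand_chain: str | None = None

    def __post_init__(self) -> None:
        if self.strand_chains is not None:
            self.strand_chains = tuple(self.strand_chains)  # type: ignore[assignment]
            for chain in self.strand_chains:
                n = len({a.residue_index for a in self.atoms if a.chain_id == chain})
                if n != self.duplex_length:
                    raise TopologyError(
                        f"strand chain {chain!r} has {n} residues, "
                        f"expected duplex_length={self.duplex_length}"
                    )
        if self.ligand_chain is not None:
            bad = [
                a.atom_name
                for a in self.atoms
                if a.chain_id == self.ligand_chain and a.role not in (Role.LIGAND, Role.METAL)
            ]
            if bad:
                raise TopologyError(f"non-ligand roles on ligand chain: {bad[:5]}")

    # -- coordinate access -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions, in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "ComplexModel":
        """New model with identical atom identities and the given coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return ComplexModel(atoms, self.duplex_length, self.strand_chains, self.ligand_chain)

    # -- selections --------------------------------------------------------

    def indices(
        self,
        *,
        chain: str | None = None,
        roles: Iterable[Role] | None = None,
        residues: Iterable[int] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        roles = set(roles) if roles is not None else None
        residues = set(residues) if residues is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if roles is not None and a.role not in roles:
                continue
            if residues is not None and a.residue_index not in residues:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    @property
    def dna_indices(self) -> np.ndarray:
        return np.asarray([i for i, a in enumerate(self.atoms) if a.role.is_dna], dtype=int)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if a.role in (Role.LIGAND, Role.METAL)],
            dtype=int,
        )

    @property
    def metal_indices(self) -> np.ndarray:
        return np.asarray([i for i, a in enumerate(self.atoms) if a.role == Role.METAL], dtype=int)

    def find_atom(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        """Index of the unique atom matching the selector; KeyError otherwise."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id
            and a.residue_index == residue_index
            and a.atom_name == atom_name
        ]
        if len(hits) != 1:
            raise KeyError(
                f"selector ({chain_id}, {residue_index}, {atom_name}) matched "
                f"{len(hits)} atoms (need exactly 1)"
            )
        return hits[0]

    def base_pair_residues(self, pair_index: int) -> tuple[int, int]:
        """Residue indices (first strand, second strand) of base pair ``pair_index``."""
        if not 1 <= pair_index <= self.duplex_length:
            raise ValueError(f"pair index {pair_index} outside 1..{self.duplex_length}")
        return pair_index, 2 * self.duplex_length + 1 - pair_index

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_index == residue_index
        ]

    def strand_sequence(self, chain_id: str) -> str:
        """One-letter base sequence of a strand, in residue order."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_index not in seen:
                seen[a.residue_index] = a.residue_name[-1]
        return "".join(seen[k] for k in sorted(seen))

    def same_topology(self, other: "ComplexModel") -> bool:
        if self.n_atoms != other.n_atoms:
            return False
        return all(a.same_identity(b) for a, b in zip(self.atoms, other.atoms))


@dataclass
class Ensemble:
    """Ordered snapshots of one ComplexModel topology (an MD-trajectory proxy)."""

    snapshots: list[ComplexModel]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise TopologyError("an ensemble needs at least one snapshot")
        first = self.snapshots[0]
        for k, snap in enumerate(self.snapshots[1:], start=2):
            if snap.n_atoms != first.n_atoms:
                raise TopologyError(
                    f"snapshot {k} has {snap.n_atoms} atoms, snapshot 1 has {first.n_atoms}"
                )
            if not snap.same_topology(first):
                raise TopologyError(f"snapshot {k} differs in atom identities from snapshot 1")
        if self.labels is not None and len(self.labels) != len(self.snapshots):
            raise ValueError("labels must align with snapshots")

    @property
    def N(self) -> int:
        return len(self.snapshots)

    @property
    def topology(self) -> ComplexModel:
        return self.snapshots[0]

    @property
    def coordinates(self) -> np.ndarray:
        """(N, n_atoms, 3) stacked coordinates."""
        return np.stack([s.coordinates for s in self.snapshots])

    def atom_distances(self, i: int, j: int) -> np.ndarray:
        """Per-snapshot distance between atoms ``i`` and ``j``."""
        xyz = self.coordinates
        return np.linalg.norm(xyz[:, i, :] - xyz[:, j, :], axis=1)
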