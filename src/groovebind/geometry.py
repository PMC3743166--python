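"""Structural descriptors: superposition, displacement, H-bonds, ring and
helix-axis geometry.

These are the quantities used to characterise a groove-bound pose: RMSD
after least-squares (Kabsch) superposition on a stable block of base pairs,
the mean displacement of ligand heavy atoms across structures after that
superposition, strict geometric hydrogen bonds (H...acceptor length below
2.6 A and deviation from donor-H...acceptor linearity below 25 deg by
default), the position of a proton relative to an aromatic ring plane
(ring-current geometry), and the angle between the ligand's metal-metal
axis and the DNA helix axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .linalg import angle_to_plane, fit_line, fit_plane, unit
from .model import ComplexModel, Role

__all__ = [
    "SelectionSpec",
    "HBondGeometryCriteria",
    "RigidTransform",
    "HBond",
    "superpose",
    "apply_transform",
    "average_displacement",
    "detect_hbonds",
    "ring_geometry",
    "helix_axis",
    "helix_ligand_angle",
    "base_pair_centroids",
    "DegenerateSelectionError",
]


class DegenerateSelectionError(ValueError):
    """Selection resolves to too few or collinear atoms for a rigid fit."""


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection by base-pair range and atom class.

    ``atom_class`` is one of ``"heavy"`` (DNA heavy atoms of the pair
    range), ``"all"`` (DNA atoms including hydrogens), ``"ligand_heavy"``
    or ``"ligand_all"`` (pair range ignored for ligand classes).
    """

    pair_first: int = 1
    pair_last: int = 0  # 0 = last pair of the duplex
    atom_class: str = "heavy"

    def resolve(self, model: ComplexModel) -> np.ndarray:
        if self.atom_class in ("ligand_heavy", "ligand_all"):
            idx = model.ligand_indices
            if self.atom_class == "ligand_heavy":
                idx = np.asarray(
                    [i for i in idx if not model.atoms[i].is_hydrogen], dtype=int
                )
            return idx
        if self.atom_class not in ("heavy", "all"):
            raise ValueError(f"unknown atom class {self.atom_class!r}")
        last = self.pair_last or model.duplex_length
        if not 1 <= self.pair_first <= last <= model.duplex_length:
            raise ValueError(
                f"pair range {self.pair_first}..{last} outside duplex "
                f"1..{model.duplex_length}"
            )
        residues: list[int] = []
        for pair in range(self.pair_first, last + 1):
            residues.extend(model.base_pair_residues(pair))
        return model.indices(
            roles=[Role.DNA_BASE, Role.DNA_SUGAR, Role.DNA_PHOSPHATE],
            residues=residues,
            heavy_only=self.atom_class == "heavy",
        )


@dataclass(frozen=True)
class HBondGeometryCriteria:
    """Strict geometric hydrogen-bond criteria (H...A length, linearity)."""

    max_length: float = 2.6   # A, H...acceptor
    max_angle: float = 25.0   # deg deviation from D-H...A linearity

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if not 0 < self.max_angle < 90:
            raise ValueError("max_angle must lie in (0, 90) degrees")


@dataclass
class RigidTransform:
    """x -> R (x - center_mobile) + center_reference."""

    rotation: np.ndarray
    center_mobile: np.ndarray
    center_reference: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.center_mobile) @ self.rotation.T + self.center_reference


def _check_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateSelectionError("superposition needs at least 3 atom pairs")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateSelectionError("selection atoms are collinear")


def superpose(
    mobile: ComplexModel,
    reference: ComplexModel,
    selection: SelectionSpec | np.ndarray,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns the transform carrying the mobile selection onto the reference
    and the post-fit RMSD over the selection, in A.  Atom correspondence is
    by position in the shared atom order.
    """
    idx = selection.resolve(mobile) if isinstance(selection, SelectionSpec) else selection
    x = mobile.coordinates[idx]
    y = reference.coordinates[idx]
    _check_selection(x)
    _check_selection(y)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    xd, yd = x - xc, y - yc
    # Kabsch: proper rotation from the SVD of the covariance, with the
    # determinant correction against improper solutions
    u, _, vt = np.linalg.svd(xd.T @ yd)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    residual = xd @ rotation.T - yd
    rmsd = float(np.sqrt((residual ** 2).sum(axis=1).mean()))
    return RigidTransform(rotation, xc, yc), rmsd


def apply_transform(model: ComplexModel, transform: RigidTransform) -> ComplexModel:
    return model.with_coordinates(transform.apply(model.coordinates))


def average_displacement(
    structures: Sequence[ComplexModel],
    selection_fit: SelectionSpec,
    selection_measure: SelectionSpec,
) -> tuple[float, float]:
    """Mean +/- sd per-atom displacement after superposition.

    Every structure is superposed onto the first over ``selection_fit``;
    displacements are per-atom distances of ``selection_measure`` atoms to
    the mean structure, pooled over structures.  Returns (mean, sd) in A.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    ref = structures[0]
    for s in structures[1:]:
        if not s.same_topology(ref):
            raise ValueError("structures do not share a topology")
    fitted = [ref.coordinates]
    for s in structures[1:]:
        transform, _ = superpose(s, ref, selection_fit)
        fitted.append(transform.apply(s.coordinates))
    stack = np.stack(fitted)
    mean_structure = stack.mean(axis=0)
    idx = selection_measure.resolve(ref)
    disp = np.linalg.norm(stack[:, idx, :] - mean_structure[None, idx, :], axis=2)
    return float(disp.mean()), float(disp.std())


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    length: float  # A, H...A
    angle: float   # deg deviation from D-H...A linearity


def detect_hbonds(
    model: ComplexModel,
    criteria: HBondGeometryCriteria | None = None,
    intermolecular_only: bool = True,
) -> list[HBond]:
    """All D-H...A triples passing the strict geometric criteria.

    Donors are hydrogens covalently bound (<1.25 A) to N/O; acceptors are
    N/O atoms (excluding the donor itself).  With ``intermolecular_only``
    the donor and acceptor must lie on opposite sides of the DNA/ligand
    divide.
    """
    criteria = criteria or HBondGeometryCriteria()
    coords = model.coordinates
    is_dna = np.zeros(model.n_atoms, dtype=bool)
    is_dna[model.dna_indices] = True
    no_idx = [
        i
        for i in range(model.n_atoms)
        if model.atoms[i].element.upper() in ("N", "O")
    ]
    no_xyz = coords[no_idx]
    bonds: list[HBond] = []
    for h in range(model.n_atoms):
        if not model.atoms[h].is_hydrogen:
            continue
        d = np.linalg.norm(no_xyz - coords[h], axis=1)
        near = np.where(d < 1.25)[0]
        if near.size == 0:
            continue
        donor = no_idx[int(near[np.argmin(d[near])])]
        for k, acc in enumerate(no_idx):
            if acc == donor:
                continue
            if intermolecular_only and is_dna[acc] == is_dna[h]:
                continue
            length = d[k]
            if length >= criteria.max_length or length < 1.25:
                continue
            v1 = coords[h] - coords[donor]
            v2 = coords[acc] - coords[h]
            cosang = np.clip(
                np.dot(unit(v1), unit(v2)), -1.0, 1.0
            )
            deviation = float(np.degrees(np.arccos(cosang)))
            if deviation < criteria.max_angle:
                bonds.append(HBond(donor, h, acc, float(length), deviation))
    return bonds


def ring_geometry(
    model: ComplexModel,
    proton: int,
    ring: Sequence[int],
) -> tuple[float, float]:
    """Distance and elevation of a proton relative to an aromatic ring.

    Returns (distance from ring centroid in A, angle in deg between the
    centroid->proton vector and the least-squares ring plane: 0 in-plane,
    90 on the normal).
    """
    ring_xyz = model.coordinates[list(ring)]
    centroid, normal = fit_plane(ring_xyz)
    vec = model.coordinates[proton] - centroid
    return float(np.linalg.norm(vec)), angle_to_plane(vec, normal)


def base_pair_centroids(model: ComplexModel) -> np.ndarray:
    """(L, 3) centroids of base heavy atoms per pair."""
    out = []
    for pair in range(1, model.duplex_length + 1):
        residues = model.base_pair_residues(pair)
        idx = model.indices(
            roles=[Role.DNA_BASE], residues=list(residues), heavy_only=True
        )
        out.append(model.coordinates[idx].mean(axis=0))
    return np.asarray(out)


def helix_axis(model: ComplexModel) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit line through base-pair centroids: (point, unit direction)."""
    if model.duplex_length < 4:
        raise ValueError("helix axis needs a duplex of at least 4 base pairs")
    return fit_line(base_pair_centroids(model))


def helix_ligand_angle(model: ComplexModel) -> float:
    """Acute angle (deg) between the metal-metal axis and the helix axis."""
    metals = model.metal_indices
    if metals.size != 2:
        raise ValueError(f"expected exactly 2 metal atoms, found {metals.size}")
    _, axis = helix_axis(model)
    coords = model.coordinates
    lig_axis = unit(coords[metals[1]] - coords[metals[0]])
    c = np.clip(abs(float(np.dot(lig_axis, axis))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))
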