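"""Synthetic construction of B-DNA/ligand complexes and snapshot ensembles.

Everything the analysis pipeline consumes can be generated here without any
external coordinate source:

* :func:`build_bdna` — an idealized fiber-model B-DNA duplex from sequence,
  with rigid planar base pairs stacked at 36 deg twist / 3.38 A rise,
  minimal sugar-phosphate backbones and first-class hydrogens (H1'
  sugar protons and base amino/imino/aromatic protons).
* :func:`build_ligand` — a rigid dumbbell proxy for a binuclear
  bis(dipyridophenazine)-bridged ruthenium compound: two planar fused-ring
  monomers joined by a single pivot bond, one Ru centre per monomer with
  four idealized peripheral pyridines at octahedral positions, phenazine
  nitrogen acceptors, and the two candidate aromatic protons per monomer
  that carry the intermolecular NOEs.
* :func:`place_in_minor_groove` — rigid placement of the ligand into the
  minor groove at a chosen base-pair register, depth and tilt.
* :func:`generate_ensemble` — seeded thermal-fluctuation snapshots around a
  pose (per-atom isotropic Gaussian noise plus a rigid-body ligand jitter),
  standing in for unrestrained MD trajectories.

Geometry here is idealized, not force-field derived: aromatic C-C 1.39 A,
metal-N 2.06 A, planar bases with zero propeller.  The statistics computed
downstream (r^-6 NOE averages, interaction enthalpies, descriptors) depend
only on topology, rigidity, symmetry and the pose, which this module
controls exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .linalg import dihedral, fit_line, rotation_about_axis, rotation_z, unit
from .model import AtomRecord, ComplexModel, Ensemble, Role, infer_role

__all__ = [
    "HelixParams",
    "LigandSpec",
    "PoseSpec",
    "build_bdna",
    "build_ligand",
    "place_in_minor_groove",
    "generate_ensemble",
    "complement",
    "reverse_complement",
    "ClashError",
    "CANDIDATE_PROTONS",
    "PHENAZINE_NITROGENS",
    "BRIDGE_RING_ATOMS",
    "monomer_swap",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

RING_BOND = 1.39  # aromatic C-C, A
GLYCOSIDIC_BOND = 1.47
METAL_N_BOND = 2.06
PIVOT_BOND = 1.48
CH_BOND = 1.08
NH_BOND = 1.01

# Geometry of the base-pair frame (helix axis = z through the origin,
# minor groove opening toward -x):
_C1_RADIUS = 5.9          # C1' distance from the helix axis
_C1_AZIMUTH = 118.5       # +/- azimuth of the two C1' atoms (deg)
_WC_NN = 2.82             # central purine-N1 ... pyrimidine-N3 distance
_P_RADIUS = 9.6           # phosphorus distance from the helix axis
_P_AZIMUTH_OFFSET = 10.0  # P azimuth relative to its C1' (sets the groove widths)
_P_Z_OFFSET = 1.69        # P offset along the axis toward the 5' neighbour


class ClashError(ValueError):
    """Ligand placement drives heavy atoms closer than the hard limit."""


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}; expected one of ACGT") from None


def reverse_complement(sequence: str) -> str:
    return "".join(complement(b) for b in reversed(sequence))


@dataclass
class HelixParams:
    """Idealized fiber-model helix parameters."""

    twist_per_step: float = 36.0   # deg
    rise_per_step: float = 3.38    # A

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_step < 60.0:
            raise ValueError("twist_per_step must lie in (0, 60) degrees")
        if not 2.0 < self.rise_per_step < 5.0:
            raise ValueError("rise_per_step must lie in (2, 5) A")


@dataclass
class LigandSpec:
    """Rigid dumbbell-ligand parameters.

    The pivot torsion about the monomer-monomer bond is the only internal
    degree of freedom of the dumbbell."""

    pivot_torsion: float = 33.0  # deg


@dataclass
class PoseSpec:
    """Minor-groove placement of the ligand on a duplex.

    ``register`` is the base-pair step the bridging ring-system centroid
    faces (placed midway between pairs ``register`` and ``register+1``);
    ``depth`` moves the centroid radially (positive = deeper into the
    groove); ``tilt`` rotates the ligand long axis away from the helix axis
    about the groove (radial) direction.
    """

    register: int = 8
    groove: str = "minor"
    depth: float = 0.0    # A inward from the default surface seat
    tilt: float = 66.17   # deg

    def __post_init__(self) -> None:
        if self.groove not in ("minor", "major"):
            raise ValueError("groove must be 'minor' or 'major'")


# ---------------------------------------------------------------------------
# base templates
# ---------------------------------------------------------------------------


def _dir(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    return np.array([math.cos(t), math.sin(t)])


def _pyrimidine_template(letter: str) -> dict[str, np.ndarray]:
    """2-D template of C or T with the glycosidic N1 at the origin."""
    center = np.array([RING_BOND, 0.0])
    angles = {"N1": 180.0, "C2": 240.0, "N3": 300.0, "C4": 0.0, "C5": 60.0, "C6": 120.0}
    atoms = {name: center + RING_BOND * _dir(a) for name, a in angles.items()}

    def exo(anchor: str, bond: float) -> np.ndarray:
        return center + (RING_BOND + bond) * _dir(angles[anchor])

    atoms["O2"] = exo("C2", 1.23)
    atoms["H6"] = exo("C6", CH_BOND)
    if letter == "C":
        atoms["N4"] = exo("C4", 1.34)
        atoms["H41"] = atoms["N4"] + NH_BOND * _dir(angles["C4"] + 58.0)
        atoms["H42"] = atoms["N4"] + NH_BOND * _dir(angles["C4"] - 58.0)
        atoms["H5"] = exo("C5", CH_BOND)
    elif letter == "T":
        atoms["H3"] = exo("N3", 1.03)
        atoms["O4"] = exo("C4", 1.23)
        atoms["C7"] = exo("C5", 1.50)
        # crude tetrahedral methyl hydrogens (one in-plane, two out of plane;
        # the out-of-plane pair is lifted off z=0 in _pair_atoms)
        d5 = _dir(angles["C5"])
        atoms["H71"] = atoms["C7"] + 1.09 * d5
        atoms["H72"] = atoms["C7"] + 1.09 * 0.5 * d5
        atoms["H73"] = atoms["C7"] + 1.09 * 0.5 * d5
    else:
        raise ValueError(f"not a pyrimidine: {letter}")
    atoms["_glyc"] = center + (RING_BOND + GLYCOSIDIC_BOND) * _dir(angles["N1"])
    return atoms


def _purine_template(letter: str) -> dict[str, np.ndarray]:
    """2-D template of A or G with the hexagon centred at the origin."""
    hexc = np.zeros(2)
    angles = {"C6": 150.0, "N1": 90.0, "C2": 30.0, "N3": -30.0, "C4": -90.0, "C5": -150.0}
    atoms = {name: hexc + RING_BOND * _dir(a) for name, a in angles.items()}
    # pentagon fused on the C4-C5 edge, on the outside of the hexagon
    apoth_hex = RING_BOND * math.cos(math.radians(30.0))
    apoth_pent = RING_BOND / (2.0 * math.tan(math.radians(36.0)))
    circ_pent = RING_BOND / (2.0 * math.sin(math.radians(36.0)))
    pentc = hexc + (apoth_hex + apoth_pent) * _dir(-120.0)
    pent_angles = {"N9": -48.0, "C8": -120.0, "N7": 168.0}
    for name, a in pent_angles.items():
        atoms[name] = pentc + circ_pent * _dir(a)

    def exo_hex(anchor: str, bond: float) -> np.ndarray:
        return hexc + (RING_BOND + bond) * _dir(angles[anchor])

    atoms["H8"] = pentc + (circ_pent + CH_BOND) * _dir(pent_angles["C8"])
    if letter == "A":
        atoms["N6"] = exo_hex("C6", 1.34)
        atoms["H61"] = atoms["N6"] + NH_BOND * _dir(angles["C6"] + 58.0)
        atoms["H62"] = atoms["N6"] + NH_BOND * _dir(angles["C6"] - 58.0)
        atoms["H2"] = exo_hex("C2", CH_BOND)
    elif letter == "G":
        atoms["O6"] = exo_hex("C6", 1.23)
        atoms["H1"] = exo_hex("N1", 1.03)
        atoms["N2"] = exo_hex("C2", 1.34)
        atoms["H21"] = atoms["N2"] + NH_BOND * _dir(angles["C2"] + 58.0)
        atoms["H22"] = atoms["N2"] + NH_BOND * _dir(angles["C2"] - 58.0)
    else:
        raise ValueError(f"not a purine: {letter}")
    atoms["_glyc"] = pentc + (circ_pent + GLYCOSIDIC_BOND) * _dir(pent_angles["N9"])
    return atoms


def _place_base(
    template: dict[str, np.ndarray],
    pin_target: np.ndarray,
    ref_atom: str,
    aim_point: np.ndarray,
    mirror: bool,
) -> dict[str, np.ndarray]:
    """Rigidly place a 2-D base template.

    The ``_glyc`` pseudo-atom (the C1' anchor) is pinned at ``pin_target``
    and the base is rotated about it until the ray towards ``ref_atom``
    (the central Watson-Crick atom, N1 of purines / N3 of pyrimidines)
    passes through ``aim_point``.  ``mirror`` flips the in-plane chirality,
    selecting which side of that ray the ring body occupies.
    """
    coords = {
        name: (np.array([p[0], -p[1]]) if mirror else np.array(p, dtype=float))
        for name, p in template.items()
    }
    anchor = coords["_glyc"]
    ref = coords[ref_atom] - anchor
    current = math.degrees(math.atan2(ref[1], ref[0]))
    aim = aim_point - pin_target
    target_deg = math.degrees(math.atan2(aim[1], aim[0]))
    rot = rotation_z(target_deg - current)[:2, :2]
    return {name: pin_target + rot @ (q - anchor) for name, q in coords.items()}


def _element_of(name: str) -> str:
    if name.startswith("RU"):
        return "Ru"
    return name.lstrip("_")[0].upper()


# In-plane chirality flags selecting which side of the glycosidic aim ray
# the ring bodies occupy (fixed so the Watson-Crick edges face each other
# and the guanine amino group points into the minor groove; see tests).
_PURINE_MIRROR = False
_PYRIMIDINE_MIRROR = True

_AIM_X: float | None = None


def _aim_point_x() -> float:
    """x of the common glycosidic aim point on the pair dyad axis.

    Solved once (ring geometry is shared by both purines and both
    pyrimidines) so that the central purine-N1 ... pyrimidine-N3 distance
    of the assembled pair equals the template value ``_WC_NN``.
    """
    global _AIM_X
    if _AIM_X is None:
        pur_t = _purine_template("A")
        pyr_t = _pyrimidine_template("T")
        c1_pu = _C1_RADIUS * _dir(_C1_AZIMUTH)
        c1_py = np.array([c1_pu[0], -c1_pu[1]])

        def gap(cx: float) -> float:
            aim = np.array([cx, 0.0])
            pu = _place_base(pur_t, c1_pu, "N1", aim, _PURINE_MIRROR)
            py = _place_base(pyr_t, c1_py, "N3", aim, _PYRIMIDINE_MIRROR)
            return float(np.linalg.norm(pu["N1"] - py["N3"])) - _WC_NN

        _AIM_X = float(brentq(gap, -1.0, 1.5))
    return _AIM_X


def _pair_atoms(alpha_letter: str) -> dict[str, dict[str, np.ndarray]]:
    """Base atoms of one pair in the pair frame, keyed by strand ('alpha'/'beta').

    Values are dicts atom name -> 3-vector (z = 0: planar pairs).  Includes a
    pseudo-entry ``_glyc`` holding the C1' anchor position of each residue.
    """
    alpha_letter = alpha_letter.upper()
    if alpha_letter not in _COMPLEMENT:
        raise ValueError(f"invalid base {alpha_letter!r}; expected one of ACGT")
    beta_letter = complement(alpha_letter)
    purine = alpha_letter if alpha_letter in "AG" else beta_letter
    pyrimidine = complement(purine)
    purine_on_alpha = alpha_letter in "AG"

    pur_t = _purine_template(purine)
    pyr_t = _pyrimidine_template(pyrimidine)
    c1_pu = _C1_RADIUS * _dir(_C1_AZIMUTH)          # purine-strand C1'
    c1_py = np.array([c1_pu[0], -c1_pu[1]])         # pyrimidine-strand C1'
    aim = np.array([_aim_point_x(), 0.0])           # on the pair dyad axis

    pur = _place_base(pur_t, c1_pu, "N1", aim, mirror=_PURINE_MIRROR)
    pyr = _place_base(pyr_t, c1_py, "N3", aim, mirror=_PYRIMIDINE_MIRROR)

    def to3d(d: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        lift = {"H72": 0.89, "H73": -0.89}  # thymine methyl out-of-plane pair
        return {
            name: np.array([p[0], p[1], lift.get(name, 0.0)]) for name, p in d.items()
        }

    pair = {"pur": to3d(pur), "pyr": to3d(pyr)}
    if purine_on_alpha:
        alpha, beta = pair["pur"], pair["pyr"]
    else:
        # the dyad: reflect the assembly in-plane about the x axis and swap strands
        def flip(d):
            return {k: np.array([p[0], -p[1], p[2]]) for k, p in d.items()}

        alpha, beta = flip(pair["pyr"]), flip(pair["pur"])
    return {"alpha": alpha, "beta": beta}


# Watson-Crick donor-acceptor template pairs per alpha-strand base letter,
# as (alpha atom, beta atom) name tuples; distances measured on the template.
_WC_CONTACTS = {
    "A": [("N1", "N3"), ("N6", "O4")],
    "T": [("N3", "N1"), ("O4", "N6")],
    "G": [("N1", "N3"), ("O6", "N4"), ("N2", "O2")],
    "C": [("N3", "N1"), ("N4", "O6"), ("O2", "N2")],
}


def watson_crick_template_distances() -> dict[str, list[tuple[str, str, float]]]:
    """Donor-acceptor distances of the rigid pair templates, per base letter."""
    out: dict[str, list[tuple[str, str, float]]] = {}
    for letter in "ACGT":
        pair = _pair_atoms(letter)
        rows = []
        for a_name, b_name in _WC_CONTACTS[letter]:
            d = float(np.linalg.norm(pair["alpha"][a_name] - pair["beta"][b_name]))
            rows.append((a_name, b_name, d))
        out[letter] = rows
    return out


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

_SUGAR_CIRC = 1.45 / (2.0 * math.sin(math.radians(36.0)))


def _backbone_atoms(
    c1p: np.ndarray, strand_sign: int, five_prime_terminal: bool
) -> list[tuple[str, np.ndarray]]:
    """Minimal sugar-phosphate backbone for one residue, in the pair frame.

    ``strand_sign`` is +1 for the first strand (residue index grows with the
    pair index) and -1 for the second.
    """
    s = float(strand_sign)
    zhat = np.array([0.0, 0.0, 1.0])
    phi1 = math.degrees(math.atan2(c1p[1], c1p[0]))
    u = np.array([*_dir(phi1), 0.0])
    that = s * np.cross(zhat, u)

    p_axis = unit(u + 0.55 * s * zhat)
    center = c1p + _SUGAR_CIRC * p_axis
    e1 = -p_axis
    e2 = unit(that - np.dot(that, p_axis) * p_axis)
    ring = {}
    for k, name in enumerate(("C1'", "C2'", "C3'", "C4'", "O4'")):
        a = math.radians(72.0 * k)
        ring[name] = center + _SUGAR_CIRC * (math.cos(a) * e1 + math.sin(a) * e2)
    c5p = ring["C4'"] + 1.51 * unit(unit(ring["C4'"] - center) + 0.9 * s * zhat)
    o3p = ring["C3'"] + 1.42 * unit(unit(ring["C3'"] - center) - 0.9 * s * zhat)

    atoms: list[tuple[str, np.ndarray]] = []
    if not five_prime_terminal:
        phi_p = phi1 + s * _P_AZIMUTH_OFFSET
        up = np.array([*_dir(phi_p), 0.0])
        p_pos = _P_RADIUS * up + np.array([0.0, 0.0, -s * _P_Z_OFFSET])
        atoms.append(("P", p_pos))
        atoms.append(("OP1", p_pos + 1.48 * unit(up + 0.8 * zhat)))
        atoms.append(("OP2", p_pos + 1.48 * unit(up - 0.8 * zhat)))
        atoms.append(("O5'", p_pos + 1.60 * unit(c5p - p_pos)))
    else:
        atoms.append(("O5'", c5p + 1.42 * unit(s * zhat)))
    atoms.append(("C5'", c5p))
    atoms.append(("C4'", ring["C4'"]))
    atoms.append(("O4'", ring["O4'"]))
    atoms.append(("C3'", ring["C3'"]))
    atoms.append(("O3'", o3p))
    atoms.append(("C2'", ring["C2'"]))
    atoms.append(("C1'", ring["C1'"]))
    return atoms


def _h1p_position(c1p, c2p, o4p, glyc_n, groove_dir) -> np.ndarray:
    """H1' on the minor-groove face of C1'.

    The direction blends the tetrahedral completion of the C1' substituents
    with a bias along ``groove_dir`` (the azimuthal direction towards the
    minor-groove gap), matching the way H1' protons line the minor-groove
    walls of B-DNA.
    """
    d = (c2p - c1p) + (o4p - c1p) + (glyc_n - c1p)
    return c1p + 1.09 * unit(unit(-d) + 1.0 * groove_dir)


# ---------------------------------------------------------------------------
# duplex builder
# ---------------------------------------------------------------------------


def build_bdna(
    sequence: str,
    params: HelixParams | None = None,
    chains: tuple[str, str] = ("A", "B"),
) -> ComplexModel:
    """Build an idealized B-DNA duplex from a sequence.

    The returned model carries the given sequence on the first strand
    (residues 1..L) and its reverse complement on the second (residues
    L+1..2L); base pair *i* is formed by residues (i, 2L+1-i).  Successive
    base-pair frames are related by the helix twist and rise.
    """
    params = params or HelixParams()
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 bases")
    for b in sequence:
        if b not in _COMPLEMENT:
            raise ValueError(f"invalid base {b!r}; expected one of ACGT")
    L = len(sequence)
    chain_a, chain_b = chains

    residues: dict[int, tuple[str, str, list[tuple[str, np.ndarray]]]] = {}
    for i, letter in enumerate(sequence, start=1):
        pair = _pair_atoms(letter)
        R = rotation_z(params.twist_per_step * (i - 1))
        shift = np.array([0.0, 0.0, params.rise_per_step * (i - 1)])
        for strand, sgn, chain in (("alpha", 1, chain_a), ("beta", -1, chain_b)):
            resi = i if strand == "alpha" else 2 * L + 1 - i
            letter_here = letter if strand == "alpha" else complement(letter)
            base = pair[strand]
            glyc = base["_glyc"]
            terminal5 = (strand == "alpha" and i == 1) or (strand == "beta" and i == L)
            backbone = _backbone_atoms(glyc, sgn, terminal5)
            bmap = dict(backbone)
            glyc_n = base["N9"] if letter_here in "AG" else base["N1"]
            phi1 = math.degrees(math.atan2(glyc[1], glyc[0]))
            u_rad = np.array([*_dir(phi1), 0.0])
            groove_dir = sgn * np.cross(np.array([0.0, 0.0, 1.0]), u_rad)
            h1p = _h1p_position(bmap["C1'"], bmap["C2'"], bmap["O4'"], glyc_n, groove_dir)
            atom_list = backbone + [("H1'", h1p)]
            atom_list += [(n, p) for n, p in base.items() if not n.startswith("_")]
            placed = [(n, R @ p + shift) for n, p in atom_list]
            residues[resi] = (chain, f"D{letter_here}", placed)

    atoms: list[AtomRecord] = []
    for resi in sorted(residues):
        chain, resname, atom_list = residues[resi]
        for name, pos in atom_list:
            element = _element_of(name)
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=element,
                    residue_name=resname,
                    residue_index=resi,
                    chain_id=chain,
                    position=pos,
                    role=infer_role("dna", name, element),
                )
            )
    return ComplexModel(atoms, duplex_length=L, strand_chains=(chain_a, chain_b))


# ---------------------------------------------------------------------------
# ligand builder
# ---------------------------------------------------------------------------

#: Candidate aromatic protons for the intermolecular NOE resonances
#: (two per monomer, flanking the phenazine nitrogens).
CANDIDATE_PROTONS = ("HC1A", "HC2A", "HC1B", "HC2B")

#: Phenazine-type nitrogen acceptors, one unprimed/primed pair per monomer.
PHENAZINE_NITROGENS = ("NP1A", "NP2A", "NP1B", "NP2B")


def monomer_swap(atom_name: str) -> str:
    """The two-fold monomer-swap involution on ligand atom names (A <-> B)."""
    if atom_name.endswith("A"):
        return atom_name[:-1] + "B"
    if atom_name.endswith("B"):
        return atom_name[:-1] + "A"
    return atom_name


def _hex_vertices(center: np.ndarray) -> dict[int, np.ndarray]:
    """Vertices of a vertical-edge hexagon keyed by angle in degrees."""
    return {a: center + RING_BOND * _dir(a) for a in (30, 90, 150, 210, 270, 330)}


def _monomer_atoms() -> list[tuple[str, np.ndarray, str]]:
    """One planar dumbbell monomer in 2-D; names lack the monomer suffix.

    Layout along +x: terminal (pivot-bearing) benzene ring, pyrazine ring
    with the two phenazine N, chelating ring with the two metal-binding N
    and the two NOE-candidate CH protons, then the Ru centre.
    """
    atoms: list[tuple[str, np.ndarray, str]] = []
    r3 = _hex_vertices(np.array([0.0, 0.0]))
    r2 = _hex_vertices(np.array([2.0 * RING_BOND * math.cos(math.radians(30.0)), 0.0]))
    r1 = _hex_vertices(np.array([4.0 * RING_BOND * math.cos(math.radians(30.0)), 0.0]))

    atoms.append(("CPV", r3[210], "C"))   # pivot carbon
    atoms.append(("CRF", r3[90], "C"))    # torsion reference, carries HC1
    atoms.append(("CRG", r3[270], "C"))   # torsion reference, carries HC2
    atoms.append(("C01", r3[150], "C"))
    atoms.append(("C02", r3[30], "C"))    # fused with r2
    atoms.append(("C03", r3[330], "C"))   # fused with r2
    atoms.append(("NP1", r2[90], "N"))    # phenazine N (unprimed)
    atoms.append(("NP2", r2[270], "N"))   # phenazine N (primed)
    atoms.append(("C04", r2[30], "C"))    # fused with r1
    atoms.append(("C05", r2[330], "C"))   # fused with r1
    atoms.append(("NC1", r1[30], "N"))    # chelating N
    atoms.append(("NC2", r1[330], "N"))   # chelating N
    atoms.append(("C06", r1[90], "C"))
    atoms.append(("C07", r1[270], "C"))
    # core hydrogens; the NOE candidate protons HC1/HC2 sit on the bridge
    # edges next to the phenazine nitrogens, on the buried moiety
    for hname, anchor, center in (
        ("HC1", r3[90], np.array([0.0, 0.0])),
        ("H02", r3[150], np.array([0.0, 0.0])),
        ("HC2", r3[270], np.array([0.0, 0.0])),
    ):
        atoms.append((hname, anchor + CH_BOND * unit(anchor - center), "H"))
    c1x = 4.0 * RING_BOND * math.cos(math.radians(30.0))
    atoms.append(("H04", r1[90] + CH_BOND * unit(r1[90] - np.array([c1x, 0.0])), "H"))
    atoms.append(("H05", r1[270] + CH_BOND * unit(r1[270] - np.array([c1x, 0.0])), "H"))
    # metal: on the local x axis, METAL_N_BOND from both chelating N
    half_nn = RING_BOND / 2.0
    dx = math.sqrt(METAL_N_BOND**2 - half_nn**2)
    ru_x = r1[30][0] + dx
    atoms.append(("RU", np.array([ru_x, 0.0]), "Ru"))
    return atoms


def _pyridine(metal: np.ndarray, direction: np.ndarray, updir: np.ndarray, idx: int):
    """Idealized pyridine bound end-on to the metal along ``direction``."""
    d = unit(direction)
    w = unit(updir - np.dot(updir, d) * d)
    n_pos = metal + METAL_N_BOND * d
    center = metal + (METAL_N_BOND + RING_BOND) * d
    atoms = [(f"NB{idx}", n_pos, "N")]
    for k in range(1, 6):
        a = math.radians(60.0 * k)
        vertex = center + RING_BOND * (math.cos(a) * (-d) + math.sin(a) * w)
        atoms.append((f"C{idx}{k}", vertex, "C"))
        h = center + (RING_BOND + CH_BOND) * (math.cos(a) * (-d) + math.sin(a) * w)
        atoms.append((f"H{idx}{k}", h, "H"))
    return atoms


#: Names (without monomer suffix) of the planar bridging ring-system atoms.
BRIDGE_RING_ATOMS = (
    "CPV", "CRF", "CRG", "C01", "C02", "C03", "NP1", "NP2", "C04", "C05",
    "NC1", "NC2", "C06", "C07",
)


def build_ligand(spec: LigandSpec | None = None) -> ComplexModel:
    """Build the rigid dumbbell ligand as a single-residue HETATM fragment.

    The two monomers are joined by the pivot bond along the x axis; monomer
    b is the two-fold image of monomer a, rotated about the pivot bond so
    the measured pivot dihedral (CRFA-CPVA-CPVB-CRGB) equals
    ``spec.pivot_torsion``.
    """
    spec = spec or LigandSpec()
    flat = _monomer_atoms()

    # 3-D monomer a: plane z=0, pivot at the origin, pivot bond along -x
    pivot2d = dict((n, p) for n, p, _ in flat)["CPV"]
    rot = rotation_z(180.0 - 210.0)[:2, :2]
    mono_a: list[tuple[str, np.ndarray, str]] = []
    for name, p, el in flat:
        q = rot @ (p - pivot2d)
        mono_a.append((name, np.array([q[0], q[1], 0.0]), el))

    ru_a = dict((n, p) for n, p, _ in mono_a)["RU"]
    # Peripheral pyridines splay outward from the bridge plane (canted
    # towards the dumbbell end), mimicking the propeller-like wrap of the
    # real bipyridine caps around each metal centre; the cant angles keep
    # the groove-facing edge of the dumbbell clear of the backbone walls.
    cant = math.radians(16.0)
    pyridine_dirs = [
        (np.array([math.sin(cant), 0.0, math.cos(cant)]), np.array([1.0, 0.0, 0.0])),
        (np.array([math.sin(cant), 0.0, -math.cos(cant)]), np.array([1.0, 0.0, 0.0])),
        (np.array([*_dir(38.0), 0.0]), np.array([0.0, 0.0, 1.0])),
        (np.array([*_dir(-38.0), 0.0]), np.array([0.0, 0.0, 1.0])),
    ]
    for idx, (d, up) in enumerate(pyridine_dirs, start=1):
        mono_a.extend(_pyridine(ru_a, d, up, idx))

    # monomer b: two-fold image about the vertical axis through the bond
    # midpoint, then rotated about the pivot bond by the torsion
    Rt = rotation_about_axis(np.array([1.0, 0.0, 0.0]), -spec.pivot_torsion)
    atoms: list[AtomRecord] = []
    for name, p, el in mono_a:
        atoms.append(
            AtomRecord(
                atom_name=name + "A",
                element=el,
                residue_name="LIG",
                residue_index=1,
                chain_id="L",
                position=p,
                role=Role.METAL if el == "Ru" else Role.LIGAND,
            )
        )
    for name, p, el in mono_a:
        q = Rt @ np.array([-p[0] - PIVOT_BOND, -p[1], p[2]])
        atoms.append(
            AtomRecord(
                atom_name=name + "B",
                element=el,
                residue_name="LIG",
                residue_index=1,
                chain_id="L",
                position=q,
                role=Role.METAL if el == "Ru" else Role.LIGAND,
            )
        )
    return ComplexModel(atoms, duplex_length=0, strand_chains=None, ligand_chain="L")


def measure_pivot_torsion(ligand: ComplexModel) -> float:
    """Dihedral across the pivot bond (CRFA-CPVA-CPVB-CRFB), degrees."""
    pos = {a.atom_name: a.position for a in ligand.atoms}
    return dihedral(pos["CRFA"], pos["CPVA"], pos["CPVB"], pos["CRFB"])


def metal_metal_distance(ligand: ComplexModel) -> float:
    pos = {a.atom_name: a.position for a in ligand.atoms}
    return float(np.linalg.norm(pos["RUA"] - pos["RUB"]))


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _pair_frames(duplex: ComplexModel):
    """Per-pair (centroid, minor-groove direction) plus the helix axis."""
    L = duplex.duplex_length
    centroids, minors = [], []
    coords = duplex.coordinates
    for i in range(1, L + 1):
        ra, rb = duplex.base_pair_residues(i)
        idx = duplex.indices(roles=[Role.DNA_BASE], residues=[ra, rb], heavy_only=True)
        centroid = coords[idx].mean(axis=0)
        c1s = []
        for r in (ra, rb):
            chain = duplex.strand_chains[0] if r <= L else duplex.strand_chains[1]
            c1s.append(coords[duplex.find_atom(chain, r, "C1'")])
        centroids.append(centroid)
        minors.append(0.5 * (c1s[0] + c1s[1]) - centroid)
    centroids = np.asarray(centroids)
    axis_point, axis_dir = fit_line(centroids)
    if np.dot(centroids[-1] - centroids[0], axis_dir) < 0:
        axis_dir = -axis_dir
    minor_dirs = []
    for m in minors:
        m = m - np.dot(m, axis_dir) * axis_dir
        minor_dirs.append(unit(m))
    return centroids, np.asarray(minor_dirs), axis_point, axis_dir


def place_in_minor_groove(
    duplex: ComplexModel, ligand: ComplexModel, pose: PoseSpec | None = None
) -> ComplexModel:
    """Rigidly place the ligand into a groove of the duplex.

    The bridging ring-system centroid is set midway between base pairs
    ``register`` and ``register+1``, seated radially in the chosen groove;
    the ligand long (metal-metal) axis is tilted away from the helix axis by
    ``pose.tilt`` about the groove direction.  DNA coordinates are never
    modified.  Raises :class:`ClashError` when any intermolecular heavy-atom
    distance falls below 1.5 A.
    """
    pose = pose or PoseSpec()
    if duplex.ligand_chain is not None:
        raise ValueError("duplex already carries a ligand chain")
    L = duplex.duplex_length
    if not 1 <= pose.register <= L - 1:
        raise ValueError(f"register {pose.register} outside 1..{L - 1}")

    centroids, minor_dirs, axis_point, axis_dir = _pair_frames(duplex)
    r = pose.register
    anchor = 0.5 * (centroids[r - 1] + centroids[r])
    m = unit(minor_dirs[r - 1] + minor_dirs[r])
    if pose.groove == "major":
        m = -m

    # Fixed seating convention: a small axial advance plus an azimuthal
    # rotation of the anchor (the dumbbell perches over the groove-facing
    # backbone ridge rather than the exact groove midline) and a roll of
    # the ring plane about the long axis.  These constants define where on
    # the groove wall the dumbbell rests; depth and tilt remain the
    # user-facing knobs.
    seat_z, seat_az, seat_roll = 0.060, 73.356, -85.911
    Raz = rotation_about_axis(axis_dir, seat_az)
    anchor = axis_point + Raz @ (anchor + seat_z * axis_dir - axis_point)
    m = Raz @ m
    seat = anchor + (11.25 - pose.depth) * m

    # ligand frame: long axis, in-plane short axis toward the phenazine-N
    # edge, plane normal
    lig_pos = {a.atom_name: a.position for a in ligand.atoms}
    bridge_idx = [
        i
        for i, a in enumerate(ligand.atoms)
        if a.atom_name[:-1] in BRIDGE_RING_ATOMS
    ]
    bridge_xyz = ligand.coordinates[bridge_idx]
    bridge_centroid = bridge_xyz.mean(axis=0)
    e1 = unit(lig_pos["RUB"] - lig_pos["RUA"])
    np_edge = 0.5 * (lig_pos["NP1A"] + lig_pos["NP1B"]) - bridge_centroid
    e2 = unit(np_edge - np.dot(np_edge, e1) * e1)
    e3 = np.cross(e1, e2)

    u = rotation_about_axis(m, -pose.tilt) @ axis_dir
    v = -m
    v = unit(v - np.dot(v, u) * u)
    w = np.cross(u, v)
    Rr = rotation_about_axis(u, seat_roll)
    v = Rr @ v
    w = Rr @ w
    R = np.column_stack([u, v, w]) @ np.column_stack([e1, e2, e3]).T

    new_lig_coords = (ligand.coordinates - bridge_centroid) @ R.T + seat

    dna_heavy = duplex.indices(heavy_only=True)
    lig_heavy = [i for i, a in enumerate(ligand.atoms) if not a.is_hydrogen]
    dmat = np.linalg.norm(
        duplex.coordinates[dna_heavy][:, None, :] - new_lig_coords[lig_heavy][None, :, :],
        axis=2,
    )
    dmin = float(dmat.min())
    if dmin < 1.5:
        raise ClashError(f"placement yields heavy-atom contact of {dmin:.2f} A (< 1.5 A)")

    atoms = [a for a in duplex.atoms]
    for a, p in zip(ligand.atoms, new_lig_coords):
        atoms.append(
            AtomRecord(
                atom_name=a.atom_name,
                element=a.element,
                residue_name=a.residue_name,
                residue_index=a.residue_index,
                chain_id=a.chain_id,
                position=p,
                role=a.role,
            )
        )
    return ComplexModel(
        atoms,
        duplex_length=duplex.duplex_length,
        strand_chains=duplex.strand_chains,
        ligand_chain=ligand.atoms[0].chain_id,
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def generate_ensemble(
    model: ComplexModel,
    n: int,
    sigma_atom: float = 0.0,
    sigma_rigid: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> Ensemble:
    """Seeded thermal-fluctuation snapshots around ``model``.

    Each snapshot adds isotropic per-atom Gaussian noise of width
    ``sigma_atom`` (A) to every atom, plus a rigid-body jitter of the whole
    ligand: a Gaussian translation (width ``sigma_rigid[0]`` A per axis) and
    a rotation about a random axis through the ligand centroid with
    Gaussian angle (width ``sigma_rigid[1]`` deg).  Identical seeds produce
    bit-identical ensembles; all-zero widths reproduce the input exactly.
    """
    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    if sigma_atom < 0 or sigma_rigid[0] < 0 or sigma_rigid[1] < 0:
        raise ValueError("noise widths must be non-negative")
    rng = np.random.default_rng(seed)
    base = model.coordinates
    lig_idx = model.ligand_indices
    snaps = []
    for _ in range(n):
        coords = base + rng.normal(0.0, 1.0, size=base.shape) * sigma_atom
        shift = rng.normal(0.0, 1.0, size=3) * sigma_rigid[0]
        axis = rng.normal(0.0, 1.0, size=3)
        angle = float(rng.normal(0.0, 1.0)) * sigma_rigid[1]
        if lig_idx.size:
            centroid = base[lig_idx].mean(axis=0)
            if np.linalg.norm(axis) > 0 and sigma_rigid[1] > 0:
                Rj = rotation_about_axis(axis, angle)
                coords[lig_idx] = (coords[lig_idx] - centroid) @ Rj.T + centroid
            coords[lig_idx] += shift
        snaps.append(model.with_coordinates(coords))
    return Ensemble(snaps, labels=[f"snap{k + 1:04d}" for k in range(n)])
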