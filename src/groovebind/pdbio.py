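"""PDB reading and writing for complexes and snapshot ensembles.

Reading goes through Bio.PDB; the chain-role mapping (chain id -> "dna" /
"ligand") supplies the structural role of every atom.  Writing emits a
conventional fixed-width PDB dialect: DNA atoms as ATOM records, ligand and
metal atoms as HETATM, hydrogens as first-class atoms, coordinates to
0.001 Angstrom, ensembles as MODEL/ENDMDL blocks.
"""

from __future__ import annotations

import io
import os
import warnings
from typing import Mapping

from Bio.PDB import PDBParser

from .model import AtomRecord, ComplexModel, Ensemble, Role, TopologyError, infer_role

__all__ = ["read_structure", "read_ensemble", "write_structure", "write_ensemble", "PDBParseError"]


class PDBParseError(ValueError):
    """Malformed PDB content; the message names the offending line."""


def _validate_coordinate_fields(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name their line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated {line[:6].strip()} record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                field = line[lo:hi]
                try:
                    float(field)
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{lineno}: non-numeric {what} coordinate field {field!r}"
                    ) from None


def _convert_model(bio_model, chain_roles: Mapping[str, str]) -> ComplexModel:
    present = {c.id for c in bio_model}
    missing = set(chain_roles) - present
    if missing:
        raise KeyError(f"chains {sorted(missing)} named in chain_roles absent from file")
    atoms: list[AtomRecord] = []
    dna_chains: list[str] = []
    ligand_chain: str | None = None
    for chain in bio_model:
        if chain.id not in chain_roles:
            raise KeyError(f"chain {chain.id!r} in file has no entry in chain_roles")
        kind = chain_roles[chain.id]
        if kind == "dna":
            dna_chains.append(chain.id)
        else:
            ligand_chain = chain.id
        for residue in chain:
            for atom in residue:
                element = atom.element if atom.element else atom.get_name()[0]
                atoms.append(
                    AtomRecord(
                        atom_name=atom.get_name(),
                        element=element.capitalize(),
                        residue_name=residue.get_resname().strip(),
                        residue_index=residue.id[1],
                        chain_id=chain.id,
                        position=atom.get_coord().astype(float),
                        role=infer_role(kind, atom.get_name(), element),
                    )
                )
    duplex_length = 0
    strand_chains = None
    if dna_chains:
        if len(dna_chains) != 2:
            raise TopologyError(f"expected 2 DNA chains, found {len(dna_chains)}")
        strand_chains = (dna_chains[0], dna_chains[1])
        duplex_length = len(
            {a.residue_index for a in atoms if a.chain_id == dna_chains[0]}
        )
    return ComplexModel(atoms, duplex_length, strand_chains, ligand_chain)


def _parse(path: str):
    _validate_coordinate_fields(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return parser.get_structure("complex", path)
    except Exception as exc:  # Bio.PDB raises PDBConstructionException subclasses
        raise PDBParseError(f"{path}: {exc}") from exc


def read_structure(path: str, chain_roles: Mapping[str, str]) -> ComplexModel:
    """Read a single-model PDB file into a role-labelled ComplexModel."""
    structure = _parse(path)
    models = list(structure)
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")
    return _convert_model(models[0], chain_roles)


def read_ensemble(path: str, chain_roles: Mapping[str, str]) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an Ensemble of snapshots."""
    structure = _parse(path)
    snapshots = [_convert_model(m, chain_roles) for m in structure]
    if not snapshots:
        raise PDBParseError(f"{path}: no coordinate records found")
    first = snapshots[0]
    for k, snap in enumerate(snapshots[1:], start=2):
        if snap.n_atoms != first.n_atoms:
            raise TopologyError(
                f"{path}: model {k} has {snap.n_atoms} atoms but model 1 has {first.n_atoms}"
            )
    return Ensemble(snapshots, labels=[f"model{k + 1}" for k in range(len(snapshots))])


def _format_atom_line(serial: int, atom: AtomRecord) -> str:
    record = "HETATM" if atom.role in (Role.LIGAND, Role.METAL) else "ATOM  "
    name = atom.atom_name
    # PDB column convention: short names start in column 14.
    name_field = name.ljust(4) if len(name) == 4 else f" {name}".ljust(4)
    x, y, z = atom.position
    return (
        f"{record}{serial:>5d} {name_field} {atom.residue_name:<3s}"
        f" {atom.chain_id}{atom.residue_index:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element.upper():>2s}"
    )


def _write_model_block(fh: io.TextIOBase, model: ComplexModel, serial0: int = 1) -> None:
    serial = serial0
    prev_chain = None
    for atom in model.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            fh.write(f"TER   {serial:>5d}\n")
            serial += 1
        fh.write(_format_atom_line(serial, atom) + "\n")
        serial += 1
        prev_chain = atom.chain_id
    fh.write(f"TER   {serial:>5d}\n")


def write_structure(
    model: ComplexModel, path: str, remarks: list[str] | None = None
) -> None:
    """Write one ComplexModel as a single-model PDB file."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write a model with no atoms")
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        for remark in remarks or []:
            fh.write(f"REMARK 250 {remark}\n")
        _write_model_block(fh, model)
        fh.write("END\n")
    os.replace(tmp, path)


def write_ensemble(
    ensemble: Ensemble, path: str, remarks: list[str] | None = None
) -> None:
    """Write an Ensemble as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        for remark in remarks or []:
            fh.write(f"REMARK 250 {remark}\n")
        for k, snap in enumerate(ensemble.snapshots, start=1):
            fh.write(f"MODEL     {k:>4d}\n")
            _write_model_block(fh, snap)
            fh.write("ENDMDL\n")
        fh.write("END\n")
    os.replace(tmp, path)
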