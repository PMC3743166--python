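"""Pipeline configuration: flat dotted-key YAML with validation.

A config file is a YAML mapping from dotted keys to scalars, e.g.::

    sequence: CGCGAATTCGCG
    pose.register: 10
    ensemble.runs: 10
    seed: 7

Unknown keys, out-of-range values and duplicated keys are validation
errors (all collected and reported together).  Every key has a default, so
the minimal config is just a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any

import yaml

from .builder import HelixParams, LigandSpec, PoseSpec
from .energetics import EnergyParams

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


class _DuplicateKeyLoader(yaml.SafeLoader):
    pass


def _mapping_no_duplicates(loader, node, deep=False):
    seen = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(
                f"duplicate key {key!r} at lines "
                f"{seen[key].start_mark.line + 1} and {key_node.start_mark.line + 1}"
            )
        seen[key] = key_node
    return yaml.constructor.SafeConstructor.construct_mapping(loader, node, deep)


_DuplicateKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _mapping_no_duplicates
)


DEFAULTS: dict[str, Any] = {
    "sequence": "CGCGAATTCGCG",
    "helix.twist_per_step": 36.0,
    "helix.rise_per_step": 3.38,
    "ligand.pivot_torsion": 33.0,
    "pose.register": 8,
    "pose.groove": "minor",
    "pose.depth": 0.0,
    "pose.tilt": 66.17,
    "ensemble.runs": 10,
    "ensemble.snapshots": 25,
    "ensemble.sigma_atom": 0.3,
    "ensemble.sigma_trans": 0.3,
    "ensemble.sigma_rot": 2.0,
    "seed": 0,
    "restraints.path": None,
    "energy.epsilon_r": 20.0,
    "energy.lj_cutoff": 6.0,
    "energy.hb_energy": -2.0,
    "energy.hb_distance_max": 3.0,
    "energy.surface_angle_min": 45.0,
    "energy.coulomb_cutoff": None,
    "energy.end": "top",
    "select.violation_tolerance": 0.1,
    "select.margin": 1e-6,
    "select.steric_weight": 1.0,
    "fit.pair_first": 7,
    "fit.pair_last": 10,
}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    sequence: str
    helix: HelixParams
    ligand: LigandSpec
    pose: PoseSpec
    runs: int
    snapshots: int
    sigma_atom: float
    sigma_rigid: tuple[float, float]
    seed: int
    restraints_path: str | None
    energy: EnergyParams
    energy_end: str
    violation_tolerance: float
    margin: float
    steric_weight: float
    fit_pair_first: int
    fit_pair_last: int
    raw: dict[str, Any] = field(default_factory=dict)


def _coerce(key: str, value: Any, errors: list[str]) -> Any:
    default = DEFAULTS[key]
    if value is None:
        return None if default is None or key == "restraints.path" else default
    if isinstance(default, bool):  # none today, guard anyway
        return bool(value)
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            if float(value) != int(float(value)):
                raise ValueError
            return int(float(value))
        except (TypeError, ValueError):
            errors.append(f"{key}: expected an integer, got {value!r}")
            return default
    if isinstance(default, float):
        try:
            return float(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected a number, got {value!r}")
            return default
    return value


def validate_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load, default-fill and validate a dotted-key YAML config.

    ``overrides`` (e.g. a CLI --seed) take precedence over the file.
    Raises :class:`ConfigError` listing every problem found.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.load(fh, Loader=_DuplicateKeyLoader)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping of dotted keys")
        data.update(loaded)
    data.update(overrides or {})

    errors: list[str] = []
    unknown = sorted(set(data) - set(DEFAULTS))
    for key in unknown:
        errors.append(f"unknown key {key!r}")
    values = dict(DEFAULTS)
    for key, value in data.items():
        if key in DEFAULTS:
            values[key] = _coerce(key, value, errors)

    seq = str(values["sequence"]).upper()
    if not seq or any(b not in "ACGT" for b in seq):
        errors.append(f"sequence: invalid characters in {values['sequence']!r}")
    if len(seq) < 2:
        errors.append("sequence: needs at least 2 bases")

    try:
        helix = HelixParams(
            twist_per_step=values["helix.twist_per_step"],
            rise_per_step=values["helix.rise_per_step"],
        )
    except ValueError as exc:
        errors.append(f"helix: {exc}")
        helix = HelixParams()
    ligand = LigandSpec(pivot_torsion=values["ligand.pivot_torsion"])
    try:
        pose = PoseSpec(
            register=values["pose.register"],
            groove=values["pose.groove"],
            depth=values["pose.depth"],
            tilt=values["pose.tilt"],
        )
    except ValueError as exc:
        errors.append(f"pose: {exc}")
        pose = PoseSpec()
    if not 1 <= values["pose.register"] <= max(1, len(seq) - 1):
        errors.append(
            f"pose.register: {values['pose.register']} outside 1..{len(seq) - 1}"
        )
    for key in ("ensemble.runs", "ensemble.snapshots"):
        if values[key] < 1:
            errors.append(f"{key}: must be >= 1")
    for key in ("ensemble.sigma_atom", "ensemble.sigma_trans", "ensemble.sigma_rot"):
        if values[key] < 0:
            errors.append(f"{key}: must be >= 0")
    if values["energy.end"] not in ("top", "bottom"):
        errors.append("energy.end: must be 'top' or 'bottom'")
    try:
        energy = EnergyParams(
            epsilon_r=values["energy.epsilon_r"],
            lj_cutoff=values["energy.lj_cutoff"],
            hb_energy=values["energy.hb_energy"],
            hb_distance_max=values["energy.hb_distance_max"],
            surface_angle_min=values["energy.surface_angle_min"],
            coulomb_cutoff=values["energy.coulomb_cutoff"],
        )
    except ValueError as exc:
        errors.append(f"energy: {exc}")
        energy = EnergyParams()
    if not 1 <= values["fit.pair_first"] <= values["fit.pair_last"] <= len(seq):
        errors.append(
            f"fit: pair range {values['fit.pair_first']}..{values['fit.pair_last']} "
            f"outside duplex 1..{len(seq)}"
        )
    rp = values["restraints.path"]
    if rp is not None and not isinstance(rp, str):
        errors.append("restraints.path: must be a path string or null")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    return PipelineConfig(
        sequence=seq,
        helix=helix,
        ligand=ligand,
        pose=pose,
        runs=values["ensemble.runs"],
        snapshots=values["ensemble.snapshots"],
        sigma_atom=values["ensemble.sigma_atom"],
        sigma_rigid=(values["ensemble.sigma_trans"], values["ensemble.sigma_rot"]),
        seed=values["seed"],
        restraints_path=rp,
        energy=energy,
        energy_end=values["energy.end"],
        violation_tolerance=values["select.violation_tolerance"],
        margin=values["select.margin"],
        steric_weight=values["select.steric_weight"],
        fit_pair_first=values["fit.pair_first"],
        fit_pair_last=values["fit.pair_last"],
        raw=values,
    )
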