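"""YAML configuration for mechanisms and experiment grids.

The schema is deliberately small: an experiment file names the study, the
mechanisms, the loss rates, the replication count and a mandatory base seed
(there is no hidden global RNG anywhere in the package). Mechanism files
carry the fields of :class:`~amputebias.amputation.MechanismSpec`.
Validation errors name the offending field path and raise
:class:`~amputebias.errors.ConfigError`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .amputation import MechanismSpec
from .errors import ConfigError, ParameterError
from .experiment import ExperimentGrid

__all__ = [
    "grid_from_yaml",
    "grid_to_yaml",
    "mechanism_from_yaml",
    "mechanism_to_yaml",
]

_GRID_FIELDS = {"study", "mechanisms", "loss_rates", "replications", "base_seed"}


def _load(path: str | Path) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"invalid YAML: {err}") from None
    if not isinstance(doc, dict):
        raise ConfigError("top level must be a mapping")
    return doc


def grid_from_yaml(path: str | Path) -> ExperimentGrid:
    doc = _load(path)
    missing = _GRID_FIELDS - doc.keys()
    if missing:
        raise ConfigError("required field missing", field_path=sorted(missing)[0])
    extra = doc.keys() - _GRID_FIELDS
    if extra:
        raise ConfigError("unknown field", field_path=sorted(extra)[0])
    for list_field in ("mechanisms", "loss_rates"):
        if not isinstance(doc[list_field], list) or not doc[list_field]:
            raise ConfigError("must be a non-empty list", field_path=list_field)
    if "base_seed" not in doc or not isinstance(doc["base_seed"], int):
        raise ConfigError("seed is mandatory and must be an integer", field_path="base_seed")
    try:
        return ExperimentGrid.from_dict(doc)
    except ParameterError as err:
        raise ConfigError(str(err)) from None


def grid_to_yaml(grid: ExperimentGrid, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(grid.to_dict(), sort_keys=False))
    return path


def mechanism_from_yaml(path: str | Path) -> MechanismSpec:
    doc = _load(path)
    for tup_field in ("percentile_cuts", "stratum_levels", "stratum_weights"):
        if doc.get(tup_field) is not None:
            doc[tup_field] = tuple(doc[tup_field])
    try:
        return MechanismSpec(**doc)
    except TypeError as err:
        raise ConfigError(str(err)) from None
    except ParameterError as err:
        raise ConfigError(str(err)) from None


def mechanism_to_yaml(spec: MechanismSpec, path: str | Path) -> Path:
    doc = {
        "mechanism_id": spec.mechanism_id,
        "loss_rate": spec.loss_rate,
        "stratum_variable": spec.stratum_variable,
        "percentile_cuts": list(spec.percentile_cuts) if spec.percentile_cuts else None,
        "stratum_levels": list(spec.stratum_levels) if spec.stratum_levels else None,
        "stratum_weights": list(spec.stratum_weights) if spec.stratum_weights else None,
        "group_proportional": spec.group_proportional,
        "group_variable": spec.group_variable,
        "label": spec.label,
        "seed": spec.seed,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
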