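"""Run configuration and artifact serialization.

Configurations are YAML with a strict schema (unknown keys rejected).
Artifacts are written as flat CSV plus full-precision JSON; every artifact
embeds a provenance block (package version, seed, configuration hash) so
that re-running with the same configuration and seed reproduces identical
files. CSV files carry the provenance as leading ``#`` comment lines
(readers should pass ``comment='#'``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .errors import ParameterDomainError

__all__ = ["RunConfig", "load_config", "save_config", "write_results", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    """Overrides applied on top of the canonical consortium parameterization."""

    substrate_conc: float | None = None
    chain_length: int | None = None
    inv_K_I: float | None = None
    inhibition_mode: str | None = None
    K_eq: float | None = None
    D_X: float | list[float] | None = None
    D_P: float | None = None
    permeabilities: list[float] | None = None
    demands: tuple[float, float] | None = None
    host_demand: float | None = None
    fractions: tuple[float, float] | None = None
    total_cells: float | None = None

    def overrides(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class SolverSection(_Strict):
    n_starts: int = 24
    constraint_tolerance: float = 1e-7
    optimality_tolerance: float = 1e-12
    symmetry_restriction: str = "A_S_nonnegative"
    n_starts_sweep: int = 6


class ExperimentSection(_Strict):
    D_X_values: list[float] | None = None
    D_P_values: list[float] | None = None
    inv_K_I_values: list[float] | None = None
    sweep: str | None = None
    sweep_values: list[float] | None = None
    n_samples: int = 200
    rel_magnitude: float = 0.3
    permeable_index: int = 1
    chain_length: int = 5


class PermeabilitySection(_Strict):
    pathway: str | None = None  # TSV path; None = packaged trp fixture
    ruleset: str | None = None  # YAML path; None = shipped default
    ignore_channeling: bool = False
    rule_column: str = "3PR"


class RunConfig(_Strict):
    """Schema-validated configuration for a reproducible run."""

    seed: int = 0
    out_dir: str = "results"
    model: ModelSection = Field(default_factory=ModelSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    experiment: ExperimentSection = Field(default_factory=ExperimentSection)
    permeability: PermeabilitySection = Field(default_factory=PermeabilitySection)


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration; errors name the offending key."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        raise ParameterDomainError(f"invalid configuration {path}: {err}") from err


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig | None, seed: int | None) -> dict:
    return {
        "package": "metcomp",
        "version": __version__,
        "seed": int(seed if seed is not None else (config.seed if config else 0)),
        "config_hash": config_hash(config) if config is not None else None,
    }


def write_results(result, out_dir, name: str = "result",
                  config: RunConfig | None = None, seed: int | None = None) -> dict:
    """Write one result object as ``<name>.csv`` + ``<name>.json``.

    ``result`` may be anything with ``to_frame()``/``to_dict()`` (phase
    diagrams, sweeps, sensitivity results) or a bare DataFrame. Returns the
    mapping of artifact kinds to paths. Identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config, seed)

    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    payload = result.to_dict() if hasattr(result, "to_dict") else {"records": frame.to_dict("records")}

    csv_path = out_dir / f"{name}.csv"
    with open(csv_path, "w", newline="") as fh:
        for key, value in sorted(prov.items()):
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")

    json_path = out_dir / f"{name}.json"
    with open(json_path, "w") as fh:
        json.dump({"provenance": prov, "result": payload}, fh, indent=1, sort_keys=True,
                  default=_json_default)
        fh.write("\n")
    return {"csv": csv_path, "json": json_path}


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
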