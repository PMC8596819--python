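"""JSON run/analysis configuration parsing and validation.

A single JSON file defines everything a docking experiment needs: an
``embedding`` block (which embedder, its parallelization and parameters, the
ligand input), a ``docking`` block (backend, receptor, write-out mode) and an
``output`` block (where poses and scores land). A second dialect configures
the analysis script (mode, score-file inputs, thresholds).

Validation is strict and total: unknown keys are rejected with the offending
path named (surfacing typos a free-form reader would silently ignore), every
default is filled in, and relative paths are resolved against the config
file's own directory so a config behaves the same from any working
directory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .docking import BACKEND_REGISTRY, WRITE_OUT_MODES

EMBEDDER_REGISTRY = ("rdkit",)  # built-in conformer generator; adapters register here

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration failed validation; the message names the bad path."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Parallelization(_Strict):
    number_cores: int = Field(default=1, ge=1)
    max_compounds_per_core: int = Field(default=8, ge=1)


class EmbedderParameters(_Strict):
    ph: float = 7.0
    ph_tolerance: float = 2.0
    force_field: str = "MMFF94"
    max_iterations: int = Field(default=600, ge=1)
    seed: int = 42


class InputBlock(_Strict):
    path: str
    format: Literal["SMILES", "SDF"] = "SMILES"


class OptionalOutputBlock(_Strict):
    path: str | None = None
    format: Literal["SMILES", "SDF"] = "SDF"


class EmbeddingBlock(_Strict):
    embedder: str = "rdkit"
    parallelization: Parallelization = Field(default_factory=Parallelization)
    parameters: EmbedderParameters = Field(default_factory=EmbedderParameters)
    input: InputBlock
    output: OptionalOutputBlock | None = None
    enumerate_stereo: bool = True
    enumerate_tautomers: bool = False
    max_states: int = Field(default=32, ge=1)

    @field_validator("embedder")
    @classmethod
    def _known_embedder(cls, v: str) -> str:
        if v not in EMBEDDER_REGISTRY:
            raise ValueError(f"unknown embedder {v!r}; registered embedders: "
                             f"{sorted(EMBEDDER_REGISTRY)}")
        return v


class DockingParameters(_Strict):
    poses_per_ligand: int = Field(default=1, ge=1)


class DockingBlock(_Strict):
    backend: str = "synthetic"
    receptor: Union[str, dict] = Field(
        description="path to a receptor-profile JSON, or an inline profile object"
    )
    parameters: DockingParameters = Field(default_factory=DockingParameters)
    write_out_mode: Literal["best_per_ligand", "best_per_enumeration", "all"] = \
        "best_per_ligand"

    @field_validator("backend")
    @classmethod
    def _known_backend(cls, v: str) -> str:
        if v not in BACKEND_REGISTRY:
            raise ValueError(f"unknown backend {v!r}; registered backends: "
                             f"{sorted(BACKEND_REGISTRY)}")
        return v

    @field_validator("write_out_mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        assert v in WRITE_OUT_MODES
        return v


class OutputBlock(_Strict):
    poses_path: str = "poses.sdf"
    scores_path: str = "scores.csv"


class RunConfiguration(_Strict):
    """A fully validated docking-experiment configuration."""

    schema_version: int = SCHEMA_VERSION
    embedding: EmbeddingBlock
    docking: DockingBlock
    output: OutputBlock = Field(default_factory=OutputBlock)

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


class AnalysisInput(_Strict):
    path: str
    direction: Literal["lower_better", "higher_better"] = "lower_better"
    name: str | None = None


class AnalysisConfiguration(_Strict):
    """Configuration of the score-analysis script."""

    schema_version: int = SCHEMA_VERSION
    mode: Literal["enrichment", "correlation", "thresholds"]
    inputs: list[AnalysisInput] = Field(min_length=1)
    experimental_direction: Literal["lower_better", "higher_better"] = "lower_better"
    score_threshold: float | None = None
    experimental_threshold: float | None = None
    report_path: str | None = None

    def model_post_init(self, __context) -> None:
        if self.mode == "thresholds" and (
            self.score_threshold is None or self.experimental_threshold is None
        ):
            raise ValueError(
                "thresholds mode requires both score_threshold and experimental_threshold"
            )

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _format_validation_error(err: ValidationError) -> str:
    parts = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        parts.append(f"{loc}: {e['msg']}")
    return "; ".join(parts)


def _resolve(path_value: str | None, base_dir: Path | None) -> str | None:
    if path_value is None or base_dir is None:
        return path_value
    p = Path(path_value)
    return str(p if p.is_absolute() else (base_dir / p).resolve())


def parse_run_config(json_text: str, base_dir: str | Path | None = None) -> RunConfiguration:
    """Parse and validate a run-configuration JSON string.

    ``base_dir`` (normally the config file's directory) anchors relative
    paths. Malformed JSON raises ``json.JSONDecodeError``; any schema
    violation — unknown key, unknown backend/embedder, missing input —
    raises ``ConfigError`` naming the offending path.
    """
    raw = json.loads(json_text)
    try:
        conf = RunConfiguration.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None
    base = Path(base_dir).resolve() if base_dir is not None else None
    if base is not None:
        conf.embedding.input.path = _resolve(conf.embedding.input.path, base)
        if conf.embedding.output is not None:
            conf.embedding.output.path = _resolve(conf.embedding.output.path, base)
        if isinstance(conf.docking.receptor, str):
            conf.docking.receptor = _resolve(conf.docking.receptor, base)
        conf.output.poses_path = _resolve(conf.output.poses_path, base)
        conf.output.scores_path = _resolve(conf.output.scores_path, base)
    return conf


def load_run_config(path: str | Path) -> RunConfiguration:
    path = Path(path)
    return parse_run_config(path.read_text(), base_dir=path.parent)


def parse_analysis_config(
    json_text: str, base_dir: str | Path | None = None
) -> AnalysisConfiguration:
    """Parse and validate an analysis-configuration JSON string."""
    raw = json.loads(json_text)
    try:
        conf = AnalysisConfiguration.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None
    except ValueError as err:
        raise ConfigError(str(err)) from None
    base = Path(base_dir).resolve() if base_dir is not None else None
    if base is not None:
        for inp in conf.inputs:
            inp.path = _resolve(inp.path, base)
        conf.report_path = _resolve(conf.report_path, base)
    return conf


def load_analysis_config(path: str | Path) -> AnalysisConfiguration:
    path = Path(path)
    return parse_analysis_config(path.read_text(), base_dir=path.parent)
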