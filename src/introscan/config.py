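"""Run configuration: a single YAML/TOML file drives the whole pipeline.

Exactly one of the ``input`` (real data paths) and ``simulate`` (synthetic
cohort parameters) blocks must be present.  Unknown keys are rejected with
a nearest-key suggestion so typos never silently fall back to defaults.
"""

from __future__ import annotations

import difflib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """A run configuration violates the schema."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Block):
    vcf: str
    metadata: str
    annotation: Optional[str] = None
    annotation_format: Literal["bed", "gff3"] = "bed"


class SimulateConfig(_Block):
    n_sites: int = Field(default=2000, ge=1)
    n_marine: int = Field(default=5, ge=0)
    n_freshwater: int = Field(default=5, ge=0)
    pi_ils: float = Field(default=0.10, ge=0.0, le=1.0)
    pi_fixed: float = Field(default=0.05, ge=0.0, le=1.0)
    alpha_marine: float = Field(default=0.35, ge=0.0, le=1.0)
    alpha_freshwater: float = Field(default=0.068, ge=0.0, le=1.0)
    missing_rate: float = Field(default=0.01, ge=0.0, le=1.0)


class DstatConfig(_Block):
    block_size: int = Field(default=5000, ge=1)
    outgroup_mode: Literal["reference_allele", "sample_ids"] = "reference_allele"
    hard_call: bool = False


class CompareConfig(_Block):
    alternative: Literal["two_sided", "greater", "less"] = "two_sided"
    continuity: bool = True


class ScanConfig(_Block):
    threshold: float = Field(default=0.5, ge=0.0, lt=1.0)
    min_called: int = Field(default=1, ge=1)


class RunConfig(_Block):
    input: Optional[InputConfig] = None
    simulate: Optional[SimulateConfig] = None
    dstat: DstatConfig = Field(default_factory=DstatConfig)
    compare: CompareConfig = Field(default_factory=CompareConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    output_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' and 'simulate' must be present")
        return self


def _friendly_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        msg = err["msg"]
        if err["type"] == "extra_forbidden":
            parent = err["loc"][:-1]
            model: type[BaseModel] = RunConfig
            for part in parent:
                fld = model.model_fields.get(str(part))
                ann = getattr(fld, "annotation", None)
                for cand in getattr(ann, "__args__", (ann,)):
                    if isinstance(cand, type) and issubclass(cand, BaseModel):
                        model = cand
                        break
            close = difflib.get_close_matches(str(err["loc"][-1]), model.model_fields, n=1)
            if close:
                msg = f"unknown key; did you mean '{close[0]}'?"
            else:
                msg = "unknown key"
        lines.append(f"{loc}: {msg}")
    return "; ".join(lines)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML or TOML run configuration.

    Defaults are filled for every omitted key; schema violations are
    reported with their key paths.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {_friendly_errors(exc)}") from exc
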