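"""Run configuration: a flat, human-editable YAML file validated at load.

Every knob of an end-to-end run lives here: generator parameters, survey
sample sizes, the swept area and colony density used to scale biomass, and
the random seed. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import SchemaError, ValidationError
from .synthetic import GeneratorConfig, RelativeNoise

PathLike = Union[str, Path]


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end biomass-estimation run needs.

    Defaults reproduce the study conditions: a trawl sample of 168 colonies
    over a 41,000 m^2 swept area and 207 ROV-observed colonies, drawn from
    one synthetic population.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    population_size: int = 4000
    trawl_sample_size: int = 168
    rov_sample_size: int = 207
    dry_subset_size: int = 54
    apply_selectivity: bool = True
    area: float = 41_000.0                 # m^2 (S)
    density: Optional[float] = None        # colonies / m^2 (delta); derived
                                           # as trawl count / area when None
    validity_min_n: float = 15.0           # weight model not applicable at or below
    colony_table: Optional[str] = None     # measured table; None -> simulate
    rov_table: Optional[str] = None        # ROV table; None with a colony
                                           # table -> no biomass stage
    report_path: Optional[str] = None

    def validate(self) -> None:
        self.generator.validate()
        if self.density is not None and self.density < 0:
            raise ValidationError("density must be >= 0")
        if self.area < 0:
            raise ValidationError("area must be >= 0")
        for name in ("population_size", "trawl_sample_size", "rov_sample_size",
                     "dry_subset_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


_NOISE_KEYS = {f.name for f in fields(RelativeNoise)}
_GENERATOR_KEYS = {f.name for f in fields(GeneratorConfig)}
_RUN_KEYS = {f.name for f in fields(RunConfig)}


def load_config(path: PathLike) -> RunConfig:
    """Load and validate a YAML run configuration.

    Layout mirrors the dataclasses: top-level RunConfig keys, a nested
    ``generator:`` mapping, and inside it an optional ``relative_noise:``
    mapping. Tuple-valued model coefficients are given as YAML lists.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise SchemaError(f"config {path}: unknown key(s) {sorted(unknown)}")

    gen_raw = dict(raw.pop("generator", {}) or {})
    unknown = set(gen_raw) - _GENERATOR_KEYS
    if unknown:
        raise SchemaError(f"config {path}: unknown generator key(s) {sorted(unknown)}")
    noise_raw = gen_raw.pop("relative_noise", None)
    if noise_raw is not None:
        unknown = set(noise_raw) - _NOISE_KEYS
        if unknown:
            raise SchemaError(
                f"config {path}: unknown relative_noise key(s) {sorted(unknown)}"
            )
        gen_raw["relative_noise"] = RelativeNoise(**noise_raw)
    for key in ("rachis_model", "total_model", "weight_model", "dry_model"):
        if key in gen_raw:
            gen_raw[key] = tuple(float(v) for v in gen_raw[key])
    generator = GeneratorConfig(**gen_raw)

    config = RunConfig(generator=generator, **raw)
    config.validate()
    return config


def save_config(config: RunConfig, path: PathLike) -> None:
    """Write a RunConfig back to the YAML layout load_config accepts."""
    gen = config.generator
    payload = {
        name: getattr(config, name)
        for name in _RUN_KEYS
        if name != "generator"
    }
    payload["generator"] = {
        f.name: (
            {n.name: getattr(gen.relative_noise, n.name)
             for n in fields(RelativeNoise)}
            if f.name == "relative_noise"
            else list(getattr(gen, f.name))
            if isinstance(getattr(gen, f.name), tuple)
            else getattr(gen, f.name)
        )
        for f in fields(GeneratorConfig)
    }
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
    )


def with_seed(config: RunConfig, seed: int) -> RunConfig:
    """Copy of a config with a different random seed."""
    return replace(config, seed=seed)
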