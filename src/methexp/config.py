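"""Pipeline configuration: YAML schema, validation, and round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .synthetic import SimulationConfig

SCHEMA_VERSION = 1


@dataclass
class PipelineParams:
    """Analysis thresholds; defaults follow the published rule set exactly."""

    min_coverage: int = 4
    mc_p: float = 1e-4
    error_rate: float = 0.01
    dmr_min_sites: int = 5
    dmr_window_sites: int = 5
    dmr_diff: float = 0.1
    dmr_p: float = 0.05
    merge_gap: int = 100
    fc: float = 2.0
    deg_adj_p: float = 0.001
    fpkm_filter: float = 1.0
    k: int = 9
    beta: float = 6.0
    tom_threshold: float = 0.2
    window: int = 1_000_000
    step: int = 200_000
    network_max_genes: int = 2000
    focal_genotype: str = "245"
    other_genotype: str = "Z16"

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        for name in ("mc_p", "dmr_p", "deg_adj_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.dmr_min_sites < 1 or self.dmr_window_sites < 1:
            raise ConfigError("DMR site counts must be >= 1")
        if not 0 <= self.dmr_diff < 1:
            raise ConfigError("dmr_diff must be in [0, 1)")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")
        if self.fc < 1:
            raise ConfigError("fc must be >= 1")
        if self.fpkm_filter < 0:
            raise ConfigError("fpkm_filter must be >= 0")
        if self.k < 1 or self.beta <= 0:
            raise ConfigError("k must be >= 1 and beta > 0")
        if self.window < 1 or self.step < 1:
            raise ConfigError("window and step must be >= 1")


@dataclass
class PipelineConfig:
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_dict(self) -> dict:
        out = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "simulation": dataclasses.asdict(self.simulation),
            "params": dataclasses.asdict(self.params),
        }
        sim = out["simulation"]
        sim["gene_length_range"] = list(sim["gene_length_range"])
        sim["genotypes"] = list(sim["genotypes"])
        sim["stages"] = list(sim["stages"])
        return out

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        seed = data.pop("seed", 0)
        sim_data = dict(data.pop("simulation", {}) or {})
        params_data = dict(data.pop("params", {}) or {})
        if data:
            raise ConfigError(f"unknown config sections: {sorted(data)}")
        for key in ("gene_length_range", "genotypes", "stages"):
            if key in sim_data:
                sim_data[key] = tuple(sim_data[key])
        sim_data.setdefault("seed", seed)
        try:
            simulation = SimulationConfig(**sim_data)
            params = PipelineParams(**params_data)
        except TypeError as err:
            raise ConfigError(f"invalid config field: {err}") from err
        return cls(
            seed=seed, schema_version=version, simulation=simulation, params=params
        )


def load_config(path: str) -> PipelineConfig:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError as err:
        raise ConfigError(f"config file not found: {path}") from err
    except yaml.YAMLError as err:
        raise ConfigError(f"malformed YAML in {path}: {err}") from err
    return PipelineConfig.from_dict(data or {})


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
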