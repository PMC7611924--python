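"""Run configuration: stage blocks with validated defaults.

Defaults encode the analysis conventions: instrument selection at
p < 5e-8, clumping at r^2 < 0.001 within a 1 Mb window, FDR q = 0.05,
palindromic-SNP frequency limit 0.42.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class SimulateBlock:
    n_families: int = 2000
    n_snps: int = 150
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_siblings_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.25, 1: 0.40, 2: 0.25, 3: 0.10}
    )
    h2: tuple[float, float, float] = (0.30, 0.30, 0.25)
    n_causal: int = 15
    shared_fraction: float = 0.5
    lifespan_years_lost: tuple[float, float, float] = (2.0, 0.0, 0.5)
    lifespan_baseline: float = 73.0
    lifespan_noise_sd: float = 10.0
    censor_age: float = 60.0
    report_sensitivity: float = 1.0
    report_specificity: float = 1.0


@dataclass
class GwasBlock:
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])


@dataclass
class ClumpBlock:
    p_thresh: float = 5e-8
    r2_thresh: float = 0.001
    window_bp: int = 1_000_000


@dataclass
class EstimatorBlock:
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    egger_t_reference: bool = False


@dataclass
class RunConfig:
    seed: int
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    gwas: GwasBlock = field(default_factory=GwasBlock)
    clump: ClumpBlock = field(default_factory=ClumpBlock)
    estimators: EstimatorBlock = field(default_factory=EstimatorBlock)
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ConfigError("fdr_q must be in (0, 1)")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


_BLOCKS = {
    "simulate": SimulateBlock,
    "gwas": GwasBlock,
    "clump": ClumpBlock,
    "estimators": EstimatorBlock,
}


def _plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _build_block(cls, data: Mapping[str, Any], where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        if key == "n_siblings_dist" and isinstance(value, Mapping):
            value = {int(k): float(v) for k, v in value.items()}
        if key == "covariates":
            value = list(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    top = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    if "seed" not in data:
        raise ConfigError("config must set a seed")
    kwargs: dict[str, Any] = {"seed": int(data["seed"])}
    if "fdr_q" in data:
        kwargs["fdr_q"] = float(data["fdr_q"])
    for name, cls in _BLOCKS.items():
        if name in data:
            block = data[name]
            if not isinstance(block, Mapping):
                raise ConfigError(f"config block {name!r} must be a mapping")
            kwargs[name] = _build_block(cls, block, name)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    return config_from_dict(data)
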