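"""Pipeline configuration: stage-keyed parameter blocks, validated strictly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .crossmodal import CVConfig
from .simulate import SimulationConfig

COVARIATE_PLACEMENTS = ("second_level", "first_level", "both", "none")


@dataclass
class ConnectivityParams:
    passband: tuple[float, float] = (0.0078, 0.1)
    fisher_z_group_stats: bool = True


@dataclass
class SbiParams:
    mask_threshold: float = 0.3
    n_components: int | None = None   # None: MDL order selection
    alpha: float = 0.05
    n_perm: int = 10000


@dataclass
class CrossModalParams:
    k_folds: int = 5
    n_repeats: int = 1000
    n_perm: int = 5000
    alpha: float = 0.05
    shrinkage: str | float = "analytic"
    covariate_placement: str = "second_level"

    def __post_init__(self) -> None:
        if self.covariate_placement not in COVARIATE_PLACEMENTS:
            raise ValueError(
                f"covariate_placement must be one of {COVARIATE_PLACEMENTS}"
            )

    def cv_config(self, seed: int) -> CVConfig:
        return CVConfig(
            k_folds=self.k_folds, n_repeats=self.n_repeats,
            seed=seed, shrinkage=self.shrinkage,
        )


@dataclass
class SecondLevelParams:
    estimator: str = "huber"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Stage-keyed configuration with one master seed.

    Per-stage seeds are derived deterministically from the master seed by
    stable hashing of the stage name; no stage consults global RNG state.
    """

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    sbi: SbiParams = field(default_factory=SbiParams)
    crossmodal: CrossModalParams = field(default_factory=CrossModalParams)
    secondlevel: SecondLevelParams = field(default_factory=SecondLevelParams)
    seed: int = 0
    out_dir: str = "inflammetry_out"
    verbosity: str = "info"

    def __post_init__(self) -> None:
        # the master seed drives the simulation seed unless set explicitly
        if self.simulate.seed == 0 and self.seed != 0:
            self.simulate = dataclasses.replace(self.simulate, seed=self.seed)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(
            f"{self.seed}:{stage}".encode()
        ).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["grid_dims"] = list(d["simulate"]["grid_dims"])
        d["connectivity"]["passband"] = list(d["connectivity"]["passband"])
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output path and verbosity excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("verbosity")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    coerced = dict(block)
    for key in ("grid_dims", "passband"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    return cls(**coerced)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; unknown keys are rejected."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    blocks = {
        "simulate": SimulationConfig,
        "connectivity": ConnectivityParams,
        "sbi": SbiParams,
        "crossmodal": CrossModalParams,
        "secondlevel": SecondLevelParams,
    }
    top_allowed = set(blocks) | {"seed", "out_dir", "verbosity"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for name, cls in blocks.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    for key in ("seed", "out_dir", "verbosity"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)
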