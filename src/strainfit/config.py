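"""Run configuration: one YAML document resolving every stage's settings.

Every pipeline run embeds its resolved configuration in its result
directory, and every stochastic stage draws from a named substream of a
single root seed, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .pso import PSOConfig
from .reduction import ReductionConfig
from .strain_metrics import ObjectiveWeights
from .synthetic_cohort import NoiseConfig
from .toy_model import ToyModelConfig


@dataclass
class MorrisSettings:
    z: int = 8
    trajectory_budget: int = 200
    max_rounds: int = 10


@dataclass
class QmcSettings:
    n: int = 2 ** 14
    n_best: int = 100


@dataclass
class CohortSettings:
    n_subjects: int = 10
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass
class RunConfig:
    registry: str = "demo"          # "demo", "default", or a registry YAML path
    seed: int = 0
    model: ToyModelConfig = field(default_factory=ToyModelConfig)
    cohort: CohortSettings = field(default_factory=CohortSettings)
    morris: MorrisSettings = field(default_factory=MorrisSettings)
    qmc: QmcSettings = field(default_factory=QmcSettings)
    pso: PSOConfig = field(default_factory=PSOConfig)
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)

    def __post_init__(self) -> None:
        # reduction shares the globally configured PSO settings and weights
        self.reduction.pso = self.pso
        self.reduction.weights = self.weights
        self.reduction.qmc_n = self.qmc.n
        self.reduction.n_best = self.qmc.n_best

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream of the root seed for one pipeline stage."""
        import zlib
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def space(self):
        from .param_space import ParameterSpace, build_default_registry, build_demo_registry
        if self.registry == "demo":
            return build_demo_registry()
        if self.registry == "default":
            return build_default_registry()
        return ParameterSpace.from_yaml(self.registry)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["reduction"].pop("pso", None)
        payload["reduction"].pop("weights", None)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        sub = {
            "model": ToyModelConfig, "morris": MorrisSettings, "qmc": QmcSettings,
            "pso": PSOConfig, "reduction": ReductionConfig, "weights": ObjectiveWeights,
        }
        for key, typ in sub.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            c = dict(kwargs["cohort"])
            if isinstance(c.get("noise"), dict):
                c["noise"] = NoiseConfig(**c["noise"])
            kwargs["cohort"] = CohortSettings(**c)
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)
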