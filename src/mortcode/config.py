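"""Run configuration: one serializable object that fully determines a
simulate -> train -> evaluate -> recode experiment given the code version."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .coder import ModelConfig, OptParams
from .oracle import DemographicsSampler, GeneratorParams

__all__ = ["RunConfig", "SimulateParams", "EvalParams", "RecodeParams"]


@dataclass(frozen=True)
class SimulateParams:
    """Corpus size and the per-year stratified exclusion into validation
    and test sets (the remainder of each year goes to training)."""

    n_chapters: int = 20
    codes_per_chapter: int = 10
    certs_per_year: int = 1450
    val_per_year: int = 75
    test_per_year: int = 125


@dataclass(frozen=True)
class EvalParams:
    bootstrap_B: int = 1000
    level: float = 0.95
    ks: tuple[int, ...] = (1, 2)
    n_bins: int = 10


@dataclass(frozen=True)
class RecodeParams:
    fixed_year: int = 2015


@dataclass(frozen=True)
class ModelDefaults:
    """ModelConfig minus the vocabulary size, which is known only after
    simulation."""

    embed_dim: int = 32
    conv_spec: tuple[tuple[int, int, int], ...] = ((3, 3, 64), (3, 3, 128))
    pooling: str = "global_max"
    use_gender: bool = True
    L: int = 6
    W: int = 20
    Y: int = 16

    def to_model_config(self, V: int, seed: int) -> ModelConfig:
        return ModelConfig(
            V=V, embed_dim=self.embed_dim, conv_spec=self.conv_spec,
            pooling=self.pooling, use_gender=self.use_gender,
            L=self.L, W=self.W, Y=self.Y, seed=seed,
        )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulate: SimulateParams = field(default_factory=SimulateParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    sampler: DemographicsSampler = field(default_factory=DemographicsSampler)
    model: ModelDefaults = field(default_factory=ModelDefaults)
    opt: OptParams = field(default_factory=OptParams)
    evaluation: EvalParams = field(default_factory=EvalParams)
    recode: RecodeParams = field(default_factory=RecodeParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub: dict | None, tuple_keys=()):
            sub = dict(sub or {})
            for k in tuple_keys:
                if k in sub:
                    sub[k] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in sub[k]
                    )
            return klass(**sub)

        return cls(
            seed=int(d.get("seed", 0)),
            simulate=build(SimulateParams, d.get("simulate")),
            generator=build(GeneratorParams, d.get("generator"), ("depth_probs",)),
            sampler=build(DemographicsSampler, d.get("sampler")),
            model=build(ModelDefaults, d.get("model"), ("conv_spec",)),
            opt=build(OptParams, d.get("opt")),
            evaluation=build(EvalParams, d.get("evaluation"), ("ks",)),
            recode=build(RecodeParams, d.get("recode")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                json.loads(json.dumps(self.to_dict(), default=list)), fh, sort_keys=False
            )
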