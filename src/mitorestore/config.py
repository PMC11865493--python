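"""Run configuration: nested YAML schema and seed substreams."""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .degradation import DegradationParams
from .nn.loss import SCoPParams
from .nn.train import TrainingConfig
from .nn.unet import NetworkConfig
from .phantom import PhantomConfig
from .sampling import NormalizationParams, SamplingConfig

__all__ = ["RunConfig", "derive_seed"]

CONFIG_VERSION = 1


def derive_seed(root_seed: int, stream: str) -> int:
    """Deterministic per-stage seed from one root seed and a stream name."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stream.encode())) % (2**31)


_SECTIONS = {
    "phantom": PhantomConfig,
    "degradation": DegradationParams,
    "normalization": NormalizationParams,
    "sampling": SamplingConfig,
    "network": NetworkConfig,
    "training": TrainingConfig,
    "loss": SCoPParams,
}


def _build_section(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    # YAML lists for tuple-typed fields
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for the end-to-end pipeline.

    A single global ``seed`` derives all stage seeds through named
    substreams so stages are independently reproducible.
    """

    seed: int = 0
    out_dir: str = "runs/out"
    n_images: int = 24
    n_test_images: int = 6
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    degradation: DegradationParams = field(default_factory=DegradationParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    loss: SCoPParams = field(default_factory=SCoPParams)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def with_derived_seeds(self) -> "RunConfig":
        """Propagate the global seed into every seeded section."""
        return dataclasses.replace(
            self,
            phantom=dataclasses.replace(self.phantom, seed=self.stage_seed("phantom")),
            degradation=dataclasses.replace(self.degradation, seed=self.stage_seed("degrade")),
            sampling=dataclasses.replace(self.sampling, seed=self.stage_seed("sample")),
            network=dataclasses.replace(self.network, seed=self.stage_seed("network")),
            training=dataclasses.replace(self.training, seed=self.stage_seed("train")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        version = data.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {version}")
        kwargs = {}
        for key, value in data.items():
            if key in _SECTIONS:
                kwargs[key] = _build_section(_SECTIONS[key], value or {}, key)
            elif key in {"seed", "out_dir", "n_images", "n_test_images"}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown top-level config key: {key!r}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = CONFIG_VERSION
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
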