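"""Run configuration: documented defaults, YAML loading, strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    scale_factor: float = 1e4      # library-size target before log1p
    n_hvg: int = 2000              # highly variable genes kept
    min_shared_genes: int = 200    # floor on the reference/query gene intersection


@dataclass
class UmapConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1


@dataclass
class DbscanConfig:
    eps: float = 0.5               # on raw UMAP coordinates — scale-sensitive
    min_samples: int = 5


@dataclass
class EmbedConfig:
    n_pcs: int = 50
    backend: str = "center_fallback"  # "harmony" if harmonypy is installed
    seed: int = 0
    umap: UmapConfig = field(default_factory=UmapConfig)
    dbscan: DbscanConfig = field(default_factory=DbscanConfig)


@dataclass
class AnnotateConfig:
    iterations: int = 500
    depth: int = 6
    learning_rate: float = 0.1
    seed: int = 0
    min_gap: float = 1e-6
    confident_op: str = "ge"


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(data, {"preprocess", "embed", "annotate"}, "run config")
        cfg = cls()
        if "preprocess" in data:
            cfg.preprocess = _build(PreprocessConfig, data["preprocess"])
        if "embed" in data:
            e = dict(data["embed"])
            _check_keys(e, {f.name for f in fields(EmbedConfig)}, "embed")
            umap_d = e.pop("umap", None)
            db_d = e.pop("dbscan", None)
            cfg.embed = EmbedConfig(**e)
            if umap_d is not None:
                cfg.embed.umap = _build(UmapConfig, umap_d)
            if db_d is not None:
                cfg.embed.dbscan = _build(DbscanConfig, db_d)
        if "annotate" in data:
            cfg.annotate = _build(AnnotateConfig, data["annotate"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.embed.seed = seed
        cfg.annotate.seed = seed
        return cfg


def _check_keys(data: dict, allowed: set[str], where: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")


def _build(cls, data: dict):
    _check_keys(data, {f.name for f in fields(cls)}, cls.__name__)
    return cls(**data)
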