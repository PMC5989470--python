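"""Run configuration, deterministic seed fan-out, and run manifests.

Every tunable constant of the pipeline lives in :class:`AnalysisConfig` so a
single config file pins an entire analysis.  The defaults target full-scale
organoid/in-vivo benchmarking data: cells are
retained with >= 1000 UMI, >= 400 detected genes and < 8000 UMI, genes when
detected in >= 5 retained cells; variable genes require mean log-normalized
expression > 0.14 and dispersion (variance/mean) > 0.4; clustering uses the
first 12 principal components and an SNN graph with modularity resolution 1.35;
marker genes are reported at ROC-AUC > 0.60 and scored at > 0.65.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["AnalysisConfig", "RunManifest", "load_config", "dump_config", "stage_seed"]


@dataclass
class AnalysisConfig:
    """All pipeline constants, validated on construction.

    Parameters mirror the stages they feed: QC filtering, log-normalization,
    variable-gene selection, PCA, SNN graph construction, modularity
    clustering, and marker/signature derivation.
    """

    scale_factor: float = 10_000.0
    min_umi: int = 1000
    min_genes: int = 400
    max_umi: int = 8000
    min_cells_per_gene: int = 5
    var_mean_cutoff: float = 0.14
    var_dispersion_cutoff: float = 0.4
    n_pcs: int = 12
    zscore_clip: float = 10.0
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.35
    cluster_method: str = "louvain"  # or "leiden"
    marker_auc_report: float = 0.60
    marker_auc_score: float = 0.65
    mito_prefixes: tuple[str, ...] = ("mt-",)
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    score_denominator: str = "lognorm"  # or "scaled_umi"
    equal_var_ttest: bool = False
    dispersion_on_counts: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if not self.min_umi < self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if self.min_genes < 0 or self.min_cells_per_gene < 0:
            raise ValueError("min_genes and min_cells_per_gene must be >= 0")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.snn_k < 1:
            raise ValueError("snn_k must be >= 1")
        if not (0 <= self.snn_prune < 1):
            raise ValueError("snn_prune must lie in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name in ("marker_auc_report", "marker_auc_score"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cluster_method not in ("louvain", "leiden"):
            raise ValueError("cluster_method must be 'louvain' or 'leiden'")
        if self.score_denominator not in ("lognorm", "scaled_umi"):
            raise ValueError("score_denominator must be 'lognorm' or 'scaled_umi'")
        if self.zscore_clip <= 0 or not math.isfinite(self.zscore_clip):
            raise ValueError("zscore_clip must be positive and finite")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        """Build a config from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("mito_prefixes", "ribo_prefixes"):
            if key in d and not isinstance(d[key], (tuple, str)):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mito_prefixes"] = list(self.mito_prefixes)
        d["ribo_prefixes"] = list(self.ribo_prefixes)
        return d

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    An empty file (or ``None``) yields the full defaults.  Unknown keys and
    out-of-range values raise ``ValueError`` naming the offending key.
    """
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return AnalysisConfig()
    if not isinstance(data, dict):
        raise ValueError("config file must contain a key-value mapping")
    return AnalysisConfig.from_dict(data)


def dump_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by stable hashing.

    CRC32 of the stage name xor-folded with the base seed; stable across
    processes and Python versions, and always < 2**31 so downstream RNG APIs
    accept it.
    """
    return (zlib.crc32(stage.encode("utf8")) ^ (base_seed * 0x9E3779B1)) % (2**31)


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a subcommand bit-identically."""

    command: str
    config: dict[str, Any]
    rng_seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    version: str = "0.1.0"
    timestamp: str = ""

    @staticmethod
    def digest(path: str | Path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()

    @classmethod
    def create(
        cls,
        command: str,
        cfg: AnalysisConfig,
        input_paths: dict[str, str | Path] | None = None,
    ) -> "RunManifest":
        inputs = {
            str(name): cls.digest(p) for name, p in (input_paths or {}).items() if Path(p).exists()
        }
        return cls(
            command=command,
            config=cfg.to_dict(),
            rng_seed=cfg.rng_seed,
            inputs=inputs,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
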