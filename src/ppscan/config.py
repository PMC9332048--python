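"""Pipeline configuration: one YAML file with per-module namespaces.

All defaults equal the reference pipeline's constants (membership Z 5.0,
scan Z0 6.0, indel penalty 20, minimum class volume 100, scan window
L1 + 50, overlap fraction 0.10, run caps m0 = {A:13, T:12, C:5, G:5}, GC
band [0.29, 0.37]). Every output file carries a header with the config hash
and master seed; per-stage seeds are derived deterministically from the
master seed and the stage name.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .class_builder import BuildParams, GAParams
from .class_cluster import MatrixAlignmentParams
from .filters import FilterParams
from .genome_scan import ScanConfig
from .synthetic_data import SynthSpec


@dataclass
class PipelineConfig:
    genome: str = "genome.fasta"
    genes: str = "genes.gff3"
    outdir: str = "ppscan_out"
    seed: int = 1
    upstream: int = 500
    downstream: int = 100
    filters: FilterParams = field(default_factory=FilterParams)
    build: BuildParams = field(default_factory=BuildParams)
    scan: ScanConfig = field(default_factory=ScanConfig)
    cluster: MatrixAlignmentParams = field(default_factory=MatrixAlignmentParams)
    synth: SynthSpec = field(default_factory=SynthSpec)
    cluster_cut: float = 0.8

    def derived_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2^31."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(_to_plain(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def header(self, stage: str) -> str:
        return f"ppscan stage={stage} config={self.config_hash()} seed={self.seed}"


def _to_plain(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    # flatten filter m0 into the documented flat keys
    f = d["filters"]
    m0 = f.pop("m0")
    for base, m in m0.items():
        f[f"m0_{base}"] = m
    d["synth"].pop("filter_params", None)
    return d


def _filters_from(d: dict) -> FilterParams:
    return FilterParams.from_dict(d)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load YAML config (missing keys keep defaults); kwargs override."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    cfg = PipelineConfig()
    for key in ("genome", "genes", "outdir", "seed", "upstream", "downstream",
                "cluster_cut"):
        if key in data:
            setattr(cfg, key, data[key])
    if "filters" in data:
        cfg.filters = _filters_from(data["filters"])
    if "build" in data:
        sub = dict(data["build"])
        ga = sub.pop("ga", {})
        cfg.build = BuildParams(**sub, ga=GAParams(**ga))
    if "scan" in data:
        sub = dict(data["scan"])
        if "variants" in sub:
            sub["variants"] = tuple(sub["variants"])
        cfg.scan = ScanConfig(**sub)
    if "cluster" in data:
        cfg.cluster = MatrixAlignmentParams(**data["cluster"])
    if "synth" in data:
        sub = dict(data["synth"])
        for key in ("composition", "class_sizes", "core", "sharpness"):
            if key in sub and isinstance(sub[key], list):
                sub[key] = tuple(sub[key])
        cfg.synth = SynthSpec(**sub)
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
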