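"""Run configuration: every tunable numeric constant of the pipeline.

Defaults are the analysis constants used throughout the package: top 50k
peaks per sample, 250 bp summit half-width, 80th-percentile score filter,
FDR < 0.1 with |log2FC| > log2(1.25) for differential peaks, background
p > 0.1, 2500 GC-matched background peaks over 20 bins, motif scan p <= 1e-4
capped at 500k instances, +/-250 bp footprint window, 10% trimmed mean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    # paths
    genome: str | None = None
    blacklist: str | None = None
    cuts: dict[str, str] = field(default_factory=dict)  # sample -> cut TSV
    peaks: dict[str, str] = field(default_factory=dict)  # sample -> narrowPeak
    pwms: str | None = None
    sample_sheet: str | None = None
    out_dir: str = "results"
    # parameters
    top_k: int = 50_000
    halfwidth: int = 250
    percentile: float = 0.80
    percentile_channel: str = "normalized"
    fdr_max: float = 0.1
    lfc_min: float = float(np.log2(1.25))
    bg_p_min: float = 0.1
    n_background: int = 2500
    gc_bins: int = 20
    scan_p: float = 1e-4
    max_instances: int = 500_000
    footprint_flank: int = 250
    trim: float = 0.10
    seed: int = 0
    window: str = "mid"
    contrast: tuple[str, str, str] = ("source", "BM", "CB")
    covariates: tuple[str, ...] = ("population",)

    def __post_init__(self) -> None:
        if not (0 <= self.percentile < 1):
            raise ValueError("percentile must be in [0, 1)")
        if not (0 < self.scan_p <= 1):
            raise ValueError("scan_p must be in (0, 1]")
        if self.gc_bins < 1 or self.n_background < 1:
            raise ValueError("gc_bins and n_background must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    #: path-like fields excluded from the parameter hash
    _PATH_FIELDS = frozenset(
        {"genome", "blacklist", "cuts", "peaks", "pwms", "sample_sheet", "out_dir"}
    )

    def hash(self) -> str:
        payload = json.dumps(
            {
                k: v
                for k, v in dataclasses.asdict(self).items()
                if k not in self._PATH_FIELDS
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"atacfoot config_hash={self.hash()} seed={self.seed}"
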