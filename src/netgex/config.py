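"""Pipeline configuration: every stage threshold with its study default."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulationParams:
    n_regions: int = 40
    n_group1: int = 40
    n_group2: int = 40
    n_timepoints: int = 150
    sites: list[str] = field(default_factory=lambda: ["siteA", "siteB"])
    network_pairs: list[list[str]] = field(default_factory=lambda: [["SC", "VN"], ["SC", "DAN"]])
    delta: float = 0.3
    n_genes: int = 200
    n_planted_genes: int = 15
    spatial_corr_length: float = 20.0
    n_donors: int = 4
    n_terms: int = 20
    term_size_min: int = 5
    term_size_max: int = 30
    site_offsets: dict = field(default_factory=lambda: {"siteB": 0.1})
    site_scales: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """All stage thresholds (study defaults) plus per-stage seeds and paths."""

    # grouping / inclusion
    hama_cut: int = 18
    fd_max: float = 0.2
    hamd_remission: int = 7
    quality_min: int = 4
    # edge / network statistics
    edge_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    # expression processing
    max_dist_mm: float = 10.0
    probe_min_fraction: float = 0.5
    # PLS
    n_components: int = 5
    n_surrogates: int = 1000
    n_boot: int = 1000
    z_thresh: float = 3.0
    # enrichment
    fdr_alpha: float = 0.05
    min_term: int = 3
    max_term_fraction: float = 0.5
    # harmonization
    protected_covariates: list[str] = field(
        default_factory=lambda: ["hamd", "hama", "age", "sex"]
    )
    glm_covariates: list[str] = field(
        default_factory=lambda: ["sex", "age", "fd", "education"]
    )
    # seeds (one per stochastic stage)
    seeds: dict = field(
        default_factory=lambda: {
            "simulate": 0, "groupdiff": 1, "pls": 2, "surrogates": 3, "bootstrap": 4,
        }
    )
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim:
            cfg.simulation = SimulationParams(
                **{k: v for k, v in sim.items() if k in {f.name for f in dataclasses.fields(SimulationParams)}}
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> dict:
    """Range-check a config; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    for name, lo, hi in [
        ("alpha", 0.0, 1.0),
        ("edge_p", 0.0, 1.0),
        ("fdr_alpha", 0.0, 1.0),
        ("probe_min_fraction", 0.0, 1.0),
        ("max_term_fraction", 0.0, 1.0),
    ]:
        v = getattr(cfg, name)
        if not (lo < v <= hi):
            errors.append(f"{name}={v} outside ({lo}, {hi}]")
    for name in ["fd_max", "max_dist_mm", "z_thresh"]:
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    for name in ["n_perm", "n_surrogates", "n_boot", "n_components"]:
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if cfg.n_perm < 100:
        warnings_.append("n_perm < 100: permutation p-values will be coarse")
    for stage in ["simulate", "groupdiff", "pls", "surrogates", "bootstrap"]:
        if stage not in cfg.seeds:
            warnings_.append(f"missing seed for stage {stage!r}; it will be auto-set")
    return {"errors": errors, "warnings": warnings_, "ok": not errors}
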