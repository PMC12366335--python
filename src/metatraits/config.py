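"""Run configuration: every tunable parameter with a default, YAML in/out.

Unknown keys are rejected with the offending key named, and a parsed
config serializes back to text with identical meaning, so effective
parameters can always be logged and replayed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class SimulateConfig:
    """Synthetic-community generator parameters (the study conditions)."""

    n_genomes: int = 50
    n_samples: int = 18
    n_sites: int = 6
    size_mu: float = float(np.log(4e6))  # median soil genome ~4 Mb
    size_sigma: float = 0.35
    gc_a: float = 30.0  # beta GC model centred near 0.60
    gc_b: float = 20.0
    rrn_max: int = 7
    base_sigma: float = 1.0
    site_sigma: float = 0.3
    sample_sigma: float = 0.2
    group_effect: float = 0.8
    affected_fraction: float = 0.5
    depth_factor: float = 20.0  # mean single-copy coverage per unit abundance
    noise: str = "poisson"
    n_reads: int = 2000  # per-read GC pool size per sample
    gc_jitter_sd: float = 0.05
    n_genes: int = 2000
    reads_per_sample: int = 200_000
    codon_bias: float = 0.3
    n_ribosomal_genes: int = 20
    codons_per_gene: int = 200
    n_votus: int = 200
    p_temperate: float = 0.65
    coupling_model: str = "anti"
    p_decoupled: float = 0.3
    noise_sd: float = 0.2


@dataclass
class AnalysisConfig:
    """Downstream estimator parameters."""

    min_prevalence: float = 0.10
    min_mean_abundance: float = 1e-5
    filter_rule: str = "and"
    min_samples: int = 5  # minimum joint observations for any correlation
    presence_threshold: float = 0.0
    rarefaction_depth: int | None = None  # None = smallest sample total
    n_perm: int = 999
    permanova_scheme: str = "site_exchange"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/default"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at {path!r}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if name in {"simulate", "analysis"}:
            sub_cls = {"simulate": SimulateConfig, "analysis": AnalysisConfig}[name]
            if not isinstance(value, dict):
                raise ValueError(f"config section {path}/{name} must be a mapping")
            kwargs[name] = _build(sub_cls, value, f"{path}/{name}")
        else:
            kwargs[name] = value
    cfg = cls(**kwargs)
    _typecheck(cfg, path)
    return cfg


def _typecheck(cfg, path: str) -> None:
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if dataclasses.is_dataclass(value):
            continue
        if f.name == "rarefaction_depth" and value is None:
            continue
        # structural checks keyed off the default's type
        default = f.default if f.default is not dataclasses.MISSING else None
        if isinstance(default, bool):
            ok = isinstance(value, bool)
        elif isinstance(default, int):
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif isinstance(default, float):
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
            if ok:
                setattr(cfg, f.name, float(value))
        elif isinstance(default, str):
            ok = isinstance(value, str)
        else:
            ok = True
        if not ok:
            raise ValueError(
                f"config key {path}/{f.name} has wrong type "
                f"{type(value).__name__} (expected {type(default).__name__})"
            )


def parse_config(source: str | Path | None = None) -> RunConfig:
    """Parse YAML text or a file path into a validated RunConfig.

    An empty or missing source yields all defaults; unknown keys raise a
    descriptive error naming the key.
    """
    if source is None:
        return RunConfig()
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).suffix in {".yml", ".yaml"}
    ):
        p = Path(source)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        text = p.read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _build(RunConfig, data, "")
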