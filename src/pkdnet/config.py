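"""Run configuration: documented defaults per stage, loaded from YAML.

Unknown keys are hard errors so that typos never silently fall back to
defaults.  Defaults mirror the study's stated parameters where one exists
(detection alpha 0.05, signature thresholds fc 1.2 / q 0.05, metabolite
filter mean 0.1 / q 0.02 / fc 2, annotation tolerance 5 ppm, overlap alpha
0.001); the remaining knobs carry the package's documented defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PreprocessConfig:
    detection_alpha: float = 0.05
    log_offset: float = 1.0
    batch_mode: str = "location_scale_eb"


@dataclass
class DiffexprConfig:
    fc_thresh: float = 1.2
    q_thresh: float = 0.05
    collapse_rule: str = "min_p"


@dataclass
class NetworkConfig:
    beta: int = 6
    signed: bool = False
    min_module_size: int = 30
    cut_height: float | None = None
    rsq_target: float = 0.8
    merge_dissim: float = 0.25
    gene_cap: int = 20000


@dataclass
class ConsensusConfig:
    scale_quantile: float = 0.95
    meta_module_cut: float = 0.5


@dataclass
class MiningConfig:
    overlap_alpha: float = 0.001
    classes: str = "genotype"


@dataclass
class MetabolomicsConfig:
    min_mean: float = 0.1
    q_thresh: float = 0.02
    fc_thresh: float = 2.0
    tol_ppm: float = 5.0
    n_components: int = 2


@dataclass
class SimulateConfig:
    n_background: int = 400
    module_sizes: tuple = (60, 50)
    genotype_effects: tuple = (1.5, 0.0)
    age_effects: tuple = (0.0, 1.0)
    noise_sd: float = 1.0
    samples_per_group: int = 8


@dataclass
class RunConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    diffexpr: DiffexprConfig = field(default_factory=DiffexprConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    metabolomics: MetabolomicsConfig = field(default_factory=MetabolomicsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_STAGES = {f.name: f for f in fields(RunConfig) if f.name != "seed"}


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting any unknown stage or parameter key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig()
    for stage, params in raw.items():
        if stage == "seed":
            cfg.seed = int(params)
            continue
        if stage not in _STAGES:
            raise ValueError(f"unknown config stage {stage!r}")
        sub = getattr(cfg, stage)
        known = {f.name for f in fields(sub)}
        for key, value in (params or {}).items():
            if key not in known:
                raise ValueError(f"unknown config key {stage}.{key}")
            if isinstance(value, list):
                value = tuple(value)
            setattr(sub, key, value)
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
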