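"""Pipeline configuration: flat key-value plain text with one section per
stage.  Unknown sections or keys fail fast, before any computation."""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """All inputs and tunables of the full pipeline.

    Defaults: soft-threshold power 12; minimum module size 30; absent-call
    exclusion above 0.90; detection in at least 6 samples for network genes;
    |R| >= 0.75 for top gene tables; p < 0.05 for differential-expression
    lists; 0.25 impairment-correlation threshold; 0.70 hub threshold;
    2e-5 module flag alpha; outlier rule mean IAC below 2 SD.
    """

    # [inputs]
    expression: str | None = None
    phenotypes: str | None = None
    presence: str | None = None
    probe_map: str | None = None
    gene_sets: str | None = None
    marker_sets: str | None = None
    region: str = "region1"

    # [study2]
    ad_expression: str | None = None
    ad_phenotypes: str | None = None
    second_region_expression: str | None = None
    second_region_phenotypes: str | None = None

    # [preprocess]
    sd_multiplier: float = 2.0
    max_absent_fraction: float = 0.90

    # [network]
    beta: float = 12.0
    min_module_size: int = 30
    cut_height: float = 0.99
    deep_split: bool = True
    min_present_samples: int = 6

    # [stats]
    n_permutations: int = 200

    # [enrichment]
    r_top: float = 0.75
    de_alpha: float = 0.05

    # [crossdisease]
    impair_threshold: float = 0.25
    hub_threshold: float = 0.70
    module_ad_alpha: float = 0.00002

    # [pipeline]
    seed: int = 0
    out_dir: str = "coexnet_out"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        for name in ("max_absent_fraction", "impair_threshold", "hub_threshold",
                     "cut_height"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.de_alpha <= 1.0:
            raise ValueError("de_alpha must lie in (0, 1]")
        if not 0.0 < self.module_ad_alpha <= 1.0:
            raise ValueError("module_ad_alpha must lie in (0, 1]")
        if self.r_top < 0.0 or self.r_top > 1.0:
            raise ValueError("r_top must lie in [0, 1]")
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")


_SECTIONS: dict[str, tuple[str, ...]] = {
    "inputs": ("expression", "phenotypes", "presence", "probe_map",
               "gene_sets", "marker_sets", "region"),
    "study2": ("ad_expression", "ad_phenotypes",
               "second_region_expression", "second_region_phenotypes"),
    "preprocess": ("sd_multiplier", "max_absent_fraction"),
    "network": ("beta", "min_module_size", "cut_height", "deep_split",
                "min_present_samples"),
    "stats": ("n_permutations",),
    "enrichment": ("r_top", "de_alpha"),
    "crossdisease": ("impair_threshold", "hub_threshold", "module_ad_alpha"),
    "pipeline": ("seed", "out_dir"),
}

_INT_FIELDS = {"min_module_size", "min_present_samples", "n_permutations", "seed"}
_FLOAT_FIELDS = {
    "sd_multiplier", "max_absent_fraction", "beta", "cut_height", "r_top",
    "de_alpha", "impair_threshold", "hub_threshold", "module_ad_alpha",
}
_BOOL_FIELDS = {"deep_split"}


def load_config(path) -> PipelineConfig:
    """Parse an INI-style config file; unknown sections/keys are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    parser.read(path)
    kwargs: dict = {}
    for section in parser.sections():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        allowed = _SECTIONS[section]
        for key, raw in parser.items(section):
            if key not in allowed:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            if key in _INT_FIELDS:
                kwargs[key] = int(raw)
            elif key in _FLOAT_FIELDS:
                kwargs[key] = float(raw)
            elif key in _BOOL_FIELDS:
                kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = raw
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    return {f.name: getattr(config, f.name) for f in fields(config)}
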