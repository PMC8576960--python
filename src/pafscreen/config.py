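"""Pipeline configuration.

A single document aggregating every tunable of the pipeline, with documented
defaults, loadable from YAML.  Unknown keys are rejected so that typos in a
config file fail loudly.  All randomness flows from ``seed``; stage-level
seeds are derived from it deterministically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # --- delineation ---
    p_search_window_ms: tuple[float, float] = (250.0, 60.0)
    min_p_amplitude: float = 0.02  # mV

    # --- HTGA Gaussian fit ---
    htga_population_size: int = 50
    htga_generations: int = 100
    htga_crossover_rate: float = 0.8
    htga_mutation_rate: float = 0.1
    max_fitted_beats: int = 30  # evenly spaced subsample of beats per subject

    # --- HRV ---
    pnn50_denominator: str = "pairs"  # or "intervals"
    histogram_bin_width_ms: float = 1000.0 / 128.0
    resample_fs: float = 4.0
    welch_nperseg: int = 256
    welch_overlap: float = 0.5
    ar_order: int = 16
    spectral_estimator: str = "welch"  # estimator feeding the feature table
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    dfa_short_range: tuple[int, ...] = tuple(range(4, 17))
    dfa_long_range: tuple[int, ...] = tuple(range(16, 65))

    # --- ensemble ---
    n_members: int = 100
    complexity_parameter: float = 0.1
    layer1_methods: tuple[str, ...] = ("bagging", "adaboost")
    stacking_oof_folds: int = 5
    stacking_naive: bool = False  # True: meta trained on in-sample layer-1 scores
    retry_budget: int = 50

    # --- evaluation ---
    cv_folds: int = 10

    # --- global ---
    seed: int = 0

    def __post_init__(self):
        if self.pnn50_denominator not in ("pairs", "intervals"):
            raise ConfigurationError("pnn50_denominator must be 'pairs' or 'intervals'")
        if self.spectral_estimator not in ("welch", "ar"):
            raise ConfigurationError("spectral_estimator must be 'welch' or 'ar'")
        if self.complexity_parameter <= 0:
            raise ConfigurationError("complexity_parameter must be positive")
        if self.n_members < 1 or self.cv_folds < 2:
            raise ConfigurationError("n_members >= 1 and cv_folds >= 2 required")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path: str) -> None:
        doc = dataclasses.asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


_TUPLE_FIELDS = {"p_search_window_ms", "layer1_methods", "dfa_short_range", "dfa_long_range"}


def load_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from YAML, rejecting unknown keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(doc):
        doc[k] = tuple(doc[k])
    return PipelineConfig(**doc)
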