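"""Analysis configuration: thresholds, permutation counts and seeding.

All tunable constants of the pipeline live in one dataclass so that a run
is fully described by (input files, config, seed).  Child RNGs for the
individual stages are derived deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .exceptions import ConfigError

__all__ = ["AnalysisConfig", "stage_rng", "stage_seed"]


@dataclass
class AnalysisConfig:
    """All thresholds and permutation counts used by the pipeline."""

    seed: int = 0
    #: channel permutations for the proteomic empirical null
    n_perm_proteome: int = 100
    #: label resamplings for the transcriptomic empirical null
    n_perm_transcriptome: int = 1000
    #: sample permutations for the fold-change correlation null
    n_perm_correlation: int = 5000
    alpha_dep: float = 0.05
    alpha_deg: float = 0.05
    alpha_deg_strict: float = 0.01
    #: peptides require isolation purity strictly above this fraction
    purity_min: float = 0.75
    #: percentile of the max-log2-intensity distribution; peptides below are dropped
    intensity_percentile: float = 5.0
    lmr_percentiles_dep: tuple[float, float] = (5.0, 95.0)
    lmr_percentiles_deg: tuple[float, float] = (2.5, 97.5)
    lmr_percentiles_yeast: tuple[float, float] = (5.0, 95.0)
    nmf_k: int = 100
    nmf_top: int = 10
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-5
    n_perm_nmf: int = 1000
    cluster_p: float = 0.01
    enrich_p: float = 0.1
    enrich_min_genes: int = 5
    dice_min_shared: int = 3
    dice_cutoff: Union[float, str] = 0.4  # a fraction, or "auto"

    def __post_init__(self) -> None:
        self.lmr_percentiles_dep = tuple(self.lmr_percentiles_dep)
        self.lmr_percentiles_deg = tuple(self.lmr_percentiles_deg)
        self.lmr_percentiles_yeast = tuple(self.lmr_percentiles_yeast)
        self.validate()

    def validate(self) -> None:
        for name in ("alpha_dep", "alpha_deg", "alpha_deg_strict", "cluster_p",
                     "enrich_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        if not (0.0 < self.purity_min < 1.0):
            raise ConfigError(f"purity_min must lie in (0, 1), got {self.purity_min!r}")
        for name in ("lmr_percentiles_dep", "lmr_percentiles_deg",
                     "lmr_percentiles_yeast"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 100.0):
                raise ConfigError(f"{name} must be a strictly ordered percentile "
                                  f"pair in [0, 100], got {(lo, hi)!r}")
        for name in ("n_perm_proteome", "n_perm_transcriptome",
                     "n_perm_correlation", "n_perm_nmf", "nmf_k", "nmf_top",
                     "nmf_max_iter", "enrich_min_genes", "dice_min_shared"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not (0.0 <= self.intensity_percentile <= 100.0):
            raise ConfigError("intensity_percentile must lie in [0, 100]")
        if isinstance(self.dice_cutoff, str):
            if self.dice_cutoff != "auto":
                raise ConfigError('dice_cutoff must be a fraction or "auto"')
        elif not (0.0 <= self.dice_cutoff <= 1.0):
            raise ConfigError("dice_cutoff must lie in [0, 1]")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("lmr_percentiles_dep", "lmr_percentiles_deg",
                    "lmr_percentiles_yeast"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
               .generate_state(1)[0])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))
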