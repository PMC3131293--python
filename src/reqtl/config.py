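"""Run configuration shared across the mapping modules.

A :class:`RunConfig` collects the knobs that every analysis step reads:
the cis-window width, the minor-allele-frequency floor, the effect-size
prior grid for the Bayes-factor engine, EM convergence settings, the
permutation count and master seed, and the posterior-probability
threshold used to call interactions.  It can be loaded from a YAML file
and overridden field-by-field (the CLI maps flags onto fields; a flag
wins over the file).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Default grid of prior standard deviations for the per-condition
#: genotype effect, in units of the pooled phenotype sd.  The grid is
#: deliberately restricted to effect scales detectable at panel sizes of
#: ~100 individuals: mixture components whose prior sd falls below the
#: sampling standard error of the genotype slope are statistically
#: indistinguishable from the null and render the genome-wide model
#: proportions unidentifiable.
DEFAULT_PRIOR_SD_GRID: tuple[float, ...] = (0.8, 1.6)


@dataclass
class RunConfig:
    cis_window_bp: int = 100_000
    maf_min: float = 0.0
    prior_sd_grid: tuple[float, ...] = DEFAULT_PRIOR_SD_GRID
    em_tolerance: float = 1e-6
    em_max_iter: int = 10_000
    n_permutations: int = 100
    seed: int = 0
    posterior_threshold: float = 0.7

    def __post_init__(self) -> None:
        self.prior_sd_grid = tuple(float(s) for s in self.prior_sd_grid)
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")
        if not all(s > 0 for s in self.prior_sd_grid):
            raise ValueError("prior_sd_grid values must be strictly positive")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior_sd_grid"] = list(self.prior_sd_grid)
        return d

    def write_manifest(self, path: str | Path, **extra) -> None:
        """Write a JSON run manifest (config, seed, package version)."""
        from . import __version__

        manifest = {"config": self.to_dict(), "version": __version__}
        manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
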