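"""Run configuration: a flat TOML file, CLI overrides, provenance hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field

from .derivation import DerivationConfig
from .fluctuations import DistanceBinning

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline command needs, serialisable for provenance."""

    input_dir: str = "."
    output_dir: str = "out"
    min_models: int = 20
    min_residues: int = 50
    break_cutoff: float = 4.5
    trim_tails: bool = True
    bin_width: float = 0.5
    profile_d_min: float = 3.0
    profile_d_max: float = 25.0
    table_d_max: float = 15.0
    n0: float = 500.0
    iterations: int | None = None        # None: mode default
    cull_threshold: float = 1e-3
    bootstrap: int = 0                   # 0: point estimate only
    ci_level: float = 0.90
    seed: int = 0
    kBT: float = 1.0
    log_level: str = "INFO"

    def profile_binning(self) -> DistanceBinning:
        return DistanceBinning(self.bin_width, self.profile_d_min,
                               self.profile_d_max)

    def table_binning(self) -> DistanceBinning:
        return DistanceBinning(self.bin_width, self.profile_d_min,
                               self.table_d_max)

    def derivation_config(self, mode: str) -> DerivationConfig:
        overrides = dict(n0=self.n0, cull_threshold=self.cull_threshold,
                         ci_level=self.ci_level, seed=self.seed)
        if self.bootstrap:
            overrides["bootstrap_replicates"] = self.bootstrap
        if self.iterations is not None:
            overrides.update(max_iterations=self.iterations,
                             selection_iteration=self.iterations)
        return DerivationConfig.for_mode(mode, **overrides)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_comments(self) -> list[str]:
        return [f"config_hash: {self.hash}",
                f"config: {json.dumps(self.as_dict(), sort_keys=True)}"]


def load_config(path=None, **overrides) -> RunConfig:
    """Load a TOML config file; unknown keys are rejected, overrides win."""
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config overrides: {sorted(unknown)}")
    return RunConfig(**values)
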