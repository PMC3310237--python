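"""Pipeline configuration: every threshold in one validated record.

The config file format is flat ``key = value`` text with optional
``[section]`` headers (sections only organise the file; keys are
global).  Values on the command line override file values.  The
defaults are the constants the discovery criteria are defined with:
inverted repeats >= 100 bp at >= 80% identity; scanned TIRs >= 50 bp;
element span <= 20 kb; tandem partners < 600 bp apart; external
truncation <= 15 bp; 9-11 bp TSD with <= 2 mismatches; 80%/80%
library redundancy; > 70% alignable internal sequence for copy calls;
700 bp / 5 nt conservation windows; 1000 bootstrap replicates at a 40%
consensus; 100 bp size bins up to 2 kb.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Invalid configuration value or file."""


PAPER_DEFAULTS = dict(
    min_ir_len=100,
    min_ir_identity=80.0,
    ir_seed_k=12,
    min_tir_len=50,
    min_scan_identity=80.0,
    scan_seed_k=10,
    max_span=20000,
    tandem_window=600,
    max_ext_truncation=15,
    tsd_len_min=9,
    tsd_len_max=11,
    tsd_max_mismatch=2,
    redundancy_identity=80.0,
    redundancy_cover=0.80,
    copy_internal_fraction=0.70,
    conservation_first_n=700,
    conservation_window=5,
    bootstrap_reps=1000,
    consensus_threshold=0.40,
    size_bin=100,
    size_max=2000,
)


@dataclass
class PipelineConfig:
    """All tunable thresholds plus run inputs/outputs and the seed."""

    # inverted-repeat discovery
    min_ir_len: int = 100
    min_ir_identity: float = 80.0
    ir_seed_k: int = 12
    # genome scan
    min_tir_len: int = 50
    min_scan_identity: float = 80.0
    scan_seed_k: int = 10
    # multi-TIR filters
    max_span: int = 20000
    tandem_window: int = 600
    max_ext_truncation: int = 15
    tsd_len_min: int = 9
    tsd_len_max: int = 11
    tsd_max_mismatch: int = 2
    # library redundancy
    redundancy_identity: float = 80.0
    redundancy_cover: float = 0.80
    # copy grouping
    copy_internal_fraction: float = 0.70
    # conservation
    conservation_first_n: int = 700
    conservation_window: int = 5
    # phylogeny
    bootstrap_reps: int = 1000
    consensus_threshold: float = 0.40
    # size distribution
    size_bin: int = 100
    size_max: int = 2000
    # run control
    seed: int = 0
    simulate: bool = True
    genome_length: int = 300000
    genome_gc: float = 0.42
    # file paths (optional inputs)
    genome_fasta: str = ""
    repeat_fasta: str = ""
    transposase_fasta: str = ""
    cargo_fasta: str = ""
    out_dir: str = "mulefinder_out"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        positive = [
            "min_ir_len", "ir_seed_k", "min_tir_len", "scan_seed_k",
            "max_span", "tandem_window", "tsd_len_min", "tsd_len_max",
            "conservation_first_n", "conservation_window",
            "bootstrap_reps", "size_bin", "size_max", "genome_length",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("min_ir_identity", "min_scan_identity", "redundancy_identity"):
            if not 0 < getattr(self, name) <= 100:
                raise ConfigError(f"{name} must be in (0, 100]")
        for name in (
            "redundancy_cover", "copy_internal_fraction",
            "consensus_threshold", "genome_gc",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.tsd_len_min > self.tsd_len_max:
            raise ConfigError("tsd_len_min must be <= tsd_len_max")
        if self.max_ext_truncation < 0 or self.tsd_max_mismatch < 0:
            raise ConfigError("truncation/mismatch limits must be >= 0")
        if self.min_ir_len < self.ir_seed_k:
            raise ConfigError("min_ir_len must be >= ir_seed_k")

    @property
    def tsd_len_range(self) -> tuple[int, int]:
        return (self.tsd_len_min, self.tsd_len_max)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def paper_defaults(cls, **overrides) -> "PipelineConfig":
        """Config with every threshold at its published default."""
        return cls(**{**PAPER_DEFAULTS, **overrides})


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, raw: str):
    typ = _FIELD_TYPES[name]
    raw = raw.strip()
    if typ == "bool":
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"cannot parse boolean {name} = {raw!r}")
    if typ == "int":
        return int(raw)
    if typ == "float":
        return float(raw)
    return raw


def read_config(path) -> PipelineConfig:
    """Parse a flat key = value config file into a PipelineConfig."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line or (line.startswith("[") and line.endswith("]")):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key = value, got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ConfigError(f"{path}:{lineno}: unknown option {key!r}")
        values[key] = _coerce(key, raw)
    return PipelineConfig(**values)


def write_config(cfg: PipelineConfig, path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")
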