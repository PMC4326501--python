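"""Pipeline configuration.

A single typed object holds every threshold used across the pipeline:
read-quality gating, adaptor/length/3'-trim rules, alignment mismatch
policy, the sequencing-error null of the editing test, and the
selection cutoffs of the expression and array analyses.  Defaults are
the values used throughout the analysis this package reproduces.

The on-disk representation is a flat ``key = value`` text file; a file
that omits a key falls back to the default for that key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Raised for invalid configuration values or files."""


@dataclass(frozen=True)
class PipelineConfig:
    #: reads with more than ``max_low_quality_positions`` bases below this
    #: phred score are discarded
    quality_threshold: int = 20
    max_low_quality_positions: int = 3
    #: post-adaptor length gate, inclusive bounds
    min_read_length: int = 15
    max_read_length: int = 28
    #: bases removed from the 3' end before alignment (non-templated tailing)
    three_prime_trim: int = 2
    #: alignment: at most this many mismatches, each with phred >= the minimum
    mismatch_quality_min: int = 30
    max_mismatches: int = 1
    #: largest tolerated 5' offset of a read within its reference (isomiR wobble)
    max_five_prime_offset: int = 3
    #: per-base error null for the binomial overrepresentation test
    sequencing_error_rate: float = 0.001
    #: family-wise alpha for editing-site calls
    editing_alpha: float = 0.05
    #: multiple-testing correction for site calls: "off" | "bonferroni" | "bh"
    editing_correction: str = "bonferroni"
    #: sites with coverage below this are reported ND (not determined)
    nd_min_reads: int = 10
    #: expression selection: sum of normalized counts must exceed this (strict)
    expr_min_sum_reads: int = 200
    expr_log2_cutoff: float = 0.5
    #: "highly expressed" subset: sum of counts at least this (inclusive)
    high_expr_min_sum: int = 10000
    expr_alpha: float = 0.05
    array_fdr_cutoff: float = 0.2
    array_log2_cutoff: float = 0.5
    #: 1-based closed seed interval on the mature miRNA
    seed_start: int = 2
    seed_end: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "sequencing_error_rate": self.sequencing_error_rate,
            "editing_alpha": self.editing_alpha,
            "expr_alpha": self.expr_alpha,
            "array_fdr_cutoff": self.array_fdr_cutoff,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "quality_threshold": self.quality_threshold,
            "max_low_quality_positions": self.max_low_quality_positions,
            "min_read_length": self.min_read_length,
            "max_read_length": self.max_read_length,
            "three_prime_trim": self.three_prime_trim,
            "mismatch_quality_min": self.mismatch_quality_min,
            "max_mismatches": self.max_mismatches,
            "max_five_prime_offset": self.max_five_prime_offset,
            "nd_min_reads": self.nd_min_reads,
            "expr_min_sum_reads": self.expr_min_sum_reads,
            "high_expr_min_sum": self.high_expr_min_sum,
        }
        for name, c in counts.items():
            if c < 0:
                raise ConfigError(f"{name} must be non-negative, got {c}")
        if self.min_read_length > self.max_read_length:
            raise ConfigError("min_read_length must not exceed max_read_length")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ConfigError("seed interval must satisfy 1 <= seed_start <= seed_end")
        if self.editing_correction not in ("off", "bonferroni", "bh"):
            raise ConfigError(
                f"editing_correction must be off|bonferroni|bh, got {self.editing_correction!r}"
            )

    @property
    def seed_span(self) -> tuple[int, int]:
        """1-based closed seed interval (start, end)."""
        return (self.seed_start, self.seed_end)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, Any] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(key, value, lineno, path)
        return cls(**kwargs)


def _coerce(key: str, value: str, lineno: int, path: str | Path) -> Any:
    target = PipelineConfig.__dataclass_fields__[key].default
    try:
        if isinstance(target, bool):
            return value.lower() in ("1", "true", "yes")
        if isinstance(target, int):
            return int(value)
        if isinstance(target, float):
            return float(value)
        return value
    except ValueError as exc:
        raise ConfigError(f"{path}:{lineno}: cannot parse {key} = {value!r}") from exc
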