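"""Read cleaning, applied in a fixed order.

1. quality gate — drop a read if more than ``max_low_quality_positions``
   bases fall strictly below ``quality_threshold`` (phred 20);
2. 3' (and optionally 5') adaptor removal;
3. length gate on the post-adaptor insert — keep 15-28 nt inclusive
   (the removal rules are strict inequalities);
4. trim the last two bases, which carry non-templated 3' modifications.

Boundary semantics are deliberate and tested: exactly three low-quality
positions is kept, four are dropped; inserts of exactly 15 or 28 nt pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .config import PipelineConfig
from .io import SequencedRead


@dataclass
class PreprocessStats:
    """Per-rule drop counters; ``dropped + retained == n_input`` always."""

    n_input: int = 0
    dropped_quality: int = 0
    dropped_length: int = 0
    dropped_short_for_trim: int = 0
    no_adaptor: int = 0  # flagged, not dropped (the length gate handles them)
    retained: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_quality + self.dropped_length + self.dropped_short_for_trim

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "dropped_quality": self.dropped_quality,
            "dropped_length": self.dropped_length,
            "dropped_short_for_trim": self.dropped_short_for_trim,
            "no_adaptor": self.no_adaptor,
            "retained": self.retained,
        }


def quality_filter(read: SequencedRead, cfg: PipelineConfig) -> bool:
    """True iff the read passes: at most ``max_low_quality_positions``
    bases strictly below the quality threshold."""
    n_low = sum(1 for q in read.quals if q < cfg.quality_threshold)
    return n_low <= cfg.max_low_quality_positions


def trim_adaptor(
    read: SequencedRead,
    adaptor3: str,
    adaptor5: str | None = None,
    min_overlap: int = 8,
) -> tuple[SequencedRead, bool]:
    """Remove the 3' (and optionally 5') adaptor; returns (read, found).

    The longest read suffix matching a prefix of ``adaptor3`` is removed,
    requiring at least ``min_overlap`` nt of overlap and tolerating one
    mismatch per 8 nt of overlap.  When the full adaptor is contained in
    the read, everything from its start onward is removed.  A read with no
    acceptable match is returned unchanged with ``found=False``.
    """
    if len(adaptor3) < min_overlap:
        raise ValueError(f"adaptor3 must be at least {min_overlap} nt")
    bases, quals, found3 = _trim3(read.bases, read.quals, adaptor3, min_overlap)
    found5 = True
    if adaptor5 is not None:
        if len(adaptor5) < min_overlap:
            raise ValueError(f"adaptor5 must be at least {min_overlap} nt")
        # symmetric rule on the reversed strings
        rb, rq, found5 = _trim3(
            bases[::-1], quals[::-1], adaptor5[::-1], min_overlap
        )
        bases, quals = rb[::-1], rq[::-1]
    return SequencedRead(read.id, bases, quals), found3 and found5


def _trim3(
    bases: str, quals: tuple[int, ...], adaptor: str, min_overlap: int
) -> tuple[str, tuple[int, ...], bool]:
    n = len(bases)
    for start in range(0, n - min_overlap + 1):  # longest suffix first
        overlap = min(n - start, len(adaptor))
        allowed = overlap // 8
        mismatches = 0
        ok = True
        for k in range(overlap):
            if bases[start + k] != adaptor[k]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return bases[:start], quals[:start], True
    return bases, quals, False


def length_filter(read: SequencedRead, cfg: PipelineConfig) -> bool:
    """True iff min_read_length <= len <= max_read_length (inclusive)."""
    return cfg.min_read_length <= len(read) <= cfg.max_read_length


def trim_three_prime(read: SequencedRead, cfg: PipelineConfig) -> SequencedRead:
    """Remove the final ``three_prime_trim`` bases and their qualities."""
    t = cfg.three_prime_trim
    if t == 0:
        return read
    if len(read) <= t:
        raise ValueError(f"{read.id}: read of {len(read)} nt cannot lose {t} bases")
    return SequencedRead(read.id, read.bases[:-t], read.quals[:-t])


def preprocess_stream(
    reads: Iterable[SequencedRead],
    cfg: PipelineConfig,
    adaptor3: str,
    adaptor5: str | None = None,
) -> tuple[list[SequencedRead], PreprocessStats]:
    """Apply quality -> adaptor -> length -> 3'-trim; conserve totals."""
    stats = PreprocessStats()
    out: list[SequencedRead] = []
    for read in reads:
        stats.n_input += 1
        if not quality_filter(read, cfg):
            stats.dropped_quality += 1
            continue
        trimmed, found = trim_adaptor(read, adaptor3, adaptor5)
        if not found:
            stats.no_adaptor += 1
        if not length_filter(trimmed, cfg):
            stats.dropped_length += 1
            continue
        if len(trimmed) <= cfg.three_prime_trim:
            stats.dropped_short_for_trim += 1
            continue
        out.append(trim_three_prime(trimmed, cfg))
        stats.retained += 1
    return out, stats
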