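"""Editing-site calling from position tallies.

Every reference position is screened for overrepresented mismatches:
for each alternate base observed there, the upper tail of
Binomial(coverage, error_rate) at the observed alternate count gives the
probability of seeing that many mismatches from sequencing error alone
(0.1% per base after phred-30 gating).  The test is one-sided — editing
can only inflate the mismatch count — and each alternate base is tested
against the full error rate, which is conservative.

Calls at coverage below ``nd_min_reads`` are reported ND (not
determined) regardless of p-value.  The editing level is the percentage
alt/(ref + alt), the same denominator as the Sanger peak-ratio
definition; bases other than the reference and alternate are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import NUCLEOTIDES, MiRNAReference
from .align import PositionTally

STATUS_SIGNIFICANT = "significant"
STATUS_NOT_SIGNIFICANT = "not_significant"
STATUS_ND = "ND"


@dataclass(frozen=True)
class EditingSiteCall:
    ref_id: str
    position: int  # 1-based on the reference
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    coverage: int
    editing_level: float  # percentage, 100 * n_alt / (n_ref + n_alt)
    p_value: float  # raw upper-tail binomial p
    p_adjusted: float
    status: str  # significant | not_significant | ND
    in_seed: bool
    is_AtoG: bool
    label: str | None = None  # signed anchor-relative label (amplicon mode)

    def __post_init__(self) -> None:
        if not 0.0 <= self.editing_level <= 100.0:
            raise ValueError("editing_level must lie in [0, 100]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class ContextProfile:
    """Nucleotide frequencies immediately up- and downstream of calls."""

    upstream: Mapping[str, float]
    downstream: Mapping[str, float]
    n_sites: int


def binomial_site_pvalue(n_alt: int, n_total: int, error_rate: float) -> float:
    """Upper-tail P(X >= n_alt) for X ~ Binomial(n_total, error_rate).

    Computed through the survival function, numerically stable for large
    totals; the floor avoids returning exactly zero for extreme counts.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must lie in (0, 1), got {error_rate}")
    if not 0 <= n_alt <= n_total:
        raise ValueError(f"need 0 <= n_alt <= n_total, got {n_alt}/{n_total}")
    if n_alt == 0:
        return 1.0
    p = float(stats.binom.sf(n_alt - 1, n_total, error_rate))
    if p > 0.0:
        return min(p, 1.0)
    # below double-precision underflow: log-space bound via the largest term
    logp = stats.binom.logpmf(n_alt, n_total, error_rate)
    return float(max(math.exp(max(logp, -745.0)), 5e-324))


def _raw_calls(
    tally: PositionTally, ref: MiRNAReference, cfg: PipelineConfig
) -> list[EditingSiteCall]:
    if tally.counts.shape[0] != len(ref):
        raise ValueError(f"tally length {tally.counts.shape[0]} != |{ref.id}| {len(ref)}")
    seed_lo, seed_hi = ref.seed_span if ref.seed_span else (cfg.seed_start, cfg.seed_end)
    calls: list[EditingSiteCall] = []
    cov = tally.coverage
    for pos in range(len(ref)):
        ref_base = ref.sequence[pos]
        n_total = int(cov[pos])
        if n_total == 0:
            continue
        n_ref = tally.count(pos, ref_base)
        for alt in NUCLEOTIDES:
            if alt == ref_base:
                continue
            n_alt = tally.count(pos, alt)
            if n_alt == 0:
                continue
            p = binomial_site_pvalue(n_alt, n_total, cfg.sequencing_error_rate)
            level = 100.0 * n_alt / (n_ref + n_alt)
            calls.append(
                EditingSiteCall(
                    ref_id=ref.id,
                    position=pos + 1,
                    ref_base=ref_base,
                    alt_base=alt,
                    n_ref=n_ref,
                    n_alt=n_alt,
                    coverage=n_total,
                    editing_level=level,
                    p_value=p,
                    p_adjusted=p,  # adjusted below
                    status=STATUS_NOT_SIGNIFICANT,
                    in_seed=seed_lo <= pos + 1 <= seed_hi,
                    is_AtoG=(ref_base == "A" and alt == "G"),
                )
            )
    return calls


def _adjust_and_flag(
    calls: list[EditingSiteCall], cfg: PipelineConfig, n_tests: int
) -> list[EditingSiteCall]:
    if cfg.editing_correction == "bh":
        from .auxstats import bh_fdr

        adj = bh_fdr([c.p_value for c in calls]) if calls else []
    elif cfg.editing_correction == "bonferroni":
        adj = [min(1.0, c.p_value * max(n_tests, 1)) for c in calls]
    else:
        adj = [c.p_value for c in calls]
    out = []
    for c, pa in zip(calls, adj):
        if c.coverage < cfg.nd_min_reads:
            status = STATUS_ND
        elif pa < cfg.editing_alpha:
            status = STATUS_SIGNIFICANT
        else:
            status = STATUS_NOT_SIGNIFICANT
        out.append(replace(c, p_adjusted=pa, status=status))
    return out


def call_sites(
    tally: PositionTally,
    ref: MiRNAReference,
    cfg: PipelineConfig,
    n_tests: int | None = None,
) -> list[EditingSiteCall]:
    """Calls for one reference.  ``n_tests`` overrides the multiple-testing
    family size when correction spans a whole sample (see
    :func:`call_sample`)."""
    calls = _raw_calls(tally, ref, cfg)
    return _adjust_and_flag(calls, cfg, n_tests if n_tests is not None else len(calls))


def call_sample(
    tallies: Mapping[str, PositionTally],
    refs: Sequence[MiRNAReference],
    cfg: PipelineConfig,
) -> list[EditingSiteCall]:
    """Calls across a whole sample, corrected over every (position x
    alternate base) test performed in the sample."""
    by_id = {r.id: r for r in refs}
    raw: list[EditingSiteCall] = []
    for rid, t in tallies.items():
        if rid not in by_id:
            raise ValueError(f"tally for unknown reference {rid!r}")
        raw.extend(_raw_calls(t, by_id[rid], cfg))
    return _adjust_and_flag(raw, cfg, len(raw))


def compare_conditions(
    calls_by_sample: Mapping[str, Sequence[EditingSiteCall]],
    cfg: PipelineConfig,
    active: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Cross-sample comparison: one row per site observed in any sample.

    Per sample the editing level (percent) or missing (no coverage / ND)
    plus a significance flag.  When ``active`` and ``control`` name an
    active-enzyme sample and its catalytically dead control, sites
    significant in the former but not the latter are flagged
    ``enzyme_specific``.
    """
    samples = list(calls_by_sample)
    index: dict[tuple, dict] = {}
    for sample, calls in calls_by_sample.items():
        for c in calls:
            key = (c.ref_id, c.position, c.ref_base, c.alt_base)
            row = index.setdefault(
                key,
                {
                    "ref_id": c.ref_id,
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "alt_base": c.alt_base,
                    "in_seed": c.in_seed,
                    "is_AtoG": c.is_AtoG,
                },
            )
            if row["ref_base"] != c.ref_base:
                raise ValueError(
                    f"inconsistent reference base at {c.ref_id}:{c.position} across samples"
                )
            level = None if c.status == STATUS_ND else c.editing_level
            row[f"{sample}_level"] = level
            row[f"{sample}_status"] = c.status
            row[f"{sample}_p"] = c.p_adjusted
    rows = []
    for key in sorted(index):
        row = index[key]
        for s in samples:
            row.setdefault(f"{s}_level", None)
            row.setdefault(f"{s}_status", STATUS_ND)
            row.setdefault(f"{s}_p", None)
        if active is not None and control is not None:
            row["enzyme_specific"] = (
                row[f"{active}_status"] == STATUS_SIGNIFICANT
                and row[f"{control}_status"] != STATUS_SIGNIFICANT
            )
        rows.append(row)
    return pd.DataFrame(rows)


def context_profile(
    calls: Sequence[EditingSiteCall], refs: Sequence[MiRNAReference]
) -> ContextProfile:
    """Neighbor nucleotide frequencies around called sites, computed on the
    reference sequence; boundary sites are excluded from the missing side."""
    if not calls:
        raise ValueError("context_profile requires at least one call")
    by_id = {r.id: r for r in refs}
    up: dict[str, int] = {b: 0 for b in NUCLEOTIDES}
    down: dict[str, int] = {b: 0 for b in NUCLEOTIDES}
    n_up = n_down = 0
    for c in calls:
        seq = by_id[c.ref_id].sequence
        i = c.position - 1
        if i - 1 >= 0:
            up[seq[i - 1]] += 1
            n_up += 1
        if i + 1 < len(seq):
            down[seq[i + 1]] += 1
            n_down += 1
    return ContextProfile(
        upstream={b: (v / n_up if n_up else 0.0) for b, v in up.items()},
        downstream={b: (v / n_down if n_down else 0.0) for b, v in down.items()},
        n_sites=len(calls),
    )


def amplicon_editing(
    tally: PositionTally,
    ref: MiRNAReference,
    cfg: PipelineConfig,
    anchor: int,
    n_tests: int | None = None,
) -> list[EditingSiteCall]:
    """A->G editing along a precursor amplicon, with signed anchor-relative
    labels: the anchor base is +1, the base before it is -1; there is no
    position zero."""
    if not 1 <= anchor <= len(ref):
        raise ValueError(f"anchor {anchor} outside {ref.id} (1..{len(ref)})")
    calls = call_sites(tally, ref, cfg, n_tests=n_tests)
    out = []
    for c in calls:
        if not c.is_AtoG:
            continue
        delta = c.position - anchor
        label = f"+{delta + 1}" if delta >= 0 else str(delta)
        out.append(replace(c, label=label))
    return out


def calls_to_report_rows(calls: Sequence[EditingSiteCall]) -> list[dict]:
    """Rows for :func:`editkit.io.write_report`; ND sites report no level."""
    rows = []
    for c in calls:
        rows.append(
            {
                "ref_id": c.ref_id,
                "position": c.position,
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                "coverage": c.coverage,
                "editing_level_pct": None if c.status == STATUS_ND else c.editing_level,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "status": c.status,
                "in_seed": c.in_seed,
                "label": c.label,
            }
        )
    return rows
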