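"""Synthetic small-RNA-seq data with the statistical structure the
analysis assumes.

The generators plant known truths — per-site A-to-G editing fractions,
per-miRNA abundances, fold-changes between two conditions — so that
every downstream stage (preprocessing, alignment, the binomial editing
caller, TMM normalization, the Poisson difference test) can be checked
against ground truth at desk scale.

The read model per molecule: the mature sequence, with each planted
site flipped A->G independently at its editing fraction; a uniform
per-base substitution error (default 0.1%, the null of the editing
test); a 2-base random non-templated 3' tail with probability 0.5
(the modification that motivates trimming the last two bases); the 3'
sequencing adaptor; and truncation to a fixed machine read length.
Qualities are drawn so that a configurable fraction of positions fall
below phred 20 and mismatch positions span phreds on both sides of 30.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, MiRNAReference, SequencedRead

#: Illumina TruSeq small-RNA 3' adaptor
DEFAULT_ADAPTOR3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_MACHINE_LENGTH = 36

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class EditingSpec:
    """Planted editing: (miRNA id, 0-based position) -> A->G fraction."""

    sites: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (mid, pos), frac in self.sites.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"editing fraction for {mid}:{pos} outside [0,1]: {frac}")

    def validate_against(self, refs: Sequence[MiRNAReference]) -> None:
        by_id = {r.id: r for r in refs}
        for (mid, pos), _ in self.sites.items():
            ref = by_id.get(mid)
            if ref is None:
                raise ValueError(f"editing site on unknown miRNA {mid!r}")
            if not 0 <= pos < len(ref):
                raise ValueError(f"editing position {mid}:{pos} outside sequence")
            if ref.sequence[pos] != "A":
                raise ValueError(
                    f"editing position {mid}:{pos} has reference base "
                    f"{ref.sequence[pos]!r}, expected 'A'"
                )

    def for_mirna(self, mid: str) -> dict[int, float]:
        return {pos: f for (m, pos), f in self.sites.items() if m == mid}


@dataclass(frozen=True)
class AbundanceSpec:
    """Expected read counts per miRNA, a library scale factor, and optional
    per-miRNA fold-changes applied in a second condition."""

    expected: Mapping[str, float]
    scale: float = 1.0
    fold_change: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.expected.values()):
            raise ValueError("expected counts must be >= 0")
        if self.scale <= 0:
            raise ValueError("library scale factor must be > 0")


def make_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (20, 24),
    rng_seed: int = 0,
) -> list[MiRNAReference]:
    """Random mature references ``syn-mir-0001`` ... with at least one A each."""
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    lo, hi = length_range
    if lo < 15:
        raise ValueError("length_range must start at >= 15 nt (reads would fail the length gate)")
    if lo > hi:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(rng_seed)
    refs = []
    for i in range(n_mirnas):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list("ACGT"), size=length)
        if not (seq == "A").any():
            seq[rng.integers(length)] = "A"
        refs.append(MiRNAReference(id=f"syn-mir-{i + 1:04d}", sequence="".join(seq)))
    return refs


def simulate_reads(
    refs: Sequence[MiRNAReference],
    abundance: AbundanceSpec,
    editing: EditingSpec | None = None,
    error_rate: float = 0.001,
    adaptor3: str = DEFAULT_ADAPTOR3,
    rng_seed: int = 0,
    machine_length: int = DEFAULT_MACHINE_LENGTH,
    tail_prob: float = 0.5,
    low_quality_fraction: float = 0.02,
) -> list[SequencedRead]:
    """Simulate adaptor-flanked mature-miRNA reads at fixed machine length.

    Per miRNA the read count is drawn Poisson(expected * scale).  Qualities:
    each position is low (phred 2-19) with probability
    ``low_quality_fraction``, otherwise uniform on phred 25-40, so mismatch
    bases fall on both sides of the phred-30 gate.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must lie in [0, 0.05]")
    editing = editing or EditingSpec()
    editing.validate_against(refs)
    rng = np.random.default_rng(rng_seed)
    reads: list[SequencedRead] = []
    for ref in refs:
        expected = abundance.expected.get(ref.id, 0.0) * abundance.scale
        n = int(rng.poisson(expected)) if expected > 0 else 0
        sites = editing.for_mirna(ref.id)
        base_seq = np.array(list(ref.sequence))
        for j in range(n):
            seq = base_seq.copy()
            for pos, frac in sites.items():
                if rng.random() < frac:
                    seq[pos] = "G"
            if error_rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                for pos in hits:
                    alts = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = alts[rng.integers(3)]
            insert = "".join(seq)
            tail = ""
            if rng.random() < tail_prob:
                tail = "".join(rng.choice(list("ACGT"), size=2))
            full = insert + tail + adaptor3
            while len(full) < machine_length:
                full += "".join(rng.choice(list("ACGT"), size=machine_length - len(full)))
            full = full[:machine_length]
            low = rng.random(machine_length) < low_quality_fraction
            quals = np.where(
                low,
                rng.integers(2, 20, size=machine_length),
                rng.integers(25, 41, size=machine_length),
            )
            reads.append(
                SequencedRead(
                    id=f"{ref.id}:read{j + 1}",
                    bases=full,
                    quals=tuple(int(q) for q in quals),
                )
            )
    return reads


def simulate_count_tables(
    n_mirnas: int,
    libsizes: Mapping[str, float],
    frac_changed: float = 0.0,
    log2_effect: float = 2.0,
    sigma: float = 1.5,
    rng_seed: int = 0,
) -> tuple[CountTable, pd.DataFrame]:
    """Two-condition count tables with Poisson noise and planted fold-changes.

    Baseline relative abundances are log-normal (``sigma`` on the natural-log
    scale); a ``frac_changed`` subset is shifted by ``±log2_effect`` (random
    sign) in the second sample.  Returns the table and a truth frame with
    columns ``changed`` and ``true_log2_effect``.
    """
    if not 0.0 <= frac_changed <= 1.0:
        raise ValueError("frac_changed must lie in [0, 1]")
    if len(libsizes) != 2:
        raise ValueError("libsizes must name exactly two samples")
    if any(v <= 0 for v in libsizes.values()):
        raise ValueError("library sizes must be > 0")
    rng = np.random.default_rng(rng_seed)
    ids = [f"syn-mir-{i + 1:04d}" for i in range(n_mirnas)]
    rel = rng.lognormal(mean=0.0, sigma=sigma, size=n_mirnas)
    rel /= rel.sum()
    (name_a, lib_a), (name_b, lib_b) = libsizes.items()
    n_changed = int(round(frac_changed * n_mirnas))
    changed_idx = rng.choice(n_mirnas, size=n_changed, replace=False)
    effect = np.zeros(n_mirnas)
    if n_changed:
        signs = rng.choice([-1.0, 1.0], size=n_changed)
        effect[changed_idx] = signs * log2_effect
    mu_a = rel * lib_a
    mu_b = rel * (2.0 ** effect) * lib_b
    counts = pd.DataFrame(
        {name_a: rng.poisson(mu_a), name_b: rng.poisson(mu_b)}, index=ids
    )
    truth = pd.DataFrame(
        {"changed": effect != 0.0, "true_log2_effect": effect}, index=ids
    )
    return CountTable(df=counts), truth
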