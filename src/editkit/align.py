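"""Alignment of cleaned reads to a mature-miRNA reference set, and
per-position base tallies.

The policy mirrors the analysis being reproduced: a read aligns if it
matches some reference at some offset with at most one mismatch, and
every mismatching base must carry phred >= 30.  A read whose best hit is
tied across distinct (reference, offset) locations is ambiguous and
excluded from both tallies and expression counts to avoid double
counting.  Reads may start up to a few bases inside the reference
(5' isomiR wobble); the maximum 5' offset is configurable.

Bases below the phred-30 gate contribute neither to the base counts nor
to coverage, so the binomial test's error-rate null (which is tied to
the phred-30 filter) matches its count denominator.  This is the
conservative extension of the mismatch-quality rule to the tally and is
discussed in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .io import NUCLEOTIDES, MiRNAReference, SequencedRead

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


class Ambiguous:
    """Sentinel outcome: equally good hits at distinct locations."""

    _instance: "Ambiguous | None" = None

    def __new__(cls) -> "Ambiguous":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "AMBIGUOUS"


AMBIGUOUS = Ambiguous()


@dataclass(frozen=True)
class Alignment:
    read_id: str
    ref_id: str
    offset: int  # 0-based start of the read on the reference
    mismatches: tuple[tuple[int, str, str, int], ...]  # (ref pos, ref base, read base, phred)
    read: SequencedRead

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class PositionTally:
    """Counts of quality-passing aligned bases per reference position."""

    ref_id: str
    counts: np.ndarray  # shape (L, 4), columns ordered A,C,G,T

    @classmethod
    def empty(cls, ref: MiRNAReference) -> "PositionTally":
        return cls(ref_id=ref.id, counts=np.zeros((len(ref), 4), dtype=np.int64))

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def count(self, pos: int, base: str) -> int:
        return int(self.counts[pos, _BASE_INDEX[base]])


def align_read(
    read: SequencedRead,
    refs: Sequence[MiRNAReference],
    cfg: PipelineConfig,
) -> Alignment | Ambiguous | None:
    """Scan the read against every admissible offset of every reference.

    Candidate hits have at most ``max_mismatches`` mismatches, each with
    phred >= ``mismatch_quality_min``; the hit with fewest mismatches
    wins.  Returns ``None`` if no candidate exists, ``AMBIGUOUS`` on a
    tie across distinct locations.
    """
    if not refs:
        raise ValueError("empty reference set")
    best: list[tuple[str, int, tuple]] = []
    best_mm = cfg.max_mismatches + 1
    for ref in refs:
        max_off = min(cfg.max_five_prime_offset, len(ref) - len(read))
        for off in range(0, max_off + 1):
            mm: list[tuple[int, str, str, int]] = []
            ok = True
            seg = ref.sequence
            for k in range(len(read)):
                rb = seg[off + k]
                qb = read.bases[k]
                if rb != qb:
                    if (
                        len(mm) >= cfg.max_mismatches
                        or read.quals[k] < cfg.mismatch_quality_min
                    ):
                        ok = False
                        break
                    mm.append((off + k, rb, qb, read.quals[k]))
            if not ok:
                continue
            if len(mm) < best_mm:
                best_mm = len(mm)
                best = [(ref.id, off, tuple(mm))]
            elif len(mm) == best_mm:
                best.append((ref.id, off, tuple(mm)))
    if not best:
        return None
    if len(best) > 1:
        return AMBIGUOUS
    ref_id, off, mm = best[0]
    return Alignment(read_id=read.id, ref_id=ref_id, offset=off, mismatches=mm, read=read)


def tally(
    alignments: Iterable[Alignment],
    refs: Sequence[MiRNAReference],
    cfg: PipelineConfig,
) -> dict[str, PositionTally]:
    """Accumulate per-position base counts from uniquely aligned reads.

    Each aligned base with phred >= ``mismatch_quality_min`` contributes 1
    to its base's count at its reference position; lower-quality bases
    contribute nothing (neither to counts nor coverage).
    """
    by_id = {r.id: r for r in refs}
    tallies = {r.id: PositionTally.empty(r) for r in refs}
    for al in alignments:
        if al.ref_id not in by_id:
            raise ValueError(f"alignment to unknown reference {al.ref_id!r}")
        ref = by_id[al.ref_id]
        t = tallies[al.ref_id]
        if al.offset + len(al.read) > len(ref):
            raise ValueError(
                f"{al.read_id}: alignment at offset {al.offset} extends past {ref.id}"
            )
        for k, (base, q) in enumerate(zip(al.read.bases, al.read.quals)):
            if q >= cfg.mismatch_quality_min and base in _BASE_INDEX:
                t.counts[al.offset + k, _BASE_INDEX[base]] += 1
    return tallies


def expression_counts(alignments: Iterable[Alignment]) -> dict[str, int]:
    """Uniquely aligned reads per miRNA (ambiguous reads never get here)."""
    counts: dict[str, int] = {}
    for al in alignments:
        counts[al.ref_id] = counts.get(al.ref_id, 0) + 1
    return counts


def align_stream(
    reads: Iterable[SequencedRead],
    refs: Sequence[MiRNAReference],
    cfg: PipelineConfig,
) -> tuple[list[Alignment], dict[str, int]]:
    """Align a stream; returns unique alignments and outcome counters
    (``aligned`` / ``unaligned`` / ``ambiguous``)."""
    out: list[Alignment] = []
    counters = {"aligned": 0, "unaligned": 0, "ambiguous": 0}
    for read in reads:
        res = align_read(read, refs, cfg)
        if res is None:
            counters["unaligned"] += 1
        elif res is AMBIGUOUS:
            counters["ambiguous"] += 1
        else:
            counters["aligned"] += 1
            out.append(res)
    return out, counters


def write_tally_tsv(
    tallies: Mapping[str, PositionTally],
    refs: Sequence[MiRNAReference],
    path,
) -> None:
    """Tally TSV: ref_id, pos_1based, ref_base, nA, nC, nG, nT, coverage."""
    by_id = {r.id: r for r in refs}
    with open(path, "w") as fh:
        fh.write("ref_id\tpos_1based\tref_base\tnA\tnC\tnG\tnT\tcoverage\n")
        for rid in sorted(tallies):
            t = tallies[rid]
            seq = by_id[rid].sequence
            for pos in range(t.counts.shape[0]):
                a, c, g, u = (int(x) for x in t.counts[pos])
                fh.write(
                    f"{rid}\t{pos + 1}\t{seq[pos]}\t{a}\t{c}\t{g}\t{u}\t{a + c + g + u}\n"
                )


def read_tally_tsv(path, refs: Sequence[MiRNAReference]) -> dict[str, PositionTally]:
    import pandas as pd

    by_id = {r.id: r for r in refs}
    df = pd.read_csv(path, sep="\t")
    tallies: dict[str, PositionTally] = {}
    for rid, grp in df.groupby("ref_id"):
        if rid not in by_id:
            raise ValueError(f"tally for unknown reference {rid!r}")
        t = PositionTally.empty(by_id[rid])
        for _, row in grp.iterrows():
            pos = int(row["pos_1based"]) - 1
            t.counts[pos] = [row["nA"], row["nC"], row["nG"], row["nT"]]
        tallies[rid] = t
    return tallies
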