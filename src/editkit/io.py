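"""Readers and writers for the on-disk formats, plus the core records.

FASTA and FASTQ parsing is delegated to Biopython; count tables and
reports are tab-separated text.  Count tables tolerate thousands
separators ("61,575") so published tables can be pasted verbatim.

Coordinates are 0-based half-open internally; all reports are 1-based
closed, counting from the 5' end of the mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

NUCLEOTIDES = "ACGT"
PHRED_OFFSET = 33  # Sanger / Illumina 1.8+ encoding


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class MiRNAReference:
    """A named mature (or star/precursor) miRNA sequence.

    ``seed_span`` is a 1-based closed interval on the sequence; ``chrom``
    and ``strand`` are optional genomic annotation carried into reports.
    """

    id: str
    sequence: str
    kind: str = "mature"  # mature | star | precursor
    seed_span: tuple[int, int] | None = None
    chrom: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.id}: sequence must be uppercase")
        bad = set(self.sequence) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")
        if self.kind not in ("mature", "star", "precursor"):
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")
        if self.seed_span is not None:
            lo, hi = self.seed_span
            if not 1 <= lo <= hi <= len(self.sequence):
                raise ValueError(f"{self.id}: seed_span {self.seed_span} outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequencedRead:
    """A read with per-base phred qualities, carried through preprocessing."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"{self.id}: phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class CountTable:
    """Per-miRNA counts per sample: a rectangular non-negative table."""

    df: pd.DataFrame  # index: miRNA ids, columns: sample names
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate miRNA ids: {dups}")
        if (self.df.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def mirnas(self) -> list[str]:
        return list(self.df.index)

    def column(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"unknown sample {sample!r}; have {self.samples}")
        return self.df[sample]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, kind: str = "mature") -> list[MiRNAReference]:
    """Read a reference FASTA; sequences are uppercased and U becomes T."""
    path = Path(path)
    records: list[MiRNAReference] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: record {i}: empty header")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise FormatError(
                f"{path}: record {i} ({rec.id}): illegal characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: record {i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(MiRNAReference(id=rec.id, sequence=seq, kind=kind))
    return records


def write_fasta(refs: Iterable[MiRNAReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id}\n{ref.sequence}\n")


# ---------------------------------------------------------------------------
# FASTQ (phred+33)

def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream reads from a 4-line-record FASTQ file (phred+33)."""
    path = Path(path)
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # truncated record / length mismatch
                raise FormatError(f"{path}: record {i + 1}: {exc}") from exc
            i += 1
            quals = tuple(ord(c) - PHRED_OFFSET for c in qual)
            if len(seq) != len(quals):
                raise FormatError(
                    f"{path}: record {i}: {len(seq)} bases but {len(quals)} qualities"
                )
            yield SequencedRead(id=title.split()[0], bases=seq.upper(), quals=quals)


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Count tables

def read_count_table(path: str | Path, normalized: bool = False) -> CountTable:
    """Read a TSV count table: first column miRNA id, header of sample names.

    Thousands separators are stripped; any other non-numeric cell raises a
    :class:`FormatError` naming the row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.isna().any():
        raise FormatError(f"{path}: missing miRNA id")
    parsed = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        for mirna, cell in raw[col].items():
            if cell is None or (isinstance(cell, float) and pd.isna(cell)):
                raise FormatError(f"{path}: missing cell at row {mirna!r}, column {col!r}")
            text = str(cell).strip().replace(",", "")
            try:
                parsed.at[mirna, col] = float(text)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {mirna!r}, column {col!r}"
                ) from exc
    if not normalized and (parsed == parsed.round()).all().all():
        parsed = parsed.astype(int)
    return CountTable(df=parsed, normalized=normalized)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="mirna")


# ---------------------------------------------------------------------------
# Reports

ND = "ND"  # literal for not-determined cells


def write_report(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    percent_columns: Sequence[str] = (),
) -> None:
    """Write report rows as TSV with a header.

    ``None`` values print as the literal ``"ND"``.  Columns named in
    ``percent_columns`` are editing levels already on the 0-100 scale and
    print with one decimal; all other floats print at full precision so a
    write/read round trip is exact.
    """
    if records:
        keys = list(columns) if columns is not None else list(records[0].keys())
        for i, row in enumerate(records):
            missing = set(keys) ^ set(row.keys()) if columns is None else set(keys) - set(row.keys())
            if missing:
                raise ValueError(f"row {i} does not share the report schema: {sorted(missing)}")
    else:
        keys = list(columns) if columns is not None else []
    pct = set(percent_columns)
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in records:
            cells = []
            for k in keys:
                v = row[k]
                if v is None:
                    cells.append(ND)
                elif k in pct and isinstance(v, float):
                    cells.append(f"{v:.1f}")
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report TSV; ``"ND"`` cells become missing values."""
    return pd.read_csv(path, sep="\t", na_values=[ND], keep_default_na=False)
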