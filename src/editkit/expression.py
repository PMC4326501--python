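"""Expression analysis: TMM normalization, the exact Poisson difference
test, fold-changes, and the selection/reversal filters.

Fold-changes use log2[(A+1)/(B+1)], pseudocounts guarding zeros.  The
difference test is the exact conditional test of equal Poisson rates:
given n = a + b, under the null a ~ Binomial(n, lib_a/(lib_a+lib_b)),
and the two-sided p-value sums all outcomes no more likely than the
observed one (minimum-likelihood rule).  Bonferroni correction spans
the miRNAs with a + b > 0 in the contrast.

Normalization is trimmed-mean-of-M-values: per-gene log2 between-sample
ratios (M) against a reference sample, doubly trimmed (30% on M, 5% on
A), combined with precision weights from the delta-method binomial
variances, and the resulting factors rescaled to multiply to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import CountTable


@dataclass(frozen=True)
class ExpressionRecord:
    mirna: str
    count_a: float
    count_b: float
    log2_ratio: float
    p_value: float
    p_adjusted: float
    significant: bool
    passes_sum_filter: bool
    passes_effect_filter: bool

    @property
    def selected(self) -> bool:
        return self.significant and self.passes_sum_filter and self.passes_effect_filter


@dataclass
class NormalizationResult:
    factors: dict[str, float]  # per-sample TMM scale factor (multiply to 1)
    table: CountTable  # normalized counts
    reference_sample: str
    trim_m: float
    trim_a: float


def fold_change(a: float, b: float) -> float:
    """log2[(a+1)/(b+1)]; finite for all non-negative counts."""
    if a < 0 or b < 0:
        raise ValueError(f"counts must be non-negative, got ({a}, {b})")
    return float(np.log2((a + 1.0) / (b + 1.0)))


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """Two-sample TMM factor (obs relative to ref), log2 scale -> 2**f."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method variance of M from binomial sampling
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    n = len(m)
    if n == 0:
        return 1.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.nansum(m[keep2] / v[keep2]) / np.nansum(1.0 / v[keep2])
    return float(2.0 ** f)


def tmm_normalize(
    table: CountTable, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """TMM library-composition normalization across >= 2 samples.

    The reference sample is the one whose 75th percentile of
    library-scaled counts is closest to the across-sample mean.  Counts
    are rescaled by effective library size (library total x factor) back
    to the mean library scale, so normalized counts stay on a reads-like
    scale; normalizing an already-normalized table returns factors of ~1.
    """
    counts = table.df.to_numpy(dtype=float)
    samples = table.samples
    if len(samples) < 2:
        raise ValueError("tmm_normalize requires at least two samples")
    libsizes = counts.sum(axis=0)
    if (libsizes == 0).any():
        bad = [s for s, l in zip(samples, libsizes) if l == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    q75 = np.array(
        [np.quantile(counts[:, j][counts[:, j] > 0] / libsizes[j], 0.75) if (counts[:, j] > 0).any() else 0
         for j in range(len(samples))]
    )
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_j
            else _tmm_pair_factor(
                counts[:, j], counts[:, ref_j], libsizes[j], libsizes[ref_j],
                trim_m, trim_a,
            )
            for j in range(len(samples))
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    effective = libsizes * factors
    scale = effective.mean() / effective
    normalized = pd.DataFrame(
        counts * scale[np.newaxis, :], index=table.df.index, columns=samples
    )
    return NormalizationResult(
        factors={s: float(f) for s, f in zip(samples, factors)},
        table=CountTable(df=normalized, normalized=True),
        reference_sample=samples[ref_j],
        trim_m=trim_m,
        trim_a=trim_a,
    )


def poisson_diff_pvalue(a: float, b: float, lib_a: float, lib_b: float) -> float:
    """Exact conditional test of equal Poisson rates (two-sided).

    Given n = a + b, the null distribution of a is
    Binomial(n, lib_a/(lib_a + lib_b)); the p-value sums the binomial
    probabilities of every outcome no more likely than the observed one.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library totals must be > 0")
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    a, b = int(round(a)), int(round(b))
    n = a + b
    if n == 0:
        return 1.0
    p = lib_a / (lib_a + lib_b)
    from scipy import stats

    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    threshold = pmf[a] * (1.0 + 1e-7)  # tolerate float ties
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def differential_table(
    table: CountTable,
    sample_a: str,
    sample_b: str,
    cfg: PipelineConfig,
) -> list[ExpressionRecord]:
    """Per-miRNA fold-change, exact Poisson-noise p-value, Bonferroni
    adjustment, and the two selection filters.

    Bonferroni divides by the number of miRNAs with a + b > 0.  A record
    is *selected* when it is significant and passes both filters:
    sum of counts strictly above ``expr_min_sum_reads`` and absolute
    log2 ratio at least ``expr_log2_cutoff``.
    """
    col_a = table.column(sample_a)
    col_b = table.column(sample_b)
    if table.normalized:
        # normalization already put both samples on a common scale; the
        # remaining total difference is composition/DE, not depth
        lib_a = lib_b = 1.0
    else:
        lib_a, lib_b = float(col_a.sum()), float(col_b.sum())
    nonzero = int(((col_a + col_b) > 0).sum())
    records = []
    for mirna in table.mirnas:
        a, b = float(col_a[mirna]), float(col_b[mirna])
        lr = fold_change(a, b)
        p = poisson_diff_pvalue(a, b, lib_a, lib_b) if a + b > 0 else 1.0
        p_adj = min(1.0, p * max(nonzero, 1))
        records.append(
            ExpressionRecord(
                mirna=mirna,
                count_a=a,
                count_b=b,
                log2_ratio=lr,
                p_value=p,
                p_adjusted=p_adj,
                significant=p_adj < cfg.expr_alpha,
                passes_sum_filter=(a + b) > cfg.expr_min_sum_reads,
                passes_effect_filter=abs(lr) >= cfg.expr_log2_cutoff,
            )
        )
    return records


def high_expression_subset(
    records: Sequence[ExpressionRecord], cfg: PipelineConfig
) -> list[ExpressionRecord]:
    """Keep records with count_a + count_b >= high_expr_min_sum (inclusive)."""
    return [r for r in records if r.count_a + r.count_b >= cfg.high_expr_min_sum]


def reversal_filter(
    contrast1: Sequence[ExpressionRecord],
    contrast2: Sequence[ExpressionRecord],
) -> list[str]:
    """miRNAs selected in the first contrast whose fold-change in the second
    contrast has strictly the opposite sign (an expression-trend reversal)."""
    lr2 = {r.mirna: r.log2_ratio for r in contrast2}
    out = []
    for r in contrast1:
        if not r.selected or r.mirna not in lr2:
            continue
        if r.log2_ratio * lr2[r.mirna] < 0:
            out.append(r.mirna)
    return out


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "count_a": r.count_a,
                "count_b": r.count_b,
                "log2_ratio": r.log2_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "passes_sum_filter": r.passes_sum_filter,
                "passes_effect_filter": r.passes_effect_filter,
                "selected": r.selected,
            }
            for r in records
        ]
    )
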