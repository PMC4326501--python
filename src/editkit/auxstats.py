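"""Self-contained auxiliary statistics.

* microarray selection: replicate log2 ratios -> one-sample t-test
  against zero -> Benjamini-Hochberg FDR (cutoff 0.2) -> effect filter
  (|mean log2 ratio| >= 0.5, boundary inclusive);
* relative qPCR quantification by the 2^-ddCt method;
* Sanger editing percentage from chromatogram peak areas,
  100 * G / (A + G).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig


@dataclass(frozen=True)
class CtMeasurement:
    """Threshold cycles for one sample: the target and an endogenous
    control (e.g. RNU6B for miRNAs, GAPDH for mRNAs)."""

    sample: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample}: {name} must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass(frozen=True)
class SangerPeaks:
    """Areas under the A and G chromatogram peaks at one site."""

    site: str
    auc_a: float
    auc_g: float

    def __post_init__(self) -> None:
        if self.auc_a < 0 or self.auc_g < 0:
            raise ValueError(f"{self.site}: peak areas must be non-negative")
        if self.auc_a + self.auc_g == 0:
            raise ValueError(f"{self.site}: both peak areas are zero")


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def array_select(
    ratios: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Microarray probe selection from replicate log2 ratios.

    ``ratios``: one row per miRNA probe, columns are replicate log2
    ratios (missing cells allowed, but every probe needs >= 2 finite
    replicates).  Returns a frame with mean_log2, p_value, q_value and
    the ``selected`` flag: q <= fdr cutoff AND |mean| >= effect cutoff.
    """
    means, pvals = [], []
    for mirna, row in ratios.iterrows():
        reps = row.dropna().astype(float).to_numpy()
        if len(reps) < 2:
            raise ValueError(f"{mirna}: need >= 2 replicates, got {len(reps)}")
        means.append(float(reps.mean()))
        if np.allclose(reps, reps[0]):
            # zero variance: identical replicates carry no test either way
            pvals.append(1.0 if reps[0] == 0 else 0.0)
        else:
            pvals.append(float(stats.ttest_1samp(reps, 0.0).pvalue))
    q = bh_fdr(pvals)
    out = pd.DataFrame(
        {
            "mean_log2": means,
            "p_value": pvals,
            "q_value": q,
        },
        index=ratios.index,
    )
    out["selected"] = (out["q_value"] <= cfg.array_fdr_cutoff) & (
        out["mean_log2"].abs() >= cfg.array_log2_cutoff
    )
    return out


def ddct_fold(sample: CtMeasurement, calibrator: CtMeasurement) -> float:
    """Relative quantity 2^-(ddCt); the calibrator maps to 1."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def sanger_editing_level(peaks: SangerPeaks) -> float:
    """Editing percentage from peak areas: 100 * G / (A + G)."""
    return 100.0 * peaks.auc_g / (peaks.auc_a + peaks.auc_g)
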