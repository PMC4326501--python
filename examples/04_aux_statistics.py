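"""The three self-contained statistics: microarray probe selection,
relative qPCR quantification, and Sanger peak-ratio editing levels."""

import numpy as np
import pandas as pd

from editkit import (
    CtMeasurement,
    PipelineConfig,
    SangerPeaks,
    array_select,
    ddct_fold,
    sanger_editing_level,
)

cfg = PipelineConfig()

# --- microarray selection: replicate log2 ratios -> t-test -> BH FDR -------
rng = np.random.default_rng(7)
null = rng.normal(0, 0.2, size=(60, 3))
true = np.array([[-1.0]] * 6) + rng.normal(0, 0.2, size=(6, 3))
ratios = pd.DataFrame(
    np.vstack([null, true]),
    index=[f"probe{i}" for i in range(60)] + [f"down{i}" for i in range(6)],
)
out = array_select(ratios, cfg)
sel = out[out["selected"]]
print(f"array selection (FDR <= {cfg.array_fdr_cutoff}, |log2| >= {cfg.array_log2_cutoff}): "
      f"{len(sel)} of {len(out)} probes selected -> {sorted(sel.index)}")

# --- 2^-ddCt: one cycle earlier than the calibrator doubles the quantity ---
calibrator = CtMeasurement("untreated", target_ct=25.0, reference_ct=20.0)
sample = CtMeasurement("enzyme_rescued", target_ct=26.3, reference_ct=20.1)
fold = ddct_fold(sample, calibrator)
print(f"qPCR relative quantity (2^-ddCt) vs untreated=1: {fold:.3f}")

# --- Sanger peak ratio: editing % = G / (A + G) areas ----------------------
level = sanger_editing_level(SangerPeaks("site+53", auc_a=320.0, auc_g=80.0))
print(f"Sanger editing level at site+53: {level:.1f}%")
# 80/(320+80) = 20%: one fifth of the transcripts read out as G.
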