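"""qRT-PCR relative quantification and RNA-seq concordance regression.

Relative expression uses the standard 2^-ddCt model with a single reference
gene (actin in the original assay): dCt = Ct_target - Ct_reference per
sample, ddCt = dCt_sample - dCt_calibrator, level = 2^-ddCt, so the
calibrator sample sits at level 1 for every gene.  Concordance regresses
pooled RNA-seq log2 expression ratios on the matching qPCR log2 ratios by
ordinary least squares and reports the Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConcordanceFit


def relative_expression(qpcr: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Per-gene, per-sample relative levels (2^-ddCt) with replicate spread.

    ``qpcr`` columns: gene_id, sample_id, ct_target, ct_reference,
    replicate.  Levels are computed per replicate against the replicate-mean
    dCt of the calibrator sample, then summarised as mean +/- standard
    error.  Returns columns gene_id, sample_id, level, se, n_replicates.
    """
    required = {"gene_id", "sample_id", "ct_target", "ct_reference"}
    if not required <= set(qpcr.columns):
        raise ValueError(f"qpcr table needs columns {sorted(required)}")
    if qpcr[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    df = qpcr.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    calib = df[df["sample_id"] == calibrator_sample]
    missing = set(df["gene_id"]) - set(calib["gene_id"])
    if missing:
        raise ValueError(f"calibrator sample lacks genes: {sorted(missing)[:5]}")
    calib_dct = calib.groupby("gene_id")["dct"].mean()
    df["level"] = 2.0 ** -(df["dct"] - df["gene_id"].map(calib_dct))
    out = (df.groupby(["gene_id", "sample_id"])["level"]
           .agg(level="mean", sd="std", n_replicates="count").reset_index())
    out["se"] = (out["sd"] / np.sqrt(out["n_replicates"])).fillna(0.0)
    return out[["gene_id", "sample_id", "level", "se", "n_replicates"]]


def regression_concordance(rnaseq_log2_ratios: np.ndarray,
                           qpcr_log2_ratios: np.ndarray) -> ConcordanceFit:
    """OLS fit (RNA-seq value) = a * (RT-PCR value) + b, with Pearson r.

    RNA-seq is the response; requires >= 3 paired points and non-constant
    qPCR values.
    """
    y = np.asarray(rnaseq_log2_ratios, dtype=float)
    x = np.asarray(qpcr_log2_ratios, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("ratio vectors must be 1-D and equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 paired ratios")
    if np.ptp(x) == 0.0:
        raise ValueError("qPCR ratios have zero variance")
    fit = stats.linregress(x, y)
    return ConcordanceFit(slope=float(fit.slope), intercept=float(fit.intercept),
                          r=float(fit.rvalue), n=len(y))


def ratio_pairs_from_tables(rnaseq: pd.DataFrame, qpcr: pd.DataFrame,
                            on: tuple[str, ...] = ("gene_id", "comparison"),
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Align RNA-seq and qPCR log2-ratio tables on gene/comparison keys."""
    merged = rnaseq.merge(qpcr, on=list(on), suffixes=("_rnaseq", "_qpcr"))
    return (merged["log2_ratio_rnaseq"].to_numpy(),
            merged["log2_ratio_qpcr"].to_numpy())
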