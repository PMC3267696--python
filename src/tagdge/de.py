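"""Two-library differential expression via the pooled-proportion Z test.

The study design has no replicates: each library is a single multinomial
draw, so a gene's expression difference between two libraries is tested as
a difference of two binomial proportions,

    z = (p_a - p_b) / sqrt( pbar (1 - pbar) (1/n_a + 1/n_b) )

with p_i = count_i / n_i the gene's share of the library's reliable tag
total, pbar the pooled proportion, and a two-sided normal p-value.  A gene
is called differential at p < 0.05 when additionally |log2(TPM ratio)| >= 1
or it is detected on one side only (the "x/0" convention: when one TPM is
zero no ratio is formed; both values are reported as printed, e.g.
"6.59/0").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import hierarchical_cluster
from .types import GENOTYPES, STAGES, DERecord, ExpressionMatrix, LibraryId

DEFAULT_P = 0.05
DEFAULT_LFC_MIN = 1.0
DEFAULT_FOLD_SCREEN = 2.0

STAGE_PAIRS = tuple(zip(STAGES[:-1], STAGES[1:]))


def z_test(count_a: int, n_a: int, count_b: int, n_b: int) -> tuple[float, float]:
    """Pooled two-proportion Z statistic and two-sided normal p-value.

    Antisymmetric in (a, b).  Convention: two empty sides give z = 0, p = 1
    (no evidence either way); the same applies whenever the pooled variance
    vanishes, which can only happen at equal proportions 0 or 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("library totals must be >= 1")
    if count_a > n_a or count_b > n_b or count_a < 0 or count_b < 0:
        raise ValueError("counts must lie in [0, total]")
    pa, pb = count_a / n_a, count_b / n_b
    pooled = (count_a + count_b) / (n_a + n_b)
    var = pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b)
    if var == 0.0:
        return 0.0, 1.0
    z = (pa - pb) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.finfo(float).tiny))


def fold_change(tpm_a: float, tpm_b: float) -> tuple[float, str, str]:
    """log2 ratio b/a, presence flag, and the printable ratio report.

    Both sides positive -> (log2(b/a), 'both', '1.58'-style string); exactly
    one zero -> (nan, 'a_only'/'b_only', 'x/0' or '0/x' with 2-dp TPMs).
    Both zero is degenerate and raises (such genes are excluded upstream).
    """
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be non-negative")
    if tpm_a == 0.0 and tpm_b == 0.0:
        raise ValueError("degenerate comparison: both TPMs are zero")
    if tpm_a > 0.0 and tpm_b > 0.0:
        lr = float(np.log2(tpm_b / tpm_a))
        return lr, "both", f"{2.0 ** lr:.2f}"
    if tpm_b == 0.0:
        return float("nan"), "a_only", f"{tpm_a:.2f}/0"
    return float("nan"), "b_only", f"0/{tpm_b:.2f}"


def test_gene(gene_id: str, count_a: int, n_a: int, count_b: int, n_b: int,
              tpm_a: float, tpm_b: float,
              p_threshold: float = DEFAULT_P,
              lfc_min: float = DEFAULT_LFC_MIN) -> DERecord:
    """Full two-library DE record for one gene (direction: b relative to a)."""
    z, p = z_test(count_a, n_a, count_b, n_b)
    lr, flag, report = fold_change(tpm_a, tpm_b)
    effect = flag != "both" or abs(lr) >= lfc_min
    call = "none"
    if p < p_threshold and effect:
        up = (flag == "b_only") or (flag == "both" and lr > 0)
        call = "up" if up else "down"
    return DERecord(gene_id=gene_id, count_a=count_a, count_b=count_b,
                    n_a=n_a, n_b=n_b, tpm_a=tpm_a, tpm_b=tpm_b,
                    log2_ratio=lr, presence_flag=flag, ratio_report=report,
                    z=z, p=p, call=call)


test_gene.__test__ = False  # not a pytest item


def _compare_columns(matrix: ExpressionMatrix, col_a: str, col_b: str,
                     p_threshold: float, lfc_min: float,
                     fold_screen: float | None = None) -> pd.DataFrame:
    """DE records for every gene detected in at least one of two libraries."""
    tpm_a = matrix.tpm[col_a]
    tpm_b = matrix.tpm[col_b]
    counts_a = matrix.counts[col_a]
    counts_b = matrix.counts[col_b]
    n_a = int(matrix.totals[col_a])
    n_b = int(matrix.totals[col_b])
    thr = matrix.expressed_threshold
    keep = (tpm_a >= thr) | (tpm_b >= thr)
    records = []
    for gene in matrix.tpm.index[keep]:
        ta, tb = float(tpm_a[gene]), float(tpm_b[gene])
        if fold_screen is not None and ta > 0 and tb > 0:
            ratio = max(ta, tb) / min(ta, tb)
            if ratio < fold_screen:
                continue
        rec = test_gene(gene, int(counts_a[gene]), n_a, int(counts_b[gene]), n_b,
                        ta, tb, p_threshold, lfc_min)
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])


def compare_stages(matrix: ExpressionMatrix, genotype: str,
                   p_threshold: float = DEFAULT_P,
                   lfc_min: float = DEFAULT_LFC_MIN) -> dict[str, pd.DataFrame]:
    """Consecutive-stage comparisons (120v150, 150v190, 190v220).

    Keys are '120v150' etc.; direction is the later stage relative to the
    earlier one.  Genes undetected in both libraries of a pair are excluded.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype: {genotype!r}")
    out = {}
    for s_a, s_b in STAGE_PAIRS:
        out[f"{s_a}v{s_b}"] = _compare_columns(
            matrix, str(LibraryId(genotype, s_a)), str(LibraryId(genotype, s_b)),
            p_threshold, lfc_min)
    return out


def compare_genotypes(matrix: ExpressionMatrix, stage: int,
                      fold_screen: float = DEFAULT_FOLD_SCREEN,
                      p_threshold: float = DEFAULT_P,
                      lfc_min: float = DEFAULT_LFC_MIN,
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """WT-vs-MT comparison at one stage with the two-stage screen.

    Genes must first show a >= ``fold_screen`` TPM difference (in either
    direction; one-side-only genes pass the screen), then clear the Z-test
    significance and |log2 ratio| thresholds.  Direction 'up' means MT > WT.
    Returns (records, tally of up/down calls).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage: {stage!r}")
    df = _compare_columns(matrix, str(LibraryId("WT", stage)), str(LibraryId("MT", stage)),
                          p_threshold, lfc_min, fold_screen=fold_screen)
    if len(df) == 0:
        return df, {"up": 0, "down": 0}
    tally = {"up": int((df["call"] == "up").sum()),
             "down": int((df["call"] == "down").sum())}
    return df, tally


def de_profile_clustering(de_sets: dict[int, set[str]],
                          matrix: ExpressionMatrix,
                          n_clusters: int = 2) -> dict[str, object]:
    """Cluster MT/WT log2 ratio profiles of genotype-DE genes.

    ``de_sets`` maps stage -> genes called DE at that stage.  The union is
    clustered on its per-stage log2(MT TPM / WT TPM) profile (zeros floored
    at half the detection threshold to keep ratios finite); the all-stage
    intersection is reported with its ratio profiles.
    """
    union = sorted(set().union(*de_sets.values())) if de_sets else []
    inter = sorted(set.intersection(*map(set, de_sets.values()))) if de_sets else []
    if not union:
        return {"ratios": pd.DataFrame(), "clusters": pd.Series(dtype=int),
                "all_stage_genes": []}
    floor = matrix.expressed_threshold / 2.0
    ratios = pd.DataFrame(index=pd.Index(union, name="gene_id"))
    for s in STAGES:
        wt = matrix.tpm.loc[union, str(LibraryId("WT", s))].clip(lower=floor)
        mt = matrix.tpm.loc[union, str(LibraryId("MT", s))].clip(lower=floor)
        ratios[f"log2_MTvsWT_{s}"] = np.log2(mt / wt)
    if len(ratios) >= 2:
        # ratio profiles are already on a log scale: cluster them directly
        linkage, idx, labels = hierarchical_cluster(2.0 ** ratios - 1.0,
                                                    n_clusters=n_clusters)
        clusters = pd.Series(labels, index=idx, name="cluster")
    else:
        clusters = pd.Series(1, index=ratios.index, name="cluster")
    return {"ratios": ratios, "clusters": clusters,
            "all_stage_genes": inter,
            "all_stage_profiles": ratios.loc[inter] if inter else ratios.iloc[0:0]}
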