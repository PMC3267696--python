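"""Expression-pattern taxonomy, per-gene classification, and clustering.

Every detected gene is placed in one of 24 numbered pattern groups from its
presence/absence signature over the four developmental stages plus — for
genes present at all stages — the shape of its profile.  The numbering is a
reconstruction pinned to three anchors:

* group 2  — present only at 150 and 220 DAF (absent at 120 and 190),
* group 10 — absent at 120 DAF, present at the other three stages,
* group 20 — present at all stages, strictly increasing.

Groups 1-14 cover the 14 non-trivial presence signatures; groups 16-24 are
nine trend classes of all-present genes; group 15 is reserved (unused), so
no single genotype realises all 24 ids.  The full table:

====== ===================== =========================================
group  signature (120..220)  meaning
====== ===================== =========================================
1      1000                  present only at 120 DAF
2      0101                  present at 150 and 220 DAF
3      0100                  present only at 150 DAF
4      0010                  present only at 190 DAF
5      0001                  present only at 220 DAF
6      1100                  present at 120 and 150 DAF
7      1010                  present at 120 and 190 DAF
8      1001                  present at 120 and 220 DAF
9      0110                  present at 150 and 190 DAF
10     0111                  absent only at 120 DAF
11     0011                  present at 190 and 220 DAF
12     1110                  absent only at 220 DAF
13     1101                  absent only at 190 DAF
14     1011                  absent only at 150 DAF
15     --                    reserved
16     1111                  stable (max/min <= stable_fold)
17     1111                  strictly decreasing
18     1111                  non-monotone, maximum at 220 DAF
19     1111                  interior peak at 150 DAF
20     1111                  strictly increasing
21     1111                  interior peak at 190 DAF
22     1111                  interior trough at 150 DAF
23     1111                  interior trough at 190 DAF
24     1111                  non-monotone, maximum at 120 DAF
====== ===================== =========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .types import STAGES, ExpressionMatrix

#: presence signature (stages ascending, '1' = expressed) -> group id
SIGNATURE_GROUPS: dict[str, int] = {
    "1000": 1, "0101": 2, "0100": 3, "0010": 4, "0001": 5,
    "1100": 6, "1010": 7, "1001": 8, "0110": 9, "0111": 10,
    "0011": 11, "1110": 12, "1101": 13, "1011": 14,
}

GROUP_SIGNATURES: dict[int, str] = {g: s for s, g in SIGNATURE_GROUPS.items()}

GROUP_STABLE = 16
GROUP_STRICT_DOWN = 17
GROUP_MAX_AT_220 = 18
GROUP_PEAK_150 = 19
GROUP_STRICT_UP = 20
GROUP_PEAK_190 = 21
GROUP_TROUGH_150 = 22
GROUP_TROUGH_190 = 23
GROUP_MAX_AT_120 = 24

ALL_PRESENT_GROUPS = (16, 17, 18, 19, 20, 21, 22, 23, 24)
#: every group id a gene can actually receive (15 is reserved)
ASSIGNABLE_GROUPS = tuple(sorted(SIGNATURE_GROUPS.values())) + ALL_PRESENT_GROUPS

DEFAULT_STABLE_FOLD = 1.5


@dataclass(frozen=True)
class PatternAssignment:
    gene_id: str
    signature: str
    trend: str  # increasing / decreasing / stable / other / n/a
    group: int


def classify_profile(tpm: np.ndarray,
                     expressed_threshold: float = 3.0,
                     stable_fold: float = DEFAULT_STABLE_FOLD) -> tuple[str, str, int | None]:
    """Classify one 4-stage TPM profile.

    Returns (signature, trend, group); group is None when the gene is
    undetected at every stage.  Trend is only meaningful for all-present
    genes; partial genes get trend 'n/a'.
    """
    tpm = np.asarray(tpm, dtype=float)
    if tpm.shape != (4,):
        raise ValueError("profile must have exactly 4 stage values")
    present = tpm >= expressed_threshold
    signature = "".join("1" if b else "0" for b in present)
    if signature == "0000":
        return signature, "n/a", None
    if signature != "1111":
        return signature, "n/a", SIGNATURE_GROUPS[signature]

    # all-present: trend classes
    if tpm.max() <= stable_fold * tpm.min():
        return signature, "stable", GROUP_STABLE
    diffs = np.diff(tpm)
    if np.all(diffs > 0):
        return signature, "increasing", GROUP_STRICT_UP
    if np.all(diffs < 0):
        return signature, "decreasing", GROUP_STRICT_DOWN
    imax = int(np.argmax(tpm))
    imin = int(np.argmin(tpm))
    if imax == 1:
        return signature, "other", GROUP_PEAK_150
    if imax == 2:
        return signature, "other", GROUP_PEAK_190
    if imin == 1:
        return signature, "other", GROUP_TROUGH_150
    if imin == 2:
        return signature, "other", GROUP_TROUGH_190
    if imax == 3:
        return signature, "other", GROUP_MAX_AT_220
    return signature, "other", GROUP_MAX_AT_120


def classify_patterns(matrix: ExpressionMatrix, genotype: str,
                      stable_fold: float = DEFAULT_STABLE_FOLD,
                      ) -> tuple[list[PatternAssignment], pd.DataFrame, list[str]]:
    """Assign every detected gene of one genotype to a pattern group.

    Returns (assignments, census, excluded_gene_ids).  The census has one
    row per group with columns count and fraction, plus the fraction of
    detected genes whose profile varied over development (everything except
    the stable all-present class) in ``census.attrs['varied_fraction']``.
    """
    cols = matrix.columns_for(genotype)
    tpm = matrix.tpm[cols]
    assignments: list[PatternAssignment] = []
    excluded: list[str] = []
    for gene_id, row in zip(tpm.index, tpm.to_numpy()):
        signature, trend, group = classify_profile(
            row, matrix.expressed_threshold, stable_fold)
        if group is None:
            excluded.append(gene_id)
        else:
            assignments.append(PatternAssignment(gene_id, signature, trend, group))

    counts = pd.Series([a.group for a in assignments], dtype=int).value_counts()
    census = pd.DataFrame({
        "group": list(ASSIGNABLE_GROUPS),
        "count": [int(counts.get(g, 0)) for g in ASSIGNABLE_GROUPS],
    })
    n_detected = max(len(assignments), 1)
    census["fraction"] = census["count"] / n_detected
    n_stable = int(counts.get(GROUP_STABLE, 0))
    census.attrs["varied_fraction"] = 1.0 - n_stable / n_detected
    census.attrs["n_detected"] = len(assignments)
    return assignments, census, excluded


def compare_taxonomies(census_a: pd.DataFrame, census_b: pd.DataFrame,
                       labels: tuple[str, str] = ("WT", "MT")) -> pd.DataFrame:
    """Report which pattern groups are shared vs exclusive to one genotype."""
    a = census_a.set_index("group")["count"]
    b = census_b.set_index("group")["count"]
    groups = sorted(set(a.index) | set(b.index))
    rows = []
    for g in groups:
        na, nb = int(a.get(g, 0)), int(b.get(g, 0))
        if na and nb:
            status = "shared"
        elif na:
            status = f"{labels[0]}_only"
        elif nb:
            status = f"{labels[1]}_only"
        else:
            status = "empty"
        rows.append((g, na, nb, status))
    return pd.DataFrame(rows, columns=["group", f"n_{labels[0]}", f"n_{labels[1]}", "status"])


def correlation_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant profiles sit at distance 1.

    A constant profile has no defined correlation with anything, so by
    convention it is placed at distance 1 (correlation 0) from every other
    profile, including other constant profiles.
    """
    x = np.asarray(profiles, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    unit = np.zeros_like(centered)
    unit[ok] = centered[ok] / norms[ok, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[~ok, :] = 1.0
    dist[:, ~ok] = 1.0
    np.fill_diagonal(dist, 0.0)
    n = len(x)
    iu = np.triu_indices(n, k=1)
    return np.maximum(dist[iu], 0.0)


def hierarchical_cluster(matrix: ExpressionMatrix | pd.DataFrame,
                         genotype: str | None = None,
                         n_clusters: int | None = None,
                         ) -> tuple[np.ndarray, pd.Index, np.ndarray | None]:
    """Average-linkage clustering of log2(TPM+1) profiles, 1-Pearson distance.

    Accepts either an ExpressionMatrix (with ``genotype`` selecting its four
    stage columns) or a plain genes x conditions DataFrame of values to
    transform.  Returns (linkage matrix, leaf index, flat cluster labels or
    None).  The +1 offset handles the zeros that absent stages produce.
    """
    if isinstance(matrix, ExpressionMatrix):
        if genotype is None:
            raise ValueError("genotype required with an ExpressionMatrix")
        values = matrix.tpm[matrix.columns_for(genotype)]
    else:
        values = matrix
    if len(values) < 2:
        raise ValueError("clustering needs at least 2 genes")
    profiles = np.log2(values.to_numpy(dtype=float) + 1.0)
    dist = correlation_distance_matrix(profiles)
    linkage = sch.linkage(dist, method="average")
    labels = None
    if n_clusters is not None:
        labels = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, values.index, labels


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, leaf_names)
    return str(tree)
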