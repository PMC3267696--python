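"""GO categorization and hypergeometric over-representation testing.

For a study set of n annotated genes drawn from an annotated population of
N genes of which K carry a term, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution — the probability of seeing at
least the observed k term-carriers if the study set were a random draw.
Only over-representation is tested, with no DAG ancestor propagation and
(by default, matching the original P = 0.05 usage) no multiple-testing
correction; Benjamini-Hochberg is available via ``fdr=True``.
"""

from __future__ import annotations

import re

import pandas as pd
from scipy import stats

from .types import EnrichmentRecord

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

_TERM_RE = re.compile(r"^GO:\d{7}$")


class GOAnnotation:
    """gene -> {(term_id, namespace, term_name)} built from a long table."""

    def __init__(self, table: pd.DataFrame):
        required = {"gene_id", "term_id", "namespace"}
        if not required <= set(table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        bad_ns = set(table["namespace"]) - set(NAMESPACES)
        if bad_ns:
            raise ValueError(f"unknown namespaces: {sorted(bad_ns)}")
        self.table = table.copy()
        if "term_name" not in self.table.columns:
            self.table["term_name"] = self.table["term_id"]

    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    def subset(self, namespace: str | None) -> pd.DataFrame:
        if namespace is None:
            return self.table
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace: {namespace!r}")
        return self.table[self.table["namespace"] == namespace]


def categorize(genes: set[str], annotation: GOAnnotation,
               namespace: str = "biological_process") -> pd.DataFrame:
    """Term-by-term gene counts and percentages for one gene set.

    Percentages are over the genes with at least one annotation in the
    namespace; a gene counts toward every term it carries.
    """
    sub = annotation.subset(namespace)
    sub = sub[sub["gene_id"].isin(genes)]
    annotated = sub["gene_id"].nunique()
    if annotated == 0:
        return pd.DataFrame(columns=["term_id", "term_name", "count", "pct"])
    grouped = (sub.groupby(["term_id", "term_name"])["gene_id"]
               .nunique().reset_index(name="count"))
    grouped["pct"] = 100.0 * grouped["count"] / annotated
    return grouped.sort_values("count", ascending=False).reset_index(drop=True)


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError("inconsistent hypergeometric parameters")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def hypergeom_enrichment(study: set[str], population: set[str],
                         annotation: GOAnnotation,
                         namespace: str | None = None,
                         p_threshold: float = 0.05,
                         full_table: bool = False,
                         fdr: bool = False) -> list[EnrichmentRecord]:
    """Hypergeometric term enrichment of ``study`` against ``population``.

    Both sets are restricted to annotated genes (the background choice
    pinned here: the annotated part of the supplied population).  Records
    are sorted by p; by default only terms with p < ``p_threshold`` are
    returned (all terms with ``full_table=True``).  With ``fdr=True`` the
    threshold applies to Benjamini-Hochberg adjusted p-values instead.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    if not study:
        return []
    sub = annotation.subset(namespace)
    annotated = set(sub["gene_id"])
    pop = population & annotated
    stu = study & annotated
    N, n = len(pop), len(stu)
    if n == 0:
        return []
    records = []
    pop_tab = sub[sub["gene_id"].isin(pop)]
    for (term_id, ns, name), term_genes in pop_tab.groupby(
            ["term_id", "namespace", "term_name"])["gene_id"]:
        carriers = set(term_genes)
        K = len(carriers)
        hits = tuple(sorted(carriers & stu))
        k = len(hits)
        p = hypergeom_pvalue(k, N, K, n)
        records.append(EnrichmentRecord(term_id=term_id, namespace=ns,
                                        term_name=name, k=k, n=n, K=K, N=N,
                                        p=p, genes=hits))
    records.sort(key=lambda r: (r.p, r.term_id))
    if fdr and records:
        m = len(records)
        adj = [r.p * m / (i + 1) for i, r in enumerate(records)]
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        keep = [r for r, a in zip(records, adj) if a < p_threshold]
    else:
        keep = [r for r in records if r.p < p_threshold]
    return records if full_table else keep


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Table-3-style output frame."""
    return pd.DataFrame([{
        "term_id": r.term_id,
        "namespace": r.namespace,
        "term_name": r.term_name,
        "cluster_frequency_pct": round(r.cluster_frequency, 1),
        "p_value": r.p,
        "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "genes": ",".join(r.genes),
    } for r in records])
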