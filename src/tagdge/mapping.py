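"""Tag-to-unigene mapping and gene-level expression matrices.

Every CATG-anchored 21-mer window of every reference gene (both strands by
default) is indexed; a clean tag maps when its sequence is a key, and the
assignment is *unambiguous* when all its hits fall in a single gene.  Gene
expression sums the TPM of its unambiguous tags only; a tag hitting one
gene on both strands counts once, preferring the sense annotation.
Matching is exact — no mismatches, no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ANCHOR,
    GENOTYPES,
    LIBRARY_ORDER,
    STAGES,
    TAG_LEN,
    TAIL_LEN,
    ExpressionMatrix,
    LibraryId,
    MappingResult,
    ReferenceGene,
    TagCountTable,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceIndex:
    """Exact 21-mer index: tag -> set of (gene_id, offset, strand)."""

    entries: dict[str, set[tuple[str, int, str]]] = field(default_factory=dict)

    def genes_for(self, tag: str) -> set[str]:
        return {g for g, _, _ in self.entries.get(tag, ())}

    def __len__(self) -> int:
        return len(self.entries)


def anchored_windows(sequence: str) -> list[tuple[int, str]]:
    """All (offset, 21-mer) anchored windows on the given strand."""
    out = []
    pos = sequence.find(ANCHOR)
    while pos >= 0:
        if pos + TAG_LEN <= len(sequence):
            out.append((pos, sequence[pos:pos + TAG_LEN]))
        pos = sequence.find(ANCHOR, pos + 1)
    return out


def build_tag_index(reference: list[ReferenceGene],
                    strands: str = "both") -> ReferenceIndex:
    """Index every anchored window of every gene.

    ``strands`` is 'both' (default), 'sense' or 'antisense'.  Offsets are
    0-based on the indexed strand's own coordinates.
    """
    if strands not in ("both", "sense", "antisense"):
        raise ValueError(f"strands must be both/sense/antisense, got {strands!r}")
    seen_ids: set[str] = set()
    index = ReferenceIndex()
    for gene in reference:
        if gene.gene_id in seen_ids:
            raise ValueError(f"duplicate gene id: {gene.gene_id}")
        seen_ids.add(gene.gene_id)
        variants = []
        if strands in ("both", "sense"):
            variants.append((gene.sequence, "+"))
        if strands in ("both", "antisense"):
            variants.append((revcomp(gene.sequence), "-"))
        for seq, strand in variants:
            for offset, window in anchored_windows(seq):
                index.entries.setdefault(window, set()).add((gene.gene_id, offset, strand))
    return index


def map_library(clean: TagCountTable, index: ReferenceIndex) -> MappingResult:
    """Map a clean tag table against the index.

    A tag is *mapped* iff its sequence is an index key and *unambiguous* iff
    its hits involve exactly one gene (strand ignored for ambiguity).
    Percentages are weighted by tag counts over the clean table; gene TPM
    and counts are summed over unambiguous tags only.  Unmapped tags are
    tallied, never an error.
    """
    df = clean.table
    total = int(df["count"].sum())
    gene_tpm: dict[str, float] = {}
    gene_count: dict[str, int] = {}
    mapped = 0
    unambiguous = 0
    for tag, count, tpm in zip(df["tag"], df["count"], df["tpm"]):
        genes = index.genes_for(tag)
        if not genes:
            continue
        mapped += count
        if len(genes) == 1:
            unambiguous += count
            (gene,) = genes
            gene_tpm[gene] = gene_tpm.get(gene, 0.0) + float(tpm)
            gene_count[gene] = gene_count.get(gene, 0) + int(count)
    reliable_total = int(round(total / (df["tpm"].sum() / 1e6))) if len(df) else 0
    return MappingResult(
        library_id=clean.library_id,
        mapped_tag_pct=100.0 * mapped / total if total else 0.0,
        unambiguous_tag_pct=100.0 * unambiguous / total if total else 0.0,
        gene_tpm=pd.Series(gene_tpm, dtype=float).sort_index(),
        gene_count=pd.Series(gene_count, dtype=int).sort_index(),
        reliable_total=reliable_total,
    )


def brute_force_map(tag: str, reference: list[ReferenceGene],
                    strands: str = "both") -> set[str]:
    """Direct substring search of one tag against every gene (test oracle)."""
    hits = set()
    for gene in reference:
        seqs = []
        if strands in ("both", "sense"):
            seqs.append(gene.sequence)
        if strands in ("both", "antisense"):
            seqs.append(revcomp(gene.sequence))
        if tag.startswith(ANCHOR) and any(tag in s for s in seqs):
            hits.add(gene.gene_id)
    return hits


def assemble_matrix(results: list[MappingResult],
                    gene_universe: list[str] | None = None,
                    expressed_threshold: float = 3.0) -> ExpressionMatrix:
    """Stack per-library mapping results into a gene x library matrix.

    Columns follow the fixed order WT then MT, stages ascending; genes
    missing from a library get 0.
    """
    ids = [r.library_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated library_id in mapping results")
    order = [lib for lib in LIBRARY_ORDER if lib in ids]
    extra = [i for i in ids if i not in LIBRARY_ORDER]
    order += extra
    by_id = {r.library_id: r for r in results}
    if gene_universe is None:
        genes: set[str] = set()
        for r in results:
            genes |= set(r.gene_tpm.index)
        gene_universe = sorted(genes)
    tpm = pd.DataFrame(index=pd.Index(gene_universe, name="gene_id"))
    counts = pd.DataFrame(index=tpm.index)
    totals = {}
    for lib in order:
        r = by_id[lib]
        tpm[str(lib)] = r.gene_tpm.reindex(gene_universe).fillna(0.0)
        counts[str(lib)] = r.gene_count.reindex(gene_universe).fillna(0).astype(int)
        totals[str(lib)] = r.reliable_total
    return ExpressionMatrix(tpm=tpm, counts=counts,
                            totals=pd.Series(totals, dtype=int),
                            expressed_threshold=expressed_threshold)


def detected_gene_sets(matrix: ExpressionMatrix, genotype: str) -> dict[str, object]:
    """Per-stage detected sets, the all-stage intersection, and the
    stage-specific (exactly-one-stage) sets for one genotype."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype: {genotype!r}")
    expressed = matrix.expressed()[matrix.columns_for(genotype)]
    per_stage = {s: set(expressed.index[expressed[str(LibraryId(genotype, s))]])
                 for s in STAGES}
    n_stages = expressed.sum(axis=1)
    detected_any = set(expressed.index[n_stages > 0])
    intersection = set(expressed.index[n_stages == 4])
    single = expressed.loc[n_stages == 1]
    stage_specific = {s: set(single.index[single[str(LibraryId(genotype, s))]])
                      for s in STAGES}
    return {
        "per_stage": per_stage,
        "detected": detected_any,
        "all_stages": intersection,
        "stage_specific": stage_specific,
    }
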