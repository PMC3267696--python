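"""Core domain containers shared across the pipeline stages.

The unit of analysis is the 21-nt DGE tag: a CATG restriction anchor plus
17 nt of downstream transcript sequence.  Libraries are identified by a
(genotype, stage) pair — WT/MT sweet orange sampled at 120/150/190/220
days after flowering (DAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

ANCHOR = "CATG"
TAG_LEN = 21
TAIL_LEN = TAG_LEN - len(ANCHOR)

GENOTYPES = ("WT", "MT")
STAGES = (120, 150, 190, 220)

#: Default adaptor 21-mer planted/filtered by the noise model and QC.
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"


class LibraryId(NamedTuple):
    """Identifier of one sequencing library: genotype x developmental stage."""

    genotype: str
    stage: int

    def __str__(self) -> str:  # e.g. "WT120"
        return f"{self.genotype}{self.stage}"

    @classmethod
    def parse(cls, text: str) -> "LibraryId":
        for g in GENOTYPES:
            if text.startswith(g):
                return cls(g, int(text[len(g):]))
        raise ValueError(f"not a library id: {text!r}")


#: Canonical column order: WT stages ascending, then MT stages ascending.
LIBRARY_ORDER = tuple(LibraryId(g, s) for g in GENOTYPES for s in STAGES)


@dataclass(frozen=True)
class ReferenceGene:
    """A unigene reference sequence hosting at least one anchored tag site."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"{self.gene_id}: sequence has non-ACGT characters")

    @property
    def canonical_tag(self) -> str | None:
        """The 3'-most anchored 21-mer on the sense strand (None if no site)."""
        pos = self.sequence.rfind(ANCHOR, 0, len(self.sequence) - TAIL_LEN)
        if pos < 0:
            return None
        return self.sequence[pos:pos + TAG_LEN]


@dataclass
class RawTagLibrary:
    """Raw tag stream of one library (may contain N's and adaptor copies)."""

    library_id: LibraryId
    tags: np.ndarray  # dtype S21, one element per sequenced tag

    def __post_init__(self) -> None:
        self.tags = np.asarray(self.tags, dtype=f"S{TAG_LEN}")

    @property
    def depth(self) -> int:
        return int(self.tags.shape[0])


@dataclass
class TagCountTable:
    """Distinct tags of one library with counts and (post-QC) TPM."""

    library_id: LibraryId
    table: pd.DataFrame  # columns: tag (str), count (int), tpm (float or NaN)

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    @property
    def n_distinct(self) -> int:
        return int(len(self.table))


@dataclass(frozen=True)
class LibrarySummary:
    """One library's QC ledger (the Table-1-style row)."""

    library_id: LibraryId
    total_sequences: int
    low_quality_count: int
    reliable_count: int
    distinct_count: int

    @property
    def low_quality_pct(self) -> float:
        return _round_half_up_pct(self.low_quality_count, self.total_sequences)

    @property
    def reliable_pct(self) -> float:
        return _round_half_up_pct(self.reliable_count, self.total_sequences)

    @property
    def distinct_pct(self) -> float:
        return _round_half_up_pct(self.distinct_count, self.total_sequences)


def _round_half_up_pct(num: int, den: int) -> float:
    """Percentage num/den rounded half-up to 2 decimal places."""
    if den == 0:
        return 0.0
    x = 100.0 * num / den
    return float(np.floor(x * 100 + 0.5) / 100)


@dataclass
class MappingResult:
    """Tag->gene mapping outcome for one library."""

    library_id: LibraryId
    mapped_tag_pct: float
    unambiguous_tag_pct: float
    gene_tpm: pd.Series     # index gene_id, unambiguous-tag TPM sums
    gene_count: pd.Series   # index gene_id, unambiguous-tag raw counts
    reliable_total: int     # post-QC library size (the TPM denominator)


@dataclass
class ExpressionMatrix:
    """Gene x library TPM (and count) matrix from unambiguous mappings."""

    tpm: pd.DataFrame     # genes x libraries (columns: str(LibraryId))
    counts: pd.DataFrame  # same shape, raw unambiguous tag counts
    totals: pd.Series     # reliable library totals, index like columns
    expressed_threshold: float = 3.0

    def columns_for(self, genotype: str) -> list[str]:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype: {genotype!r}")
        return [str(LibraryId(genotype, s)) for s in STAGES]

    def expressed(self) -> pd.DataFrame:
        """Boolean detection mask: TPM >= expressed_threshold."""
        return self.tpm >= self.expressed_threshold


@dataclass
class DERecord:
    """Per-gene two-library comparison."""

    gene_id: str
    count_a: int
    count_b: int
    n_a: int
    n_b: int
    tpm_a: float
    tpm_b: float
    log2_ratio: float       # NaN when a side is zero
    presence_flag: str      # both / a_only / b_only
    ratio_report: str       # "1.58" or Table-2 style "6.59/0" / "0/3.43"
    z: float
    p: float
    call: str               # up / down / none


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation result for one GO term."""

    term_id: str
    namespace: str
    term_name: str
    k: int  # annotated study hits
    n: int  # annotated study size
    K: int  # annotated population hits
    N: int  # annotated population size
    p: float
    genes: tuple[str, ...]

    @property
    def cluster_frequency(self) -> float:
        """Percent of annotated study genes carrying the term."""
        return 100.0 * self.k / self.n if self.n else 0.0


@dataclass(frozen=True)
class ConcordanceFit:
    """OLS fit of RNA-seq log2 ratios on qRT-PCR log2 ratios."""

    slope: float
    intercept: float
    r: float
    n: int


@dataclass
class TruthTable:
    """Planted ground truth of a synthetic design.

    ``genes`` columns: gene_id, group, shallow (bool), plus one design-scale
    expected-TPM column per library (``tpm_WT120`` ...) and one DE-flag
    column per stage (``de_120`` ... in {up, down, none}, MT relative to WT).
    ``planted_terms`` are the GO terms truly enriched among DE genes.
    """

    genes: pd.DataFrame
    planted_terms: set[str] = field(default_factory=set)

    @staticmethod
    def tpm_col(lib: LibraryId) -> str:
        return f"tpm_{lib}"

    def expected_tpm(self, lib: LibraryId | str) -> pd.Series:
        lib = LibraryId.parse(lib) if isinstance(lib, str) else lib
        return self.genes.set_index("gene_id")[self.tpm_col(lib)]

    def expected_matrix(self) -> pd.DataFrame:
        """Design-scale expectation, genes x 8 libraries."""
        cols = {str(l): self.genes[self.tpm_col(l)].to_numpy() for l in LIBRARY_ORDER}
        return pd.DataFrame(cols, index=self.genes["gene_id"])

    def asymptotic_tpm(self) -> pd.DataFrame:
        """Large-depth TPM limit: the per-library closure of the design.

        Tag sampling is multinomial in each library, so realized TPM converges
        to the design intensity renormalised to 1e6 per library column.
        """
        m = self.expected_matrix()
        return m * (1e6 / m.sum(axis=0))

    def de_genes(self) -> pd.Index:
        """Genes planted as MT-vs-WT differential at any stage."""
        flags = self.genes[[f"de_{s}" for s in STAGES]]
        return pd.Index(self.genes.loc[(flags != "none").any(axis=1), "gene_id"])


def as_tag_array(tags: Iterable[str | bytes]) -> np.ndarray:
    """Coerce an iterable of 21-nt tags to the canonical S21 array form."""
    arr = np.asarray(list(tags) if not isinstance(tags, np.ndarray) else tags,
                     dtype=f"S{TAG_LEN}")
    return arr
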