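"""Synthetic reference, ground truth and raw tag library generation.

The generator emulates an eight-library tag-profiling study — two genotypes
(WT and its bud-mutant MT) sampled at 120/150/190/220 DAF — with planted
expression-pattern groups, genotype fold changes, noise tags, and GO-term
enrichment among the differential genes, so that every downstream stage of
the pipeline can be scored against a known truth.

Tag chemistry is NlaIII-style: each transcript's observable tag is the
3'-most CATG-anchored 21-mer on the sense strand.  Noise mirrors the QC
filter taxonomy: tags containing ambiguous bases (N), copies of a fixed
adaptor 21-mer, and a small residual per-base substitution rate.

Expected TPM values in the truth table are on the *design* scale: sampling
within a library is multinomial over design intensities, so realized TPM
converges to the per-library closure (``TruthTable.asymptotic_tpm``).  The
default group weights are complement/reversal-paired across stages, which
keeps each library's intensity mass within a few percent of nominal and
the closure close to the design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patterns import (
    ASSIGNABLE_GROUPS,
    GROUP_MAX_AT_120,
    GROUP_MAX_AT_220,
    GROUP_PEAK_150,
    GROUP_PEAK_190,
    GROUP_SIGNATURES,
    GROUP_STABLE,
    GROUP_STRICT_DOWN,
    GROUP_STRICT_UP,
    GROUP_TROUGH_150,
    GROUP_TROUGH_190,
)
from .types import (
    ANCHOR,
    DEFAULT_ADAPTOR,
    GENOTYPES,
    STAGES,
    TAG_LEN,
    TAIL_LEN,
    LibraryId,
    RawTagLibrary,
    ReferenceGene,
    TruthTable,
)

_BASES = np.frombuffer(b"ACGT", dtype="u1")

#: Default pattern-group mix.  Weights are equal within complementary
#: signature pairs (e.g. present-only-120 vs absent-only-120) and within
#: time-reversed trend pairs, so the eight libraries carry near-equal tag
#: mass and TPM stays composition-stable.  The anchors echo the study's
#: census flavour: the strictly-increasing, absent-at-120 and
#: present-150+220 classes are the heavyweights.
DEFAULT_GROUP_WEIGHTS: dict[int, float] = {
    1: 0.08, 10: 0.08,
    2: 0.07, 7: 0.07,
    3: 0.025, 14: 0.025,
    4: 0.025, 13: 0.025,
    5: 0.025, 12: 0.025,
    6: 0.025, 11: 0.025,
    8: 0.025, 9: 0.025,
    GROUP_STABLE: 0.12,
    GROUP_STRICT_DOWN: 0.08, GROUP_STRICT_UP: 0.08,
    GROUP_MAX_AT_220: 0.025, GROUP_MAX_AT_120: 0.025,
    GROUP_PEAK_150: 0.03, GROUP_PEAK_190: 0.03,
    GROUP_TROUGH_150: 0.03, GROUP_TROUGH_190: 0.03,
}

#: Archetype stage multipliers for the non-monotone all-present classes,
#: in time-reversed pairs (mass balance across stages).
_RESIDUAL_SHAPES: dict[int, tuple[float, float, float, float]] = {
    GROUP_MAX_AT_220: (1.0, 2.2, 1.4, 3.5),
    GROUP_MAX_AT_120: (3.5, 1.4, 2.2, 1.0),
    GROUP_PEAK_150: (1.0, 3.0, 1.5, 1.2),
    GROUP_PEAK_190: (1.2, 1.5, 3.0, 1.0),
    GROUP_TROUGH_150: (3.0, 1.0, 1.5, 3.5),
    GROUP_TROUGH_190: (3.5, 1.5, 1.0, 3.0),
}

# Abundance tiers (TPM, log-uniform).  Floors sit well above the 3-TPM
# detection threshold so planted patterns are identifiable at the study's
# 2.5 M-tag depth; the shallow tier sits below it to exercise the filter.
PARTIAL_TPM_RANGE = (10.0, 3000.0)
TREND_TPM_RANGE = (100.0, 2000.0)
SHALLOW_TPM_RANGE = (0.5, 2.0)
STEP_RATIO_RANGE = (1.7, 2.3)

DEFAULT_LOWQ_RATE = 0.07
DEFAULT_ADAPTOR_RATE = 0.02
DEFAULT_ERROR_RATE = 0.001
DEFAULT_DEPTH = 2_500_000


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_reference(n_genes: int,
                       length_range: tuple[int, int] = (200, 3000),
                       seed: int = 0) -> list[ReferenceGene]:
    """Generate a unigene reference set with guaranteed anchored tag sites.

    Every sequence contains at least one CATG with >= 17 nt downstream; a
    site is planted when the random sequence happens to lack one.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    lo, hi = length_range
    if hi < TAG_LEN + len(ANCHOR):
        raise ValueError(f"length_range upper bound must be >= {TAG_LEN + len(ANCHOR)}")
    lo = max(lo, TAG_LEN + len(ANCHOR))
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if seq.rfind(ANCHOR, 0, length - TAIL_LEN) < 0:
            pos = int(rng.integers(0, length - TAG_LEN + 1))
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR):]
        genes.append(ReferenceGene(f"G{i + 1:0{width}d}", seq))
    return genes


def _profile_for_group(rng: np.random.Generator, group: int, shallow: bool) -> np.ndarray:
    """Design-scale WT expected TPM over the four stages for one gene."""
    if group in GROUP_SIGNATURES:  # partial presence, flat where present
        mask = np.array([c == "1" for c in GROUP_SIGNATURES[group]], dtype=float)
        lo, hi = SHALLOW_TPM_RANGE if shallow else PARTIAL_TPM_RANGE
        return mask * _log_uniform(rng, lo, hi)

    # all-present trend classes
    if group == GROUP_STABLE:
        shape = np.ones(4)
    elif group in (GROUP_STRICT_UP, GROUP_STRICT_DOWN):
        steps = rng.uniform(*STEP_RATIO_RANGE, size=3)
        shape = np.concatenate([[1.0], np.cumprod(steps)])
        if group == GROUP_STRICT_DOWN:
            shape = shape[::-1]
    else:
        base = np.asarray(_RESIDUAL_SHAPES[group])
        shape = base * np.exp(rng.uniform(-0.05, 0.05, size=4))
    shape = shape / shape.mean()
    if shallow:
        # shallow genes stay flat below the filter regardless of class
        return np.full(4, _log_uniform(rng, *SHALLOW_TPM_RANGE))
    return shape * _log_uniform(rng, *TREND_TPM_RANGE)


def design_truth(n_genes: int,
                 group_weights: dict[int, float] | None = None,
                 de_fraction: float = 0.1,
                 fc_range: tuple[float, float] = (1.5, 2.5),
                 seed: int = 0,
                 shallow_fraction: float = 0.05,
                 de_down_fraction: float = 0.5) -> TruthTable:
    """Draw the planted design: groups, expected TPM per library, DE flags.

    ``de_fraction`` of non-shallow genes carry a genotype effect: the MT
    profile is the WT profile scaled by 2**f at every present stage, with
    |f| = |log2 fold change| drawn uniformly from ``fc_range`` (>= 1 so
    every flagged gene clears the call threshold by design) and direction
    down (MT < WT) with probability ``de_down_fraction``.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if fc_range[0] < 1.0:
        raise ValueError("planted |log2 fold changes| must be >= 1")
    weights = dict(group_weights or DEFAULT_GROUP_WEIGHTS)
    bad = set(weights) - set(ASSIGNABLE_GROUPS)
    if bad:
        raise ValueError(f"unassignable groups in weights: {sorted(bad)}")
    w = np.array(list(weights.values()), dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("group weights must sum to 1")

    rng = np.random.default_rng(seed)
    group_ids = np.array(list(weights.keys()))
    groups = rng.choice(group_ids, size=n_genes, p=w / w.sum())
    shallow = rng.random(n_genes) < shallow_fraction

    wt = np.stack([_profile_for_group(rng, int(g), bool(s))
                   for g, s in zip(groups, shallow)])
    mt = wt.copy()

    is_de = (rng.random(n_genes) < de_fraction) & ~shallow
    direction = np.where(rng.random(n_genes) < de_down_fraction, "down", "up")
    lfc = rng.uniform(*fc_range, size=n_genes)
    factor = np.where(direction == "up", 2.0 ** lfc, 2.0 ** -lfc)
    mt[is_de] = mt[is_de] * factor[is_de, None]

    # nominal per-million design scale (shared across libraries so that
    # cross-library ratios are untouched)
    col_sums = np.concatenate([wt.sum(axis=0), mt.sum(axis=0)])
    scale = 1e6 / col_sums.mean()
    wt *= scale
    mt *= scale

    width = len(str(n_genes))
    data: dict[str, object] = {
        "gene_id": [f"G{i + 1:0{width}d}" for i in range(n_genes)],
        "group": groups.astype(int),
        "shallow": shallow,
    }
    for j, stage in enumerate(STAGES):
        data[TruthTable.tpm_col(LibraryId("WT", stage))] = wt[:, j]
    for j, stage in enumerate(STAGES):
        data[TruthTable.tpm_col(LibraryId("MT", stage))] = mt[:, j]
    for j, stage in enumerate(STAGES):
        present = wt[:, j] > 0
        data[f"de_{stage}"] = np.where(is_de & present, direction, "none")
    return TruthTable(genes=pd.DataFrame(data))


def _random_acgt(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=(n, TAG_LEN))]


def _apply_substitutions(rng: np.random.Generator, tags: np.ndarray,
                         error_rate: float) -> np.ndarray:
    """Per-base substitution errors; each hit becomes a different base."""
    if error_rate <= 0 or tags.size == 0:
        return tags
    mat = np.frombuffer(tags.tobytes(), dtype="u1").reshape(-1, TAG_LEN).copy()
    mask = rng.random(mat.shape, dtype=np.float32) < error_rate
    n_hits = int(mask.sum())
    if n_hits:
        # map A,C,G,T bytes to 0..3, shift by 1-3 mod 4, map back
        lut = np.zeros(256, dtype="u1")
        lut[_BASES] = np.arange(4)
        idx = lut[mat[mask]]
        mat[mask] = _BASES[(idx + rng.integers(1, 4, size=n_hits)) % 4]
    return np.frombuffer(mat.tobytes(), dtype=f"S{TAG_LEN}")


def simulate_library(truth: TruthTable,
                     reference: list[ReferenceGene],
                     library_id: LibraryId | str,
                     depth: int = DEFAULT_DEPTH,
                     lowq_rate: float = DEFAULT_LOWQ_RATE,
                     adaptor_rate: float = DEFAULT_ADAPTOR_RATE,
                     error_rate: float = DEFAULT_ERROR_RATE,
                     seed: int = 0,
                     adaptor: str = DEFAULT_ADAPTOR) -> RawTagLibrary:
    """Draw one raw library of exactly ``depth`` 21-nt tags.

    Clean tags are each gene's canonical tag, drawn multinomially with
    probabilities proportional to the library's expected TPM; planted noise
    is N-containing tags (~``lowq_rate``), adaptor copies (~``adaptor_rate``)
    and residual per-base substitutions at ``error_rate``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for name, rate in (("lowq_rate", lowq_rate), ("adaptor_rate", adaptor_rate),
                       ("error_rate", error_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    lib = LibraryId.parse(library_id) if isinstance(library_id, str) else library_id

    ref_by_id = {g.gene_id: g for g in reference}
    missing = set(truth.genes["gene_id"]) - set(ref_by_id)
    if missing:
        raise ValueError(f"truth genes absent from reference: {sorted(missing)[:5]}")

    expected = truth.expected_tpm(lib)
    tag_list, intensity = [], []
    for gene_id, tpm in expected.items():
        if tpm <= 0:
            continue
        tag = ref_by_id[gene_id].canonical_tag
        if tag is None:
            raise ValueError(f"reference gene {gene_id} has no anchored tag site")
        tag_list.append(tag.encode())
        intensity.append(tpm)
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size == 0:
        raise ValueError(f"no gene is expressed in library {lib}")

    rng = np.random.default_rng(seed)
    n_lowq, n_adaptor, n_clean = rng.multinomial(
        depth, [lowq_rate, adaptor_rate, 1.0 - lowq_rate - adaptor_rate])

    gene_counts = rng.multinomial(n_clean, intensity / intensity.sum())
    clean = np.repeat(np.array(tag_list, dtype=f"S{TAG_LEN}"), gene_counts)
    clean = _apply_substitutions(rng, clean, error_rate)

    lowq = _random_acgt(rng, n_lowq)
    if n_lowq:
        n_mask = rng.random(lowq.shape) < 0.08
        none = ~n_mask.any(axis=1)
        n_mask[none, rng.integers(0, TAG_LEN, size=int(none.sum()))] = True
        lowq[n_mask] = ord("N")
    lowq = np.frombuffer(lowq.tobytes(), dtype=f"S{TAG_LEN}")

    adaptor_tags = np.full(n_adaptor, adaptor.encode(), dtype=f"S{TAG_LEN}")

    tags = np.concatenate([clean, lowq, adaptor_tags])
    tags = tags[rng.permutation(depth)]
    return RawTagLibrary(library_id=lib, tags=tags)


def simulate_all_libraries(truth: TruthTable,
                           reference: list[ReferenceGene],
                           depth: int = DEFAULT_DEPTH,
                           seed: int = 0,
                           **noise) -> dict[LibraryId, RawTagLibrary]:
    """Simulate the full eight-library design with per-library child seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(len(GENOTYPES) * len(STAGES))
    out = {}
    for child_seed, lib in zip(seeds, (LibraryId(g, s) for g in GENOTYPES for s in STAGES)):
        out[lib] = simulate_library(truth, reference, lib, depth=depth,
                                    seed=int(child_seed) % (2**31), **noise)
    return out


_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


def emit_go_annotation(truth: TruthTable,
                       n_terms: int = 30,
                       planted_term_fraction_in_de: float = 0.5,
                       background_fraction: float = 0.05,
                       seed: int = 0,
                       n_planted: int = 2) -> pd.DataFrame:
    """Emit a gene->GO table with terms planted among the DE genes.

    Planted terms annotate DE genes at ``planted_term_fraction_in_de`` and
    all other genes at ``background_fraction``; the remaining terms annotate
    every gene at the background rate (setting the planted fraction equal to
    the background yields a null annotation with no truly enriched term).
    Updates ``truth.planted_terms`` in place and returns the long table
    (gene_id, term_id, namespace, term_name).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    for name, frac in (("planted_term_fraction_in_de", planted_term_fraction_in_de),
                       ("background_fraction", background_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    n_planted = min(n_planted, n_terms)
    rng = np.random.default_rng(seed)
    gene_ids = truth.genes["gene_id"].to_numpy()
    is_de = np.isin(gene_ids, truth.de_genes().to_numpy())

    rows = []
    planted: set[str] = set()
    for t in range(n_terms):
        term_id = f"GO:{t + 1:07d}"
        namespace = _NAMESPACES[t % len(_NAMESPACES)]
        name = f"synthetic term {t + 1}"
        if t < n_planted:
            prob = np.where(is_de, planted_term_fraction_in_de, background_fraction)
            if planted_term_fraction_in_de > background_fraction:
                planted.add(term_id)
        else:
            prob = np.full(len(gene_ids), background_fraction)
        hit = rng.random(len(gene_ids)) < prob
        rows.extend((g, term_id, namespace, name) for g in gene_ids[hit])
    truth.planted_terms = planted
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace", "term_name"])


def simulate_qpcr(truth: TruthTable,
                  gene_ids: list[str],
                  replicates: int = 3,
                  ct_sd: float = 0.25,
                  bias_sd: float = 0.9,
                  ref_ct: float = 20.0,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table for selected genes over all 8 samples.

    The target Ct tracks -log2(expression); a per-(gene, MT sample)
    distortion of sd ``bias_sd`` (log2 units) models platform discordance
    between qPCR and tag counting, and each well gets technical noise of sd
    ``ct_sd`` cycles.  The reference (actin-style) gene is flat at
    ``ref_ct``.  Columns: gene_id, sample_id, ct_target, ct_reference,
    replicate.
    """
    rng = np.random.default_rng(seed)
    asym = truth.asymptotic_tpm()
    rows = []
    for gene in gene_ids:
        offset = rng.uniform(0.0, 5.0)
        for g in GENOTYPES:
            for stage in STAGES:
                lib = str(LibraryId(g, stage))
                expr = max(float(asym.loc[gene, lib]), 1e-3)
                log2_expr = np.log2(expr)
                if g == "MT":
                    log2_expr += rng.normal(0.0, bias_sd)
                for rep in range(1, replicates + 1):
                    rows.append((gene, lib,
                                 ref_ct + offset - log2_expr + rng.normal(0, ct_sd),
                                 ref_ct + rng.normal(0, ct_sd),
                                 rep))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "ct_target",
                                       "ct_reference", "replicate"])
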