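"""End-to-end orchestration: simulate -> QC -> map -> patterns -> DE ->
enrichment -> concordance, with serialisable configuration and a checksum
manifest for byte-level reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import de as de_mod
from . import enrichment as enr
from . import io as tio
from . import mapping as map_mod
from . import patterns as pat
from . import simulate as sim
from . import tags as tags_mod
from .types import (
    DEFAULT_ADAPTOR,
    GENOTYPES,
    LIBRARY_ORDER,
    STAGES,
    ExpressionMatrix,
    LibraryId,
    TruthTable,
)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    n_genes: int = 1000
    depth: int = 500_000
    de_fraction: float = 0.1
    shallow_fraction: float = 0.05
    lowq_rate: float = sim.DEFAULT_LOWQ_RATE
    adaptor_rate: float = sim.DEFAULT_ADAPTOR_RATE
    error_rate: float = sim.DEFAULT_ERROR_RATE
    adaptor: str = DEFAULT_ADAPTOR
    tpm_min: float = 3.0
    expressed_threshold: float = 3.0
    p_threshold: float = 0.05
    lfc_min: float = 1.0
    fold_screen: float = 2.0
    strands: str = "both"
    stable_fold: float = 1.5
    n_go_terms: int = 30
    n_qpcr_genes: int = 22
    reference_fasta: str | None = None  # optional pre-existing inputs
    tag_dir: str | None = None
    annotation_tsv: str | None = None

    def __post_init__(self) -> None:
        for name in ("tpm_min", "expressed_threshold", "p_threshold",
                     "lfc_min", "fold_screen", "stable_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """In-memory products of one full run."""

    truth: TruthTable | None
    summaries: dict[str, object]
    range_report: dict[str, float | int]
    matrix: ExpressionMatrix
    mapping: dict[str, object]
    assignments: dict[str, list]
    censuses: dict[str, pd.DataFrame]
    taxonomy_comparison: pd.DataFrame
    stage_de: dict[str, pd.DataFrame]
    genotype_de: dict[int, pd.DataFrame]
    genotype_tallies: dict[int, dict[str, int]]
    de_profiles: dict[str, object]
    enrichment: dict[int, pd.DataFrame]
    concordance_fit: conc.ConcordanceFit | None
    annotation: pd.DataFrame = field(default=None)


def _load_inputs(config: PipelineConfig):
    """Simulate inputs, or load them when the config points at files."""
    if config.reference_fasta is not None:
        for name in ("reference_fasta", "tag_dir", "annotation_tsv"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} missing or not found: {p}")
        reference = tio.read_fasta(config.reference_fasta)
        libraries = {}
        for lib in LIBRARY_ORDER:
            path = Path(config.tag_dir) / f"{lib}.tags.txt"
            if not path.exists():
                raise FileNotFoundError(f"tag file not found: {path}")
            libraries[lib] = tio.read_tags(path, lib)
        annotation = tio.read_tsv(config.annotation_tsv)
        return None, reference, libraries, annotation

    reference = sim.generate_reference(config.n_genes, seed=config.seed)
    truth = sim.design_truth(config.n_genes, de_fraction=config.de_fraction,
                             shallow_fraction=config.shallow_fraction,
                             seed=config.seed + 1)
    libraries = sim.simulate_all_libraries(
        truth, reference, depth=config.depth, seed=config.seed + 2,
        lowq_rate=config.lowq_rate, adaptor_rate=config.adaptor_rate,
        error_rate=config.error_rate, adaptor=config.adaptor)
    annotation = sim.emit_go_annotation(truth, n_terms=config.n_go_terms,
                                        seed=config.seed + 3)
    return truth, reference, libraries, annotation


def run_analysis(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in memory and return the products."""
    truth, reference, libraries, annotation = _load_inputs(config)

    clean_tables, summaries = {}, {}
    for lib, raw in libraries.items():
        counted = tags_mod.count_tags(raw)
        clean, summary = tags_mod.qc_filter(counted, adaptor=config.adaptor,
                                            tpm_min=config.tpm_min)
        clean_tables[lib] = clean
        summaries[str(lib)] = summary
    range_report = tags_mod.summarize_libraries(list(summaries.values()))

    index = map_mod.build_tag_index(reference, strands=config.strands)
    results = [map_mod.map_library(clean_tables[lib], index) for lib in libraries]
    matrix = map_mod.assemble_matrix(
        results, gene_universe=[g.gene_id for g in reference],
        expressed_threshold=config.expressed_threshold)
    mapping_summary = {
        str(r.library_id): {"mapped_pct": r.mapped_tag_pct,
                            "unambiguous_pct": r.unambiguous_tag_pct}
        for r in results}

    assignments, censuses = {}, {}
    for g in GENOTYPES:
        a, census, _excluded = pat.classify_patterns(matrix, g,
                                                     stable_fold=config.stable_fold)
        assignments[g], censuses[g] = a, census
    taxonomy_cmp = pat.compare_taxonomies(censuses["WT"], censuses["MT"])

    stage_de = de_mod.compare_stages(matrix, "WT", p_threshold=config.p_threshold,
                                     lfc_min=config.lfc_min)
    genotype_de, tallies, de_sets = {}, {}, {}
    for s in STAGES:
        df, tally = de_mod.compare_genotypes(matrix, s, fold_screen=config.fold_screen,
                                             p_threshold=config.p_threshold,
                                             lfc_min=config.lfc_min)
        genotype_de[s], tallies[s] = df, tally
        de_sets[s] = set(df.loc[df["call"] != "none", "gene_id"]) if len(df) else set()
    de_profiles = de_mod.de_profile_clustering(de_sets, matrix)

    go = enr.GOAnnotation(annotation)
    detected = set(matrix.tpm.index[(matrix.expressed()).any(axis=1)])
    enrichment = {}
    for s in STAGES:
        recs = enr.hypergeom_enrichment(de_sets[s], detected, go,
                                        p_threshold=config.p_threshold)
        enrichment[s] = enr.records_to_frame(recs)

    fit = None
    if truth is not None:
        fit = _qpcr_concordance(truth, matrix, de_sets, config)

    return PipelineResult(truth=truth, summaries=summaries, range_report=range_report,
                          matrix=matrix, mapping=mapping_summary,
                          assignments=assignments, censuses=censuses,
                          taxonomy_comparison=taxonomy_cmp, stage_de=stage_de,
                          genotype_de=genotype_de, genotype_tallies=tallies,
                          de_profiles=de_profiles, enrichment=enrichment,
                          concordance_fit=fit, annotation=annotation)


def _qpcr_concordance(truth: TruthTable, matrix: ExpressionMatrix,
                      de_sets: dict[int, set[str]],
                      config: PipelineConfig) -> conc.ConcordanceFit | None:
    """Validate a panel of called-DE genes against simulated qRT-PCR."""
    called = sorted(set().union(*de_sets.values()))
    panel = called[:config.n_qpcr_genes]
    if len(panel) < 3:
        return None
    qpcr = sim.simulate_qpcr(truth, panel, seed=config.seed + 4)
    floor = config.expressed_threshold / 2.0
    rna_rows, q_rows = [], []
    for s in STAGES:
        wt_lib, mt_lib = str(LibraryId("WT", s)), str(LibraryId("MT", s))
        rel = conc.relative_expression(qpcr[qpcr["sample_id"].isin([wt_lib, mt_lib])],
                                       calibrator_sample=wt_lib)
        mt_level = rel[rel["sample_id"] == mt_lib].set_index("gene_id")["level"]
        for gene in panel:
            wt = max(float(matrix.tpm.loc[gene, wt_lib]), floor)
            mt = max(float(matrix.tpm.loc[gene, mt_lib]), floor)
            rna_rows.append(np.log2(mt / wt))
            q_rows.append(np.log2(max(float(mt_level[gene]), 1e-6)))
    return conc.regression_concordance(np.array(rna_rows), np.array(q_rows))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage and write the output directory with a manifest.

    Identical config and seed produce byte-identical outputs (and hence an
    identical manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_analysis(config)

    config.to_yaml(out / "config.yaml")

    summary_rows = []
    for lib in LIBRARY_ORDER:
        s = result.summaries[str(lib)]
        summary_rows.append({
            "library": str(lib), "total_sequences": s.total_sequences,
            "low_quality": s.low_quality_count, "low_quality_pct": s.low_quality_pct,
            "reliable": s.reliable_count, "reliable_pct": s.reliable_pct,
            "distinct": s.distinct_count, "distinct_pct": s.distinct_pct,
        })
    tio.write_tsv(pd.DataFrame(summary_rows), out / "library_summary.tsv")

    tio.write_tsv(pd.DataFrame([
        {"library": lib, **vals} for lib, vals in result.mapping.items()
    ]), out / "mapping_summary.tsv")

    tio.write_tsv(result.matrix.tpm.reset_index(), out / "expression_matrix.tsv",
                  float_format="%.6g")

    for g in GENOTYPES:
        tio.write_tsv(pd.DataFrame([a.__dict__ for a in result.assignments[g]]),
                      out / f"patterns_{g}.tsv")
        tio.write_tsv(result.censuses[g], out / f"pattern_census_{g}.tsv")
    tio.write_tsv(result.taxonomy_comparison, out / "taxonomy_comparison.tsv")

    for name, df in result.stage_de.items():
        tio.write_tsv(df, out / f"de_stages_WT_{name}.tsv")
    for s, df in result.genotype_de.items():
        tio.write_tsv(df, out / f"de_genotype_{s}.tsv")
    tio.write_tsv(pd.DataFrame([
        {"stage": s, **result.genotype_tallies[s]} for s in STAGES
    ]), out / "de_tally.tsv")

    for s, df in result.enrichment.items():
        tio.write_tsv(df, out / f"enrichment_{s}.tsv")

    if result.concordance_fit is not None:
        f = result.concordance_fit
        tio.write_tsv(pd.DataFrame([{"slope": f.slope, "intercept": f.intercept,
                                     "r": f.r, "n": f.n}]),
                      out / "concordance_fit.tsv", float_format="%.10g")

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
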