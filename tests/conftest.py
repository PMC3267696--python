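"""Shared fixtures: one full-scale synthetic study, reused across suites.

The heavyweight session fixtures simulate the standard design — 1,000
genes, eight libraries of 2.5 M tags, default noise — once, and a matching
noise-free WT half-design for the sampling-only properties.
"""

from __future__ import annotations

import numpy as np
import pytest

from tagdge import (
    LibraryId,
    assemble_matrix,
    build_tag_index,
    count_tags,
    design_truth,
    generate_reference,
    map_library,
    qc_filter,
    simulate_library,
)
from tagdge.pipeline import PipelineConfig, run_analysis
from tagdge.types import STAGES

SEED = 11
N_GENES = 1000
DEPTH = 2_500_000


@pytest.fixture(scope="session")
def study_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, n_genes=N_GENES, depth=DEPTH)


@pytest.fixture(scope="session")
def study(study_config):
    """Full default-noise run of the standard eight-library design."""
    return run_analysis(study_config)


@pytest.fixture(scope="session")
def study_truth(study_config):
    """The standard design's ground truth (regenerated deterministically)."""
    return design_truth(study_config.n_genes, seed=study_config.seed + 1)


@pytest.fixture(scope="session")
def study_reference(study_config):
    return generate_reference(study_config.n_genes, seed=study_config.seed)


@pytest.fixture(scope="session")
def noisefree_wt_matrix(study_truth, study_reference):
    """WT half-design at full depth with all noise channels off."""
    index = build_tag_index(study_reference)
    results = []
    for i, s in enumerate(STAGES):
        raw = simulate_library(study_truth, study_reference, LibraryId("WT", s),
                               depth=DEPTH, lowq_rate=0.0, adaptor_rate=0.0,
                               error_rate=0.0, seed=1000 + i)
        clean, _ = qc_filter(count_tags(raw))
        results.append(map_library(clean, index))
    return assemble_matrix(results,
                           gene_universe=[g.gene_id for g in study_reference])


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(60, length_range=(200, 800), seed=5)


@pytest.fixture(scope="session")
def small_truth():
    return design_truth(60, de_fraction=0.2, seed=6)
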