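"""Generator invariants: anchors, determinism, planted structure, noise."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from tagdge import (
    LibraryId,
    count_tags,
    design_truth,
    emit_go_annotation,
    generate_reference,
    simulate_library,
)
from tagdge.io import write_fasta
from tagdge.simulate import simulate_qpcr
from tagdge.types import ANCHOR, STAGES, TAG_LEN, TruthTable


class TestGenerateReference:
    def test_every_gene_has_an_anchored_site(self):
        for gene in generate_reference(2, seed=1):
            tag = gene.canonical_tag
            assert tag is not None and tag.startswith(ANCHOR) and len(tag) == TAG_LEN

    def test_fasta_output_is_byte_identical_across_runs(self, tmp_path):
        paths = []
        for run in (1, 2):
            genes = generate_reference(100, seed=7)
            p = tmp_path / f"run{run}.fa"
            write_fasta(genes, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_all_anchored_windows_are_wellformed_21mers(self):
        # scan every sequence by hand for CATG+17 windows
        for gene in generate_reference(50, seed=3):
            seq = gene.sequence
            windows = [seq[i:i + TAG_LEN] for i in range(len(seq) - TAG_LEN + 1)
                       if seq[i:i + 4] == ANCHOR]
            assert windows, gene.gene_id
            assert all(len(w) == TAG_LEN and w.startswith(ANCHOR) for w in windows)
            assert gene.canonical_tag == windows[-1]

    def test_rejects_impossible_length_range(self):
        with pytest.raises(ValueError):
            generate_reference(5, length_range=(10, 24), seed=0)


class TestDesignTruth:
    def test_pure_increasing_design_increases_at_every_gene(self):
        truth = design_truth(50, group_weights={20: 1.0}, seed=1,
                             shallow_fraction=0.0)
        m = truth.expected_matrix()
        wt = m[[f"WT{s}" for s in STAGES]].to_numpy()
        assert np.all(np.diff(wt, axis=1) > 0)

    def test_absent_at_120_group_is_flat_elsewhere(self):
        truth = design_truth(40, group_weights={10: 1.0}, seed=2,
                             shallow_fraction=0.0)
        m = truth.expected_matrix()
        assert (m["WT120"] == 0).all()
        later = m[[f"WT{s}" for s in STAGES[1:]]].to_numpy()
        assert np.all(later > 0)
        assert np.allclose(later, later[:, :1])  # equal positive value

    def test_de_fraction_within_binomial_99ci(self):
        n, frac = 1000, 0.1
        truth = design_truth(n, de_fraction=frac, seed=5, shallow_fraction=0.0)
        k = len(truth.de_genes())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, frac)
        assert lo <= k <= hi

    def test_flagged_genes_have_design_lfc_at_least_one(self):
        truth = design_truth(300, de_fraction=0.3, seed=9, shallow_fraction=0.0)
        m = truth.expected_matrix()
        for _, row in truth.genes.iterrows():
            for s in STAGES:
                flag = row[f"de_{s}"]
                if flag == "none":
                    continue
                wt = m.loc[row["gene_id"], f"WT{s}"]
                mt = m.loc[row["gene_id"], f"MT{s}"]
                lfc = np.log2(mt / wt)
                assert abs(lfc) >= 1.0
                assert (lfc > 0) == (flag == "up")

    def test_absent_stages_have_zero_expectation(self):
        from tagdge.patterns import GROUP_SIGNATURES

        truth = design_truth(400, seed=3)
        m = truth.expected_matrix()
        for _, row in truth.genes.iterrows():
            sig = GROUP_SIGNATURES.get(int(row["group"]), "1111")
            for bit, s in zip(sig, STAGES):
                v = m.loc[row["gene_id"], f"WT{s}"]
                assert (v == 0) == (bit == "0")

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            design_truth(10, group_weights={20: 0.5, 10: 0.3}, seed=0)


class TestSimulateLibrary:
    def test_noise_free_library_contains_only_canonical_tags(self, small_truth,
                                                             small_reference):
        raw = simulate_library(small_truth, small_reference, "WT150",
                               depth=50_000, lowq_rate=0, adaptor_rate=0,
                               error_rate=0, seed=4)
        canonical = {g.canonical_tag.encode() for g in small_reference}
        assert set(np.unique(raw.tags)) <= canonical

    def test_depth_is_conserved_exactly(self, small_truth, small_reference):
        raw = simulate_library(small_truth, small_reference, "MT190",
                               depth=12_345, seed=5)
        assert raw.depth == 12_345
        assert count_tags(raw).total == 12_345

    def test_low_quality_fraction_within_binomial_99ci(self, small_truth,
                                                       small_reference):
        depth, rate = 500_000, 0.09
        raw = simulate_library(small_truth, small_reference, "WT120",
                               depth=depth, lowq_rate=rate, adaptor_rate=0,
                               error_rate=0, seed=6)
        n_with_n = int(np.char.count(raw.tags.astype(str), "N").astype(bool).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], depth, rate)
        assert lo <= n_with_n <= hi

    def test_same_seed_gives_identical_tag_stream(self, small_truth, small_reference):
        a = simulate_library(small_truth, small_reference, "WT220", depth=20_000, seed=9)
        b = simulate_library(small_truth, small_reference, "WT220", depth=20_000, seed=9)
        assert np.array_equal(a.tags, b.tags)

    def test_absent_stage_yields_zero_canonical_counts(self, small_reference):
        # half the genes absent at 120 DAF, half stably expressed
        truth = design_truth(60, group_weights={10: 0.5, 16: 0.5}, seed=6,
                             shallow_fraction=0.0)
        raw = simulate_library(truth, small_reference, "WT120", depth=10_000,
                               lowq_rate=0, adaptor_rate=0, error_rate=0, seed=7)
        ref = {g.gene_id: g for g in small_reference}
        absent = truth.genes.loc[truth.genes["group"] == 10, "gene_id"]
        absent_tags = {ref[g].canonical_tag.encode() for g in absent}
        assert not absent_tags & set(np.unique(raw.tags))

    def test_rejects_gene_missing_from_reference(self, small_truth, small_reference):
        with pytest.raises(ValueError, match="absent from reference"):
            simulate_library(small_truth, small_reference[:-5], "WT120",
                             depth=100, seed=0)


def test_empirical_tpm_converges_to_asymptotic_expectation(
        study_truth, noisefree_wt_matrix):
    """Sampling-only simulation at full depth recovers the design closure:
    no gene deviates beyond multinomial sampling noise (|z| < 6 on expected
    counts) and the typical relative error at >= 50 TPM is well under 5%."""
    asym = study_truth.asymptotic_tpm()
    for s in STAGES:
        col = f"WT{s}"
        expected = asym[col]
        observed = noisefree_wt_matrix.tpm[col].reindex(expected.index)
        n = noisefree_wt_matrix.totals[col]
        mu = expected * n / 1e6  # expected counts
        strong = expected >= 50
        z = (observed[strong] - expected[strong]) * n / 1e6 / np.sqrt(mu[strong])
        assert np.abs(z).max() < 6, f"{col}: worst studentized error {np.abs(z).max():.2f}"
        rel = np.abs(observed[strong] - expected[strong]) / expected[strong]
        assert np.median(rel) < 0.05, f"{col}: median relative error {np.median(rel):.3f}"


class TestGoAnnotation:
    def test_null_annotation_plants_no_term(self, small_truth):
        emit_go_annotation(small_truth, planted_term_fraction_in_de=0.05,
                           background_fraction=0.05, seed=1)
        assert small_truth.planted_terms == set()

    def test_planted_term_reaches_expected_study_frequency(self):
        truth = design_truth(1000, de_fraction=0.1, seed=8, shallow_fraction=0.0)
        table = emit_go_annotation(truth, planted_term_fraction_in_de=0.5,
                                   background_fraction=0.05, seed=2, n_planted=1)
        de = set(truth.de_genes())
        term = next(iter(truth.planted_terms))
        carriers = set(table.loc[table["term_id"] == term, "gene_id"])
        freq = len(carriers & de) / len(de)
        lo, hi = stats.binom.ppf([0.005, 0.995], len(de), 0.5) / len(de)
        assert lo <= freq <= hi

    def test_fixed_seed_gives_identical_table(self, small_truth):
        a = emit_go_annotation(small_truth, seed=3)
        b = emit_go_annotation(small_truth, seed=3)
        assert a.equals(b)

    def test_zero_terms_rejected(self, small_truth):
        with pytest.raises(ValueError):
            emit_go_annotation(small_truth, n_terms=0, seed=0)


def test_qpcr_table_shape_and_determinism(small_truth):
    genes = list(small_truth.genes["gene_id"][:5])
    a = simulate_qpcr(small_truth, genes, replicates=3, seed=4)
    b = simulate_qpcr(small_truth, genes, replicates=3, seed=4)
    assert a.equals(b)
    assert len(a) == 5 * 8 * 3
    assert set(a["sample_id"]) == {str(LibraryId(g, s)) for g in ("WT", "MT")
                                   for s in STAGES}
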