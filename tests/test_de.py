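"""Z-test correctness, fold-change conventions, stage/genotype comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tagdge import compare_genotypes, compare_stages, fold_change, z_test
from tagdge.de import de_profile_clustering, test_gene
from tagdge.types import STAGES, ExpressionMatrix


def _matrix(tpm_rows, totals=None, genotypes=("WT", "MT")):
    cols = [f"{g}{s}" for g in genotypes for s in STAGES]
    tpm = pd.DataFrame(tpm_rows, index=cols).T
    totals = totals or {c: 10**6 for c in cols}
    totals = pd.Series(totals)
    counts = (tpm * totals / 1e6).round().astype(int)
    return ExpressionMatrix(tpm=tpm, counts=counts, totals=totals)


class TestZTest:
    def test_equal_proportions_give_null(self):
        z, p = z_test(10, 10**6, 10, 10**6)
        assert z == 0.0 and p == 1.0

    def test_both_empty_convention(self):
        assert z_test(0, 10**6, 0, 10**6) == (0.0, 1.0)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        za, pa = z_test(a, 10**6, b, 2 * 10**6)
        zb, pb = z_test(b, 2 * 10**6, a, 10**6)
        assert za == pytest.approx(-zb, abs=1e-12)
        assert pa == pytest.approx(pb, abs=1e-12)

    def test_matches_independent_pooled_implementation(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(1)
        for _ in range(1000):
            n_a, n_b = rng.integers(10**5, 10**7, size=2)
            a = int(rng.integers(0, 3000))
            b = int(rng.integers(0, 3000))
            if a == 0 and b == 0:
                continue
            z, p = z_test(a, int(n_a), b, int(n_b))
            z_ref, p_ref = proportions_ztest([a, b], [n_a, n_b])
            assert z == pytest.approx(z_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_within_tenfold_of_exact_conditional_test(self):
        # conditional on the total, counts are binomial: exact two-sided
        a, n_a, b, n_b = 10, 10**6, 40, 10**6
        _, p = z_test(a, n_a, b, n_b)
        exact = stats.binomtest(a, a + b, n_a / (n_a + n_b)).pvalue
        assert exact / 10 < p < exact * 10

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(2)
        n_a, n_b = 3 * 10**6, 4 * 10**6
        tpm = np.exp(rng.uniform(np.log(20), np.log(500), size=10_000))
        prop = tpm / 1e6
        rejected = 0
        for pr in prop:
            a = rng.binomial(n_a, pr)
            b = rng.binomial(n_b, pr)
            _, p = z_test(int(a), n_a, int(b), n_b)
            rejected += p < 0.05
        assert 0.04 <= rejected / 10_000 <= 0.06

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            z_test(5, 4, 0, 10)


class TestFoldChange:
    def test_positive_ratio_log2(self):
        lr, flag, report = fold_change(1.0, 4.94)
        assert lr == pytest.approx(np.log2(4.94))
        assert flag == "both" and report == "4.94"

    def test_equal_tpms_give_zero(self):
        lr, _, _ = fold_change(7.7, 7.7)
        assert lr == 0.0

    def test_one_sided_presence_report(self):
        lr, flag, report = fold_change(6.59, 0.0)
        assert np.isnan(lr) and flag == "a_only" and report == "6.59/0"
        lr, flag, report = fold_change(0.0, 3.43)
        assert flag == "b_only" and report == "0/3.43"

    def test_double_zero_degenerate(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)


class TestCompareStages:
    def test_null_design_false_positive_rate(self):
        # identical generating TPMs in both libraries of each pair
        rng = np.random.default_rng(3)
        n = 2000
        tpm = np.exp(rng.uniform(np.log(10), np.log(500), size=n))
        prop = tpm / tpm.sum()
        rows, cols = {}, [f"WT{s}" for s in STAGES]
        counts = {c: rng.multinomial(3 * 10**6, prop) for c in cols}
        tpm_tab = {c: counts[c] / 3e6 * 1e6 for c in cols}
        matrix = ExpressionMatrix(
            tpm=pd.DataFrame(tpm_tab, index=[f"g{i}" for i in range(n)]),
            counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(n)]),
            totals=pd.Series({c: 3 * 10**6 for c in cols}))
        de = compare_stages(matrix, "WT")
        for name, df in de.items():
            rate = (df["call"] != "none").mean()
            assert rate < 0.07, f"{name}: {rate:.3f}"

    def test_planted_upregulated_gene_called(self):
        # 2.5-fold at 100 TPM: safely past the |log2 ratio| >= 1 boundary
        rng = np.random.default_rng(4)
        calls = 0
        for _ in range(200):
            a = rng.binomial(3 * 10**6, 100e-6)
            b = rng.binomial(3 * 10**6, 250e-6)
            rec = test_gene("g", int(a), 3 * 10**6, int(b), 3 * 10**6,
                            a / 3, b / 3)
            calls += rec.call == "up"
        assert calls / 200 > 0.99

    def test_gene_absent_from_both_excluded(self):
        m = _matrix({"gone": [0, 0, 0, 0, 0, 0, 0, 0],
                     "there": [9, 9, 9, 9, 9, 9, 9, 9]})
        de = compare_stages(m, "WT")
        for df in de.values():
            assert "gone" not in set(df["gene_id"])


class TestCompareGenotypes:
    def test_fold_screen_one_is_superset_of_default(self, study):
        m = study.matrix
        strict, _ = compare_genotypes(m, 150, fold_screen=2.0)
        loose, _ = compare_genotypes(m, 150, fold_screen=1.0)
        assert set(strict["gene_id"]) <= set(loose["gene_id"])
        strict_calls = set(strict.loc[strict["call"] != "none", "gene_id"])
        loose_calls = set(loose.loc[loose["call"] != "none", "gene_id"])
        assert strict_calls <= loose_calls

    def test_symmetric_null_has_balanced_tallies(self):
        rng = np.random.default_rng(5)
        n = 3000
        tpm = np.exp(rng.uniform(np.log(5), np.log(80), size=n))
        prop = tpm / tpm.sum()
        cols = [f"{g}{s}" for g in ("WT", "MT") for s in STAGES]
        counts = {c: rng.multinomial(3 * 10**6, prop) for c in cols}
        tpm_tab = {c: counts[c] / 3e6 * 1e6 for c in cols}
        idx = [f"g{i}" for i in range(n)]
        m = ExpressionMatrix(tpm=pd.DataFrame(tpm_tab, index=idx),
                             counts=pd.DataFrame(counts, index=idx),
                             totals=pd.Series({c: 3 * 10**6 for c in cols}))
        _, tally = compare_genotypes(m, 120)
        total = tally["up"] + tally["down"]
        if total >= 10:
            lo, hi = stats.binom.ppf([0.005, 0.995], total, 0.5)
            assert lo <= tally["up"] <= hi

    def test_planted_direction_asymmetry_recovered(self, study_reference):
        from tagdge import design_truth

        # more down-regulated than up-regulated genes planted in MT
        truth = design_truth(1000, de_fraction=0.15, de_down_fraction=0.8, seed=21)
        tallies = _genotype_tallies_from_truth(truth, study_reference)
        for s in STAGES:
            assert tallies[s]["down"] > tallies[s]["up"]

    def test_unknown_stage_rejected(self, study):
        with pytest.raises(ValueError):
            compare_genotypes(study.matrix, 999)


def _genotype_tallies_from_truth(truth, reference):
    """Small-depth end-to-end run from a custom truth design."""
    from tagdge import (assemble_matrix, build_tag_index, count_tags,
                        map_library, qc_filter, simulate_all_libraries)

    libs = simulate_all_libraries(truth, reference, depth=400_000, seed=22)
    index = build_tag_index(reference)
    results = [map_library(qc_filter(count_tags(raw))[0], index)
               for raw in libs.values()]
    matrix = assemble_matrix(results,
                             gene_universe=[g.gene_id for g in reference])
    return {s: compare_genotypes(matrix, s)[1] for s in STAGES}


class TestDeProfileClustering:
    def _matrix_with_ratios(self, ratio_rows):
        rows = {}
        for gene, ratios in ratio_rows.items():
            wt = [50.0] * 4
            mt = [50.0 * 2.0 ** r for r in ratios]
            rows[gene] = wt + mt
        return _matrix(rows)

    def test_all_stage_de_gene_in_intersection(self):
        m = self._matrix_with_ratios({"g1": [2, 2, 2, 2], "g2": [2, 0, 0, 0]})
        de_sets = {120: {"g1", "g2"}, 150: {"g1"}, 190: {"g1"}, 220: {"g1"}}
        out = de_profile_clustering(de_sets, m)
        assert out["all_stage_genes"] == ["g1"]

    def test_two_opposite_archetypes_recovered(self):
        # opposite-signed profiles, both turning at 150 DAF
        up = [1.8, 3.0, 2.0, 1.5]
        down = [-1.8, -3.0, -2.0, -1.5]
        rng = np.random.default_rng(6)
        rows = {}
        for i in range(6):
            jit = rng.normal(0, 0.05, 4)
            rows[f"u{i}"] = list(np.array(up) + jit)
        for i in range(6):
            jit = rng.normal(0, 0.05, 4)
            rows[f"d{i}"] = list(np.array(down) + jit)
        m = self._matrix_with_ratios(rows)
        genes = set(rows)
        out = de_profile_clustering({s: genes for s in STAGES}, m, n_clusters=2)
        clusters = out["clusters"]
        ups = {clusters[f"u{i}"] for i in range(6)}
        downs = {clusters[f"d{i}"] for i in range(6)}
        assert len(ups) == 1 and len(downs) == 1 and ups != downs

    def test_identical_ratios_collapse_to_one_cluster(self):
        rows = {f"g{i}": [1.5, 2.5, 1.0, 0.5] for i in range(4)}
        m = self._matrix_with_ratios(rows)
        out = de_profile_clustering({s: set(rows) for s in STAGES}, m,
                                    n_clusters=2)
        assert out["clusters"].nunique() == 1

    def test_empty_union_gives_empty_output(self, study):
        out = de_profile_clustering({s: set() for s in STAGES}, study.matrix)
        assert out["all_stage_genes"] == [] and len(out["ratios"]) == 0
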