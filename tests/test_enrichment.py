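"""TAV counting, FDR, permutation null and the enrichment decision rule."""

import numpy as np
import pytest
from scipy import stats

from annoherit import (
    DEFAULT_THRESHOLDS,
    GwasTable,
    SimScenario,
    assign_annotations,
    classify_enrichment,
    compute_fdr,
    count_significant,
    permutation_test,
    run_gwas,
    simulate_genotypes,
    simulate_phenotypes,
    evaluate_class,
    threshold_sweep,
)


def _uniform_gwas(n, seed=0, trait="t"):
    rng = np.random.default_rng(seed)
    p = rng.uniform(np.finfo(float).tiny, 1.0, n)
    return GwasTable([f"s{i}" for i in range(n)], [trait], p[:, None])


class TestCounting:
    def test_strict_inequality(self):
        t = GwasTable(["a", "b", "c"], ["t"], np.array([[9e-5], [1e-4], [0.5]]))
        assert count_significant(t, "t", ["a", "b", "c"], 1e-4) == 1

    def test_threshold_one_counts_everything(self):
        t = _uniform_gwas(100)
        assert count_significant(t, "t", list(t.snp_ids), 1.0) == 100

    def test_empty_subset_warns_and_returns_zero(self):
        t = _uniform_gwas(10)
        with pytest.warns(UserWarning, match="empty"):
            assert count_significant(t, "t", [], 0.5) == 0

    def test_poisson_scale_counts(self):
        counts = [
            count_significant(_uniform_gwas(10_000, seed=s), "t",
                              [f"s{i}" for i in range(10_000)], 1e-4)
            for s in range(30)
        ]
        assert 0.2 < np.mean(counts) < 3.0  # expectation 1 per replicate


class TestFdr:
    def test_forced_example(self):
        assert compute_fdr(1e-4, 20_000, 4) == pytest.approx(0.5)

    def test_expected_equals_observed_gives_one(self):
        assert compute_fdr(0.01, 1000, 10) == 1.0

    def test_no_discoveries_is_na(self):
        assert np.isnan(compute_fdr(1e-4, 20_000, 0))

    def test_capped_at_one(self):
        assert compute_fdr(0.5, 1000, 2) == 1.0


class TestPermutationNull:
    def test_degenerate_null_all_zero(self):
        t = GwasTable(["a", "b", "c"], ["t"], np.array([[0.5], [0.6], [0.7]]))
        nulls, up, lo = permutation_test(t, "t", 2, list(t.snp_ids), 1e-4, seed=0)
        assert np.all(nulls == 0) and up == 0 and lo == 0

    def test_full_set_draw_equals_genome_count(self):
        t = _uniform_gwas(500, seed=1)
        k = count_significant(t, "t", list(t.snp_ids), 0.05)
        nulls, up, lo = permutation_test(t, "t", 500, list(t.snp_ids), 0.05, seed=2)
        assert np.all(nulls == k) and up == lo == k

    def test_null_matches_binomial_order_statistics(self):
        # uniform p, threshold 0.01, n=1000 of 10000: mean ~ 10 and the
        # criticals bracket the binomial 5%/95% quantiles
        t = _uniform_gwas(10_000, seed=3)
        nulls, up, lo = permutation_test(
            t, "t", 1000, list(t.snp_ids), 0.01, n_perm=1000, seed=4
        )
        assert abs(nulls.mean() - 10.0) < 1.5
        assert abs(lo - stats.binom.ppf(0.05, 1000, 0.01)) <= 2
        assert abs(up - stats.binom.ppf(0.95, 1000, 0.01)) <= 2

    def test_subset_and_count_routes_agree_in_distribution(self):
        t = _uniform_gwas(2000, seed=5)
        a, _, _ = permutation_test(
            t, "t", 500, list(t.snp_ids), 0.05, n_perm=3000, seed=6
        )
        b, _, _ = permutation_test(
            t, "t", 500, list(t.snp_ids), 0.05, n_perm=3000, seed=7, method="subset"
        )
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_determinism_and_low_nperm_warning(self):
        t = _uniform_gwas(200, seed=8)
        a, *_ = permutation_test(t, "t", 50, list(t.snp_ids), 0.1, seed=9)
        b, *_ = permutation_test(t, "t", 50, list(t.snp_ids), 0.1, seed=9)
        assert np.array_equal(a, b)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(t, "t", 50, list(t.snp_ids), 0.1, n_perm=50, seed=9)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "m,up,lo,status",
        [
            (12, 10, 2, "enriched"),
            (10, 10, 2, "ns"),  # tie with the upper critical is not enrichment
            (0, 10, 1, "depleted"),
            (1, 10, 1, "ns"),
        ],
    )
    def test_strict_rule(self, m, up, lo, status):
        assert classify_enrichment(m, up, lo) == status


class TestSweep:
    def test_default_threshold_grid(self):
        assert DEFAULT_THRESHOLDS == (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)

    def test_class_equal_to_genome_is_never_significant(self, small_data):
        genotypes, annotations, design, _ = small_data
        gwas = run_gwas(genotypes, design).gwas
        from annoherit import AnnotationClass, AnnotationTable

        whole = AnnotationTable(
            list(gwas.snp_ids),
            [AnnotationClass("all")],
            np.ones((len(gwas.snp_ids), 1), dtype=np.uint8),
        )
        sweep = threshold_sweep(gwas, whole, master_seed=3)
        assert (sweep["status"] == "ns").all()

    def test_monotone_counts_in_threshold(self):
        t = _uniform_gwas(5000, seed=11)
        subset = list(t.snp_ids)[:800]
        counts = [count_significant(t, "t", subset, thr) for thr in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)]
        assert counts == sorted(counts)

    def test_planted_class_is_detected(self):
        # strong per-SNP effects planted in one small class: the enrichment
        # test at p < 1e-4 should call it in >= 90% of replicates
        detected = 0
        for rep in range(20):
            sc = SimScenario(
                n_individuals=400, n_snps=2000, seed=100 + rep,
                class_h2={"missense": 0.4},
            )
            g = simulate_genotypes(sc)
            a = assign_annotations(sc, g)
            design, _ = simulate_phenotypes(sc, g, a)
            gwas = run_gwas(g, design).gwas
            res = evaluate_class(gwas, "trait", a, "missense", 1e-4, seed=rep)
            detected += res.status == "enriched"
        assert detected >= 18
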