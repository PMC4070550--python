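"""Synthetic-data generator: determinism, allele-frequency behaviour,
annotation nesting, and planted-heritability bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoherit import (
    ClassSpec,
    FixedEffectSpec,
    SimScenario,
    ValidationError,
    assign_annotations,
    simulate_genotypes,
    simulate_phenotypes,
)


def test_same_seed_is_bit_identical(small_scenario):
    g1 = simulate_genotypes(small_scenario)
    g2 = simulate_genotypes(small_scenario)
    assert np.array_equal(g1.counts, g2.counts)
    a1 = assign_annotations(small_scenario, g1)
    a2 = assign_annotations(small_scenario, g2)
    assert np.array_equal(a1.membership, a2.membership)
    d1, _ = simulate_phenotypes(small_scenario, g1, a1)
    d2, _ = simulate_phenotypes(small_scenario, g2, a2)
    assert np.array_equal(d1.y, d2.y)


def test_maf_half_gives_mean_genotype_one():
    sc = SimScenario(n_individuals=2000, n_snps=50, maf_range=(0.5, 0.5), seed=3)
    g = simulate_genotypes(sc)
    # mean genotype per SNP is 2p = 1, within 4 binomial SDs of the mean
    sd = np.sqrt(2 * 0.5 * 0.5 / sc.n_individuals)
    assert np.all(np.abs(g.counts.mean(axis=0) - 1.0) < 4 * sd)


def test_frequencies_and_heterozygosity_match_analytic():
    sc = SimScenario(n_individuals=500, n_snps=2000, maf_range=(0.05, 0.5), seed=1)
    g = simulate_genotypes(sc)
    assert np.all(g.freqs > 0.01) and np.all(g.freqs < 0.99)
    # observed heterozygosity vs 2p(1-p) averaged over the drawn p vector
    het_obs = (g.counts == 1).mean()
    het_exp = np.mean(2 * g.freqs * (1 - g.freqs))
    # het_exp uses sample freqs, so the comparison is tight up to MC error
    mc_sd = np.sqrt(het_exp * (1 - het_exp) / g.counts.size)
    assert abs(het_obs - het_exp) < 6 * mc_sd + 1e-3


def test_degenerate_maf_range_rejected():
    with pytest.raises(ValidationError):
        SimScenario(n_individuals=10, n_snps=10, maf_range=(0.4, 0.1))
    with pytest.raises(ValidationError):
        SimScenario(n_individuals=10, n_snps=10, maf_range=(0.0, 0.5))


def test_total_h2_at_least_one_rejected():
    with pytest.raises(ValidationError):
        SimScenario(
            n_individuals=10, n_snps=100,
            class_h2={"intergenic": 0.7}, residual_h2_background=0.3,
        )


def test_nesting_closure_and_class_sizes(small_data):
    _, annotations, _, _ = small_data
    missense = annotations.members_mask("missense")
    assert np.all(annotations.members_mask("cds")[missense])
    assert np.all(annotations.members_mask("intragenic")[missense])
    # exactly one top-level class per SNP
    top = annotations.members_mask("intergenic").astype(int) + annotations.members_mask(
        "intragenic"
    ).astype(int)
    assert np.all(top == 1)


def test_intergenic_count_forced_by_rounding():
    sc = SimScenario(n_individuals=4, n_snps=10000, seed=0)
    g = simulate_genotypes(sc)
    a = assign_annotations(sc, g)
    assert abs(a.n_members("intergenic") - 6700) <= 1


def test_zero_proportion_class_unusable():
    sc = SimScenario(
        n_individuals=4,
        n_snps=100,
        seed=0,
        class_spec=(
            ClassSpec("intergenic", 1.0),
            ClassSpec("empty", 0.0, parent="intergenic"),
        ),
    )
    a = assign_annotations(sc, simulate_genotypes(sc))
    assert "empty" in a.class_names
    assert a.n_members("empty") == 0
    assert not a.usable("empty")


def test_children_exceeding_parent_rejected():
    with pytest.raises(ValidationError, match="children"):
        SimScenario(
            n_individuals=4,
            n_snps=100,
            class_spec=(
                ClassSpec("intergenic", 0.7),
                ClassSpec("intragenic", 0.3),
                ClassSpec("intron", 0.4, parent="intragenic"),
            ),
        )


def test_no_random_components_gives_exact_fixed_effects():
    sc = SimScenario(
        n_individuals=50,
        n_snps=100,
        seed=2,
        env_fraction=0.0,
        fixed_effects=(FixedEffectSpec("breed", (0.0, 1.5)),),
    )
    g = simulate_genotypes(sc)
    a = assign_annotations(sc, g)
    design, truth = simulate_phenotypes(sc, g, a)
    # y is exactly the breed effect: only the two level values appear
    assert set(np.round(design.y, 12)) <= {0.0, 1.5}
    assert truth.total_h2_realized == 0.0


def test_regression_on_realized_genetic_value_recovers_slope_one(small_data):
    genotypes, annotations, design, truth = small_data
    g = truth.genetic_values["missense"]
    slope = float(g @ design.y) / float(g @ g)
    assert abs(slope - 1.0) < 0.15


def test_variance_budget_for_disjoint_components(disjoint_scenario):
    g = simulate_genotypes(disjoint_scenario)
    a = assign_annotations(disjoint_scenario, g)
    design, truth = simulate_phenotypes(disjoint_scenario, g, a)
    # disjoint causal classes + orthogonalized noise: var(y) within 2%
    assert abs(design.y.var() - 1.0) < 0.02
    assert truth.class_h2_realized["classA"] == pytest.approx(0.3, abs=0.02)
    assert sum(truth.class_h2_realized.values()) == pytest.approx(
        truth.total_h2_realized
    )


@settings(max_examples=15, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    p_intron=st.floats(0.05, 0.25),
    p_cds=st.floats(0.01, 0.05),
)
def test_nesting_closure_property(seed, p_intron, p_cds):
    sc = SimScenario(
        n_individuals=3,
        n_snps=400,
        seed=seed,
        class_spec=(
            ClassSpec("intergenic", 0.6),
            ClassSpec("intragenic", 0.4),
            ClassSpec("intron", p_intron, parent="intragenic"),
            ClassSpec("cds", p_cds, parent="intragenic"),
        ),
    )
    a = assign_annotations(sc, simulate_genotypes(sc))
    for child in ("intron", "cds"):
        mask = a.members_mask(child)
        assert np.all(a.members_mask("intragenic")[mask])
        target = p_cds if child == "cds" else p_intron
        assert abs(a.n_members(child) - round(target * 400)) <= 1


def test_ld_mode_correlates_neighbours():
    sc = SimScenario(
        n_individuals=600, n_snps=200, seed=9, ld_block_length=20, ld_copy_prob=0.9
    )
    g = simulate_genotypes(sc)
    cors = []
    for j in range(1, 200):
        if j % 20 == 0:
            continue  # block boundary: fresh draw
        a, b = g.counts[:, j - 1], g.counts[:, j]
        if a.std() > 0 and b.std() > 0:
            cors.append(np.corrcoef(a, b)[0, 1])
    assert np.mean(cors) > 0.3
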