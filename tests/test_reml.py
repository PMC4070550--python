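"""AI-REML: grid-search oracle, recovery of planted variance components,
boundary behaviour, the random-intergenic comparison and per-SNP variance."""

import numpy as np
import pytest

from annoherit import (
    ClassSpec,
    SimScenario,
    TraitDesign,
    ValidationError,
    assign_annotations,
    compute_grm,
    fit_reml,
    per_snp_variance,
    random_intergenic_comparison,
    simulate_genotypes,
    simulate_phenotypes,
)


def naive_restricted_ll(y, X, G, sg, se):
    """Independent dense evaluation of the restricted log-likelihood."""
    n = len(y)
    V = sg * G + se * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    s1, d1 = np.linalg.slogdet(V)
    s2, d2 = np.linalg.slogdet(XtVX)
    if s1 <= 0 or s2 <= 0:
        return -np.inf
    return -0.5 * (d1 + d2 + float(y @ P @ y))


def _instance(seed, n=25, m=60, h2=0.5):
    sc = SimScenario(n_individuals=n, n_snps=m, seed=seed,
                     class_h2={"intergenic": h2})
    g = simulate_genotypes(sc)
    a = assign_annotations(sc, g)
    design, _ = simulate_phenotypes(sc, g, a)
    return design, compute_grm(g)


def test_optimum_beats_grid_oracle():
    for seed in (1, 2, 3):
        design, grm = _instance(seed)
        fit = fit_reml(design, grm)
        vy = design.y.var()
        grid = np.linspace(1e-6, 2.5 * vy, 60)
        best = max(
            naive_restricted_ll(design.y, design.X, grm.values, sg, se)
            for sg in grid
            for se in grid
        )
        assert fit.loglik >= best - 1e-6
        # and the reported log-likelihood matches the independent formula
        sg, se = fit.variances
        assert fit.loglik == pytest.approx(
            naive_restricted_ll(design.y, design.X, grm.values, sg, se), abs=1e-6
        )


def test_null_heritability_sits_at_boundary():
    # with no genetic signal the estimate piles up at the zero boundary;
    # at n=500 the truncated sampling spread keeps the mean below 0.05
    ests = []
    for seed in range(50):
        sc = SimScenario(n_individuals=500, n_snps=500, seed=700 + seed)
        g = simulate_genotypes(sc)
        a = assign_annotations(sc, g)
        design, _ = simulate_phenotypes(sc, g, a)  # pure noise trait
        fit = fit_reml(design, compute_grm(g))
        ests.append(fit.h2["all"])
    assert np.mean(ests) < 0.05


def test_single_component_recovery_small():
    hits = 0
    for seed in range(10):
        design, grm = _instance(800 + seed, n=300, m=1500, h2=0.5)
        fit = fit_reml(design, grm)
        hits += abs(fit.h2["all"] - 0.5) < 2 * fit.se_h2["all"]
    assert hits >= 8


def test_joint_two_component_recovery(disjoint_scenario):
    g = simulate_genotypes(disjoint_scenario)
    a = assign_annotations(disjoint_scenario, g)
    design, truth = simulate_phenotypes(disjoint_scenario, g, a)
    grms = [compute_grm(g, a.members(c), c) for c in ("classA", "classB")]
    fit = fit_reml(design, grms)
    assert abs(fit.h2["classA"] - 0.3) < 2.5 * max(fit.se_h2["classA"], 0.05)
    assert abs(fit.h2["classB"] - 0.1) < 2.5 * max(fit.se_h2["classB"], 0.05)
    # variance bookkeeping: h2 fractions plus residual fraction sum to 1
    total = fit.total_variance
    assert sum(fit.h2.values()) + fit.variances[-1] / total == pytest.approx(1.0)


def test_monotone_loglik_vs_start(small_data):
    genotypes, annotations, design, _ = small_data
    grm = compute_grm(genotypes)
    fit = fit_reml(design, grm)
    vy = design.y.var()
    start = naive_restricted_ll(design.y, design.X, grm.values, vy / 2, vy / 2)
    assert fit.converged and fit.loglik >= start


def test_stationarity_at_optimum(small_data):
    # at an interior optimum the REML score vanishes: tr(PG) = y'PGPy
    genotypes, _, design, _ = small_data
    grm = compute_grm(genotypes)
    fit = fit_reml(design, grm)
    sg, se = fit.variances
    if min(sg, se) > 1e-6:  # interior
        n = design.n
        V = sg * grm.values + se * np.eye(n)
        Vinv = np.linalg.inv(V)
        X = design.X
        P = Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv
        Py = P @ design.y
        score_g = float(Py @ grm.values @ Py - np.sum(P * grm.values))
        score_e = float(Py @ Py - np.trace(P))
        assert abs(score_g) < 1e-4 * n
        assert abs(score_e) < 1e-4 * n


def test_joint_vs_marginal_on_orthogonal_classes(disjoint_scenario):
    g = simulate_genotypes(disjoint_scenario)
    a = assign_annotations(disjoint_scenario, g)
    design, _ = simulate_phenotypes(disjoint_scenario, g, a)
    grms = {c: compute_grm(g, a.members(c), c) for c in ("classA", "classB")}
    joint = fit_reml(design, list(grms.values()))
    for c in ("classA", "classB"):
        single = fit_reml(design, grms[c])
        tol = 3 * max(single.se_h2[c], joint.se_h2[c], 0.02)
        assert abs(joint.h2[c] - single.h2[c]) < tol


def test_singular_design_rejected(small_data):
    genotypes, _, design, _ = small_data
    X = np.column_stack([design.X, design.X[:, 0]])
    with pytest.raises(ValidationError):
        bad = TraitDesign(design.ids, design.y, X, ["intercept", "dup"])


class TestRandomIntergenicComparison:
    def test_planted_class_flagged_increase(self):
        sc = SimScenario(
            n_individuals=250, n_snps=2000, seed=51,
            class_spec=(ClassSpec("probe", 0.1), ClassSpec("intergenic", 0.9)),
            class_h2={"probe": 0.4}, residual_h2_background=0.05,
        )
        g = simulate_genotypes(sc)
        a = assign_annotations(sc, g)
        design, _ = simulate_phenotypes(sc, g, a)
        comp = random_intergenic_comparison(design, g, a, "probe", master_seed=5)
        assert comp.significant == "increase"
        assert comp.difference > 0.2

    def test_single_replicate_is_na(self, small_data):
        genotypes, annotations, design, _ = small_data
        with pytest.warns(UserWarning, match="n_reps"):
            comp = random_intergenic_comparison(
                design, genotypes, annotations, "cds", n_reps=1, master_seed=1
            )
        assert comp.significant == "NA"
        assert np.isnan(comp.difference)

    def test_class_larger_than_pool_rejected(self, small_data):
        genotypes, annotations, design, _ = small_data
        with pytest.raises(ValidationError, match="larger"):
            random_intergenic_comparison(
                design, genotypes, annotations, "intergenic",
                intergenic_class="cds",
            )


class TestPerSnpVariance:
    def test_forced_example(self):
        assert per_snp_variance(0.20, 2000) == pytest.approx(100.0)

    def test_zero_h2(self):
        assert per_snp_variance(0.0, 500) == 0.0

    def test_halves_when_n_doubles(self):
        assert per_snp_variance(0.3, 2000) == pytest.approx(
            per_snp_variance(0.3, 1000) / 2
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            per_snp_variance(0.1, 0)
        with pytest.raises(ValidationError):
            per_snp_variance(-0.1, 10)
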