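"""Threshold-based trait-associated-variant (TAV) counting, per-threshold FDR,
and the size-matched permutation enrichment/depletion test.

For an annotation class of n SNPs and a trait, m is the number of class SNPs
with GWAS p < threshold (strict).  The null distribution of m is obtained by
drawing n SNPs uniformly without replacement from the full genotyped panel
1000 times and counting significant SNPs in each draw; a class is enriched
when its observed m exceeds the 950th (ascending) null count and depleted
when it falls below the 50th, i.e. a two-sided 5% permutation rule.

Because the draw is uniform without replacement, the null count is exactly
Hypergeometric(N, K, n) where K is the number of significant SNPs in the
panel; the default sampling path draws counts from that distribution
directly, which is an exact implementation of the permutation (not an
approximation).  `method="subset"` materializes the SNP subsets instead; the
two routes agree in distribution and a test checks that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .data import AnnotationTable, GwasTable, ValidationError

#: the threshold grid used for the FDR / enrichment sweep
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8,
)

#: TAV definition used for the headline analyses
DEFAULT_TAV_THRESHOLD = 1e-4


@dataclass
class EnrichmentResult:
    class_name: str
    trait: str
    threshold: float
    n: int
    m: int
    fdr: float  # NaN when m == 0
    null_counts: np.ndarray = field(repr=False)
    upper_crit: int
    lower_crit: int
    status: str  # enriched | depleted | ns
    seed: int


def count_significant(
    gwas: GwasTable, trait: str, snp_subset: list[str], threshold: float
) -> int:
    """Number of subset SNPs with p < threshold (strict inequality)."""
    if not snp_subset:
        warnings.warn("empty SNP subset: significant count is 0", stacklevel=2)
        return 0
    sub = gwas.reordered(list(snp_subset))
    return int((sub.trait_pvalues(trait) < threshold).sum())


def compute_fdr(threshold: float, n: int, m: int) -> float:
    """FDR at a p-value threshold: expected false positives over observed.

    fdr = min(1, threshold * n / m); reported as NaN when m = 0 (no
    discoveries to attribute a false-discovery rate to).
    """
    if n < 1:
        raise ValidationError("class size n must be >= 1")
    if m == 0:
        return float("nan")
    return min(1.0, threshold * n / m)


def _criticals(null_counts: np.ndarray, n_perm: int) -> tuple[int, int]:
    """95th/5th percentile order statistics of the null counts.

    At n_perm = 1000 these are exactly the 950th and 50th elements of the
    ascending sort (the '950th highest / 50th lowest' two-sided 5% rule);
    for other n_perm the ceil(0.95 n)-th and floor(0.05 n + 1)-th positions
    (1-based) are used.
    """
    order = np.sort(null_counts)
    if n_perm == 1000:
        hi, lo = 950, 50
    else:
        hi = math.ceil(0.95 * n_perm)
        lo = math.floor(0.05 * n_perm + 1)
        lo = min(lo, n_perm)
    return int(order[hi - 1]), int(order[lo - 1])


def permutation_test(
    gwas: GwasTable,
    trait: str,
    n: int,
    genome_snp_ids: list[str],
    threshold: float,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "hypergeometric",
) -> tuple[np.ndarray, int, int]:
    """Null counts of significant SNPs in size-n random draws, plus criticals.

    Returns (null_counts, upper_crit, lower_crit).
    """
    N = len(genome_snp_ids)
    if n > N:
        raise ValidationError(f"class size {n} exceeds genome panel {N}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100: 5% criticals are ill-defined", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    genome = gwas.reordered(list(genome_snp_ids))
    sig = genome.trait_pvalues(trait) < threshold
    K = int(sig.sum())
    if method == "hypergeometric":
        if K == 0 or n == 0:
            null_counts = np.zeros(n_perm, dtype=np.int64)
        elif K == N:
            null_counts = np.full(n_perm, n, dtype=np.int64)
        else:
            null_counts = rng.hypergeometric(K, N - K, n, size=n_perm)
    elif method == "subset":
        null_counts = np.empty(n_perm, dtype=np.int64)
        for r in range(n_perm):
            idx = rng.choice(N, size=n, replace=False)
            null_counts[r] = int(sig[idx].sum())
    else:
        raise ValidationError(f"unknown permutation method {method!r}")
    upper, lower = _criticals(null_counts, n_perm)
    return null_counts, upper, lower


def classify_enrichment(m: int, upper_crit: int, lower_crit: int) -> str:
    """Strict decision rule: a tie with a critical value is not significant."""
    if m > upper_crit:
        return "enriched"
    if m < lower_crit:
        return "depleted"
    return "ns"


def evaluate_class(
    gwas: GwasTable,
    trait: str,
    annotations: AnnotationTable,
    class_name: str,
    threshold: float,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "hypergeometric",
) -> EnrichmentResult:
    """Full enrichment test of one class x trait at one threshold."""
    members = annotations.members(class_name)
    n = len(members)
    m = count_significant(gwas, trait, members, threshold) if n else 0
    null_counts, upper, lower = permutation_test(
        gwas, trait, n, list(gwas.snp_ids), threshold,
        n_perm=n_perm, seed=seed, method=method,
    )
    return EnrichmentResult(
        class_name=class_name,
        trait=trait,
        threshold=threshold,
        n=n,
        m=m,
        fdr=compute_fdr(threshold, max(n, 1), m),
        null_counts=null_counts,
        upper_crit=upper,
        lower_crit=lower,
        status=classify_enrichment(m, upper, lower),
        seed=seed,
    )


def threshold_sweep(
    gwas: GwasTable,
    annotations: AnnotationTable,
    traits: list[str] | None = None,
    class_names: list[str] | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_perm: int = 1000,
    master_seed: int = 0,
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Enrichment/FDR sweep over classes x traits x thresholds (long format).

    Seeds are derived per (class, trait, threshold) from the master seed by
    stable hashing, so adding a trait or class never changes existing rows.
    """
    traits = traits if traits is not None else list(gwas.traits)
    class_names = class_names if class_names is not None else annotations.class_names
    annotations = annotations.reordered(list(gwas.snp_ids))
    rows = []
    for cname in class_names:
        for trait in traits:
            for t in thresholds:
                seed = derive_seed(master_seed, "enrich", cname, trait, repr(t))
                res = evaluate_class(
                    gwas, trait, annotations, cname, t,
                    n_perm=n_perm, seed=seed, method=method,
                )
                rows.append(
                    {
                        "class": cname,
                        "trait": trait,
                        "threshold": t,
                        "n": res.n,
                        "m": res.m,
                        "fdr": res.fdr,
                        "lower_crit": res.lower_crit,
                        "upper_crit": res.upper_crit,
                        "status": res.status,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


def status_matrix(sweep: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Class x trait matrix of '+', '-', 'ns' at one threshold."""
    sub = sweep[np.isclose(sweep["threshold"], threshold)]
    symbol = {"enriched": "+", "depleted": "-", "ns": "ns"}
    mat = sub.pivot(index="class", columns="trait", values="status")
    return mat.map(lambda s: symbol.get(s, s))
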