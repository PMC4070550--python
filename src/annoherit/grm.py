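"""Genomic relationship matrices per annotation class, and distances between
them.

The GRM follows the standardized allele-count estimator
G_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
with sample allele frequencies computed on the SNP subset at hand (matching
GCTA's behaviour on SNP-filtered input).  Missing genotypes are imputed to
2 p_i inside the computation only, contributing zero to the numerator.
Monomorphic SNPs are excluded (their standardization is undefined); a class
whose SNPs are all monomorphic is unusable for a GRM.

Similarity between class GRMs is summarised by the Euclidean (Frobenius)
distance between the matrices; classes sharing many SNPs have nearby GRMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, ValidationError


class GrmUnusableError(ValidationError):
    """Raised when a SNP set cannot support a GRM (all monomorphic/missing)."""


@dataclass
class Grm:
    class_name: str
    ids: list[str]
    values: np.ndarray
    n_snps: int
    excluded_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("GRM must be square over the individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("GRM must be symmetric")
        if self.n_snps < 1:
            raise ValidationError("GRM must use at least one SNP")


@dataclass
class GrmDistanceMatrix:
    class_names: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        k = len(self.class_names)
        if self.distances.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")


def compute_grm(
    genotypes: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    class_name: str = "all",
) -> Grm:
    """Standardized-genotype GRM over a SNP subset.

    Frequencies are recomputed from the sample restricted to the subset;
    monomorphic and all-missing SNPs are excluded and listed.
    """
    snp_ids = list(snp_subset) if snp_subset is not None else list(genotypes.snp_ids)
    if not snp_ids:
        raise GrmUnusableError(f"class {class_name!r}: empty SNP set")
    idx = genotypes.snp_indexer(snp_ids)
    counts = genotypes.counts[:, idx]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(counts, axis=0) / 2.0
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    excluded = [s for s, u in zip(snp_ids, usable) if not u]
    if not usable.any():
        raise GrmUnusableError(
            f"class {class_name!r} unusable for GRM: all {len(snp_ids)} SNPs "
            "monomorphic or missing"
        )
    counts = counts[:, usable]
    p = p[usable]
    denom = np.sqrt(2 * p * (1 - p))
    W = (counts - 2 * p) / denom
    W = np.nan_to_num(W, nan=0.0)  # mean imputation: (2p - 2p)/sd = 0
    N = int(usable.sum())
    G = (W @ W.T) / N
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return Grm(class_name, list(genotypes.ids), G, N, excluded)


def grm_distance(a: Grm, b: Grm, include_diagonal: bool = True) -> float:
    """Euclidean (Frobenius) distance between two GRMs over the same ids.

    `include_diagonal=False` restricts to the strict lower triangle, for
    sensitivity to whether self-relationships are counted.
    """
    if a.ids != b.ids:
        raise ValidationError(
            f"GRMs {a.class_name!r} and {b.class_name!r} are over different "
            "individual sets/orders"
        )
    diff = a.values - b.values
    if include_diagonal:
        return float(np.linalg.norm(diff))
    tri = np.tril_indices_from(diff, k=-1)
    return float(np.linalg.norm(diff[tri]))


def distance_heatmap(
    grms: list[Grm],
    include_diagonal: bool = True,
    plot_path: str | None = None,
) -> GrmDistanceMatrix:
    """Pairwise distance matrix between class GRMs (optionally plotted)."""
    k = len(grms)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = grm_distance(
                grms[i], grms[j], include_diagonal=include_diagonal
            )
    names = [g.class_name for g in grms]
    result = GrmDistanceMatrix(names, D)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.6 * k, 1 + 0.6 * k))
        im = ax.imshow(D, cmap="viridis")
        ax.set_xticks(range(k), names, rotation=90)
        ax.set_yticks(range(k), names)
        fig.colorbar(im, ax=ax, label="Euclidean distance")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return result
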