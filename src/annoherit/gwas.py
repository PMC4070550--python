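"""Per-SNP association scan by ordinary least squares.

For each SNP the model y = X b + x beta + eps is fitted and the two-sided
t-test p-value for beta reported.  Computation uses the
Frisch-Waugh-Lovell residualization: y and every genotype column are
projected off the fixed-effect design once, after which each SNP is a simple
regression -- algebraically identical to the full OLS fit, including the
degrees of freedom n - rank(X) - 1.

This is deliberately a plain fixed-effects scan (no relatedness correction):
it exists so the pipeline is closed under synthetic data, where individuals
are unrelated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeMatrix, GwasTable, TraitDesign, ValidationError

_P_FLOOR = np.nextafter(0.0, 1.0)  # keep p strictly positive


@dataclass
class GwasScanResult:
    gwas: GwasTable
    betas: np.ndarray
    monomorphic: list[str]


def run_gwas(
    genotypes: GenotypeMatrix,
    design: TraitDesign,
    trait_name: str = "trait",
) -> GwasScanResult:
    """OLS scan of one trait over all SNPs.

    Monomorphic SNPs (no genotypic variance after projection on X) are
    assigned p = 1 and listed in `monomorphic`.
    """
    if design.ids != genotypes.ids:
        raise ValidationError("design individuals must match genotype rows")
    X, y = design.X, design.y
    n, p_rank = X.shape
    if n <= p_rank + 1:
        raise ValidationError("need more individuals than fixed effects + 1")

    Q, _ = np.linalg.qr(X)
    ey = y - Q @ (Q.T @ y)
    G = np.nan_to_num(genotypes.counts, nan=np.nan)
    # mean-impute missing before projection so a sparse missing pattern does
    # not silently shift a SNP's test
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean, G)
    eG = G - Q @ (Q.T @ G)

    sxx = np.einsum("ij,ij->j", eG, eG)
    sxy = eG.T @ ey
    syy = float(ey @ ey)
    df = n - p_rank - 1

    mono = sxx <= 1e-12 * max(1.0, float(np.max(sxx, initial=1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        rss = syy - beta * sxy
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / df
        se = np.sqrt(np.where(mono, np.inf, sigma2 / np.where(mono, 1.0, sxx)))
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        tstat = np.nan_to_num(tstat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(mono, 1.0, np.clip(pvals, _P_FLOOR, 1.0))

    gwas = GwasTable(list(genotypes.snp_ids), [trait_name], pvals[:, None])
    mono_ids = [s for s, m in zip(genotypes.snp_ids, mono) if m]
    return GwasScanResult(gwas=gwas, betas=beta, monomorphic=mono_ids)


def run_gwas_multi(
    genotypes: GenotypeMatrix, designs: dict[str, TraitDesign]
) -> GwasTable:
    """Scan several traits sharing the genotype matrix; one GwasTable out."""
    cols, traits = [], []
    for trait, design in designs.items():
        res = run_gwas(genotypes, design, trait)
        cols.append(res.gwas.pvalues[:, 0])
        traits.append(trait)
    return GwasTable(list(genotypes.snp_ids), traits, np.column_stack(cols))
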