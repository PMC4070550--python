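"""Joint logistic regression of SNP significance on annotation memberships.

Each SNP contributes one observation: the outcome is 1 when its GWAS p-value
falls below the TAV threshold, and the predictors are its binary class
memberships, all fitted simultaneously so that signal present in one class
through overlap with another is absorbed by the joint model.  A positive
coefficient means enrichment of significant SNPs in that class net of the
other classes; reported per class are the log-odds coefficient and the
-log10 Wald p-value.  A drop-class mode refits without chosen classes (e.g.
removing CDS to expose its synonymous/missense children).

The fit is maximum likelihood via iteratively reweighted least squares with
step-halving; quasi-separation is detected by coefficient divergence and the
affected classes reported as NA rather than with meaningless huge values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .data import AnnotationTable, GwasTable, ValidationError

_SEP_BOUND = 30.0  # |log-odds| beyond this on a binary design ~ separation


@dataclass
class LogisticFit:
    trait: str
    classes: list[str]  # fitted classes, in coefficient order
    coefficients: np.ndarray  # log-odds, NaN where separated
    se: np.ndarray
    wald_neglog10_p: np.ndarray
    intercept: float
    intercept_se: float
    converged: bool
    n_iterations: int
    loglik: float
    dropped: list[str]  # zero-variance or user-dropped classes
    separated: list[str]

    def coefficient(self, class_name: str) -> float:
        return float(self.coefficients[self.classes.index(class_name)])

    def neglog10_p(self, class_name: str) -> float:
        return float(self.wald_neglog10_p[self.classes.index(class_name)])


def binarize(gwas: GwasTable, trait: str, threshold: float) -> np.ndarray:
    """0/1 significance vector: 1 iff p < threshold (strict)."""
    return (gwas.trait_pvalues(trait) < threshold).astype(np.uint8)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), numerically via log1p/logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    membership: np.ndarray,
    class_names: list[str],
    drop_classes: list[str] | None = None,
    trait: str = "trait",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Joint ML logistic fit of y on binary memberships, with intercept.

    Raises on a degenerate outcome (all 0 or all 1) and on exactly collinear
    membership columns (the colliding pair/set is named).  Zero-variance
    columns are excluded from the fit and listed in `dropped`.
    """
    y = np.asarray(y, dtype=float).ravel()
    membership = np.asarray(membership, dtype=float)
    if membership.ndim != 2 or membership.shape[0] != y.size:
        raise ValidationError("membership must be SNPs x classes, rows matching y")
    if len(class_names) != membership.shape[1]:
        raise ValidationError("class_names must match membership columns")
    if y.min() == y.max():
        raise ValidationError(
            f"outcome is constant (all {int(y[0])}): cannot fit logistic model; "
            "lower the significance threshold or check the GWAS input"
        )

    drop = set(drop_classes or [])
    unknown = drop - set(class_names)
    if unknown:
        raise ValidationError(f"drop_classes not in registry: {sorted(unknown)}")

    keep_idx, kept, dropped = [], [], sorted(drop)
    for j, name in enumerate(class_names):
        if name in drop:
            continue
        col = membership[:, j]
        if col.min() == col.max():
            dropped.append(name)
            continue
        keep_idx.append(j)
        kept.append(name)
    if not kept:
        raise ValidationError("no usable (non-constant) annotation columns")

    # duplicate / collinear detection before fitting
    Xc = membership[:, keep_idx]
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            if np.array_equal(Xc[:, a], Xc[:, b]):
                raise ValidationError(
                    f"classes {kept[a]!r} and {kept[b]!r} have identical "
                    "membership columns (collinear)"
                )
    X = np.column_stack([np.ones(y.size), Xc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # an exhaustive taxonomy (e.g. intergenic + intragenic covering every
        # SNP) is collinear with the intercept: drop a minimal set of columns
        # found by pivoted QR (never the intercept), report them, and refit
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(int(j) for j in piv[rank:])
        if 0 in bad:  # keep the intercept; sacrifice a membership column
            bad.remove(0)
            keepable = [int(j) for j in piv[:rank] if j != 0]
            bad.append(keepable[-1])
        names = ["intercept", *kept]
        removed = [names[j] for j in sorted(bad)]
        warnings.warn(
            f"membership design is rank deficient; dropping {removed}",
            stacklevel=2,
        )
        return fit_logistic(
            y,
            membership,
            class_names,
            drop_classes=sorted(set(drop) | set(removed)),
            trait=trait,
            max_iter=max_iter,
            tol=tol,
        )

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _bernoulli_loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            cand_ll = _bernoulli_loglik(y, X @ cand)
            if cand_ll >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break  # cannot improve
        beta, new_ll = cand, cand_ll
        eta = X @ beta
        if abs(new_ll - ll) < tol * (1 + abs(ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    separated_mask = np.abs(beta[1:]) > _SEP_BOUND
    separated = [kept[j] for j in np.flatnonzero(separated_mask)]
    if separated:
        converged = False
        warnings.warn(
            f"quasi-separation: coefficients diverged for {separated}", stacklevel=2
        )

    mu = special.expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(X.shape[1], np.nan)

    coefs = beta[1:].copy()
    se = se_all[1:].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coefs / se
    # -log10 p computed on the log scale so tiny p-values stay exact
    neglog10 = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    coefs[separated_mask] = np.nan
    se[separated_mask] = np.nan
    neglog10[separated_mask] = np.nan

    return LogisticFit(
        trait=trait,
        classes=kept,
        coefficients=coefs,
        se=se,
        wald_neglog10_p=neglog10,
        intercept=float(beta[0]),
        intercept_se=float(se_all[0]),
        converged=converged,
        n_iterations=it,
        loglik=ll,
        dropped=dropped,
        separated=separated,
    )


def fit_trait(
    gwas: GwasTable,
    annotations: AnnotationTable,
    trait: str,
    threshold: float = 1e-4,
    drop_classes: list[str] | None = None,
) -> LogisticFit:
    """Binarize a trait's p-values and jointly fit all annotation classes."""
    annotations = annotations.reordered(list(gwas.snp_ids))
    y = binarize(gwas, trait, threshold)
    return fit_logistic(
        y,
        annotations.membership,
        annotations.class_names,
        drop_classes=drop_classes,
        trait=trait,
    )
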