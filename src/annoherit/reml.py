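"""Restricted maximum likelihood variance-component estimation (GREML).

Model: y = Xb + sum_c g_c + e, with g_c ~ N(0, G_c sigma2_c) for each class
GRM and e ~ N(0, I sigma2_e).  Components are estimated by average-
information (AI) REML with EM fallback steps and step-halving, so the
restricted log-likelihood never decreases across accepted iterations.
Variances are constrained to a small positive floor; components pinned at
the floor are flagged "constrained" and excluded from the AI matrix when
standard errors are computed (their SEs are reported as 0).

Heritability per component is sigma2_c over the total of all fitted
components (the joint-model ratio); the pairwise ratio
sigma2_c / (sigma2_c + sigma2_e) is also reported for single-GRM reading.

On top of the solver sit the two headline analyses: the comparison of a
class's h2 against five size-matched random intergenic SNP sets (significant
when outside mean +/- 2 x the spread of the replicate h2 values), and the
per-SNP genetic variance (h2 / n_snps) x 100 / 1e-4.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import AnnotationTable, GenotypeMatrix, TraitDesign, ValidationError
from .grm import Grm, GrmUnusableError, compute_grm

logger = logging.getLogger(__name__)

_FLOOR_FRACTION = 1e-8  # variance floor as a fraction of var(y)
_RIDGE = 1e-6  # diagonal ridge applied only when V fails to factorize


@dataclass
class RemlFit:
    component_names: list[str]  # GRM class names + "residual"
    variances: np.ndarray
    se_variances: np.ndarray
    h2: dict[str, float]  # per genetic component, over total variance
    se_h2: dict[str, float]
    h2_pairwise: dict[str, float]  # sigma_c / (sigma_c + sigma_e)
    loglik: float
    n_iterations: int
    converged: bool
    constrained: list[str]
    n: int
    var_y: float

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())


def _align_grm(grm: Grm, ids: list[str]) -> np.ndarray:
    index = {v: i for i, v in enumerate(grm.ids)}
    missing = [v for v in ids if v not in index]
    if missing:
        raise ValidationError(
            f"GRM {grm.class_name!r} lacks phenotyped individuals: {missing[:5]}"
        )
    idx = np.array([index[v] for v in ids])
    return grm.values[np.ix_(idx, idx)]


def _restricted_loglik(
    y: np.ndarray, X: np.ndarray, Gs: list[np.ndarray], sigma: np.ndarray
) -> float:
    """Restricted log-likelihood at a variance-component vector (cheap path)."""
    n = y.size
    V = sigma[-1] * np.eye(n)
    for s, G in zip(sigma[:-1], Gs):
        V += s * G
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        V[np.diag_indices_from(V)] += _RIDGE * float(np.var(y))
        c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv_X = cho_solve((c, low), X)
    Vinv_y = cho_solve((c, low), y)
    XtVX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    yPy = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + yPy)


def fit_reml(
    design: TraitDesign,
    grms: list[Grm] | Grm,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RemlFit:
    """AI-REML fit of one or several GRMs plus a residual component."""
    if isinstance(grms, Grm):
        grms = [grms]
    if not grms:
        raise ValidationError("need at least one GRM")
    y, X = design.y, design.X
    n = y.size
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular fixed-effect design")
    Gs = [_align_grm(g, design.ids) for g in grms]
    names = [g.class_name for g in grms] + ["residual"]
    k = len(Gs) + 1

    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValidationError("phenotype has zero variance")
    floor = _FLOOR_FRACTION * var_y
    sigma = np.full(k, var_y / k)

    def clamp(s: np.ndarray) -> np.ndarray:
        return np.maximum(s, floor)

    ll = _restricted_loglik(y, X, Gs, sigma)
    converged = False
    it = 0
    ridged = False
    for it in range(1, max_iter + 1):
        # full quantities at current sigma
        V = sigma[-1] * np.eye(n)
        for s, G in zip(sigma[:-1], Gs):
            V += s * G
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            V[np.diag_indices_from(V)] += _RIDGE * var_y
            c, low = cho_factor(V, lower=True)
            if not ridged:
                logger.info("added ridge %.1e to V diagonal", _RIDGE * var_y)
                ridged = True
        Vinv = cho_solve((c, low), np.eye(n))
        VinvX = Vinv @ X
        XtVX = X.T @ VinvX
        P = Vinv - VinvX @ np.linalg.solve(XtVX, VinvX.T)
        Py = P @ y

        U = np.empty((n, k))
        trPG = np.empty(k)
        for i, G in enumerate(Gs):
            U[:, i] = G @ Py
            trPG[i] = float(np.sum(P * G))
        U[:, -1] = Py
        trPG[-1] = float(np.trace(P))
        yPGPy = Py @ U  # vector of y'P G_i P y
        score = 0.5 * (yPGPy - trPG)
        AI = 0.5 * (U.T @ (P @ U))

        accepted = False
        # active set: components at the floor whose gradient points further
        # down stay fixed this iteration, so the AI system is not distorted
        # by clamped directions
        at_floor = sigma <= floor * (1 + 1e-6)
        active = ~(at_floor & (score < 0))
        if not active.any():
            converged = True
            break
        delta = None
        try:
            delta_a = np.linalg.solve(AI[np.ix_(active, active)], score[active])
            delta = np.zeros(k)
            delta[active] = delta_a
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(12):
                cand = clamp(sigma + step * delta)
                cand_ll = _restricted_loglik(y, X, Gs, cand)
                if cand_ll >= ll - 1e-10:
                    sigma, new_ll, accepted = cand, cand_ll, True
                    break
                step *= 0.5
        if not accepted:
            # EM fallback: guaranteed ascent direction, also step-halved
            em = sigma + (sigma**2) * (yPGPy - trPG) / n
            step = 1.0
            for _ in range(12):
                cand = clamp(sigma + step * (em - sigma))
                cand_ll = _restricted_loglik(y, X, Gs, cand)
                if cand_ll >= ll - 1e-10:
                    sigma, new_ll, accepted = cand, cand_ll, True
                    break
                step *= 0.5
        if not accepted:
            converged = True  # no ascent possible: at a (boundary) optimum
            break
        if abs(new_ll - ll) < tol * (1.0 + abs(ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    else:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations", stacklevel=2
        )

    # final quantities for SEs
    V = sigma[-1] * np.eye(n)
    for s, G in zip(sigma[:-1], Gs):
        V += s * G
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        V[np.diag_indices_from(V)] += _RIDGE * var_y
        c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    VinvX = Vinv @ X
    P = Vinv - VinvX @ np.linalg.solve(X.T @ VinvX, VinvX.T)
    Py = P @ y
    U = np.empty((n, k))
    for i, G in enumerate(Gs):
        U[:, i] = G @ Py
    U[:, -1] = Py
    AI = 0.5 * (U.T @ (P @ U))

    pinned = sigma <= floor * (1 + 1e-6)
    constrained = [names[i] for i in np.flatnonzero(pinned)]
    free = ~pinned
    cov = np.zeros((k, k))
    if free.any():
        AI_free = AI[np.ix_(free, free)]
        try:
            cov_free = np.linalg.inv(AI_free)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(AI_free)
        cov[np.ix_(free, free)] = cov_free
    se_var = np.sqrt(np.clip(np.diag(cov), 0, None))

    total = float(sigma.sum())
    h2 = {names[i]: float(sigma[i] / total) for i in range(k - 1)}
    h2_pair = {
        names[i]: float(sigma[i] / (sigma[i] + sigma[-1])) for i in range(k - 1)
    }
    se_h2 = {}
    for i in range(k - 1):
        grad = np.full(k, -sigma[i] / total**2)
        grad[i] += 1.0 / total
        se_h2[names[i]] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    return RemlFit(
        component_names=names,
        variances=sigma,
        se_variances=se_var,
        h2=h2,
        se_h2=se_h2,
        h2_pairwise=h2_pair,
        loglik=ll,
        n_iterations=it,
        converged=converged,
        constrained=constrained,
        n=n,
        var_y=var_y,
    )


# ---------------------------------------------------------------------------
# random intergenic comparison
# ---------------------------------------------------------------------------


@dataclass
class RandomSetComparison:
    class_name: str
    trait: str
    class_h2: float
    class_se: float
    replicate_h2: list[float]
    mean_random_h2: float
    random_se: float  # spread (sd, ddof=1) of the replicate h2 values
    difference: float
    significant: str  # "increase", "decrease" or "ns"; "NA" if undecidable
    n_snps: int
    seeds: list[int] = field(default_factory=list)


def random_intergenic_comparison(
    design: TraitDesign,
    genotypes: GenotypeMatrix,
    annotations: AnnotationTable,
    class_name: str,
    trait: str = "trait",
    n_reps: int = 5,
    master_seed: int = 0,
    intergenic_class: str = "intergenic",
    class_fit: RemlFit | None = None,
) -> RandomSetComparison:
    """Does a class explain more variance than matched random intergenic SNPs?

    Fits the class GRM, then `n_reps` GRMs each built from the same number of
    SNPs sampled without replacement from the intergenic set.  The class is
    flagged a significant increase (decrease) when its h2 lies above (below)
    the replicate mean by more than twice the spread of the replicate h2
    values.  Non-convergent replicates are excluded; with fewer than two
    survivors the comparison is reported NA.
    """
    members = annotations.members(class_name)
    n_class = len(members)
    intergenic = annotations.members(intergenic_class)
    if n_class > len(intergenic):
        raise ValidationError(
            f"class {class_name!r} ({n_class} SNPs) larger than the "
            f"intergenic pool ({len(intergenic)})"
        )
    if n_reps < 2:
        warnings.warn("n_reps < 2: no replicate SE definable, comparison is NA",
                      stacklevel=2)

    if class_fit is None:
        class_fit = fit_reml(design, compute_grm(genotypes, members, class_name))
    class_h2 = class_fit.h2[class_name]
    class_se = class_fit.se_h2[class_name]

    values: list[float] = []
    seeds: list[int] = []
    for r in range(n_reps):
        seed = (int(master_seed) + r) % (2**31)
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        draw = [intergenic[i] for i in rng.choice(len(intergenic), n_class, replace=False)]
        try:
            fit = fit_reml(design, compute_grm(genotypes, draw, f"random{r}"))
        except (GrmUnusableError, ValidationError) as exc:
            logger.info("replicate %d unusable: %s", r, exc)
            continue
        if not fit.converged:
            logger.info("replicate %d non-convergent; excluded", r)
            continue
        values.append(fit.h2[f"random{r}"])

    if len(values) < 2:
        return RandomSetComparison(
            class_name, trait, class_h2, class_se, values,
            float("nan"), float("nan"), float("nan"), "NA", n_class, seeds,
        )
    mean_r = float(np.mean(values))
    se_r = float(np.std(values, ddof=1))
    diff = class_h2 - mean_r
    if diff > 2 * se_r:
        flag = "increase"
    elif diff < -2 * se_r:
        flag = "decrease"
    else:
        flag = "ns"
    return RandomSetComparison(
        class_name, trait, class_h2, class_se, values,
        mean_r, se_r, diff, flag, n_class, seeds,
    )


def per_snp_variance(h2: float, n_snps: int) -> float:
    """Genetic variance explained per SNP: (h2 / n) x 100 / 1e-4.

    h2 = 0.20 over 2000 SNPs gives 100.0; doubling n at fixed h2 halves it.
    """
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    if h2 < 0:
        raise ValidationError("h2 must be >= 0")
    return (h2 / n_snps) * 100.0 / 1e-4
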