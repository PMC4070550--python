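"""Shared data model: genotypes, annotation classes, GWAS p-values, trait designs.

SNP identity is by id string only; genomic coordinates never enter the
analysis (annotation classes are pure SNP sets).  Missing genotypes are kept
as NaN in the stored matrix and only mean-imputed inside GRM construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


class ValidationError(ValueError):
    """An in-memory table violates one of its invariants."""


class FormatError(ValueError):
    """An input file cannot be parsed into a valid table."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of allele counts in {0, 1, 2, NaN}.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (rows).
    snp_ids : list of str
        SNP identifiers (columns).
    counts : ndarray of float, shape (n_individuals, n_snps)
        Allele counts; missing genotypes are NaN.
    """

    ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray
    _freqs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.snp_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        bad = ~(np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"genotype for individual {self.ids[i]!r}, SNP {self.snp_ids[j]!r} "
                f"is {self.counts[i, j]!r}; allele counts must be 0, 1, 2 or missing"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate individual ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def freqs(self) -> np.ndarray:
        """Per-SNP sample allele frequency p_i, missing genotypes excluded."""
        if self._freqs is None:
            with np.errstate(invalid="ignore"):
                self._freqs = np.nanmean(self.counts, axis=0) / 2.0
        return self._freqs

    def snp_indexer(self, snp_ids: list[str]) -> np.ndarray:
        """Column indices of the requested SNP ids, in the requested order."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise ValidationError(f"SNP ids not in genotype matrix: {missing[:5]}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = self.snp_indexer(snp_ids)
        return GenotypeMatrix(list(self.ids), list(snp_ids), self.counts[:, idx])


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationClass:
    """A named functional class with an optional parent (nesting)."""

    name: str
    parent: str | None = None


@dataclass
class AnnotationTable:
    """Per-SNP binary memberships in a registry of (possibly nested) classes.

    `membership[i, c] == 1` iff SNP i belongs to class c.  Nesting closure
    (every member of a child class is a member of its parent) is a validated
    invariant, mirroring e.g. synonymous ⊂ CDS ⊂ intragenic.
    """

    snp_ids: list[str]
    classes: list[AnnotationClass]
    membership: np.ndarray
    conservation_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.uint8)
        if self.membership.shape != (len(self.snp_ids), len(self.classes)):
            raise ValidationError(
                f"membership shape {self.membership.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.classes)} classes"
            )
        if not np.isin(self.membership, (0, 1)).all():
            raise ValidationError("membership entries must be 0/1")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate class names in registry")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids in annotation table")
        self._check_acyclic()
        self._check_closure()
        if self.conservation_score is not None:
            self.conservation_score = np.asarray(self.conservation_score, dtype=float)
            if self.conservation_score.shape != (len(self.snp_ids),):
                raise ValidationError("conservation_score length mismatch")

    def _check_acyclic(self) -> None:
        parents = {c.name: c.parent for c in self.classes}
        for name in parents:
            seen = {name}
            node = parents[name]
            while node is not None:
                if node not in parents:
                    raise ValidationError(f"class {name!r} has unknown parent {node!r}")
                if node in seen:
                    raise ValidationError(f"cycle in class registry at {node!r}")
                seen.add(node)
                node = parents[node]

    def _check_closure(self) -> None:
        col = {c.name: i for i, c in enumerate(self.classes)}
        for c in self.classes:
            if c.parent is None:
                continue
            child = self.membership[:, col[c.name]].astype(bool)
            parent = self.membership[:, col[c.parent]].astype(bool)
            violated = child & ~parent
            if violated.any():
                bad = [self.snp_ids[i] for i in np.flatnonzero(violated)[:5]]
                raise ValidationError(
                    f"nesting violated: SNPs {bad} in {c.name!r} but not in "
                    f"parent {c.parent!r}"
                )

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def column(self, class_name: str) -> int:
        try:
            return self.class_names.index(class_name)
        except ValueError:
            raise ValidationError(f"unknown annotation class {class_name!r}") from None

    def members_mask(self, class_name: str) -> np.ndarray:
        return self.membership[:, self.column(class_name)].astype(bool)

    def members(self, class_name: str) -> list[str]:
        return [s for s, m in zip(self.snp_ids, self.members_mask(class_name)) if m]

    def n_members(self, class_name: str) -> int:
        return int(self.membership[:, self.column(class_name)].sum())

    def usable(self, class_name: str, min_snps: int = 1) -> bool:
        """Whether the class has enough SNPs to build a GRM on."""
        return self.n_members(class_name) >= min_snps

    def reordered(self, snp_ids: list[str]) -> "AnnotationTable":
        """Row-align to a reference SNP id order (alignment is id-pure)."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise ValidationError(f"annotation table lacks SNPs: {missing[:5]}")
        idx = np.array([lookup[s] for s in snp_ids], dtype=int)
        score = None if self.conservation_score is None else self.conservation_score[idx]
        return AnnotationTable(list(snp_ids), list(self.classes), self.membership[idx], score)


def filter_by_score(
    table: AnnotationTable, class_name: str, min_score: float
) -> AnnotationTable:
    """Retain membership of `class_name` only where conservation score >= min_score.

    The inclusive threshold mirrors conservation filtering at a cut-off such as
    0.800 (a score exactly at the cut-off is kept).  Other classes untouched.
    """
    col = table.column(class_name)
    mask = table.members_mask(class_name)
    if table.conservation_score is None:
        raise ValidationError("annotation table has no conservation scores")
    scores = table.conservation_score
    unscored = mask & np.isnan(scores)
    if unscored.any():
        bad = [table.snp_ids[i] for i in np.flatnonzero(unscored)[:10]]
        raise ValidationError(
            f"members of {class_name!r} without conservation score: {bad}"
        )
    membership = table.membership.copy()
    keep = mask & (scores >= min_score)
    membership[:, col] = keep.astype(np.uint8)
    return AnnotationTable(
        list(table.snp_ids), list(table.classes), membership, scores.copy()
    )


# ---------------------------------------------------------------------------
# GWAS p-values
# ---------------------------------------------------------------------------


@dataclass
class GwasTable:
    """Per-SNP, per-trait association p-values in (0, 1]."""

    snp_ids: list[str]
    traits: list[str]
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.pvalues.ndim == 1:
            self.pvalues = self.pvalues[:, None]
        if self.pvalues.shape != (len(self.snp_ids), len(self.traits)):
            raise ValidationError(
                f"pvalues shape {self.pvalues.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.traits)} traits"
            )
        if not np.isfinite(self.pvalues).all():
            raise ValidationError("non-finite p-values")
        if (self.pvalues <= 0).any():
            i, j = map(int, np.argwhere(self.pvalues <= 0)[0])
            raise ValidationError(
                f"p-value for SNP {self.snp_ids[i]!r}, trait {self.traits[j]!r} "
                "is <= 0; p-values must lie in (0, 1]"
            )
        if (self.pvalues > 1).any():
            raise ValidationError("p-values above 1")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids in GWAS table")

    def trait_pvalues(self, trait: str) -> np.ndarray:
        try:
            j = self.traits.index(trait)
        except ValueError:
            raise ValidationError(f"unknown trait {trait!r}") from None
        return self.pvalues[:, j]

    def reordered(self, snp_ids: list[str]) -> "GwasTable":
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise ValidationError(f"GWAS table lacks SNPs: {missing[:5]}")
        idx = np.array([lookup[s] for s in snp_ids], dtype=int)
        return GwasTable(list(snp_ids), list(self.traits), self.pvalues[idx])


# ---------------------------------------------------------------------------
# trait design
# ---------------------------------------------------------------------------


@dataclass
class TraitDesign:
    """Phenotype vector plus fixed-effect design (intercept + covariates)."""

    ids: list[str]
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValidationError("X rows must match length of y")
        if len(self.ids) != self.y.size:
            raise ValidationError("ids must match length of y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValidationError(
                f"fixed-effect design is rank deficient (columns {self.covariate_names})"
            )

    @property
    def n(self) -> int:
        return self.y.size


def build_design(
    pheno: pd.DataFrame,
    trait: str,
    covariates: list[str] | None = None,
    id_column: str = "iid",
) -> TraitDesign:
    """Build a TraitDesign from a phenotype/covariate DataFrame.

    Categorical covariates are reference-level (drop-first) dummy coded on top
    of an intercept, the usual coding for covariates such as breed and sex.
    """
    covariates = covariates or []
    for c in [id_column, trait, *covariates]:
        if c not in pheno.columns:
            raise ValidationError(f"phenotype table lacks column {c!r}")
    y = pheno[trait].to_numpy(dtype=float)
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        dummies = pd.get_dummies(pheno[cov].astype("category"), drop_first=True)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(dtype=float))
            names.append(f"{cov}={level}")
    X = np.column_stack(cols)
    return TraitDesign(list(pheno[id_column].astype(str)), y, X, names)
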