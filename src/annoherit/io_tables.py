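"""Readers and writers for the pipeline's plain-text table formats.

All tables are tab-delimited with a header row.  The annotation format
carries the class registry (parent links) in `#class` comment lines so a
round-trip preserves nesting.  GRMs are persisted in a GCTA-text-like lower
triangle layout (id1, id2, n_snps, value).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    AnnotationClass,
    AnnotationTable,
    FormatError,
    GenotypeMatrix,
    GwasTable,
)

_MISSING_CODES = {"NA", "NaN", "nan", ".", ""}


def _check_rectangular(path: str | Path, comment: str | None = None) -> None:
    """Reject silently-truncated files: every row must have the header's width."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        width = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (comment and row[0].startswith(comment)):
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {width}"
                )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix.

    format="tsv": first column `iid`, one column of {0,1,2,NA} per SNP.
    format="raw": PLINK --recode A style; the first six columns
    (FID IID PAT MAT SEX PHENOTYPE) are metadata, IID is the individual id.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if format == "tsv":
        if df.columns[0] != "iid":
            raise FormatError(f"{path}: first column must be 'iid', got {df.columns[0]!r}")
        ids = df.iloc[:, 0].tolist()
        snp_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]
    elif format == "raw":
        expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != expected:
            raise FormatError(f"{path}: PLINK raw header must start with {expected}")
        ids = df["IID"].tolist()
        snp_ids = list(df.columns[6:])
        body = df.iloc[:, 6:]
    else:
        raise FormatError(f"unknown genotype format {format!r}")

    counts = np.empty(body.shape, dtype=float)
    values = body.to_numpy()
    for j, snp in enumerate(snp_ids):
        for i, raw in enumerate(values[:, j]):
            token = "" if raw is None else str(raw).strip()
            if token in _MISSING_CODES:
                counts[i, j] = np.nan
            elif token in ("0", "1", "2"):
                counts[i, j] = float(token)
            else:
                raise FormatError(
                    f"{path}: invalid allele count {token!r} at individual "
                    f"{ids[i]!r}, SNP {snp!r} (row {i + 2}, column {snp!r})"
                )
    return GenotypeMatrix(ids, snp_ids, counts)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("iid\t" + "\t".join(genotypes.snp_ids) + "\n")
        for i, iid in enumerate(genotypes.ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in genotypes.counts[i]
            ]
            fh.write(iid + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read an annotation table: `#class <name> <parent|.>` comment lines, then
    a header `snp_id`, one 0/1 column per class, optional `conservation_score`."""
    registry: list[AnnotationClass] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#class" and len(parts) == 3:
                parent = None if parts[2] == "." else parts[2]
                registry.append(AnnotationClass(parts[1], parent))
    _check_rectangular(path, comment="#")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "snp_id":
        raise FormatError(f"{path}: first column must be 'snp_id'")
    snp_ids = df["snp_id"].astype(str).tolist()
    score = None
    if "conservation_score" in df.columns:
        score = df["conservation_score"].to_numpy(dtype=float)
    class_cols = [
        c for c in df.columns[1:] if c != "conservation_score"
    ]
    if registry:
        names = [c.name for c in registry]
        if set(names) != set(class_cols):
            raise FormatError(
                f"{path}: registry classes {names} do not match columns {class_cols}"
            )
        # column order follows the registry
        class_cols = names
    else:
        registry = [AnnotationClass(c) for c in class_cols]
    membership = df[class_cols].to_numpy()
    if not np.isin(membership, (0, 1)).all():
        raise FormatError(f"{path}: membership entries must be 0/1")
    return AnnotationTable(snp_ids, registry, membership.astype(np.uint8), score)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in table.classes:
            fh.write(f"#class\t{c.name}\t{c.parent or '.'}\n")
        header = ["snp_id", *table.class_names]
        if table.conservation_score is not None:
            header.append("conservation_score")
        fh.write("\t".join(header) + "\n")
        for i, snp in enumerate(table.snp_ids):
            row = [snp, *(str(int(v)) for v in table.membership[i])]
            if table.conservation_score is not None:
                s = table.conservation_score[i]
                row.append("NA" if np.isnan(s) else f"{s:.6g}")
            fh.write("\t".join(row) + "\n")


def export_bed(table: AnnotationTable, class_name: str, path: str | Path) -> None:
    """Export a class's SNPs as a 0-based half-open BED with fabricated
    coordinates (one synthetic chromosome, unit-spaced positions).

    The analysis itself is coordinate-free; this exists for interoperability
    round-trips only.
    """
    mask = table.members_mask(class_name)
    with open(path, "w") as fh:
        for i in np.flatnonzero(mask):
            fh.write(f"chrS\t{i}\t{i + 1}\t{table.snp_ids[i]}\n")


# ---------------------------------------------------------------------------
# GWAS tables
# ---------------------------------------------------------------------------


def read_gwas(path: str | Path) -> GwasTable:
    """Read per-SNP, per-trait p-values: header `snp_id` + one column per trait."""
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "snp_id":
        raise FormatError(f"{path}: first column must be 'snp_id'")
    snp_ids = df["snp_id"].astype(str).tolist()
    traits = list(df.columns[1:])
    if not traits:
        raise FormatError(f"{path}: no trait columns")
    pvalues = df[traits].to_numpy(dtype=float)
    if (pvalues <= 0).any():
        i, j = map(int, np.argwhere(pvalues <= 0)[0])
        raise FormatError(
            f"{path}: p-value {pvalues[i, j]} for SNP {snp_ids[i]!r}, trait "
            f"{traits[j]!r} is <= 0 (p = 0 is rejected: -log10 is undefined)"
        )
    return GwasTable(snp_ids, traits, pvalues)


def write_gwas(gwas: GwasTable, path: str | Path) -> None:
    df = pd.DataFrame(gwas.pvalues, columns=gwas.traits)
    df.insert(0, "snp_id", gwas.snp_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# phenotypes / misc
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "iid":
        raise FormatError(f"{path}: first column must be 'iid'")
    df["iid"] = df["iid"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_truth(truth: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GRM text format
# ---------------------------------------------------------------------------


def write_grm(grm, path: str | Path) -> None:
    """Persist a GRM as lower triangle + diagonal: id1, id2, n_snps, value."""
    with open(path, "w") as fh:
        fh.write(f"#class\t{grm.class_name}\n")
        fh.write("id1\tid2\tn_snps\tvalue\n")
        for i, id1 in enumerate(grm.ids):
            for j in range(i + 1):
                fh.write(
                    f"{id1}\t{grm.ids[j]}\t{grm.n_snps}\t{grm.values[i, j]:.12g}\n"
                )


def read_grm(path: str | Path):
    from .grm import Grm

    class_name = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#class"):
            class_name = first.rstrip("\n").split("\t")[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    ids: list[str] = []
    seen = set()
    for v in df["id1"].astype(str):
        if v not in seen:
            seen.add(v)
            ids.append(v)
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    values = np.zeros((n, n))
    for id1, id2, val in zip(df["id1"].astype(str), df["id2"].astype(str), df["value"]):
        i, j = index[id1], index[id2]
        values[i, j] = values[j, i] = val
    n_snps = int(df["n_snps"].iloc[0])
    return Grm(class_name, ids, values, n_snps, [])
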