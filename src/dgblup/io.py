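"""Plain-text readers and writers for genotypes, pedigrees, phenotypes,
marker effects and relationship matrices.

Genotypes travel as a tab-separated table: a header row of locus ids, then
one row per individual (id followed by 0/1/2 codes, NA for missing; post-QC
files may hold fractional imputed dosages). Pedigree and phenotype tables
are CSV with named columns. Relationship matrices round-trip as long-format
TSV over the upper triangle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerEffects
from .relmat import RelationshipMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_effects",
    "write_effects",
    "read_matrix",
    "write_matrix",
]

_MISSING_TOKENS = {"NA", "NaN", "nan", ""}


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, genotypes.locus_ids)) + "\n")
        for i in range(genotypes.n):
            row = genotypes.codes[i]
            toks = [
                "NA"
                if np.isnan(c)
                else (str(int(c)) if float(c).is_integer() else repr(float(c)))
                for c in row
            ]
            fh.write(str(genotypes.ids[i]) + "\t" + "\t".join(toks) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Parse a genotype TSV; malformed tokens raise with the line number."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise ValueError(f"{path}: line 1: first header column must be 'id'")
        locus_ids = np.array(header[1:])
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            toks = line.rstrip("\n").split("\t")
            if len(toks) != len(locus_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(locus_ids) + 1} "
                    f"columns, found {len(toks)}"
                )
            ids.append(toks[0])
            vals = np.empty(len(locus_ids))
            for j, t in enumerate(toks[1:]):
                if t in _MISSING_TOKENS:
                    vals[j] = np.nan
                else:
                    try:
                        x = float(t)
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: invalid genotype token {t!r}"
                        ) from None
                    if not (0.0 <= x <= 2.0):
                        raise ValueError(
                            f"{path}: line {lineno}: genotype {t!r} outside [0, 2]"
                        )
                    vals[j] = x
            rows.append(vals)
    return GenotypeMatrix(
        codes=np.array(rows), ids=np.array(ids), locus_ids=locus_ids
    )


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"{path}: pedigree is missing column {col!r}")
    df[["sire", "dam"]] = df[["sire", "dam"]].fillna("")
    if "generation" not in df.columns:
        df["generation"] = np.where((df["sire"] == "") & (df["dam"] == ""), 0, 1)
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "yd", "eop"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table is missing column {col!r}")
    if (df["eop"] <= 0).any():
        raise ValueError(f"{path}: EOP weights must be positive")
    return df


def align_phenotypes(
    genotypes: GenotypeMatrix, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Inner alignment of phenotypes to genotyped individuals; ids present
    in the phenotype file but not genotyped (or vice versa) are reported."""
    geno_ids = set(map(str, genotypes.ids))
    pheno_ids = set(phenotypes["id"])
    missing = sorted(pheno_ids - geno_ids)
    if missing:
        raise ValueError(
            f"phenotyped ids without genotypes: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    order = {v: i for i, v in enumerate(map(str, genotypes.ids))}
    return phenotypes.sort_values(by="id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )


def write_effects(effects: MarkerEffects, locus_ids, path) -> None:
    pd.DataFrame({"locus": locus_ids, "a": effects.a, "d": effects.d}).to_csv(
        path, sep="\t", index=False
    )


def read_effects(path) -> tuple[MarkerEffects, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return MarkerEffects(a=df["a"].to_numpy(), d=df["d"].to_numpy()), df[
        "locus"
    ].to_numpy()


def write_matrix(M: RelationshipMatrix, path) -> None:
    """Upper triangle (including diagonal) as long-format TSV."""
    iu = np.triu_indices(M.n)
    df = pd.DataFrame(
        {
            "i": M.ids[iu[0]],
            "j": M.ids[iu[1]],
            "value": M.values[iu],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# kind={M.kind}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix(path) -> RelationshipMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        kind = first.split("kind=")[1] if first.startswith("#") else "A"
        df = pd.read_csv(fh, sep="\t", dtype={"i": str, "j": str})
    ids = list(dict.fromkeys(df["i"]))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    M = np.zeros((n, n))
    for i, j, v in zip(df["i"], df["j"], df["value"]):
        M[index[i], index[j]] = M[index[j], index[i]] = v
    return RelationshipMatrix(values=M, kind=kind, ids=np.array(ids))
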