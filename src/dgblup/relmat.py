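"""Pedigree and genomic relationship matrices.

Builds Wright's numerator relationship matrix A from a pedigree (tabular
method), the VanRaden genomic additive matrix G* = W_a W_a' / (2 sum p q)
from centered allele counts, and the genomic dominance matrix
D* = W_d W_d' / (4 sum p^2 q^2) from the dominance coding. G* is rescaled so
its mean diagonal and mean off-diagonal match A, then blended
G = 0.95 G* + 0.05 A; D is blended with the identity, D = 0.95 D* + 0.05 I,
both for numerical stability of downstream mixed-model solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "MarkerDesign",
    "marker_design",
    "pedigree_A",
    "build_G_star",
    "build_D_star",
    "scale_to_A",
    "blend",
    "offdiag_summary",
    "build_G",
    "build_D",
]


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship structure with a kind tag."""

    values: np.ndarray
    kind: str  # one of A, G_star, G, D_star, D, I
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("id list does not match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        # enforce exact symmetry for downstream linear algebra
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids) -> "RelationshipMatrix":
        index = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids absent from relationship matrix: {missing[:5]}")
        rows = np.array([index[i] for i in ids])
        return RelationshipMatrix(
            values=self.values[np.ix_(rows, rows)], kind=self.kind, ids=np.asarray(ids)
        )


@dataclass
class MarkerDesign:
    """Centered additive (W_a) and dominance (W_d) design matrices.

    W_a entries are 2-2p, 1-2p, -2p for codes 2, 1, 0 (zero for mean-imputed
    codes); W_d entries are -2q^2, 2pq, -2p^2 (zero for imputed). The
    denominators 2*sum(p q) and 4*sum(p^2 q^2) normalise the cross-products
    to relationship scale.
    """

    W_a: np.ndarray
    W_d: np.ndarray
    denom_a: float
    denom_d: float


def marker_design(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> MarkerDesign:
    """Build W_a, W_d and their denominators from a complete genotype matrix.

    ``freqs`` overrides the observed allele frequencies (e.g. base-population
    frequencies supplied externally).
    """
    if genotypes.has_missing:
        raise ValueError("genotypes contain missing codes; run QC first")
    codes = genotypes.codes
    p = genotypes.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    q = 1.0 - p
    W_a = codes - 2.0 * p
    W_d = np.zeros_like(codes)
    W_d[codes == 2.0] = (-2.0 * q**2 * np.ones_like(codes))[codes == 2.0]
    W_d[codes == 1.0] = (2.0 * p * q * np.ones_like(codes))[codes == 1.0]
    W_d[codes == 0.0] = (-2.0 * p**2 * np.ones_like(codes))[codes == 0.0]
    denom_a = float(2.0 * np.sum(p * q))
    denom_d = float(4.0 * np.sum(p**2 * q**2))
    if denom_a <= 0 or denom_d <= 0:
        raise ValueError("all loci monomorphic: relationship denominators are zero")
    return MarkerDesign(W_a=W_a, W_d=W_d, denom_a=denom_a, denom_d=denom_d)


def pedigree_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    Requires parents to precede offspring (topological order); founders are
    taken as unrelated and non-inbred. A cycle (an individual among its own
    ancestors) surfaces as an ordering violation.
    """
    ids = pedigree["id"].to_numpy()
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    A = np.zeros((n, n))
    for i in range(n):
        s = index.get(sires[i], -1) if sires[i] != "" else -1
        d = index.get(dams[i], -1) if dams[i] != "" else -1
        if (sires[i] != "" and s == -1) or (dams[i] != "" and d == -1):
            raise ValueError(
                f"parent of {ids[i]!r} not listed before it (unordered or cyclic "
                "pedigree)"
            )
        if s >= i or d >= i:
            raise ValueError(f"pedigree not topologically ordered at {ids[i]!r}")
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += A[:i, s]
        if d >= 0:
            row += A[:i, d]
        A[i, :i] = A[:i, i] = 0.5 * row
    return RelationshipMatrix(values=A, kind="A", ids=ids)


def build_G_star(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G* = W_a W_a' / (2 sum p q)."""
    md = marker_design(genotypes, freqs)
    G = md.W_a @ md.W_a.T / md.denom_a
    return RelationshipMatrix(values=G, kind="G_star", ids=genotypes.ids)


def build_D_star(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Genomic dominance relationship matrix D* = W_d W_d' / (4 sum p^2 q^2)."""
    md = marker_design(genotypes, freqs)
    D = md.W_d @ md.W_d.T / md.denom_d
    return RelationshipMatrix(values=D, kind="D_star", ids=genotypes.ids)


def _mean_diag_offdiag(M: np.ndarray) -> tuple[float, float]:
    n = M.shape[0]
    md = float(np.trace(M) / n)
    mo = float((M.sum() - np.trace(M)) / (n * (n - 1))) if n > 1 else 0.0
    return md, mo


def scale_to_A(G_star: RelationshipMatrix, A: RelationshipMatrix) -> RelationshipMatrix:
    """Affine rescaling alpha + beta*G* matching A's mean diagonal and mean
    off-diagonal (the unique affine map satisfying both moment conditions)."""
    if G_star.n != A.n:
        raise ValueError("matrix dimensions differ")
    md_g, mo_g = _mean_diag_offdiag(G_star.values)
    md_a, mo_a = _mean_diag_offdiag(A.values)
    spread = md_g - mo_g
    if abs(spread) < 1e-12:
        raise ValueError(
            "degenerate scaling: G* mean diagonal equals mean off-diagonal"
        )
    beta = (md_a - mo_a) / spread
    alpha = md_a - beta * md_g
    return RelationshipMatrix(
        values=alpha + beta * G_star.values, kind="G_star", ids=G_star.ids
    )


def blend(
    M_star: RelationshipMatrix,
    partner: RelationshipMatrix,
    weight: float = 0.95,
    kind: str | None = None,
) -> RelationshipMatrix:
    """weight*M* + (1-weight)*partner; A is the partner for the additive
    matrix, the identity for the dominance matrix."""
    if not (0.0 <= weight <= 1.0):
        raise ValueError("blend weight must lie in [0, 1]")
    if M_star.n != partner.n:
        raise ValueError("matrix dimensions differ")
    values = weight * M_star.values + (1.0 - weight) * partner.values
    if kind is None:
        kind = "G" if M_star.kind.startswith("G") else "D"
    return RelationshipMatrix(values=values, kind=kind, ids=M_star.ids)


def identity_matrix(ids) -> RelationshipMatrix:
    ids = np.asarray(ids)
    return RelationshipMatrix(values=np.eye(len(ids)), kind="I", ids=ids)


def build_G(
    genotypes: GenotypeMatrix,
    A: RelationshipMatrix,
    weight: float = 0.95,
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """G* scaled to A's diagonal/off-diagonal means, then blended with A."""
    order = list(genotypes.ids)
    G_star = build_G_star(genotypes, freqs)
    return blend(scale_to_A(G_star, A.subset(order)), A.subset(order), weight, "G")


def build_D(
    genotypes: GenotypeMatrix, weight: float = 0.95, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """D* blended with the identity."""
    D_star = build_D_star(genotypes, freqs)
    return blend(D_star, identity_matrix(genotypes.ids), weight, "D")


def offdiag_summary(M: RelationshipMatrix, threshold: float = 0.05) -> dict:
    """Mean, SD and proportion of |value| > threshold over the strict upper
    triangle — the usual summary of how informative a relationship matrix is."""
    iu = np.triu_indices(M.n, k=1)
    vals = M.values[iu]
    if vals.size == 0:
        return {"mean": 0.0, "sd": 0.0, "prop_extreme": 0.0, "threshold": threshold}
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0)),
        "prop_extreme": float(np.mean(np.abs(vals) > threshold)),
        "threshold": threshold,
    }
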