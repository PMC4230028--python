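"""Shared in-memory containers for genotypes, marker effects and variance components.

Genotype codes count copies of the minor allele A1 (0, 1, 2). Missing calls
are stored as NaN; after quality control, missing codes are mean-imputed with
the expected dosage 2*p_k, so post-QC matrices may hold fractional codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerEffects",
    "VarianceComponents",
    "make_pedigree_table",
]


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-count matrix with locus metadata.

    Parameters
    ----------
    codes
        (n, m) array of minor-allele counts; NaN marks a missing call.
    ids
        Individual identifiers, length n.
    locus_ids
        Locus identifiers, length m.
    """

    codes: np.ndarray
    ids: np.ndarray
    locus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.ids = np.asarray(self.ids)
        self.locus_ids = np.asarray(self.locus_ids)
        n, m = self.codes.shape
        if len(self.ids) != n or len(self.locus_ids) != m:
            raise ValueError("id lists do not match genotype matrix shape")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.codes) & ((self.codes < 0) | (self.codes > 2))
        if bad.any():
            raise ValueError("genotype codes must lie in [0, 2] or be NaN")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def allele_freq(self) -> np.ndarray:
        """Observed A1 frequency per locus, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.codes, axis=0) / 2.0
        return p

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        cols = np.arange(self.m) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            codes=self.codes[np.ix_(rows, cols)],
            ids=self.ids[rows],
            locus_ids=self.locus_ids[cols],
        )


@dataclass
class MarkerEffects:
    """Per-locus additive (a) and dominance (d) effects in trait units.

    The substitution effect alpha_k = a_k + d_k (q_k - p_k) is always derived
    from (a, d, p); it is never stored independently.
    """

    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.a.shape != self.d.shape:
            raise ValueError("a and d must have equal length")

    @property
    def m(self) -> int:
        return self.a.size

    def alpha(self, p: np.ndarray) -> np.ndarray:
        """Allele substitution effects a + d(q - p) at frequencies ``p``."""
        p = np.asarray(p, dtype=float)
        return self.a + self.d * (1.0 - 2.0 * p)

    def genotypic_values(self, codes: np.ndarray) -> np.ndarray:
        """Total genotypic value per individual: +a, d, -a for codes 2, 1, 0."""
        codes = np.asarray(codes, dtype=float)
        het = (codes == 1.0).astype(float)
        return (codes - 1.0) @ self.a + het @ self.d


@dataclass
class VarianceComponents:
    """Animal-level variances (sigma_A^2, sigma_D^2, sigma_E^2), optionally
    with the marker-level pair (sigma_a^2, sigma_d^2)."""

    sigma_A2: float
    sigma_D2: float = 0.0
    sigma_E2: float = 0.0
    sigma_a2: float | None = None
    sigma_d2: float | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_A2", "sigma_D2", "sigma_E2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dominance_ratio(self) -> float:
        """sigma_D^2 / (sigma_A^2 + sigma_D^2), the share of dominance in the
        total genetic variance."""
        tot = self.sigma_A2 + self.sigma_D2
        if tot <= 0:
            return 0.0
        return self.sigma_D2 / tot


def make_pedigree_table(ids, sires, dams, generation) -> pd.DataFrame:
    """Assemble a pedigree DataFrame (id, sire, dam, generation).

    Unknown parents are encoded as the empty string "". Parents must appear
    before their offspring.
    """
    df = pd.DataFrame(
        {
            "id": np.asarray(ids),
            "sire": np.asarray(sires),
            "dam": np.asarray(dams),
            "generation": np.asarray(generation),
        }
    )
    seen: set = set()
    for row in df.itertuples(index=False):
        for parent in (row.sire, row.dam):
            if parent != "" and parent not in seen:
                raise ValueError(
                    f"parent {parent!r} of {row.id!r} does not precede it"
                )
        seen.add(row.id)
    return df
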