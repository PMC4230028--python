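"""SNP editing: call-rate, minor-allele-frequency and Hardy-Weinberg filters.

The pipeline mirrors routine chip-data editing: loci with call rate below a
threshold, MAF below a threshold, or a highly significant departure from
Hardy-Weinberg proportions are dropped; residual missing calls at retained
loci are mean-imputed with the expected dosage 2*p_k, which contributes zero
to the centered additive and dominance design matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "call_rate_filter",
    "maf_filter",
    "hwe_filter",
    "apply_qc",
]


@dataclass
class QCThresholds:
    call_rate: float = 0.9
    maf: float = 0.005
    hwe_alpha: float = 1e-5
    # "low" drops loci with MAF below the threshold (standard practice);
    # "high" drops loci above it.
    maf_direction: str = "low"


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_input: int
    excluded_call_rate: int
    excluded_maf: int
    excluded_hwe: int
    retained: int
    retained_locus_ids: np.ndarray = field(repr=False)
    n_imputed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.excluded_call_rate
            + self.excluded_maf
            + self.excluded_hwe
            + self.retained
        )
        if total != self.n_input:
            raise ValueError("exclusion counts do not add up to input loci")

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "call_rate": self.thresholds.call_rate,
                "maf": self.thresholds.maf,
                "hwe_alpha": self.thresholds.hwe_alpha,
                "maf_direction": self.thresholds.maf_direction,
            },
            "n_input": self.n_input,
            "excluded": {
                "call_rate": self.excluded_call_rate,
                "maf": self.excluded_maf,
                "hwe": self.excluded_hwe,
            },
            "retained": self.retained,
            "n_imputed": self.n_imputed,
        }


def call_rate_filter(genotypes: GenotypeMatrix, threshold: float = 0.9) -> np.ndarray:
    """Mask of loci whose fraction of non-missing calls is >= threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("call-rate threshold must lie in (0, 1]")
    called = 1.0 - np.isnan(genotypes.codes).mean(axis=0)
    return called >= threshold


def maf_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.005, direction: str = "low"
) -> np.ndarray:
    """Mask of loci kept by the MAF filter.

    With ``direction="low"`` loci with minor-allele frequency below the
    threshold are excluded.
    """
    p = genotypes.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    if direction == "low":
        return maf >= threshold
    if direction == "high":
        return maf <= threshold
    raise ValueError("direction must be 'low' or 'high'")


def hwe_chi2(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus 1-df goodness-of-fit chi-square against Hardy-Weinberg
    proportions at the observed allele frequency, and its P-value.

    Monomorphic loci have an undefined test; they are returned with
    chi2 = 0, P = 1 (they are the MAF filter's responsibility).
    """
    codes = genotypes.codes
    n11 = np.nansum(codes == 2.0, axis=0).astype(float)
    n12 = np.nansum(codes == 1.0, axis=0).astype(float)
    n22 = np.nansum(codes == 0.0, axis=0).astype(float)
    n = n11 + n12 + n22
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n11 + n12) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
        obs = np.stack([n11, n12, n22])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(
            axis=0
        )
    mono = (p <= 0) | (p >= 1) | np.isnan(p)
    chi2 = np.where(mono, 0.0, chi2)
    pval = stats.chi2.sf(chi2, df=1)
    pval = np.where(mono, 1.0, pval)
    return chi2, pval


def hwe_filter(genotypes: GenotypeMatrix, alpha: float = 1e-5) -> np.ndarray:
    """Mask of loci kept by the Hardy-Weinberg test (P >= alpha keeps)."""
    _, pval = hwe_chi2(genotypes)
    return pval >= alpha


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full editing pipeline and mean-impute surviving missing codes.

    Filters act conjunctively; the report attributes each excluded locus to
    the first filter it fails, in the order call rate -> MAF -> HWE. The
    output matrix has no missing codes (imputed dosage 2*p_k from observed
    calls) and loci reindexed.
    """
    thr = thresholds or QCThresholds()
    keep_cr = call_rate_filter(genotypes, thr.call_rate)
    keep_maf = maf_filter(genotypes, thr.maf, thr.maf_direction)
    keep_hwe = hwe_filter(genotypes, thr.hwe_alpha)

    fail_cr = ~keep_cr
    fail_maf = keep_cr & ~keep_maf
    fail_hwe = keep_cr & keep_maf & ~keep_hwe
    keep = keep_cr & keep_maf & keep_hwe

    codes = genotypes.codes[:, keep].copy()
    p = np.nanmean(codes, axis=0) / 2.0
    missing = np.isnan(codes)
    n_imputed = int(missing.sum())
    if n_imputed:
        codes[missing] = np.broadcast_to(2.0 * p, codes.shape)[missing]
    out = GenotypeMatrix(
        codes=codes, ids=genotypes.ids, locus_ids=genotypes.locus_ids[keep]
    )
    report = QCReport(
        thresholds=thr,
        n_input=genotypes.m,
        excluded_call_rate=int(fail_cr.sum()),
        excluded_maf=int(fail_maf.sum()),
        excluded_hwe=int(fail_hwe.sum()),
        retained=int(keep.sum()),
        retained_locus_ids=genotypes.locus_ids[keep],
        n_imputed=n_imputed,
    )
    return out, report
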