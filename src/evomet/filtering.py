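"""SNP-calling filters for pool-seq count tables.

A site is kept when every population's read depth lies in
``[min_cov, max_cov]`` (inclusive) and the pooled minor-allele frequency —
total alt reads over total reads across all populations, folded to <= 0.5 —
is at least ``min_maf``. These are the standard pool-seq calling criteria
for evolve-and-resequence scans (20-200x depth, 2% combined MAF).
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import SnpCountTable

__all__ = ["filter_snps", "snp_filter_mask"]


def snp_filter_mask(
    table: SnpCountTable,
    min_cov: int = 20,
    max_cov: int = 200,
    min_maf: float = 0.02,
    fold_maf: bool = True,
) -> np.ndarray:
    """Boolean keep-mask implementing the calling criteria row-wise."""
    cov = table.coverage()
    cov_ok = np.all((cov >= min_cov) & (cov <= max_cov), axis=1)
    total = cov.sum(axis=1)
    alt_total = table.alt.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt_total / np.maximum(total, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq) if fold_maf else freq
    return cov_ok & (maf >= min_maf)


def filter_snps(
    table: SnpCountTable,
    min_cov: int = 20,
    max_cov: int = 200,
    min_maf: float = 0.02,
    fold_maf: bool = True,
) -> SnpCountTable:
    """Return the sub-table of SNPs passing the calling criteria, in order."""
    mask = snp_filter_mask(table, min_cov, max_cov, min_maf, fold_maf)
    if not mask.any():
        warnings.warn("no SNPs pass the filter", stacklevel=2)
    return table.subset(mask)
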