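"""Generalized Cochran-Mantel-Haenszel test for 2 x J x K count tables.

Alleles are the 2-level factor, treatments the J-level factor, and matched
replicate sets (strata) the K layers. For stratum k with allele-1 row total
R_k, column totals C_k1..C_kJ and grand total N_k, let n_k be the vector of
allele-1 counts in the first J-1 treatments. Then

    G = sum_k (n_k - E_k),    E_k[j]    = R_k C_kj / N_k,
    V = sum_k Cov_k,          Cov_k[jj'] = R_k (N_k - R_k)
                                           (N_k d_jj' C_kj - C_kj C_kj')
                                           / (N_k^2 (N_k - 1)),

and Q = G' V^-1 G is asymptotically chi-square with J-1 degrees of freedom
under no allele-treatment association in any stratum. No continuity
correction is applied. Strata with N_k < 2 or a zero row or column margin
carry no information and contribute zero to G and V.

Read counts are used directly as cell counts, the standard pool-seq
evolve-and-resequence practice; overdispersion relative to the chi-square
reference is handled downstream by permutation-based FDR calibration rather
than by correcting the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SnpCountTable, StudyDesign

__all__ = ["CmhResult", "cmh_statistic", "scan"]

_RANK_TOL = 1e-12


@dataclass
class CmhResult:
    """Per-SNP generalized CMH scan output."""

    chrom: np.ndarray
    pos: np.ndarray
    Q: np.ndarray
    df: int
    p: np.ndarray
    usable: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.Q)


def cmh_statistic(tables: np.ndarray) -> tuple[float, int, float]:
    """Generalized CMH statistic for one SNP.

    Parameters
    ----------
    tables
        (K, 2, J) stratified counts: ``tables[k, a, j]`` is the read count
        of allele ``a`` in treatment ``j`` within stratum ``k``.

    Returns
    -------
    (Q, df, p); Q is ``nan`` when the covariance is singular in a direction
    the contrast vector needs (the SNP is then unusable).
    """
    tables = np.asarray(tables, dtype=np.float64)
    if tables.ndim != 3 or tables.shape[1] != 2:
        raise ValueError("expected (K, 2, J) stratified tables")
    if np.any(tables < 0):
        raise ValueError("negative counts")
    Q, usable = _cmh_core(tables[None, ...])
    df = tables.shape[2] - 1
    if not usable[0]:
        return float("nan"), df, 1.0
    return float(Q[0]), df, float(stats.chi2.sf(Q[0], df))


def _cmh_core(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Q over a batch of (K, 2, J) tables.

    ``tables`` has shape (S, K, 2, J). Returns (Q, usable) of length S.
    """
    S, K, _, J = tables.shape
    n1 = tables[:, :, 0, :]  # allele-1 counts (S, K, J)
    C = tables.sum(axis=2)  # column totals (S, K, J)
    R = n1.sum(axis=2)  # row-1 totals (S, K)
    N = C.sum(axis=2)  # grand totals (S, K)

    # informative strata: N >= 2, both allele rows present, all columns present
    ok = (N >= 2) & (R > 0) & (R < N) & np.all(C > 0, axis=2)
    w = ok.astype(np.float64)

    Ns = np.where(N > 0, N, 1.0)
    E = R[..., None] * C / Ns[..., None]
    G = ((n1 - E)[:, :, : J - 1] * w[..., None]).sum(axis=1)  # (S, J-1)

    scale = R * (N - R) / (Ns**2 * np.maximum(N - 1.0, 1.0))  # (S, K)
    Cj = C[:, :, : J - 1]
    cov = -Cj[:, :, :, None] * Cj[:, :, None, :]
    diag = np.arange(J - 1)
    cov[:, :, diag, diag] += N[..., None] * Cj
    V = (cov * (scale * w)[..., None, None]).sum(axis=1)  # (S, J-1, J-1)

    # eigen-solve; exact rank deficiency uses the pseudo-inverse, G outside
    # the range of V marks the SNP unusable
    evals, evecs = np.linalg.eigh(V)
    lead = evals[:, -1]
    usable = lead > 0
    tol = _RANK_TOL * np.maximum(lead, 0)[:, None]
    keep = evals > tol
    proj = np.einsum("sij,si->sj", evecs, G)  # G in eigenbasis
    gnorm = np.linalg.norm(G, axis=1)
    off_range = (~keep) & (np.abs(proj) > np.sqrt(_RANK_TOL) * np.maximum(gnorm, 1.0)[:, None])
    usable &= ~off_range.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(keep, proj**2 / np.where(keep, evals, 1.0), 0.0)
    Q = terms.sum(axis=1)
    Q = np.where(usable, Q, np.nan)
    return Q, usable


def _stratified_counts(table: SnpCountTable, layout: np.ndarray) -> np.ndarray:
    """(S, K, 2, J) per-SNP stratified allele counts from a (K, J) layout.

    Layout cells of -1 (stratum missing a treatment) become zero columns,
    which the core then drops stratum-wise.
    """
    K, J = layout.shape
    safe = np.maximum(layout, 0)
    alt = table.alt[:, safe.ravel()].reshape(-1, K, J).astype(np.float64)
    ref = table.ref[:, safe.ravel()].reshape(-1, K, J).astype(np.float64)
    missing = layout < 0
    if missing.any():
        alt[:, missing] = 0.0
        ref[:, missing] = 0.0
    return np.stack([alt, ref], axis=2)


def scan(table: SnpCountTable, design: StudyDesign) -> CmhResult:
    """Generalized CMH test at every SNP, stratified by the design.

    Alleles form the 2-level margin (alt = row 1), treatments the columns
    ordered by sorted treatment label, strata the layers. Unusable SNPs
    (singular covariance, e.g. monomorphic sites) get Q = 0, p = 1 and
    ``usable=False`` so they can never enter a significant set.
    """
    layout = design.layout(table.populations)
    tables = _stratified_counts(table, layout)
    Q, usable = _cmh_core(tables)
    df = design.n_treatments - 1
    p = np.ones(table.n_snps)
    p[usable] = stats.chi2.sf(Q[usable], df)
    Qout = np.where(usable, Q, 0.0)
    return CmhResult(table.chrom.copy(), table.pos.copy(), Qout, df, p, usable)


def scan_statistics(table: SnpCountTable, layout: np.ndarray) -> np.ndarray:
    """Q only, given a precomputed layout (hot path for permutation reruns).

    Unusable SNPs report 0 so they never exceed a positive threshold.
    """
    Q, usable = _cmh_core(_stratified_counts(table, layout))
    return np.where(usable, Q, 0.0)
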