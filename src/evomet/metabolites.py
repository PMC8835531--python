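"""Univariate and multivariate metabolomics statistics.

Per metabolite: one-way ANOVA across treatments with Benjamini-Hochberg
adjustment, Tukey HSD and Fisher LSD pairwise post-hocs, and a hard
Bonferroni gate (default p <= 1.2e-5). Multivariate summaries: PCA on
autoscaled abundances and Ward/Euclidean hierarchical clustering.
Over-representation analysis (ORA) of a candidate metabolite list against
a set library uses the upper-tail hypergeometric test with
fold-enrichment = observed hits / expected hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .io import MetaboliteMatrix, MetaboliteSetLibrary, StudyDesign

__all__ = [
    "MetaboliteTestResult",
    "OraResult",
    "test_metabolites",
    "pca_summary",
    "ward_cluster_order",
    "ora",
    "hypergeometric_enrichment",
    "focal_metabolites",
]


@dataclass
class MetaboliteTestResult:
    """Per-metabolite ANOVA + post-hoc battery, one row per metabolite."""

    table: pd.DataFrame  # metabolite_id, F, p, p_adj, passes_bonferroni, ...
    pairwise: pd.DataFrame  # metabolite_id, pair, p_tukey, p_lsd
    fdr_q: float
    bonferroni_cut: float

    def significant(self, by: str = "bonferroni") -> list[str]:
        if by == "bonferroni":
            mask = self.table["passes_bonferroni"]
        elif by == "fdr":
            mask = self.table["p_adj"] <= self.fdr_q
        else:
            raise ValueError("by must be 'bonferroni' or 'fdr'")
        return self.table.loc[mask.fillna(False), "metabolite_id"].tolist()


def _treatment_groups(matrix: MetaboliteMatrix, design: StudyDesign):
    t_of = design.treatment_of()
    labels = matrix.sample_populations.map(
        lambda p: t_of.get(p, p)  # population-level or already-treatment-level ids
    )
    levels = sorted(labels.unique())
    return labels, levels


def test_metabolites(
    matrix: MetaboliteMatrix,
    design: StudyDesign,
    fdr_q: float = 0.01,
    bonferroni_cut: float = 1.2e-5,
    welch: bool = False,
    posthoc: bool = True,
) -> MetaboliteTestResult:
    """One-way ANOVA per metabolite with BH adjustment and post-hoc tests.

    ``matrix`` samples map to treatments through the design (sample
    population ids may already be treatment labels). Metabolites with zero
    within-group variance in every group get F = nan, p = nan and fail the
    Bonferroni gate. ``welch=True`` swaps in Welch's unequal-variance ANOVA.
    """
    labels, levels = _treatment_groups(matrix, design)
    if len(levels) < 2:
        raise ValueError("need >= 2 treatment groups")
    rows, pair_rows = [], []
    for met in matrix.metabolites:
        y = matrix.abundance[met]
        groups = [y[labels == lv].to_numpy() for lv in levels]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"metabolite {met!r}: need >= 2 samples per treatment")
        if all(np.ptp(g) == 0 for g in groups):
            rows.append((met, np.nan, np.nan))
            continue
        if welch:
            F, p = _welch_anova(groups)
        else:
            res = stats.f_oneway(*groups)
            F, p = float(res.statistic), float(res.pvalue)
        rows.append((met, F, p))
        if not posthoc:
            continue
        tuk = stats.tukey_hsd(*groups)
        lsd = _fisher_lsd(groups, levels)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pair = f"{levels[i]}-{levels[j]}"
                pair_rows.append((met, pair, float(tuk.pvalue[i, j]), lsd[pair]))

    table = pd.DataFrame(rows, columns=["metabolite_id", "F", "p"])
    p_adj = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        p_adj[ok] = multipletests(table["p"][ok], method="fdr_bh")[1]
    table["p_adj"] = p_adj
    table["passes_bonferroni"] = table["p"] <= bonferroni_cut
    pairwise = pd.DataFrame(pair_rows, columns=["metabolite_id", "pair", "p_tukey", "p_lsd"])
    return MetaboliteTestResult(table, pairwise, fdr_q, bonferroni_cut)


def _welch_anova(groups) -> tuple[float, float]:
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    A = (w * (m - mw) ** 2).sum() / (k - 1)
    B = 1 + 2 * (k - 2) / (k**2 - 1) * ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    F = A / B
    df2 = (k**2 - 1) / (3 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum())
    return float(F), float(stats.f.sf(F, k - 1, df2))


def _fisher_lsd(groups, levels) -> dict[str, float]:
    """Unprotected pairwise t-tests with the pooled ANOVA MSE."""
    n = np.array([len(g) for g in groups], dtype=float)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n.sum() - len(groups))
    dfe = n.sum() - len(groups)
    out = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            se = np.sqrt(mse * (1 / n[i] + 1 / n[j]))
            if se == 0:
                out[f"{levels[i]}-{levels[j]}"] = np.nan
                continue
            t = (groups[i].mean() - groups[j].mean()) / se
            out[f"{levels[i]}-{levels[j]}"] = 2 * stats.t.sf(abs(t), dfe)
    return out


# ---------------------------------------------------------------------------
# multivariate summaries


def pca_summary(matrix: MetaboliteMatrix, scaling: str = "autoscale"):
    """PCA of the abundance matrix.

    Columns are mean-centered and (with ``scaling='autoscale'``) divided by
    their standard deviation before the decomposition; zero-variance
    metabolites are dropped with a warning. Returns (scores, loadings,
    variance_fractions); fractions sum to 1.
    """
    X = matrix.abundance.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance metabolites before PCA",
                      stacklevel=2)
    X = X[:, keep]
    Xc = X - X.mean(axis=0)
    if scaling == "autoscale":
        Xc = Xc / X.std(axis=0, ddof=1)
    elif scaling not in (None, "center"):
        raise ValueError("scaling must be 'autoscale', 'center' or None")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    fractions = s**2 / (s**2).sum()
    return scores, Vt.T, fractions


def ward_cluster_order(matrix: MetaboliteMatrix) -> list[str]:
    """Dendrogram leaf order of samples under Ward linkage on Euclidean
    distances (the ordering used to lay out abundance heatmaps)."""
    Z = linkage(matrix.abundance.to_numpy(dtype=float), method="ward")
    return [matrix.samples[i] for i in leaves_list(Z)]


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass
class OraResult:
    """Per-set over-representation summary."""

    table: pd.DataFrame  # set_id, set_size, hits, expected, fold_enrichment, p, p_adj

    def top_sets(self, k: int) -> list[str]:
        df = self.table.sort_values(["p", "set_id"], kind="stable")
        return df["set_id"].head(k).tolist()


def hypergeometric_enrichment(
    candidates: set[str], sets: dict[str, list[str]], universe: list[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``candidates`` in each set.

    N = |universe|, M = set size, n = candidate-list size, h = hits;
    p = P(X >= h), expected = n*M/N, fold = h/expected (nan when the
    expected count is zero). BH adjustment across sets.
    """
    uni = set(universe)
    cand = set(candidates) & uni
    N, n = len(uni), len(cand)
    rows = []
    for sid in sorted(sets):
        members = set(sets[sid]) & uni
        M = len(members)
        h = len(cand & members)
        expected = n * M / N if N else 0.0
        fold = h / expected if expected > 0 else np.nan
        p = float(stats.hypergeom.sf(h - 1, N, M, n))
        rows.append((sid, M, h, expected, fold, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "hits", "expected",
                                     "fold_enrichment", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


def ora(candidates: list[str], library: MetaboliteSetLibrary) -> OraResult:
    """ORA of a candidate metabolite list against a set library."""
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    extra = set(candidates) - set(library.reference)
    if extra:
        raise ValueError(f"candidates outside the reference metabolome: {sorted(extra)[:5]}")
    return OraResult(hypergeometric_enrichment(set(candidates), library.sets, library.reference))


def focal_metabolites(
    test_results: MetaboliteTestResult,
    ora_results: OraResult | None,
    top_k_pathways: int = 10,
    library: MetaboliteSetLibrary | None = None,
) -> list[str]:
    """Metabolites to carry into the genomic-prediction stage.

    Bonferroni-passing metabolites, intersected (when ORA results and the
    library are given) with the membership of the top ``top_k_pathways``
    sets ranked by ORA p-value (ties break by set_id). Sorted output.
    """
    passing = set(test_results.significant(by="bonferroni"))
    if ora_results is None or library is None:
        return sorted(passing)
    if top_k_pathways == 0:
        return []
    top = ora_results.top_sets(top_k_pathways)
    members = {m for sid in top for m in library.sets.get(sid, [])}
    return sorted(passing & members)
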