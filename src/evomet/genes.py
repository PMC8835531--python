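"""Marker-to-gene candidate mapping and generic term enrichment.

Stable markers are genomic positions, not causal variants; nearby genes are
the interpretable unit. A gene is a candidate when its body overlaps (by at
least 1 bp) a window of total span ``window_bp`` centered on the marker
(clipped at position 1). Term enrichment over a user-supplied term -> gene
library reuses the hypergeometric over-representation machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneAnnotation
from .metabolites import hypergeometric_enrichment

__all__ = ["genes_near_markers", "marker_windows_bp", "term_enrichment"]

logger = logging.getLogger(__name__)


def marker_windows_bp(
    markers: pd.DataFrame, window_bp: int = 5000, one_sided_span: bool = False
) -> pd.DataFrame:
    """1-based inclusive search interval around each marker.

    Default: total span ``window_bp`` centered on the marker (+- window/2);
    ``one_sided_span=True`` switches to +- window_bp (total span doubled).
    """
    half = window_bp if one_sided_span else window_bp // 2
    pos = markers["pos"].to_numpy(dtype=np.int64)
    return pd.DataFrame({
        "chrom": markers["chrom"],
        "start": np.maximum(pos - half, 1),
        "end": pos + half,
    })


def genes_near_markers(
    markers: pd.DataFrame,
    annotation: GeneAnnotation,
    window_bp: int = 5000,
    one_sided_span: bool = False,
) -> list[str]:
    """Deduplicated, sorted gene ids overlapping any marker window."""
    if not {"chrom", "pos"}.issubset(markers.columns):
        raise ValueError("markers need columns chrom, pos")
    windows = marker_windows_bp(markers, window_bp, one_sided_span)
    genes = annotation.genes
    known = set(genes["chrom"])
    missing = sorted(set(windows["chrom"]) - known)
    if missing:
        logger.info("markers on chromosomes absent from annotation: %s", missing)
    hits: set[str] = set()
    for chrom, grp in windows.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        for _, w in grp.iterrows():
            overlap = (gs <= w["end"]) & (ge >= w["start"])
            hits.update(g["gene_id"].to_numpy()[overlap])
    return sorted(hits)


def term_enrichment(
    genes: list[str],
    term_library: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list in each term's gene set.

    Same contract as metabolite ORA: hits, expected = n*M/N, fold =
    hits/expected, upper-tail hypergeometric p, BH-adjusted p across terms.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    return hypergeometric_enrichment(set(genes), term_library, universe)
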