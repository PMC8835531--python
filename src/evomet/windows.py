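"""Reduce significant SNPs to 50-kb window-representative markers.

Linked neutral variants make individual significant SNPs redundant, so the
significant set is collapsed to one marker per genomic window: windows are
non-overlapping 50-kb tiles anchored at position 1 on each chromosome arm
([1, w], [w+1, 2w], ...), and a tile contributes its largest-Q SNP provided
it holds at least ``min_sig_snps`` significant SNPs. Each marker's
per-population alt-allele frequencies are the predictors handed to the
fused lasso additive model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SnpCountTable

__all__ = ["MarkerSet", "select_markers", "marker_frequencies", "window_id"]


def window_id(chrom, pos, window_size: int = 50_000):
    """Tile label ``chrom:tile`` for a 1-based position (tiles anchor at 1)."""
    tile = (np.asarray(pos, dtype=np.int64) - 1) // window_size
    return np.char.add(
        np.char.add(np.asarray(chrom, dtype=str), ":"), tile.astype(str)
    )


@dataclass
class MarkerSet:
    """Window-representative markers and their per-population frequencies."""

    markers: pd.DataFrame  # columns: chrom, pos, Q, window_id
    window_size: int
    min_sig_snps: int
    freq_matrix: pd.DataFrame | None = None  # populations x markers, in [0,1]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_names(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.markers["chrom"], self.markers["pos"])]


def select_markers(
    sig_snps: pd.DataFrame,
    window_size: int = 50_000,
    min_sig_snps: int = 3,
) -> MarkerSet:
    """Pick the most significant SNP of every qualifying window.

    ``sig_snps`` needs columns chrom, pos, Q. Ties on Q break toward the
    smaller position; output is sorted by (chrom, window).
    """
    if not {"chrom", "pos", "Q"}.issubset(sig_snps.columns):
        raise ValueError("sig_snps needs columns chrom, pos, Q")
    if len(sig_snps) == 0:
        empty = pd.DataFrame(columns=["chrom", "pos", "Q", "window_id"])
        return MarkerSet(empty, window_size, min_sig_snps)
    df = sig_snps.copy().reset_index(drop=True)
    df["window_id"] = window_id(df["chrom"], df["pos"], window_size)
    rows = []
    for wid, grp in df.groupby("window_id", sort=True):
        if len(grp) < min_sig_snps:
            continue
        best = grp.sort_values(["Q", "pos"], ascending=[False, True]).iloc[0]
        rows.append((best["chrom"], int(best["pos"]), float(best["Q"]), wid))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "Q", "window_id"])
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return MarkerSet(out, window_size, min_sig_snps)


def marker_frequencies(table: SnpCountTable, markers: MarkerSet) -> pd.DataFrame:
    """Populations x markers alt-allele frequency matrix (alt / coverage)."""
    index = table.snp_index()
    cols = {}
    for _, row in markers.markers.iterrows():
        key = (row["chrom"], int(row["pos"]))
        if key not in index:
            raise KeyError(f"marker {key} absent from count table")
        i = index[key]
        cov = table.ref[i] + table.alt[i]
        if np.any(cov == 0):
            raise ValueError(f"marker {key} has zero coverage in some population")
        cols[f"{key[0]}:{key[1]}"] = table.alt[i] / cov
    freq = pd.DataFrame(cols, index=list(table.populations))
    markers.freq_matrix = freq
    return freq
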