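"""Synthetic pool-seq + metabolome data with known ground truth.

The generator emulates the structure of a three-treatment, ten-replicate
experimentally evolved *Drosophila* study: biallelic SNPs on five
chromosome arms, treatment-correlated allele-frequency shifts at causal
loci, Balding-Nichols drift around treatment means, binomial read counts
at bounded Poisson coverage, and metabolite abundances that are noisy
linear functions of causal allele frequencies.

Causal loci are realized as small clusters of SNPs inside one 50-kb tile
that share the locus's per-population frequency (read noise independent
per SNP) — a minimal stand-in for the selected haplotype blocks that make
window-level marker reduction meaningful. Each locus occupies a distinct
tile so window-level recovery is well-defined.

All randomness flows from ``config.seed``: identical configs give
identical datasets and byte-identical fixture bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MetaboliteMatrix,
    MetaboliteSetLibrary,
    SnpCountTable,
    StudyDesign,
    write_design,
    write_gmt,
    write_metabolites,
    write_snp_table,
)
from .windows import window_id

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate",
    "simulate_metabolite_sets",
    "write_fixture_bundle",
]

_TREATMENT_NAMES = ["A", "C", "S"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults = the emulated
    three-treatment, ten-replicate design)."""

    n_treatments: int = 3
    n_reps: int = 10
    n_snps: int = 5000
    chrom_arms: dict = field(
        default_factory=lambda: {
            "2L": 1_000_000, "2R": 1_000_000, "3L": 1_000_000,
            "3R": 1_000_000, "X": 1_000_000,
        }
    )
    n_causal_loci: int = 20
    snps_per_causal_locus: int = 5
    delta: float = 0.3  # causal between-treatment frequency shift
    F: float = 0.02  # Balding-Nichols drift coefficient
    coverage_mean: float = 60.0
    coverage_bounds: tuple = (20, 200)
    window_size: int = 50_000
    n_metabolites: int = 20
    n_causal_metabolites: int = 10
    loci_per_metabolite: int = 3
    effect_weight: float = 1.0  # |w| per causal locus, sign randomized
    residual_sd: float = 0.1
    samples_per_population: int = 3
    baseline_abundance: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must be in (0, 1)")
        lo, hi = self.coverage_bounds
        if lo > hi or lo < 1:
            raise ValueError("coverage bounds must satisfy 1 <= lo <= hi")
        if self.n_causal_loci * self.snps_per_causal_locus > self.n_snps:
            raise ValueError("causal cluster SNPs exceed n_snps")
        if self.n_causal_metabolites > self.n_metabolites:
            raise ValueError("n_causal_metabolites > n_metabolites")
        n_tiles = sum(l // self.window_size for l in self.chrom_arms.values())
        if self.n_causal_loci > n_tiles:
            raise ValueError("more causal loci than 50-kb tiles")
        if self.loci_per_metabolite > max(self.n_causal_loci, 1):
            raise ValueError("loci_per_metabolite exceeds n_causal_loci")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    causal_loci: pd.DataFrame  # locus_id, chrom, focal_pos, window_id, shifted_treatment, ...
    causal_positions: dict  # locus_id -> list of (chrom, pos) cluster members
    causal_windows: list  # window ids ("chrom:tile")
    pop_frequencies: pd.DataFrame  # populations x locus_id realized frequencies
    metabolite_weights: dict  # metabolite -> {locus_id: weight}
    causal_metabolites: list

    def to_json_dict(self) -> dict:
        return {
            "causal_loci": self.causal_loci.to_dict(orient="records"),
            "causal_positions": {
                k: [[c, int(p)] for c, p in v] for k, v in self.causal_positions.items()
            },
            "causal_windows": list(self.causal_windows),
            "pop_frequencies": {
                p: [float(x) for x in row]
                for p, row in self.pop_frequencies.iterrows()
            },
            "locus_order": list(self.pop_frequencies.columns),
            "metabolite_weights": self.metabolite_weights,
            "causal_metabolites": list(self.causal_metabolites),
        }


def _bn_draw(rng, mean, F, size):
    """Balding-Nichols beta draw around ``mean`` with drift F."""
    a = mean * (1.0 - F) / F
    b = (1.0 - mean) * (1.0 - F) / F
    return rng.beta(a, b, size=size)


def simulate(config: SimulationConfig):
    """Generate (SnpCountTable, StudyDesign, MetaboliteMatrix, SyntheticTruth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    J, K = config.n_treatments, config.n_reps
    n_pops = J * K
    if J <= len(_TREATMENT_NAMES):
        tnames = _TREATMENT_NAMES[:J]
    else:
        tnames = [f"T{j + 1}" for j in range(J)]
    pops = [f"{t}{k + 1}" for t in tnames for k in range(K)]
    treatments = np.repeat(tnames, K)
    strata = np.tile(np.arange(1, K + 1), J)
    design = StudyDesign(pops, treatments.astype(object), strata)

    arms = list(config.chrom_arms)
    lengths = np.array([config.chrom_arms[a] for a in arms], dtype=np.int64)
    w = config.window_size

    # --- causal loci: distinct 50-kb tiles, clustered member SNPs ---------
    all_tiles = [(a, t) for a, ln in zip(arms, lengths) for t in range(ln // w)]
    tile_idx = rng.choice(len(all_tiles), size=config.n_causal_loci, replace=False)
    causal_rows = []
    causal_positions: dict[str, list] = {}
    pos_taken: set[tuple[str, int]] = set()
    cluster = config.snps_per_causal_locus
    for l, ti in enumerate(sorted(tile_idx)):
        arm, tile = all_tiles[ti]
        lo, hi = tile * w + 1, (tile + 1) * w
        center = (lo + hi) // 2
        spread = np.linspace(-5000, 5000, cluster).astype(np.int64)
        posns = np.clip(center + spread, lo, hi)
        posns = np.unique(posns)
        while len(posns) < cluster:  # degenerate tiny windows
            posns = np.unique(np.append(posns, rng.integers(lo, hi + 1)))
        lid = f"L{l + 1}"
        causal_positions[lid] = [(arm, int(p)) for p in posns[:cluster]]
        pos_taken.update(causal_positions[lid])
        causal_rows.append((lid, arm, int(center), f"{arm}:{tile}"))

    # --- neutral SNP positions -------------------------------------------
    n_causal_snps = config.n_causal_loci * cluster
    n_neutral = config.n_snps - n_causal_snps
    arm_choice = rng.choice(len(arms), size=int(n_neutral * 1.3) + 50,
                            p=lengths / lengths.sum())
    neutral = []
    for ai in arm_choice:
        p = int(rng.integers(1, lengths[ai] + 1))
        key = (arms[ai], p)
        if key not in pos_taken:
            pos_taken.add(key)
            neutral.append(key)
        if len(neutral) == n_neutral:
            break
    if len(neutral) < n_neutral:
        raise RuntimeError("could not place all neutral SNPs; enlarge arms")

    # assemble the site list, sorted by (arm order, pos)
    sites = []  # (chrom, pos, locus_id or None)
    for lid, members in causal_positions.items():
        sites.extend((c, p, lid) for c, p in members)
    sites.extend((c, p, None) for c, p in neutral)
    arm_rank = {a: i for i, a in enumerate(arms)}
    sites.sort(key=lambda s: (arm_rank[s[0]], s[1]))
    chrom = np.array([s[0] for s in sites], dtype=object)
    pos = np.array([s[1] for s in sites], dtype=np.int64)
    locus_of = np.array([s[2] if s[2] else "" for s in sites], dtype=object)
    S = len(sites)

    # --- allele frequencies ----------------------------------------------
    lids = [r[0] for r in causal_rows]
    p0_locus = {lid: rng.uniform(0.05, 0.95) for lid in lids}
    shifted_t = {lid: tnames[rng.integers(J)] for lid in lids}
    tmeans = {}  # locus -> per-treatment mean
    for lid in lids:
        p0 = p0_locus[lid]
        d = config.delta if p0 <= 0.5 else -config.delta
        tmeans[lid] = {
            t: float(np.clip(p0 + (d if t == shifted_t[lid] else 0.0), 0.01, 0.99))
            for t in tnames
        }
    # per-locus per-population realized frequencies (shared by cluster SNPs)
    p_locus_pop = np.empty((len(lids), n_pops))
    for li, lid in enumerate(lids):
        for j, t in enumerate(tnames):
            cols = slice(j * K, (j + 1) * K)
            p_locus_pop[li, cols] = _bn_draw(rng, tmeans[lid][t], config.F, K)
    locus_index = {lid: i for i, lid in enumerate(lids)}

    p_pop = np.empty((S, n_pops))
    neutral_mask = locus_of == ""
    p0_neutral = rng.uniform(0.05, 0.95, size=int(neutral_mask.sum()))
    p_pop[neutral_mask] = _bn_draw(
        rng, p0_neutral[:, None], config.F, (int(neutral_mask.sum()), n_pops)
    )
    for i in np.flatnonzero(~neutral_mask):
        p_pop[i] = p_locus_pop[locus_index[locus_of[i]]]

    # --- read counts -------------------------------------------------------
    lo, hi = config.coverage_bounds
    cov = np.clip(rng.poisson(config.coverage_mean, size=(S, n_pops)), lo, hi)
    alt = rng.binomial(cov, p_pop)
    ref = cov - alt
    table = SnpCountTable(chrom, pos, ref, alt, pops)

    # --- metabolites -------------------------------------------------------
    mets = [f"met{m + 1}" for m in range(config.n_metabolites)]
    causal_mets = mets[: config.n_causal_metabolites]
    weights: dict[str, dict[str, float]] = {}
    li_cycle = 0
    for met in causal_mets:
        wmap = {}
        for _ in range(config.loci_per_metabolite):
            lid = lids[li_cycle % len(lids)]
            li_cycle += 1
            wmap[lid] = float(rng.choice([-1.0, 1.0]) * config.effect_weight)
        weights[met] = wmap
    samples, sample_pops, values = [], [], []
    ns = config.samples_per_population
    y_pop = np.zeros((n_pops, config.n_metabolites))
    for mi, met in enumerate(mets):
        base = config.baseline_abundance
        if met in weights:
            for lid, wgt in weights[met].items():
                y_pop[:, mi] += wgt * p_locus_pop[locus_index[lid]]
        y_pop[:, mi] += base
    for pi, popid in enumerate(pops):
        for s in range(ns):
            samples.append(f"{popid}_s{s + 1}")
            sample_pops.append(popid)
            values.append(y_pop[pi] + rng.normal(0, config.residual_sd,
                                                 config.n_metabolites))
    abundance = pd.DataFrame(values, index=samples, columns=mets)
    abundance.index.name = "sample_id"
    matrix = MetaboliteMatrix(abundance, pd.Series(sample_pops, index=samples,
                                                   name="population_id"))

    causal_df = pd.DataFrame(causal_rows,
                             columns=["locus_id", "chrom", "focal_pos", "window_id"])
    causal_df["shifted_treatment"] = [shifted_t[l] for l in causal_df["locus_id"]]
    for t in tnames:
        causal_df[f"freq_{t}"] = [tmeans[l][t] for l in causal_df["locus_id"]]
    truth = SyntheticTruth(
        causal_loci=causal_df,
        causal_positions=causal_positions,
        causal_windows=sorted(causal_df["window_id"]),
        pop_frequencies=pd.DataFrame(p_locus_pop.T, index=pops, columns=lids),
        metabolite_weights=weights,
        causal_metabolites=causal_mets,
    )
    return table, design, matrix, truth


def simulate_metabolite_sets(
    truth: SyntheticTruth,
    all_metabolites: list[str],
    n_sets: int = 6,
    seed: int = 0,
) -> MetaboliteSetLibrary:
    """A toy pathway library: causal metabolites concentrated in the first
    sets, remaining metabolites spread across the rest."""
    rng = np.random.default_rng(seed)
    causal = list(truth.causal_metabolites)
    others = [m for m in all_metabolites if m not in causal]
    sets: dict[str, list[str]] = {f"pathway{i + 1}": [] for i in range(n_sets)}
    n_causal_sets = max(1, n_sets // 3)
    for i, m in enumerate(causal):
        sets[f"pathway{i % n_causal_sets + 1}"].append(m)
    for i, m in enumerate(others):
        sets[f"pathway{n_causal_sets + i % (n_sets - n_causal_sets) + 1}"].append(m)
    # light random cross-membership to avoid degenerate disjoint sets
    for m in rng.choice(all_metabolites, size=min(4, len(all_metabolites)), replace=False):
        sid = f"pathway{rng.integers(n_sets) + 1}"
        if m not in sets[sid]:
            sets[sid].append(m)
    return MetaboliteSetLibrary(sets, list(all_metabolites))


def write_fixture_bundle(
    table: SnpCountTable,
    design: StudyDesign,
    matrix: MetaboliteMatrix,
    truth: SyntheticTruth,
    out_dir,
    config: SimulationConfig | None = None,
    gene_halfwidth: int = 1000,
) -> dict[str, Path]:
    """Write the five-file fixture bundle: sync counts, design CSV,
    metabolite CSV, truth JSON, and a toy GFF3 with one gene spanning each
    causal locus plus background genes between them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snps": out / "snps.sync",
        "design": out / "design.csv",
        "metabolites": out / "metabolites.csv",
        "truth": out / "truth.json",
        "genes": out / "genes.gff3",
    }
    write_snp_table(table, paths["snps"], dialect="sync")
    write_design(design, paths["design"])
    write_metabolites(matrix, paths["metabolites"])
    payload = truth.to_json_dict()
    if config is not None:
        payload["config"] = {k: (dict(v) if isinstance(v, dict) else
                                 list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(config).items()}
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        gid = 0
        for _, row in truth.causal_loci.iterrows():
            gid += 1
            start = max(1, int(row["focal_pos"]) - gene_halfwidth)
            end = int(row["focal_pos"]) + gene_halfwidth
            fh.write(f"{row['chrom']}\tsim\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID=gene_causal_{row['locus_id']}\n")
            # a background gene one window away
            fh.write(f"{row['chrom']}\tsim\tgene\t{end + 60000}\t{end + 62000}\t.\t-\t.\t"
                     f"ID=gene_bg_{gid}\n")
    return paths
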