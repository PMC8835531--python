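"""End-to-end recovery benchmarks on synthetic data.

These drive the whole analysis path — filter, CMH scan, plug-in FDR
calibration, window-marker reduction, metabolite ANOVA gating, FLAM
stability selection — against the generator's ground truth, and score how
well the FLAM marker union recovers the causal 50-kb windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cmh, fdr, filtering, flam, metabolites, windows
from .simulate import SimulationConfig, simulate

__all__ = ["recovery_run", "recovery_experiment", "null_fdp_run"]


def recovery_run(
    seed: int,
    sim_overrides: dict | None = None,
    B: int = 100,
    q: float = 0.005,
    n_perm: int = 100,
    threshold: float = 0.5,
) -> dict:
    """One full pipeline pass on a fresh synthetic dataset.

    Returns headline counts plus causal-window recall and precision of the
    FLAM marker union. All stage seeds derive from ``seed``.
    """
    cfg = SimulationConfig(seed=seed, **(sim_overrides or {}))
    table, design, matrix, truth = simulate(cfg)
    filt = filtering.filter_snps(table)
    res = cmh.scan(filt, design)
    calib = fdr.calibrate(res, filt, design, B=B, q=q, rng=(seed * 7 + 1) % 2**31)
    sig = fdr.significant_snps(res, calib)
    sig_df = pd.DataFrame({"chrom": res.chrom[sig], "pos": res.pos[sig],
                           "Q": res.Q[sig]})
    mset = windows.select_markers(sig_df)
    out = {
        "n_snps": table.n_snps,
        "n_filtered": filt.n_snps,
        "n_significant": int(len(sig)),
        "C": calib.C,
        "n_markers": mset.n_markers,
    }
    tests = metabolites.test_metabolites(matrix, design, posthoc=False)
    focal = metabolites.focal_metabolites(tests, None)
    out["n_focal_metabolites"] = len(focal)
    cw = set(truth.causal_windows)
    if mset.n_markers == 0 or not focal:
        out.update(union_size=0, recall=0.0, precision=float("nan"))
        return out
    freq = windows.marker_frequencies(filt, mset)
    responses = matrix.population_means()[focal]
    _, union = flam.per_metabolite_scan(responses, freq, n_perm=n_perm,
                                        threshold=threshold,
                                        seed=(seed * 13 + 5) % 2**31)
    name2wid = {f"{r.chrom}:{r.pos}": r.window_id for r in mset.markers.itertuples()}
    union_w = {name2wid[m] for m in union}
    out["union_size"] = len(union)
    out["recall"] = len(union_w & cw) / len(cw) if cw else float("nan")
    out["precision"] = (len(union_w & cw) / len(union_w)) if union_w else float("nan")
    return out


def recovery_experiment(seeds, **kw) -> pd.DataFrame:
    """Recovery metrics across seeds (one row per synthetic replicate)."""
    return pd.DataFrame([recovery_run(int(s), **kw) for s in seeds])


def null_fdp_run(seed: int, n_snps: int = 2000, B: int = 50, q: float = 0.05) -> float:
    """Realized false-discovery proportion on a global-null dataset (every
    discovery is false, so the FDP is 1 when anything is called)."""
    cfg = SimulationConfig(seed=seed, n_snps=n_snps,
                           chrom_arms={"2L": 500_000, "2R": 500_000},
                           n_causal_loci=0, n_metabolites=2,
                           n_causal_metabolites=0, loci_per_metabolite=0)
    table, design, _, _ = simulate(cfg)
    res = cmh.scan(table, design)
    calib = fdr.calibrate(res, table, design, B=B, q=q, rng=(seed * 31 + 7) % 2**31)
    sig = fdr.significant_snps(res, calib)
    return 1.0 if len(sig) > 0 else 0.0
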