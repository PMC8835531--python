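"""End-to-end orchestration: scan -> calibrate -> markers -> metabolite
stats -> FLAM -> genes, from one YAML config, with a provenance manifest
and checksum-based stage resumption.

Stage outputs are plain text files in the run directory. A stage is
re-executed only when its parameter/input fingerprint changed or any of
its outputs is missing or altered; deleting one stage's outputs re-runs
that stage and everything downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmh, fdr, filtering, flam, genes, io, metabolites, simulate, windows

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "evomet_run",
    "inputs": {
        "snps": None, "snps_dialect": "sync", "design": None,
        "metabolites": None, "gff": None, "metabolite_sets": None,
    },
    "simulate": {},  # SimulationConfig overrides; used when inputs.snps is null
    "filter": {"min_cov": 20, "max_cov": 200, "min_maf": 0.02},
    "calibrate": {"B": 100, "q": 0.005},
    "markers": {"window_size": 50_000, "min_sig_snps": 3},
    "metabolites": {"fdr_q": 0.01, "bonferroni_cut": 1.2e-5, "top_k_pathways": 10},
    "flam": {"n_perm": 100, "threshold": 0.5, "alpha": 0.5},
    "genes": {"window_bp": 5000},
}

STAGES = ["filter", "cmh", "calibrate", "markers", "metab", "flam", "genes"]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _key(params: dict, upstream: list[str]) -> str:
    return hashlib.sha256(
        json.dumps({"params": params, "upstream": upstream}, sort_keys=True).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry["key"] != key:
            return False
        for f, digest in entry["outputs"].items():
            p = self.path.parent / f
            if not p.exists() or _sha(p) != digest:
                return False
        return True

    def record(self, stage: str, key: str, outputs: list[Path], wall: float, info: dict):
        self.data["stages"][stage] = {
            "key": key,
            "outputs": {p.name: _sha(p) for p in outputs},
            "wall_seconds": round(wall, 3),
            **info,
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True) + "\n")

    def digest_of(self, stage: str) -> list[str]:
        entry = self.data["stages"].get(stage, {})
        return sorted(entry.get("outputs", {}).values())


def run_pipeline(config, out_dir=None) -> dict:
    """Run all stages; returns {'run_dir', 'executed', 'results'}.

    ``config`` is a YAML path or a dict (defaults filled in). Stages whose
    fingerprints match the existing manifest are skipped and their outputs
    reloaded from disk.
    """
    cfg = load_config(config)
    run_dir = Path(out_dir or cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir / "manifest.json")
    seed_root = np.random.SeedSequence(cfg["seed"])
    stage_seeds = dict(zip(["simulate", "calibrate", "flam"], seed_root.spawn(3)))
    executed: dict[str, bool] = {}
    results: dict = {}

    # ------------------------------------------------------------------ inputs
    inp = cfg["inputs"]
    if inp["snps"] is None:
        sim_cfg = simulate.SimulationConfig(**cfg["simulate"])
        if "seed" not in cfg["simulate"]:
            sim_cfg.seed = int(stage_seeds["simulate"].generate_state(1)[0] % (2**31))
        bundle_dir = run_dir / "inputs"
        table, design, matrix, truth = simulate.simulate(sim_cfg)
        paths = simulate.write_fixture_bundle(table, design, matrix, truth,
                                              bundle_dir, config=sim_cfg)
        inp = dict(inp, snps=str(paths["snps"]), design=str(paths["design"]),
                   metabolites=str(paths["metabolites"]), gff=str(paths["genes"]))
        results["truth"] = truth
    table = io.read_snp_table(inp["snps"], dialect=inp.get("snps_dialect", "sync"))
    if inp["snps"].endswith(".sync"):
        # sync carries no population names; take them from the design file
        design = io.read_design(inp["design"])
        if len(design.populations) == table.n_populations:
            table.populations = list(design.populations)
    design = io.read_design(inp["design"])
    matrix = io.read_metabolites(inp["metabolites"])
    library = None
    if inp.get("metabolite_sets"):
        library = io.read_gmt(inp["metabolite_sets"], reference=matrix.metabolites)

    def stage(name, params, upstream_stages, outputs, fn):
        key = _key(params, [d for s in upstream_stages for d in manifest.digest_of(s)]
                   + [_sha(Path(f)) for f in params.pop("_files", [])])
        outputs = [run_dir / o for o in outputs]
        upstream_ran = any(executed.get(s, False) for s in upstream_stages)
        if not upstream_ran and manifest.fresh(name, key, outputs):
            executed[name] = False
            logger.info("stage %s: up to date, skipping", name)
            return False
        t0 = time.time()
        info = fn(outputs) or {}
        manifest.record(name, key, outputs, time.time() - t0, info)
        executed[name] = True
        logger.info("stage %s: done in %.1fs %s", name, time.time() - t0, info)
        return True

    # ------------------------------------------------------------------ filter
    def do_filter(outs):
        filt = filtering.filter_snps(table, **cfg["filter"])
        io.write_snp_table(filt, outs[0], dialect="counts")
        return {"n_in": table.n_snps, "n_out": filt.n_snps}

    stage("filter", {**cfg["filter"], "_files": [inp["snps"]]}, [],
          ["filtered.counts.tsv"], do_filter)
    filt = io.read_snp_table(run_dir / "filtered.counts.tsv", dialect="counts")
    filt.populations = list(table.populations)
    results["filtered"] = filt

    # ------------------------------------------------------------------ cmh
    def do_cmh(outs):
        res = cmh.scan(filt, design)
        pd.DataFrame({"chrom": res.chrom, "pos": res.pos, "Q": res.Q,
                      "df": res.df, "p": res.p, "usable": res.usable}
                     ).to_csv(outs[0], sep="\t", index=False)
        return {"n_snps": res.n_snps}

    stage("cmh", {"_files": [inp["design"]]}, ["filter"], ["cmh.tsv"], do_cmh)
    cmh_df = pd.read_csv(run_dir / "cmh.tsv", sep="\t")
    obs = cmh.CmhResult(cmh_df["chrom"].to_numpy(object), cmh_df["pos"].to_numpy(),
                        cmh_df["Q"].to_numpy(), int(cmh_df["df"].iloc[0]),
                        cmh_df["p"].to_numpy(), cmh_df["usable"].to_numpy(bool))
    results["cmh"] = obs

    # ------------------------------------------------------------------ calibrate
    cal_seed = int(stage_seeds["calibrate"].generate_state(1)[0] % (2**31))

    def do_calibrate(outs):
        calib = fdr.calibrate(obs, filt, design, rng=cal_seed, **cfg["calibrate"])
        sig = fdr.significant_snps(obs, calib)
        json.dump({"C": calib.C, "R": calib.R, "Vhat": calib.Vhat,
                   "fdr_at_C": calib.fdr_at_C, "no_solution": calib.no_solution,
                   "B": calib.B, "q": calib.q, "seed": cal_seed},
                  open(outs[0], "w"), indent=1)
        cmh_df.iloc[sig].to_csv(outs[1], sep="\t", index=False)
        return {"n_significant": int(len(sig)), "C": calib.C}

    stage("calibrate", {**cfg["calibrate"], "seed": cal_seed}, ["filter", "cmh"],
          ["calibration.json", "significant.tsv"], do_calibrate)
    sig_df = pd.read_csv(run_dir / "significant.tsv", sep="\t")
    results["calibration"] = json.loads((run_dir / "calibration.json").read_text())
    results["significant"] = sig_df

    # ------------------------------------------------------------------ markers
    def do_markers(outs):
        mset = windows.select_markers(sig_df, **cfg["markers"])
        freq = windows.marker_frequencies(filt, mset) if mset.n_markers else \
            pd.DataFrame(index=list(filt.populations))
        mset.markers.to_csv(outs[0], sep="\t", index=False)
        freq.to_csv(outs[1])
        return {"n_markers": mset.n_markers}

    stage("markers", cfg["markers"], ["filter", "calibrate"],
          ["markers.tsv", "marker_freqs.csv"], do_markers)
    markers_df = pd.read_csv(run_dir / "markers.tsv", sep="\t")
    freq = pd.read_csv(run_dir / "marker_freqs.csv", index_col=0)
    results["markers"] = markers_df
    results["marker_freqs"] = freq

    # ------------------------------------------------------------------ metab
    met_params = dict(cfg["metabolites"])
    top_k = met_params.pop("top_k_pathways", 10)

    def do_metab(outs):
        tests = metabolites.test_metabolites(matrix, design, **met_params)
        tests.table.to_csv(outs[0], sep="\t", index=False)
        focal_kwargs = {}
        if library is not None:
            passing = tests.significant(by="bonferroni")
            ora_res = metabolites.ora(passing, library) if passing else None
            if ora_res is not None:
                ora_res.table.to_csv(run_dir / "ora.tsv", sep="\t", index=False)
            focal = metabolites.focal_metabolites(tests, ora_res, top_k, library)
        else:
            focal = metabolites.focal_metabolites(tests, None, top_k)
        json.dump({"focal_metabolites": focal}, open(outs[1], "w"), indent=1)
        return {"n_focal": len(focal)}

    stage("metab", {**met_params, "top_k": top_k,
                    "_files": [inp["metabolites"], inp["design"]]},
          [], ["metab_tests.tsv", "focal.json"], do_metab)
    focal = json.loads((run_dir / "focal.json").read_text())["focal_metabolites"]
    results["metab_tests"] = pd.read_csv(run_dir / "metab_tests.tsv", sep="\t")
    results["focal_metabolites"] = focal

    # ------------------------------------------------------------------ flam
    flam_seed = int(stage_seeds["flam"].generate_state(1)[0] % (2**31))

    def do_flam(outs):
        if len(focal) == 0 or freq.shape[1] == 0:
            payload = {"per_metabolite": {}, "union": [], "seed": flam_seed}
        else:
            responses = matrix.population_means()[focal]
            sel, union = flam.per_metabolite_scan(
                responses, freq, seed=flam_seed, **cfg["flam"])
            payload = {
                "per_metabolite": {
                    m: {"stable_set": r.stable_set, "lam": r.lam,
                        "frequencies": r.selection_frequency.round(4).to_dict()}
                    for m, r in sel.items()
                },
                "union": union, "seed": flam_seed,
            }
        json.dump(payload, open(outs[0], "w"), indent=1)
        return {"union_size": len(payload["union"])}

    stage("flam", {**cfg["flam"], "seed": flam_seed}, ["markers", "metab"],
          ["flam.json"], do_flam)
    results["flam"] = json.loads((run_dir / "flam.json").read_text())

    # ------------------------------------------------------------------ genes
    def do_genes(outs):
        union = results["flam"]["union"]
        if inp.get("gff") and union:
            ann = io.read_gff(inp["gff"])
            ann.check_namespace(set(filt.chrom))
            sub = markers_df[[f"{c}:{p}" in union for c, p in
                              zip(markers_df["chrom"], markers_df["pos"])]]
            glist = genes.genes_near_markers(sub, ann, **cfg["genes"])
        else:
            glist = []
        json.dump({"candidate_genes": glist}, open(outs[0], "w"), indent=1)
        return {"n_genes": len(glist)}

    gene_files = [inp["gff"]] if inp.get("gff") else []
    stage("genes", {**cfg["genes"], "_files": gene_files}, ["flam", "markers"],
          ["candidate_genes.json"], do_genes)
    results["candidate_genes"] = json.loads(
        (run_dir / "candidate_genes.json").read_text())["candidate_genes"]

    return {"run_dir": run_dir, "executed": executed, "results": results}
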