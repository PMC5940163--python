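"""Configuration-driven orchestration of the full analysis.

A run executes, in order: ingest (or simulate) -> GRM / structure / h2 ->
model fits -> evaluation -> reports, writing all artifacts plus a manifest
(config echo, seeds, stage timings) under one output directory.  The
manifest plus the same build reproduce a run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (center_standardize, filter_markers, impute_missing_mean,
                      read_genotype_table, read_phenotype_table,
                      write_genotype_table, write_phenotype_table)
from .evaluation import (EvaluationReport, default_model_factories, evaluate,
                         make_partitions)
from .kinship import (genomic_heritability_reml, pca_on_grm,
                      structure_significance, vanraden_grm, write_grm,
                      write_pca_scores)
from .multienv import MultiEnvData, save_mxe_fit, site_correlations
from .simulate import SimConfig, simulate_dataset
from .wgr import MCMCSettings, PriorSpec, fit_wgr, save_fit

log = logging.getLogger("cottongs")

FAST_MCMC = dict(n_iter=6_000, burn_in=1_000, thin=5)
FULL_MCMC = dict(n_iter=210_000, burn_in=10_000, thin=20)
VALID_SCHEMES = ("single_site_random", "cv1", "cv2")
VALID_MODELS = ("single_site", "across_site", "mxe")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _mcmc_from_cfg(cfg: dict, seed: int, fast: bool) -> MCMCSettings:
    base = dict(FAST_MCMC if fast else FULL_MCMC)
    base.update(cfg.get("mcmc", {}))
    base["seed"] = seed
    return MCMCSettings(**base)


def run_pipeline(cfg: dict, outdir: str | Path, fast: bool = False) -> dict:
    """Execute the configured stages; returns the run manifest."""
    t_all = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "fast": fast,
                      "config": cfg, "stages": {}}

    models = tuple(cfg.get("models", ["single_site", "across_site", "mxe"]))
    bad = set(models) - set(VALID_MODELS)
    if bad:
        raise ValueError(f"invalid model name(s) {sorted(bad)}; valid: {VALID_MODELS}")
    schemes = tuple(cfg.get("schemes", ["cv2"]))
    bad = set(schemes) - set(VALID_SCHEMES)
    if bad:
        raise ValueError(f"invalid scheme(s) {sorted(bad)}; valid: {VALID_SCHEMES}")

    # ---- stage: data ----
    t0 = time.time()
    if "simulate" in cfg:
        sim = SimConfig(**{**cfg["simulate"], "seed": seed})
        g, phen, truth = simulate_dataset(sim)
        write_genotype_table(g, outdir / "genotypes.csv")
        write_phenotype_table(phen, outdir / "phenotypes.csv")
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        np.savetxt(tdir / "b0.csv", truth.b0, delimiter=",")
        np.savetxt(tdir / "tbv.csv", truth.tbv, delimiter=",")
        pd.DataFrame({"site": sim.site_ids, "realized_h2": truth.realized_h2,
                      "sigma2_e": truth.sigma2_e}).to_csv(
            tdir / "per_site.csv", index=False)
    else:
        gpath = Path(cfg["genotypes"])
        ppath = Path(cfg["phenotypes"])
        for p in (gpath, ppath):
            if not p.exists():
                raise FileNotFoundError(f"input file {p} does not exist")
        g = read_genotype_table(gpath, cfg.get("genotype_dialect", "dosage_csv"))
        phen = read_phenotype_table(ppath)
    log.info("data stage: %d lines x %d markers, %d phenotype records",
             g.n_lines, g.n_markers, len(phen))
    manifest["stages"]["data"] = {"seconds": round(time.time() - t0, 2),
                                  "n_lines": g.n_lines, "n_markers": g.n_markers}

    # ---- stage: preprocessing ----
    t0 = time.time()
    filt = cfg.get("filter", {})
    g_f = filter_markers(g, filt.get("min_call_rate", 0.80),
                         filt.get("min_maf", 0.05))
    g_i = impute_missing_mean(g_f)
    X = center_standardize(g_i)
    manifest["stages"]["preprocess"] = {
        "seconds": round(time.time() - t0, 2),
        **getattr(g_f, "filter_log", {}),
    }

    # ---- stage: GRM / structure / h2 ----
    t0 = time.time()
    grm_cfg = cfg.get("grm", {})
    grm = vanraden_grm(g_i, grm_cfg.get("n_subset"), seed=seed)
    write_grm(grm, outdir / "grm.csv")
    pca = pca_on_grm(grm, k=min(10, grm.n))
    write_pca_scores(pca, outdir / "pca_scores.csv")
    st = structure_significance(pca, grm.n_markers_used, grm.n,
                                alpha=grm_cfg.get("alpha", 0.01))
    trait = cfg.get("trait", "trait")
    h2_rows = []
    h2_per_site = {}
    for site in phen.sites():
        sl = phen.site_slice(site, trait)
        idx = {l: i for i, l in enumerate(grm.line_ids)}
        sl = sl[sl["line"].isin(idx)]
        rows = [idx[l] for l in sl["line"]]
        if len(rows) < 10:
            continue
        sub = grm.values[np.ix_(rows, rows)]
        from .kinship import GRM as _GRM
        est = genomic_heritability_reml(
            sl["mean"].to_numpy(float),
            _GRM([grm.line_ids[i] for i in rows], sub, grm.n_markers_used))
        h2_rows.append((site, est.h2g, est.se, est.sigma2_g, est.sigma2_e,
                        est.converged))
        h2_per_site[site] = est.h2g
    pd.DataFrame(h2_rows, columns=["site", "h2g", "se", "sigma2_g",
                                   "sigma2_e", "converged"]
                 ).to_csv(outdir / "heritability.csv", index=False)
    manifest["stages"]["kinship"] = {
        "seconds": round(time.time() - t0, 2),
        "structured": st.structured,
        "pc1_pct": round(100 * float(pca.variance_fraction[0]), 2),
        "pc2_pct": round(100 * float(pca.variance_fraction[1]), 2),
    }

    # ---- stage: model fits + evaluation ----
    t0 = time.time()
    prior = PriorSpec(**cfg.get("prior", {"model": "BayesB"}))
    mcmc = _mcmc_from_cfg(cfg, seed, fast)
    data = MultiEnvData.from_tables(phen, X, trait)
    corr, corr_se = site_correlations(data)
    corr.to_csv(outdir / "site_correlations.csv")
    facs = default_model_factories(prior, mcmc, models)
    n_reps = int(cfg.get("n_reps", 50))
    frac = float(cfg.get("frac_train", 0.70))
    summaries = []
    for scheme in schemes:
        if scheme == "cv2":
            parts = make_partitions(scheme="cv2", n_reps=n_reps,
                                    frac_train=frac, seed=seed,
                                    cells=data.cells()[["line", "site"]])
        else:
            parts = make_partitions(n_lines=X.n_lines, scheme=scheme,
                                    n_reps=n_reps, frac_train=frac, seed=seed)
        report = evaluate(facs, data, parts, h2_per_site)
        report.per_rep.to_csv(outdir / f"per_rep_{scheme}.csv", index=False)
        report.selection.to_csv(outdir / f"selection_{scheme}.csv", index=False)
        summaries.append(report.summary)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    summary.to_csv(outdir / "summary.csv", index=False)
    manifest["stages"]["evaluate"] = {"seconds": round(time.time() - t0, 2),
                                      "schemes": list(schemes),
                                      "models": list(models),
                                      "n_reps": n_reps}

    manifest["total_seconds"] = round(time.time() - t_all, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest
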