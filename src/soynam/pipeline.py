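"""End-to-end orchestration: simulate -> prep -> blup -> gwas -> bins.

One master seed drives everything; per-stage seeds are spawned
deterministically from it, so a rerun with the same config is bit-identical
and individual stages can be reproduced in isolation.  Every run writes a
manifest recording the config hash, stage seeds, output checksums and
record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bins as bins_mod
from . import blup as blup_mod
from . import genoprep, gwas, io, simulate
from .config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "blup", "gwas", "bins")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"config_sha256": config.digest(), "seed": config.seed,
                "stage_seeds": seeds, "stages": {}}
    config.to_yaml(outdir / "config.yaml")
    state: dict = {}

    for stage in STAGES:
        if not config.stages.get(stage, True):
            manifest["stages"][stage] = {"status": "skipped"}
            logger.info("stage %-8s skipped", stage)
            continue
        try:
            files, counts = _RUNNERS[stage](config, seeds[stage], outdir, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in files},
            "records": counts,
        }
        logger.info("stage %-8s ok: %s", stage, counts)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _run_simulate(cfg: RunConfig, seed: int, outdir: Path, state: dict):
    ss = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    gmap = simulate.simulate_map(cfg.n_chromosomes, cfg.cm_length,
                                 cfg.markers_per_chromosome,
                                 bp_model=cfg.bp_model, seed=sub[0])
    panel = simulate.simulate_founders(gmap, cfg.group_counts,
                                       allele_freq=cfg.allele_freq, seed=sub[1])
    matings = panel.founder_ids[:cfg.n_families]
    if len(matings) < cfg.n_families:
        raise ValueError("panel has fewer founders than requested families")
    pop = simulate.derive_rils(panel, matings, cfg.rils_per_family,
                               final_generation=cfg.final_generation, seed=sub[2])
    arch = simulate.assign_trait_architecture(
        gmap, panel, cfg.n_qtl, cfg.group_effects,
        polygenic_var=cfg.polygenic_var, traits=cfg.traits, seed=sub[3])
    gvalues = simulate.genetic_values(pop, arch, seed=sub[4])
    parent_vals = simulate.founder_parent_values(panel, arch)
    design = simulate.design_trial(pop, cfg.checks, cfg.n_environments,
                                   sets_evaluated=cfg.sets_evaluated,
                                   planting_date_model=cfg.planting_date_model,
                                   seed=sub[5])
    entry_values = pd.concat([gvalues, parent_vals])
    plots = simulate.simulate_plots(
        design, entry_values, cfg.variance_components,
        planting_slope=cfg.planting_slope, missing_rate=cfg.missing_rate,
        seed=sub[5])

    state.update(gmap=gmap, panel=panel, pop=pop, arch=arch,
                 gvalues=gvalues, design=design, plots=plots)
    files = []
    io.write_map_tsv(gmap, outdir / "map.tsv"); files.append(outdir / "map.tsv")
    io.write_genotypes_csv(pop.geno, pop.ril_ids, gmap.markers,
                           outdir / "genotypes.csv")
    files.append(outdir / "genotypes.csv")
    if cfg.vcf_export:
        io.write_vcf(pop.geno, pop.ril_ids, gmap, outdir / "genotypes.vcf")
        files.append(outdir / "genotypes.vcf")
    io.write_table(plots.table, outdir / "plots.csv", sep=",")
    files.append(outdir / "plots.csv")
    truth = pd.concat(
        [arch.effects[t].rename_axis("founder").reset_index().assign(trait=t)
         for t in arch.traits()], ignore_index=True)
    io.write_table(truth, outdir / "truth_qtl_effects.tsv")
    files.append(outdir / "truth_qtl_effects.tsv")
    io.write_table(gvalues.rename_axis("entry").reset_index(),
                   outdir / "truth_genetic_values.tsv")
    files.append(outdir / "truth_genetic_values.tsv")
    counts = {"rils": pop.n_rils, "markers": gmap.n_markers,
              "sets": design.n_sets(), "plots": len(plots.table)}
    return files, counts


def _run_prep(cfg: RunConfig, seed: int, outdir: Path, state: dict):
    pop, panel = state["pop"], state["panel"]
    report = genoprep.filter_markers(pop, maf_threshold=cfg.maf_threshold)
    qc = genoprep.qc_rils(pop, panel)
    filtered = genoprep.apply_marker_filter(pop, report)
    state["filter_report"], state["qc"], state["pop_filtered"] = report, qc, filtered
    files = []
    io.write_table(report.table, outdir / "filter_report.tsv")
    files.append(outdir / "filter_report.tsv")
    io.write_table(qc.flags.rename("flag").rename_axis("ril").reset_index(),
                   outdir / "qc_report.tsv")
    files.append(outdir / "qc_report.tsv")
    counts = {"markers_in": pop.gmap.n_markers,
              "markers_kept": filtered.gmap.n_markers,
              "markers_eliminated": len(report.eliminated),
              "rils_pass": int((qc.flags == genoprep.FLAG_PASS).sum()),
              "families_flagged": len(qc.families_to_remove)}
    return files, counts


def _run_blup(cfg: RunConfig, seed: int, outdir: Path, state: dict):
    plots = state["plots"]
    pop = state.get("pop_filtered") or state["pop"]
    all_blocks = list(dict.fromkeys(plots.table["block"]))
    blups_by_trait, rows, blk_rows = {}, [], []
    for t in plots.traits:
        stage1 = blup_mod.fit_check_block_model(plots, t, all_blocks=all_blocks)
        stage2 = blup_mod.fit_entry_model(plots, t, block_effects=stage1)
        blups_by_trait[t] = stage2
        herit = blup_mod.heritability(stage2.sigma2_g, stage2.sigma2_res,
                                      stage2.env_counts.to_numpy())
        ril_blups = stage2.blups[stage2.blups.index.isin(pop.ril_ids)]
        prop, s2a, s2w = blup_mod.variance_among_families(
            ril_blups, pop.family)
        rows.append({"trait": t, "sigma2_blk": stage1.sigma2_blk,
                     "sigma2_g": stage2.sigma2_g,
                     "sigma2_res": stage2.sigma2_res,
                     "H": herit.H, "H_ci_low": herit.ci_low,
                     "H_ci_high": herit.ci_high,
                     "harmonic_envs": herit.e_harmonic,
                     "prop_among_families": prop})
        for b, v in stage1.block_blups.items():
            blk_rows.append({"trait": t, "block": b, "blup": v})
    state["entry_blups"] = blups_by_trait
    varcomp = pd.DataFrame(rows)
    state["varcomp"] = varcomp
    if len(plots.traits) >= 2:
        corr = blup_mod.genetic_correlations(
            {t: b.blups for t, b in blups_by_trait.items()})
        io.write_table(corr.rename_axis("trait").reset_index(),
                       outdir / "genetic_correlations.tsv")
    files = []
    io.write_table(pd.DataFrame(blk_rows), outdir / "block_effects.tsv")
    files.append(outdir / "block_effects.tsv")
    long = pd.concat([b.blups.rename("blup").rename_axis("entry").reset_index()
                      .assign(trait=t) for t, b in blups_by_trait.items()],
                     ignore_index=True)
    io.write_table(long[["entry", "trait", "blup"]], outdir / "entry_blups.tsv")
    files.append(outdir / "entry_blups.tsv")
    io.write_table(varcomp, outdir / "varcomp.tsv")
    files.append(outdir / "varcomp.tsv")
    if (outdir / "genetic_correlations.tsv").exists():
        files.append(outdir / "genetic_correlations.tsv")
    counts = {"traits": len(plots.traits), "entries": len(long["entry"].unique())}
    return files, counts


def _run_gwas(cfg: RunConfig, seed: int, outdir: Path, state: dict):
    pop = state.get("pop_filtered") or state["pop"]
    scan_cfg = gwas.ScanConfig(window_cm=cfg.window_cm,
                               sig_threshold=cfg.sig_threshold)
    results = {}
    files = []
    n_sig = 0
    for t, eb in state["entry_blups"].items():
        res = gwas.genome_scan(eb.blups, pop, config=scan_cfg, trait=t)
        results[t] = res
        out = res.stats.copy()
        for fam in res.families:
            out[f"alpha_{fam}"] = res.alpha[fam].to_numpy()
        path = outdir / f"scan_{t}.tsv"
        io.write_table(out, path)
        files.append(path)
        n_sig += len(res.significant())
    meta = {t: r.metadata() for t, r in results.items()}
    meta["seed"] = cfg.seed
    (outdir / "scan_meta.json").write_text(json.dumps(meta, indent=2))
    files.append(outdir / "scan_meta.json")
    state["scans"] = results
    return files, {"traits_scanned": len(results), "significant_markers": n_sig}


def _run_bins(cfg: RunConfig, seed: int, outdir: Path, state: dict):
    pop = state.get("pop_filtered") or state["pop"]
    regions = []
    effect_tables = []
    for t, res in state["scans"].items():
        rs = bins_mod.regions_from_scan(res, gap=cfg.gap_cm)
        regions.extend(rs)
        if len(res.significant()):
            effect_tables.append(gwas.estimate_family_effects(res, pop))
    xbins = bins_mod.cross_trait_bins(regions, gap=cfg.gap_cm)
    files = []
    reg_df = pd.DataFrame([{
        "trait": r.trait, "chrom": r.chrom, "span_lo_cM": r.span[0],
        "span_hi_cM": r.span[1], "peak_marker": r.peak_marker,
        "peak_cM": r.peak_cm, "peak_neg_log10_p": r.peak_score,
        "n_markers": len(r.markers)} for r in regions])
    io.write_table(reg_df, outdir / "regions.tsv")
    files.append(outdir / "regions.tsv")
    io.write_table(bins_mod.bins_table(xbins), outdir / "bins.tsv")
    files.append(outdir / "bins.tsv")
    if effect_tables:
        eff = pd.concat(effect_tables, ignore_index=True)
        io.write_table(bins_mod.group_effect_summary(eff),
                       outdir / "effect_summary.tsv")
        files.append(outdir / "effect_summary.tsv")
    return files, {"regions": len(regions), "bins": len(xbins)}


_RUNNERS = {"simulate": _run_simulate, "prep": _run_prep, "blup": _run_blup,
            "gwas": _run_gwas, "bins": _run_bins}


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


def validate_inputs(map_path=None, genotypes_path=None, plots_path=None) -> dict:
    """Check external input files for structural violations.

    Returns ``{"fatal": [...], "warnings": [...]}``; an empty ``fatal`` list
    means the inputs are usable.
    """
    fatal, warn = [], []
    gmap = None
    if map_path is not None:
        try:
            gmap = io.read_map_tsv(map_path)
        except Exception as exc:
            fatal.append(f"map: {exc}")
    geno = None
    if genotypes_path is not None:
        geno = io.read_genotypes_csv(genotypes_path)
        vals = geno.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            fatal.append("genotypes: doses outside {0,1,2,NA}")
        if gmap is not None:
            extra = set(geno.columns) - set(gmap.markers)
            if extra:
                fatal.append(f"genotypes: {len(extra)} markers absent from map")
    if plots_path is not None:
        plots = io.read_table(plots_path, sep=",")
        req = {"plot", "entry", "environment", "block", "planting_date"}
        missing = req - set(plots.columns)
        if missing:
            fatal.append(f"plots: missing columns {sorted(missing)}")
        else:
            for col in ("entry", "block", "environment"):
                if plots[col].isna().any():
                    fatal.append(f"plots: unresolvable {col} references")
            blocks_per_env = plots.groupby("block")["environment"].nunique()
            if (blocks_per_env > 1).any():
                fatal.append("plots: a block spans multiple environments")
            if "lodging" in plots.columns:
                v = plots["lodging"].dropna()
                if ((v < 1) | (v > 5)).any():
                    fatal.append("plots: lodging values outside [1, 5]")
            if geno is not None:
                known = set(geno.index)
                rils = plots.loc[plots.get("role", "ril") == "ril", "entry"]
                unknown = set(rils) - known
                if unknown:
                    warn.append(f"plots: {len(unknown)} RIL entries lack genotypes")
    return {"fatal": fatal, "warnings": warn}
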