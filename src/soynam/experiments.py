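"""Desk-scale simulation experiments exercising the full method.

These are the reproducible studies behind the package's headline checks:
design-count reproduction at the reference germplasm scale, null
calibration of the genome scan's region-wise significance rule, detection
power for a large yield QTL, heritability CI coverage, among-family
variance recovery and family-specific allele-effect recovery.  Problem
sizes are chosen so each study runs in minutes on one core while keeping
the statistical structure (family nesting, linkage, polygenic background)
of the full design; docs/methods.md discusses what the reduced scale does
and does not demonstrate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import blup, gwas, simulate


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def make_population(seed: int, n_families: int = 10, rils_per_family: int = 30,
                    n_chromosomes: int = 2, cm_length: float = 100.0,
                    markers_per_chromosome: int = 30,
                    allele_freq: float = 0.5,
                    group_counts=None) -> simulate.RILPopulation:
    """A scaled NAM population with the study's family/linkage structure."""
    s = _spawn(seed, 3)
    gmap = simulate.simulate_map(n_chromosomes, cm_length,
                                 markers_per_chromosome, seed=s[0])
    if group_counts is None:
        n_el = max(1, n_families - 2 * (n_families // 3))
        group_counts = {"EL": n_el, "BX": n_families // 3,
                        "PI": n_families // 3}
    panel = simulate.simulate_founders(gmap, group_counts,
                                       allele_freq=allele_freq, seed=s[1])
    matings = panel.founder_ids[:n_families]
    return simulate.derive_rils(panel, matings, rils_per_family, seed=s[2])


# ---------------------------------------------------------------------------
# design counts at the reference germplasm scale
# ---------------------------------------------------------------------------


def paper_scale_design_counts(seed: int) -> dict:
    """Full-design simulation: 40 matings x 140 F5 RILs laid out in
    augmented 40-entry sets.  Marker density is kept light (the counts under
    test concern germplasm and layout, not the genome)."""
    s = _spawn(seed, 3)
    gmap = simulate.simulate_map(20, 100.0, 10, seed=s[0])
    panel = simulate.simulate_founders(gmap, seed=s[1])  # 17 EL + 15 BX + 8 PI
    pop = simulate.derive_rils(panel, panel.founder_ids, 140, seed=s[2])
    design = simulate.design_trial(pop, ["CHK1", "CHK2", "CHK3"],
                                   n_environments=1, seed=s[2])
    set_sizes = {sid: len(m) for sid, m in design.set_members.items()}
    return {"n_rils": pop.n_rils,
            "n_founders": len(panel.founder_ids),
            "n_sets": design.n_sets(),
            "set_sizes": sorted(set(set_sizes.values()))}


# ---------------------------------------------------------------------------
# null calibration of the region-wise significance rule
# ---------------------------------------------------------------------------


def null_scan_replicate(seed: int, pop=None, sig_threshold: float = 3.0,
                        window_cm: float = 5.0, family_var: float = 0.3,
                        noise_var: float = 0.7, **pop_kwargs) -> dict:
    """One global-null dataset and scan.

    Phenotype = family-level polygenic background + iid noise, with no
    marker effects anywhere: between-family genetic structure is present
    (the polygenic K term must absorb it) but no marker carries signal.  A
    background drawn from N(0, K) would itself be a sum of marker effects
    and so would not be a marker-free null.
    """
    s = _spawn(seed, 2)
    if pop is None:
        pop = make_population(s[0], **pop_kwargs)
    rng = np.random.default_rng(s[1])
    fams = pop.families()
    fam_eff = dict(zip(fams, rng.normal(0.0, np.sqrt(family_var), len(fams))))
    y = (pop.family.map(fam_eff).to_numpy()
         + rng.normal(0.0, np.sqrt(noise_var), pop.n_rils))
    res = gwas.genome_scan(pd.Series(y, index=pop.ril_ids), pop,
                           config=gwas.ScanConfig(window_cm=window_cm,
                                                  sig_threshold=sig_threshold))
    sig = res.significant()
    n_regions_tested = int(np.ceil(
        pop.gmap.frame.groupby("chrom")["cM"].max() / 5.0).sum())
    return {"any_significant": len(sig) > 0,
            "n_significant_markers": len(sig),
            "n_regions_tested": n_regions_tested,
            "n_markers": pop.gmap.n_markers}


def null_calibration(n_reps: int, seed: int, **kwargs) -> dict:
    """Fraction of null replicates declaring >= 1 significant 5-cM region."""
    seeds = _spawn(seed, n_reps)
    hits, n_regions = 0, 0
    for s in seeds:
        rec = null_scan_replicate(s, **kwargs)
        hits += int(rec["any_significant"])
        n_regions = rec["n_regions_tested"]
    return {"prob_any_significant": hits / n_reps, "n_reps": n_reps,
            "n_hits": hits, "n_regions_tested": n_regions}


# ---------------------------------------------------------------------------
# power for a shared large-effect QTL
# ---------------------------------------------------------------------------


def power_replicate(seed: int, effect: float = 150.0, n_families: int = 10,
                    rils_per_family: int = 50, noise_sd: float = 150.0,
                    markers_per_chromosome: int = 20,
                    cm_length: float = 60.0,
                    adjacency: int = 2, sig_threshold: float = 3.0) -> dict:
    """One replicate of the detection study: a single QTL with the same
    substitution effect in every family, placed mid-chromosome and forced to
    segregate in all families."""
    s = _spawn(seed, 3)
    pop = make_population(s[0], n_families=n_families,
                          rils_per_family=rils_per_family,
                          n_chromosomes=2, cm_length=cm_length,
                          markers_per_chromosome=markers_per_chromosome)
    panel = pop.panel
    qtl_idx = markers_per_chromosome // 2
    qtl_marker = str(pop.gmap.markers[qtl_idx])
    panel.haplotypes[1:, qtl_idx] = 1  # every founder carries the alt allele
    pop.geno[:, qtl_idx] = (pop.origin[:, qtl_idx]).astype(np.int8)

    founders = panel.founder_ids
    arch = simulate.TraitArchitecture(
        qtl={"trait": [qtl_marker]},
        effects={"trait": pd.DataFrame({qtl_marker: [effect] * len(founders)},
                                       index=founders)},
        polygenic_var={"trait": 0.0})
    g = simulate.genetic_values(pop, arch)["trait"]
    rng = np.random.default_rng(s[1])
    y = pd.Series(g.to_numpy() + rng.normal(0, noise_sd, len(g)),
                  index=pop.ril_ids)
    res = gwas.genome_scan(y, pop,
                           config=gwas.ScanConfig(sig_threshold=sig_threshold))
    stats = res.stats
    peak = stats.loc[stats["neg_log10_p"].idxmax()]
    qtl_row = int(np.flatnonzero(stats["marker"] == qtl_marker)[0])
    peak_row = int(stats["neg_log10_p"].idxmax())
    detected = (peak["neg_log10_p"] >= sig_threshold
                and abs(peak_row - qtl_row) <= adjacency
                and peak["chrom"] == stats["chrom"].iloc[qtl_row])
    return {"detected": bool(detected), "peak_marker": str(peak["marker"]),
            "peak_score": float(peak["neg_log10_p"]),
            "qtl_marker": qtl_marker, "result": res, "phenotype": y,
            "pop": pop}


def power_study(n_reps: int, seed: int, **kwargs) -> dict:
    seeds = _spawn(seed, n_reps)
    det = [power_replicate(s, **kwargs)["detected"] for s in seeds]
    return {"power": float(np.mean(det)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# heritability coverage
# ---------------------------------------------------------------------------


def heritability_replicate(seed: int, h_target: float, n_entries: int = 150,
                           sigma2_g: float = 1.0) -> blup.HeritabilityEstimate:
    """Simulate an unbalanced entry x environment table at a target
    entry-mean heritability and re-estimate it via the entry model."""
    rng = np.random.default_rng(seed)
    env_pool = np.array([3, 4, 5, 6, 7])
    counts = np.where(rng.random(n_entries) < 0.6, 7,
                      rng.choice(env_pool[:-1], n_entries))
    e_bar = blup.harmonic_mean(counts)
    sigma2_res = e_bar * sigma2_g * (1.0 / h_target - 1.0)
    rows = []
    g = rng.normal(0, np.sqrt(sigma2_g), n_entries)
    for i in range(n_entries):
        for e in range(counts[i]):
            rows.append({"plot": f"{i}_{e}", "entry": f"G{i:04d}",
                         "environment": f"E{e}", "block": f"B{e}",
                         "planting_date": 135, "role": "ril",
                         "y": g[i] + rng.normal(0, np.sqrt(sigma2_res))})
    plots = pd.DataFrame(rows)
    fit = blup.fit_entry_model(plots, "y", use_planting_date=False)
    return blup.heritability(fit.sigma2_g, fit.sigma2_res,
                             fit.env_counts.to_numpy())


def heritability_coverage(n_reps: int, seed: int, h_target: float,
                          **kwargs) -> dict:
    seeds = _spawn(seed, n_reps)
    cover, ests = 0, []
    for s in seeds:
        est = heritability_replicate(s, h_target, **kwargs)
        ests.append(est.H)
        cover += int(est.ci_low <= h_target <= est.ci_high)
    return {"coverage": cover / n_reps, "mean_H": float(np.mean(ests)),
            "target": h_target, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# among-family variance recovery
# ---------------------------------------------------------------------------


def family_variance_recovery(seed: int, target: float = 0.57,
                             n_families: int = 40, rils_per_family: int = 140,
                             n_reps: int = 10) -> dict:
    """Mean recovered among-family proportion over independent replicates of
    the full 40 x 140 family structure (one replicate's estimate carries a
    sampling SD of ~0.055 with 40 families, so the recovery is reported as a
    mean over replicates)."""
    seeds = _spawn(seed, n_reps)
    props = []
    for s in seeds:
        rng = np.random.default_rng(s)
        fam_eff = rng.normal(0, np.sqrt(target), n_families)
        vals, fams = [], []
        for f in range(n_families):
            vals.append(fam_eff[f] + rng.normal(0, np.sqrt(1 - target),
                                                rils_per_family))
            fams.extend([f"F{f:02d}"] * rils_per_family)
        idx = [f"{f}_{i}" for f, i in zip(fams, range(len(fams)))]
        prop, _, _ = blup.variance_among_families(
            pd.Series(np.concatenate(vals), index=idx),
            pd.Series(fams, index=idx))
        props.append(prop)
    return {"mean_proportion": float(np.mean(props)), "target": target,
            "n_reps": n_reps, "per_rep": props}


# ---------------------------------------------------------------------------
# family-specific allele-effect recovery
# ---------------------------------------------------------------------------


def qtl_effect_recovery(seed: int, target_effect: float = 239.0,
                        n_families: int = 8, rils_per_family: int = 60,
                        noise_sd: float = 150.0) -> dict:
    """Plant one family-specific substitution effect at a QTL (other
    families draw contrasting effects) and recover it from the scan's
    per-family BLUP at that marker, with its prediction-error SD."""
    s = _spawn(seed, 3)
    # genome geometry matters here: with a 20-chromosome genome the markers
    # sharing a chromosome with the QTL (the only ones in LD with it beyond
    # the exclusion window) carry ~5% of K's weight, as in a real soybean
    # map, so the polygenic term does not soak up the family-specific signal
    pop = make_population(s[0], n_families=n_families,
                          rils_per_family=rils_per_family,
                          n_chromosomes=20, cm_length=80.0,
                          markers_per_chromosome=25)
    panel = pop.panel
    qtl_idx = 12
    qtl_marker = str(pop.gmap.markers[qtl_idx])
    panel.haplotypes[1:, qtl_idx] = 1
    pop.geno[:, qtl_idx] = pop.origin[:, qtl_idx].astype(np.int8)

    founders = panel.founder_ids
    rng = np.random.default_rng(s[1])
    effects = rng.normal(-100.0, 120.0, len(founders))
    effects[0] = target_effect
    target_family = pop.families()[0]
    arch = simulate.TraitArchitecture(
        qtl={"trait": [qtl_marker]},
        effects={"trait": pd.DataFrame({qtl_marker: effects}, index=founders)},
        polygenic_var={"trait": 0.0})
    g = simulate.genetic_values(pop, arch)["trait"]
    y = pd.Series(g.to_numpy() + rng.normal(0, noise_sd, len(g)),
                  index=pop.ril_ids)
    res = gwas.genome_scan(y, pop, markers=[qtl_marker])
    alpha = float(res.alpha.at[qtl_marker, target_family])
    sd = float(res.alpha_sd.at[qtl_marker, target_family])
    return {"alpha_hat": alpha, "posterior_sd": sd, "target": target_effect,
            "within_3sd": abs(alpha - target_effect) <= 3 * sd}
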