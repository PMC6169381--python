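"""Marker filtering, RIL quality control, cM interpolation and dense-marker
projection.

Per-family marker filtering removes markers that are monomorphic or show
severe segregation distortion (minor allele frequency strictly below 10%)
in any family.  RIL QC flags lines identical to a parent (likely selfs of
the seed parent) or carrying alleles absent from both parents (pedigree
errors); a family in which a majority of lines carry non-parental alleles
is flagged for removal.  Dense founder-only markers are projected onto RILs
through the framework-marker parental-origin calls: a dense marker flanked
by two framework markers with the same homozygous origin inherits that
parent's genotype, while recombinant, heterozygous or missing intervals
project as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (MISSING, ORIGIN_COMMON, ORIGIN_FOUNDER, FounderPanel,
                       GeneticMap, RILPopulation)

STATUS_SEGREGATING = "segregating"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_LOW_MAF = "low_MAF"
STATUS_NO_DATA = "no_data"

FLAG_PASS = "pass"
FLAG_IDENTICAL = "identical_to_parent"
FLAG_NON_PARENTAL = "non_parental_allele"


@dataclass
class MarkerFilterReport:
    """Per-family marker status plus the genome-wide elimination list."""

    table: pd.DataFrame  # family, marker, MAF, status
    eliminated: list[str]  # markers failing (monomorphic/low_MAF/no_data) in any family

    def keep_markers(self) -> list[str]:
        order = self.table.drop_duplicates("marker")["marker"]
        bad = set(self.eliminated)
        return [m for m in order if m not in bad]

    def family_keep_lists(self) -> dict[str, list[str]]:
        out = {}
        for fam, sub in self.table.groupby("family", sort=False):
            out[fam] = sub.loc[sub["status"] == STATUS_SEGREGATING, "marker"].tolist()
        return out


@dataclass
class RilQcReport:
    flags: pd.Series  # ril id -> flag
    family_fail_fraction: pd.Series  # family -> fraction non_parental
    families_to_remove: list[str]


def filter_markers(pop: RILPopulation, maf_threshold: float = 0.10) -> MarkerFilterReport:
    """Classify every marker within every family by minor allele frequency.

    MAF is computed on allele counts excluding missing genotypes.  A marker
    is eliminated genome-wide if it fails (monomorphic, MAF strictly below
    the threshold, or no data) in any single family.
    """
    markers = pop.gmap.markers
    rows = []
    eliminated: set[str] = set()
    for fam in pop.families():
        g = pop.geno[pop.family_rows(fam)].astype(float)
        g[g == MISSING] = np.nan
        n_obs = np.sum(~np.isnan(g), axis=0)
        alt = np.nansum(g, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_obs)
        maf = np.minimum(p, 1.0 - p)
        status = np.where(maf == 0.0, STATUS_MONOMORPHIC,
                          np.where(maf < maf_threshold, STATUS_LOW_MAF,
                                   STATUS_SEGREGATING))
        status = np.where(n_obs == 0, STATUS_NO_DATA, status)
        maf = np.where(n_obs == 0, np.nan, maf)
        for j, mk in enumerate(markers):
            rows.append((fam, mk, maf[j], status[j]))
            if status[j] != STATUS_SEGREGATING:
                eliminated.add(mk)
    table = pd.DataFrame(rows, columns=["family", "marker", "MAF", "status"])
    elim_ordered = [m for m in markers if m in eliminated]
    return MarkerFilterReport(table, elim_ordered)


def apply_marker_filter(pop: RILPopulation, report: MarkerFilterReport) -> RILPopulation:
    """Restrict a population (and its map/panel) to the retained markers."""
    keep = report.keep_markers()
    midx = pop.gmap.marker_index()
    cols = midx[keep].to_numpy()
    gmap = GeneticMap(pop.gmap.frame.iloc[cols].reset_index(drop=True))
    panel = pop.panel
    if panel is not None:
        panel = FounderPanel(panel.ids, panel.groups,
                             panel.haplotypes[:, cols], gmap,
                             common_id=panel.common_id)
    return RILPopulation(pop.ril_ids, pop.family, pop.family_founder,
                         pop.geno[:, cols], pop.origin[:, cols], gmap, panel)


def qc_rils(pop: RILPopulation, panel: FounderPanel,
            family_fail_threshold: float = 0.5) -> RilQcReport:
    """Flag RILs identical to a parent or carrying non-parental alleles.

    Comparisons ignore missing genotypes.  non_parental_allele takes
    precedence over identical_to_parent.  Families whose non-parental
    fraction exceeds ``family_fail_threshold`` are listed for removal.
    """
    common_hap = panel.haplotype(panel.common_id)
    flags = {}
    for fam in pop.families():
        founder_hap = panel.haplotype(pop.family_founder[fam])
        parent_geno = np.stack([2 * common_hap, 2 * founder_hap])  # doses
        seg = common_hap != founder_hap
        for i in pop.family_rows(fam):
            g = pop.geno[i]
            obs = g != MISSING
            # non-parental: any allele copy not carried by either parent.
            # Parents jointly carry {common, founder} alleles; at
            # non-segregating markers only the shared allele is parental.
            bad = obs & ~seg & (g != parent_geno[0])
            # at segregating markers doses 0/1/2 are all combinations of
            # parental alleles, so nothing to flag there
            if bad.any():
                flags[pop.ril_ids[i]] = FLAG_NON_PARENTAL
            elif (np.array_equal(g[obs], parent_geno[0][obs])
                  or np.array_equal(g[obs], parent_geno[1][obs])):
                flags[pop.ril_ids[i]] = FLAG_IDENTICAL
            else:
                flags[pop.ril_ids[i]] = FLAG_PASS
    fs = pd.Series(flags).reindex(pop.ril_ids)
    fail = (fs == FLAG_NON_PARENTAL).groupby(pop.family).mean()
    remove = fail.index[fail > family_fail_threshold].tolist()
    return RilQcReport(fs, fail, remove)


def interpolate_cM(query_bp, frame_bp, frame_cm) -> np.ndarray:
    """Linear interpolation of genetic position from physical position.

    ``frame_bp`` must be strictly increasing.  Queries at a frame point
    return its cM exactly; queries beyond the terminal points are clamped to
    the terminal cM values.
    """
    frame_bp = np.asarray(frame_bp, dtype=float)
    frame_cm = np.asarray(frame_cm, dtype=float)
    if frame_bp.size < 2:
        raise ValueError("interpolation frame needs at least 2 points")
    if not np.all(np.diff(frame_bp) > 0):
        raise ValueError("frame bp must be strictly increasing")
    return np.interp(np.asarray(query_bp, dtype=float), frame_bp, frame_cm)


def project_dense_markers(
    pop: RILPopulation,
    dense_map: GeneticMap,
    dense_haplotypes: np.ndarray,
    panel: FounderPanel | None = None,
) -> pd.DataFrame:
    """Project founder-genotyped dense markers onto RILs via framework origins.

    ``dense_haplotypes`` is (n_panel_lines, n_dense_markers) aligned with the
    panel's line order; the common parent's row gives the reference allele at
    each dense marker.  For each dense marker the two flanking framework
    markers on the same chromosome are located by bp (closed intervals, left
    flank wins bp ties; markers outside the framework inherit the nearest
    terminal framework marker's origin call).  When both flank origins agree
    and are homozygous, the line inherits that parent's dense genotype;
    otherwise the call is missing.  The projection can therefore never emit
    an allele absent from the two family parents.
    """
    panel = panel or pop.panel
    if panel is None:
        raise ValueError("a founder panel is required for projection")
    if dense_haplotypes.shape != (len(panel.ids), dense_map.n_markers):
        raise ValueError("dense haplotypes must be panel lines x dense markers")

    n = pop.n_rils
    out = np.full((n, dense_map.n_markers), MISSING, dtype=np.int8)
    common_row = panel.ids.index(panel.common_id)
    fam_rows = {f: pop.family_rows(f) for f in pop.families()}
    founder_row = {f: panel.ids.index(pop.family_founder[f]) for f in pop.families()}

    fw = pop.gmap.frame
    for chrom in dense_map.chromosomes():
        dsel = dense_map.chrom_indices(chrom)
        fsel = np.flatnonzero((fw["chrom"] == chrom).to_numpy())
        if len(fsel) == 0:
            continue  # no framework on this chromosome: stays missing
        fw_bp = fw["bp"].to_numpy()[fsel]
        d_bp = dense_map.frame["bp"].to_numpy()[dsel]
        # flanking framework indices, closed on both ends, left flank wins ties
        right = np.searchsorted(fw_bp, d_bp, side="left")
        left = right - 1
        exact = (right < len(fw_bp)) & (fw_bp[np.minimum(right, len(fw_bp) - 1)] == d_bp)
        left[exact] = right[exact]
        left = np.clip(left, 0, len(fw_bp) - 1)
        right = np.clip(right, 0, len(fw_bp) - 1)

        o_left = pop.origin[:, fsel[left]]
        o_right = pop.origin[:, fsel[right]]
        concordant = (o_left == o_right) & (
            (o_left == ORIGIN_COMMON) | (o_left == ORIGIN_FOUNDER))

        for fam, rows in fam_rows.items():
            h_common = dense_haplotypes[common_row, dsel]
            h_founder = dense_haplotypes[founder_row[fam], dsel]
            sub = concordant[rows]
            orig = o_left[rows]
            allele = np.where(orig == ORIGIN_FOUNDER,
                              h_founder[None, :], h_common[None, :])
            vals = np.where(sub, (2 * allele).astype(np.int8), MISSING)
            out[np.ix_(rows, dsel)] = vals
    return pd.DataFrame(out, index=pop.ril_ids, columns=dense_map.markers)
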