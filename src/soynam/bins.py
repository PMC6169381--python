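"""Post-processing of scan results into genomic regions and effect summaries.

Significant markers are chained into marker-trait-association (MTA) regions
per trait by single-linkage clustering along the genetic map: a new region
starts whenever the gap to the previous significant marker on the same
chromosome exceeds 5 cM (strictly; a gap of exactly 5 cM stays together).
Regions from different traits whose peaks lie within the same chaining
distance are merged into cross-trait bins.  Per-family allele effects at a
peak are classified by sign pattern (all negative, all-but-k negative,
mixed, ...), and effects are averaged by founder group (EL/BX/PI) to
contrast elite and exotic contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MtaRegion:
    trait: str
    chrom: str
    markers: list[str]          # member markers sorted by cM
    peak_marker: str
    peak_cm: float
    peak_score: float           # -log10 p at the peak
    span: tuple[float, float]   # cM interval covered


@dataclass
class CrossTraitBin:
    chrom: str
    index: int                  # 1-based, ordered by position within chromosome
    regions: list[MtaRegion]

    @property
    def traits(self) -> list[str]:
        return sorted({r.trait for r in self.regions})

    @property
    def position_cm(self) -> float:
        return float(np.mean([r.peak_cm for r in self.regions]))


def _chain(positions: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split sorted positions into runs with consecutive gaps <= gap."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > gap) + 1
    return np.split(np.arange(len(positions)), breaks)


def bin_regions(sig: pd.DataFrame, trait: str = "", gap: float = 5.0) -> list[MtaRegion]:
    """Chain significant markers into MTA regions.

    ``sig`` needs columns marker, chrom, cM, neg_log10_p.  Peak = the member
    with the highest score; ties break to the lower cM, then the
    lexicographically smaller marker id.  Input row order never matters.
    """
    regions: list[MtaRegion] = []
    if len(sig) == 0:
        return regions
    sig = sig.sort_values(["chrom", "cM", "marker"]).reset_index(drop=True)
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        cm = sub["cM"].to_numpy(dtype=float)
        for run in _chain(cm, gap):
            members = sub.iloc[run]
            peak = members.sort_values(
                ["neg_log10_p", "cM", "marker"],
                ascending=[False, True, True]).iloc[0]
            regions.append(MtaRegion(
                trait=trait, chrom=str(chrom),
                markers=members["marker"].tolist(),
                peak_marker=peak["marker"], peak_cm=float(peak["cM"]),
                peak_score=float(peak["neg_log10_p"]),
                span=(float(cm[run[0]]), float(cm[run[-1]])),
            ))
    return regions


def regions_from_scan(result, gap: float = 5.0) -> list[MtaRegion]:
    """MTA regions for one trait's scan result at its own threshold."""
    sig = result.significant()[["marker", "chrom", "cM", "neg_log10_p"]]
    return bin_regions(sig, trait=result.trait, gap=gap)


def cross_trait_bins(regions: list[MtaRegion], gap: float = 5.0) -> list[CrossTraitBin]:
    """Chain region peaks across traits into shared bins (peaks more than
    ``gap`` cM apart land in separate bins)."""
    out: list[CrossTraitBin] = []
    by_chrom: dict[str, list[MtaRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.peak_cm, r.trait, r.peak_marker))
        peaks = np.array([r.peak_cm for r in rs])
        for b, run in enumerate(_chain(peaks, gap)):
            out.append(CrossTraitBin(chrom=chrom, index=b + 1,
                                     regions=[rs[i] for i in run]))
    return out


def bins_table(bins: list[CrossTraitBin]) -> pd.DataFrame:
    """Chromosome x bin layout with one column per trait (peak cM or NA)."""
    traits = sorted({r.trait for b in bins for r in b.regions})
    rows = []
    for b in bins:
        row = {"chrom": b.chrom, "bin": b.index, "position_cM": b.position_cm,
               "n_traits": len(b.traits), "multi_trait": len(b.traits) > 1}
        for t in traits:
            hits = [r.peak_cm for r in b.regions if r.trait == t]
            row[t] = min(hits) if hits else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_allele_pattern(effects, max_exceptions: int = 2) -> str:
    """Sign-pattern label for the estimable per-family effects at a peak.

    Effects exactly 0 count as neither positive nor negative.  A minority of
    at most ``max_exceptions`` opposite-sign effects yields an
    ``all_but_k_*`` label; anything more balanced is ``mixed``.
    """
    e = np.asarray(effects, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("no estimable effects to classify")
    n_pos = int(np.sum(e > 0))
    n_neg = int(np.sum(e < 0))
    if n_pos == 0 and n_neg == 0:
        return "mixed"          # all exactly zero
    if n_pos == 0:
        return "all_negative"
    if n_neg == 0:
        return "all_positive"
    if n_pos <= max_exceptions and n_pos < n_neg:
        return f"all_but_{n_pos}_negative"
    if n_neg <= max_exceptions and n_neg < n_pos:
        return f"all_but_{n_neg}_positive"
    return "mixed"


def group_effect_summary(effects: pd.DataFrame) -> pd.DataFrame:
    """Mean allele-substitution effect per founder group and overall.

    ``effects`` is the long table from ``estimate_family_effects`` (columns
    group, effect, ...); every estimable (family, marker) pair carries equal
    weight.  Adds a ``unique_positive`` flag per group: markers where that
    group contributes a positive effect while no EL family does (exotic
    alleles absent from the elite pool)."""
    est = effects[np.isfinite(effects["effect"])]
    if len(est) == 0:
        raise ValueError("no estimable effects to summarize")
    rows = []
    el_pos_markers = set(
        est.loc[(est["group"] == "EL") & (est["effect"] > 0), "marker"])
    for grp, sub in est.groupby("group", sort=True):
        uniq = 0
        if grp != "EL":
            pos_markers = set(sub.loc[sub["effect"] > 0, "marker"])
            uniq = len(pos_markers - el_pos_markers)
        rows.append({"group": grp, "mean_effect": float(sub["effect"].mean()),
                     "n": len(sub), "n_unique_positive_markers": uniq})
    rows.append({"group": "overall", "mean_effect": float(est["effect"].mean()),
                 "n": len(est), "n_unique_positive_markers": np.nan})
    return pd.DataFrame(rows)
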