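"""Family-nested random-effect genome scan with polygenic control.

At each marker the entry genotypic values (stage-2 BLUPs) are modeled as

    v = mu + W a + phi + eps

where W holds one column per family in which the marker segregates, coded
as the entry's founder-allele fraction (0, 1/2, 1 relative to the common
parent's allele), a ~ N(0, I s2a) are family-specific allele-substitution
effects, and phi ~ N(0, K s2p) is a polygenic term with K a VanRaden
genomic relationship matrix computed while *excluding* markers inside a
cM "linkage window" around the tested marker (so tightly linked markers do
not absorb the signal being tested).  Because W is on the founder-allele
fraction scale and the lines are inbred, each a_f is the expected trait
difference between a line fixed for family f's founder allele and one
fixed for the common-parent allele.

Significance of sigma2_alpha = 0 is assessed by a restricted likelihood
ratio test against the boundary mixture 0.5*chi2_0 + 0.5*chi2_1; the method
label travels with the result metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import boundary_lrt_pvalue, fit_marker_model, fit_polygenic_null
from .kinship import KinshipBuilder, vanraden_kinship
from .simulate import MISSING, FounderPanel, RILPopulation

logger = logging.getLogger(__name__)

compute_kinship = vanraden_kinship  # module-level alias for the scan's K step

P_VALUE_METHOD = "restricted LRT, 0.5*chi2_0 + 0.5*chi2_1 boundary mixture"


@dataclass
class ScanConfig:
    window_cm: float = 5.0          # half-width of the linkage window
    sig_threshold: float = 3.0      # -log10(p) significance cutoff
    kinship_mode: str = "window"    # "window" (per marker) or "chromosome"
    reestimate_background: bool = True  # False = fixed-background fast mode
    pvalue_method: str = P_VALUE_METHOD

    def __post_init__(self) -> None:
        if self.window_cm < 0:
            raise ValueError("linkage window must be non-negative")
        if self.sig_threshold <= 0:
            raise ValueError("significance threshold must be positive")
        if self.kinship_mode not in ("window", "chromosome"):
            raise ValueError(f"unknown kinship_mode {self.kinship_mode!r}")


@dataclass
class GwasScanResult:
    stats: pd.DataFrame       # per marker: position, -log10 p, variance components
    alpha: pd.DataFrame       # markers x families, NaN = not estimable
    alpha_sd: pd.DataFrame    # matching prediction-error SDs
    families: list[str]
    config: ScanConfig
    trait: str = ""

    def significant(self) -> pd.DataFrame:
        s = self.stats
        return s[s["neg_log10_p"] >= self.config.sig_threshold]

    def metadata(self) -> dict:
        return {
            "trait": self.trait,
            "window_cm": self.config.window_cm,
            "sig_threshold": self.config.sig_threshold,
            "kinship_mode": self.config.kinship_mode,
            "reestimate_background": self.config.reestimate_background,
            "pvalue_method": self.config.pvalue_method,
            "n_markers": int(len(self.stats)),
            "n_families": len(self.families),
        }


def _relative_doses(geno_col: np.ndarray, common_dose: int) -> np.ndarray:
    """Dose of the non-common allele; missing stays MISSING."""
    out = geno_col.astype(np.int8)
    if common_dose == 2:
        keep = out != MISSING
        out = np.where(keep, 2 - out, MISSING).astype(np.int8)
    elif common_dose not in (0,):
        raise ValueError("common parent must be homozygous at every marker")
    return out


def _family_design(d_rel: np.ndarray, fam_codes: np.ndarray,
                   n_fam: int) -> tuple[np.ndarray, np.ndarray]:
    """W (n x q) on the founder-allele-fraction scale and the indices of the
    families in which the marker segregates.

    Each family's column is centered within the family, making W orthogonal
    to family means: the allele-substitution effect is identified from
    within-family segregation only, while between-family differences remain
    with the polygenic term.  Without this, family-mean variation that the
    finite-marker K does not fully absorb would inflate the marker variance
    under the null.  Centering leaves the slope (and hence the substitution
    effect alpha) unchanged.
    """
    seg = []
    for f in range(n_fam):
        rows = fam_codes == f
        vals = d_rel[rows]
        if len(vals) and vals.min() != vals.max():
            seg.append(f)
    W = np.zeros((len(d_rel), len(seg)))
    for k, f in enumerate(seg):
        rows = fam_codes == f
        frac = d_rel[rows] / 2.0
        W[rows, k] = frac - frac.mean()
    return W, np.asarray(seg, dtype=int)


def scan_marker(j: int, y: np.ndarray, fam_codes: np.ndarray, n_fam: int,
                geno: np.ndarray, common_dose: int,
                builder: KinshipBuilder, exclude: np.ndarray,
                null_cache: dict | None = None,
                fix_background: bool = False) -> dict:
    """Fit the scan model at one marker column; returns a flat record."""
    raw = geno[:, j]
    obs = raw != MISSING
    d_rel = _relative_doses(raw, common_dose)
    W_full, seg = _family_design(np.where(obs, d_rel, 0), fam_codes, n_fam)
    rec = {"neg_log10_p": 0.0, "p_value": 1.0, "sigma2_alpha": 0.0,
           "sigma2_poly": np.nan, "sigma2_res": np.nan,
           "mu": np.nan, "n_estimable": len(seg),
           "alpha": np.full(n_fam, np.nan), "alpha_sd": np.full(n_fam, np.nan)}
    if np.ptp(y[obs]) < 1e-12:        # degenerate response
        rec["alpha"][:] = np.nan
        rec["alpha"][np.isin(np.arange(n_fam), seg)] = 0.0
        return rec

    cache_key = None if null_cache is None else (tuple(exclude), obs.tobytes())
    if cache_key is not None and cache_key in null_cache:
        rot0, null = null_cache[cache_key]
    else:
        K = builder.kinship(exclude).values
        if obs.all():
            ys, Ks = y, K
        else:
            ys, Ks = y[obs], K[np.ix_(obs, obs)]
        from ._lmm import rotate_problem
        rot0 = rotate_problem(ys, np.ones((len(ys), 1)), np.zeros((len(ys), 0)), Ks)
        null = fit_polygenic_null(rot=rot0)
        if cache_key is not None:
            null_cache[cache_key] = (rot0, null)
    rec["sigma2_poly"] = null.sigma2_phi
    rec["sigma2_res"] = null.sigma2_e
    if len(seg) == 0:                  # monomorphic in every family
        return rec

    Ws = W_full if obs.all() else W_full[obs]
    full = fit_marker_model(rot=rot0.with_design(Ws), null_fit=null,
                            fix_lp=null.log_ratios[0] if fix_background else None)
    p = boundary_lrt_pvalue(null.neg2_reml, full.neg2_reml)
    rec.update(p_value=p, neg_log10_p=float(-np.log10(max(p, 1e-300))),
               sigma2_alpha=full.sigma2_alpha, sigma2_poly=full.sigma2_phi,
               sigma2_res=full.sigma2_e, mu=float(full.beta[0]))
    rec["alpha"][seg] = full.alpha
    rec["alpha_sd"][seg] = full.alpha_sd
    return rec


def genome_scan(blups: pd.Series, pop: RILPopulation,
                config: ScanConfig | None = None,
                markers: list[str] | None = None,
                trait: str = "") -> GwasScanResult:
    """Run the family-nested scan over every retained marker.

    ``blups`` is indexed by RIL id; entries absent from the population are
    ignored and RILs without a BLUP are dropped.  Per-marker failures are
    recorded as flagged rows (p = 1) rather than aborting the scan.
    """
    config = config or ScanConfig()
    ids = [r for r in pop.ril_ids if r in blups.index]
    if len(ids) < 10:
        raise ValueError("too few entries shared between BLUPs and population")
    rows = pd.Series(np.arange(pop.n_rils), index=pop.ril_ids)[ids].to_numpy()
    y = blups[ids].to_numpy(dtype=float)
    fams = pop.families()
    fam_codes = pop.family[ids].map({f: i for i, f in enumerate(fams)}).to_numpy()
    geno = pop.geno[rows]
    common_hap = (pop.panel.haplotype(pop.panel.common_id)
                  if pop.panel is not None else np.zeros(pop.gmap.n_markers, dtype=np.int8))

    frame = pop.gmap.frame
    midx = pop.gmap.marker_index()
    test_idx = (midx[markers].to_numpy() if markers is not None
                else np.arange(pop.gmap.n_markers))
    chrom = frame["chrom"].to_numpy()
    cm = frame["cM"].to_numpy(dtype=float)

    builder = KinshipBuilder(geno, ids)
    null_cache: dict = {}
    records, alphas, alpha_sds = [], [], []
    for count, j in enumerate(test_idx):
        if config.kinship_mode == "chromosome":
            exclude = np.flatnonzero(chrom == chrom[j])
        else:
            exclude = np.flatnonzero((chrom == chrom[j])
                                     & (np.abs(cm - cm[j]) <= config.window_cm))
        try:
            rec = scan_marker(j, y, fam_codes, len(fams), geno,
                              int(2 * common_hap[j]), builder, exclude,
                              null_cache if config.kinship_mode == "chromosome"
                              else None,
                              fix_background=not config.reestimate_background)
            failed = ""
        except Exception as exc:  # noqa: BLE001 - flagged, never aborts
            logger.warning("marker %s failed: %s", frame["marker"].iloc[j], exc)
            rec = {"neg_log10_p": 0.0, "p_value": 1.0, "sigma2_alpha": np.nan,
                   "sigma2_poly": np.nan, "sigma2_res": np.nan, "mu": np.nan,
                   "n_estimable": 0, "alpha": np.full(len(fams), np.nan),
                   "alpha_sd": np.full(len(fams), np.nan)}
            failed = str(exc)
        records.append({
            "marker": frame["marker"].iloc[j], "chrom": chrom[j],
            "bp": int(frame["bp"].iloc[j]), "cM": cm[j],
            "neg_log10_p": rec["neg_log10_p"], "p_value": rec["p_value"],
            "sigma2_alpha": rec["sigma2_alpha"],
            "sigma2_poly": rec["sigma2_poly"], "sigma2_res": rec["sigma2_res"],
            "n_estimable": rec["n_estimable"], "error": failed,
        })
        alphas.append(rec["alpha"])
        alpha_sds.append(rec["alpha_sd"])
        if (count + 1) % 50 == 0:
            logger.info("scan %s: %d/%d markers", trait, count + 1, len(test_idx))

    stats = pd.DataFrame(records)
    mk = stats["marker"]
    return GwasScanResult(
        stats=stats,
        alpha=pd.DataFrame(np.vstack(alphas), index=mk, columns=fams),
        alpha_sd=pd.DataFrame(np.vstack(alpha_sds), index=mk, columns=fams),
        families=fams, config=config, trait=trait,
    )


def estimate_family_effects(result: GwasScanResult,
                            pop: RILPopulation,
                            panel: FounderPanel | None = None,
                            significant_only: bool = True) -> pd.DataFrame:
    """Long table of per-family allele-substitution estimates with founder
    and group annotation.  Positive = the founder allele raises the trait
    relative to the common-parent allele.  Not-estimable combinations are
    preserved as NaN effects."""
    panel = panel or pop.panel
    stats = result.significant() if significant_only else result.stats
    rows = []
    for _, srow in stats.iterrows():
        mk = srow["marker"]
        for fam in result.families:
            founder = pop.family_founder[fam]
            rows.append({
                "marker": mk, "chrom": srow["chrom"], "cM": srow["cM"],
                "neg_log10_p": srow["neg_log10_p"],
                "family": fam, "founder": founder,
                "group": panel.groups[founder] if panel else "",
                "effect": result.alpha.at[mk, fam],
                "effect_sd": result.alpha_sd.at[mk, fam],
                "estimable": bool(np.isfinite(result.alpha.at[mk, fam])),
            })
    return pd.DataFrame(rows)
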