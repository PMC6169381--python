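"""Two-stage mixed-model phenotype analysis for augmented sets trials.

Stage 1 fits the check plots only: trait = planting date (fixed covariate)
+ check variety (fixed) + block (random) + residual, yielding shrunken
(BLUP) block effects and check BLUEs.  Stage 2 fits the non-check entries:
trait = planting date + stage-1 block value (both fixed covariates with
their own slopes) + entry (random) + residual, yielding entry genotypic
BLUPs and the variance components that feed broad-sense heritability.
Heritability on an entry-mean basis divides the residual variance by the
harmonic mean of the per-entry environment counts; confidence intervals use
F-quantile (Knapp-type) bounds on the same harmonic mean.  All variance
components are REML estimates (statsmodels MixedLM, the analog of lme4's
lmer), clamped at the zero boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PlotTable


def harmonic_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty count vector")
    if (x <= 0).any():
        raise ValueError("counts must be positive")
    return float(len(x) / np.sum(1.0 / x))


@dataclass
class BlockEffectEstimates:
    block_blups: pd.Series      # block id -> shrunken effect (trait units)
    check_blues: pd.Series      # check id -> BLUE at the mean planting date
    pldate_slope: float
    intercept: float
    sigma2_blk: float
    sigma2_res: float
    pldate_center: float
    trait: str


@dataclass
class EntryBlups:
    blups: pd.Series            # entry -> genotypic BLUP (deviation from mu)
    coefficients: dict          # fixed-effect solutions incl. covariate slopes
    sigma2_g: float
    sigma2_res: float
    env_counts: pd.Series       # entry -> number of environments observed
    trait: str


@dataclass
class HeritabilityEstimate:
    H: float
    basis: str
    ci_low: float
    ci_high: float
    e_harmonic: float
    n_harmonic: float | None = None


def _plots_frame(plots) -> pd.DataFrame:
    return plots.table if isinstance(plots, PlotTable) else plots


def _fit_mixedlm(endog, exog, groups):
    """REML random-intercept fit with convergence fallbacks."""
    import statsmodels.api as sm

    model = sm.MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        last_err = None
        for method in (["lbfgs"], ["bfgs"], ["cg"], ["powell"]):
            try:
                res = model.fit(reml=True, method=method, maxiter=500)
                if np.isfinite(res.llf):
                    return res
            except (np.linalg.LinAlgError, ValueError) as e:  # pragma: no cover
                last_err = e
        raise RuntimeError(f"mixed model failed to converge: {last_err}")


def fit_check_block_model(plots, trait: str,
                          all_blocks=None) -> BlockEffectEstimates:
    """Stage-1 model on the check plots: shrunken block effects.

    ``all_blocks`` optionally lists every block in the trial; blocks without
    check data receive a BLUP of 0 (fully shrunk).  Raises if fewer than two
    blocks carry data or the fixed design (checks + planting date) is
    singular, e.g. when all checks sit in a single block.
    """
    df = _plots_frame(plots)
    sub = df[(df["role"] == "check") & df[trait].notna()].copy()
    if sub["block"].nunique() < 2:
        raise ValueError("check-block model needs checks observed in >= 2 blocks")
    center = float(sub["planting_date"].mean())
    checks = sorted(sub["entry"].unique())
    dummies = pd.get_dummies(sub["entry"], drop_first=True, dtype=float)
    has_dates = sub["planting_date"].nunique() > 1  # constant date drops out
    cols = [np.ones(len(sub))]
    if has_dates:
        cols.append(sub["planting_date"].to_numpy(dtype=float) - center)
    cols.append(dummies.to_numpy())
    exog = np.column_stack(cols)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("check/planting-date fixed design is unidentifiable")
    res = _fit_mixedlm(sub[trait].to_numpy(dtype=float), exog, sub["block"])

    fe = np.asarray(res.fe_params, dtype=float)
    intercept = float(fe[0])
    slope = float(fe[1]) if has_dates else 0.0
    blues = {checks[0]: intercept}
    for name, coef in zip(dummies.columns, fe[1 + int(has_dates):]):
        blues[name] = intercept + float(coef)
    re = {g: float(np.asarray(v).ravel()[0]) for g, v in res.random_effects.items()}
    blocks = list(all_blocks) if all_blocks is not None else sorted(re)
    blups = pd.Series({b: re.get(b, 0.0) for b in blocks}, name="block_blup")
    return BlockEffectEstimates(
        block_blups=blups,
        check_blues=pd.Series(blues).reindex(checks),
        pldate_slope=slope,
        intercept=intercept,
        sigma2_blk=max(0.0, float(np.asarray(res.cov_re)[0, 0])),
        sigma2_res=float(res.scale),
        pldate_center=center,
        trait=trait,
    )


def fit_entry_model(plots, trait: str,
                    block_effects: BlockEffectEstimates | None = None,
                    use_planting_date: bool = True) -> EntryBlups:
    """Stage-2 model on the non-check entries (RILs and family parents).

    Planting date and the stage-1 shrunken block value each enter as fixed
    covariates with estimated slopes.  Entries observed in a single plot are
    retained (and strongly shrunk); entries with no data are absent from the
    result rather than zero-filled.
    """
    df = _plots_frame(plots)
    sub = df[(df["role"] != "check") & df[trait].notna()].copy()
    if len(sub) == 0:
        raise ValueError(f"no non-missing {trait!r} observations for entries")
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    if use_planting_date and sub["planting_date"].nunique() > 1:
        center = float(sub["planting_date"].mean())
        cols.append(sub["planting_date"].to_numpy(dtype=float) - center)
        names.append("pldate_slope")
    if block_effects is not None:
        bv = sub["block"].map(block_effects.block_blups)
        missing_blocks = sorted(sub.loc[bv.isna(), "block"].unique())
        if missing_blocks:
            raise ValueError(f"no stage-1 block estimate for blocks {missing_blocks}")
        if bv.nunique() > 1:
            cols.append(bv.to_numpy(dtype=float))
            names.append("blk_slope")
    exog = np.column_stack(cols)
    res = _fit_mixedlm(sub[trait].to_numpy(dtype=float), exog, sub["entry"])
    coefs = dict(zip(names, np.asarray(res.fe_params, dtype=float)))
    blups = pd.Series({g: float(np.asarray(v).ravel()[0]) for g, v in res.random_effects.items()},
                      name=trait).sort_index()
    env_counts = sub.groupby("entry")["environment"].nunique().reindex(blups.index)
    return EntryBlups(
        blups=blups,
        coefficients=coefs,
        sigma2_g=max(0.0, float(np.asarray(res.cov_re)[0, 0])),
        sigma2_res=float(res.scale),
        env_counts=env_counts,
        trait=trait,
    )


def heritability(sigma2_g: float, sigma2_res: float, env_counts,
                 basis: str = "entry_mean", alpha: float = 0.05,
                 sigma2_within: float | None = None,
                 family_sizes=None) -> HeritabilityEstimate:
    """Broad-sense heritability with harmonic-mean replication.

    entry_mean basis: H = s2g / (s2g + s2res / e_bar) with e_bar the harmonic
    mean of per-entry environment counts.  family_mean basis treats sigma2_g
    as the among-family component and requires ``sigma2_within`` plus
    ``family_sizes``: H = s2a / (s2a + s2w/n_bar + s2res/(n_bar * e_bar)).
    The 95% CI uses F-quantile bounds with df1 = groups - 1 and
    df2 = sum(e_i) - groups, both on the harmonic-mean scale.
    """
    if sigma2_g < 0 or sigma2_res < 0:
        raise ValueError("variance components must be non-negative")
    e_bar = harmonic_mean(env_counts)
    n_entries = len(np.asarray(env_counts, dtype=float))
    n_bar = None
    if basis == "entry_mean":
        denom = sigma2_g + sigma2_res / e_bar
        n_groups = n_entries
    elif basis == "family_mean":
        if sigma2_within is None or family_sizes is None:
            raise ValueError("family_mean basis needs sigma2_within and family_sizes")
        n_bar = harmonic_mean(family_sizes)
        denom = sigma2_g + sigma2_within / n_bar + sigma2_res / (n_bar * e_bar)
        n_groups = len(np.asarray(family_sizes, dtype=float))
    else:
        raise ValueError(f"unknown heritability basis {basis!r}")
    H = 0.0 if denom == 0 else sigma2_g / denom

    df1 = max(n_groups - 1, 1)
    df2 = max(int(round(np.sum(np.asarray(env_counts, dtype=float)))) - n_entries, 1)
    if H >= 1.0:
        lo, hi = H, H
    else:
        f_obs = 1.0 / (1.0 - H)
        lo = 1.0 - stats.f.ppf(1 - alpha / 2, df1, df2) / f_obs
        hi = 1.0 - stats.f.ppf(alpha / 2, df1, df2) / f_obs
    return HeritabilityEstimate(
        H=float(np.clip(H, 0.0, 1.0)),
        basis=basis,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        e_harmonic=e_bar,
        n_harmonic=n_bar,
    )


def variance_among_families(values: pd.Series, families: pd.Series):
    """Partition genotypic values into among- and within-family variance.

    One-way random-effects (REML) decomposition; returns
    (proportion_among, sigma2_among, sigma2_within).
    """
    values, families = values.align(families, join="inner")
    values = values.dropna()
    families = families[values.index]
    if families.nunique() < 2:
        raise ValueError("among-family variance undefined with a single family")
    exog = np.ones((len(values), 1))
    res = _fit_mixedlm(values.to_numpy(dtype=float), exog, families)
    s2a = max(0.0, float(np.asarray(res.cov_re)[0, 0]))
    s2w = float(res.scale)
    total = s2a + s2w
    prop = 0.0 if total == 0 else s2a / total
    return prop, s2a, s2w


def genetic_correlations(blups_by_trait: dict[str, pd.Series]) -> pd.DataFrame:
    """Product-moment correlations of entry BLUPs across traits, on the
    intersection of entries with predictions for every trait."""
    if len(blups_by_trait) < 2:
        raise ValueError("need at least two traits")
    frame = pd.DataFrame(blups_by_trait).dropna()
    if len(frame) < 3:
        raise ValueError("fewer than 3 entries shared across traits")
    corr = frame.corr()
    np.fill_diagonal(corr.values, 1.0)
    return corr
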