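"""Synthetic NAM population, trait-architecture and field-trial generator.

Emulates the structure of a soybean nested association mapping experiment:
a panel of fully homozygous founders (elite EL, exotic-derived BX and plant
introduction PI groups) each mated to one common hub parent; recombinant
inbred lines advanced by single-seed descent (F2 onward, one offspring per
generation, Haldane map function with no interference); multi-environment
augmented incomplete-block yield trials in 40-entry sets (35 RILs, the two
family parents and three checks) with a Julian planting-date covariate and
unbalanced environment coverage.

Genotypes are coded as dose of the non-common (alternate) allele in
{0, 1, 2}; -1 marks missing.  The common parent carries the reference allele
everywhere, so a founder's haplotype is simply the set of markers at which
it differs from the hub line.  Parental origin is tracked per marker through
every meiosis, which downstream marker projection relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
ORIGIN_COMMON = 0
ORIGIN_FOUNDER = 2
ORIGIN_HET = 1

COMMON_GROUP = "COMMON"
FOUNDER_GROUPS = ("EL", "BX", "PI")
#: founder counts of the reference germplasm design (17 elite, 15 exotic-derived
#: breeding lines, 8 plant introductions) mated to one common hub parent
DEFAULT_GROUP_COUNTS = {"EL": 17, "BX": 15, "PI": 8}

TRAITS = ("yield", "maturity", "height", "lodging", "seed_mass")


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM, assuming no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker coordinates in both bp and cM, per chromosome.

    ``frame`` has columns ``marker, chrom, bp, cM`` sorted by (chrom, bp);
    within a chromosome bp is strictly increasing and cM non-decreasing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["marker", "chrom", "bp", "cM"]
        missing = [c for c in req if c not in self.frame.columns]
        if missing:
            raise ValueError(f"map frame missing columns {missing}")
        f = self.frame.reset_index(drop=True)
        if f["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        for chrom, sub in f.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"cM not non-decreasing on chromosome {chrom}")
            if (bp < 1).any():
                raise ValueError("bp positions must be 1-based positive")
        self.frame = f

    @property
    def markers(self) -> np.ndarray:
        return self.frame["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())

    def marker_index(self) -> pd.Series:
        return pd.Series(np.arange(self.n_markers), index=self.frame["marker"])

    def recomb_fractions(self, chrom) -> np.ndarray:
        """Per-interval recombination fractions along one chromosome."""
        cm = self.frame.loc[self.chrom_indices(chrom), "cM"].to_numpy(dtype=float)
        return np.asarray(haldane_r(np.diff(cm)))


@dataclass
class FounderPanel:
    """Homozygous parent panel: one common hub line plus grouped founders.

    ``haplotypes`` is (n_lines, n_markers) in {0, 1}: a single haplotype per
    line suffices because every parent is fully inbred.
    """

    ids: list[str]
    groups: dict[str, str]
    haplotypes: np.ndarray
    gmap: GeneticMap
    common_id: str = "common"

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.ids), self.gmap.n_markers):
            raise ValueError("haplotype matrix does not match panel ids x map markers")
        n_common = sum(1 for g in self.groups.values() if g == COMMON_GROUP)
        if n_common != 1:
            raise ValueError("panel must contain exactly one COMMON line")
        if self.groups.get(self.common_id) != COMMON_GROUP:
            raise ValueError("common_id must carry the COMMON group label")

    @property
    def founder_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.common_id]

    def haplotype(self, line_id: str) -> np.ndarray:
        return self.haplotypes[self.ids.index(line_id)]


@dataclass
class TraitArchitecture:
    """QTL positions and per-founder substitution effects for each trait.

    Effects are homozygous-line substitutions relative to the common parent:
    a RIL fixed for founder f's allele at QTL q shifts by ``effects[trait]``
    entry (f, q).  The common parent's effect is identically zero.  Each trait
    also carries an unlinked polygenic variance.
    """

    qtl: dict[str, list[str]]
    effects: dict[str, pd.DataFrame]  # trait -> founders x qtl markers
    polygenic_var: dict[str, float]

    def traits(self) -> list[str]:
        return list(self.qtl)


@dataclass
class RILPopulation:
    """Family-structured recombinant inbred lines with origin tracking."""

    ril_ids: list[str]
    family: pd.Series  # ril id -> family id
    family_founder: dict[str, str]  # family id -> founder id
    geno: np.ndarray  # (n, m) int8 dose of alternate allele, -1 missing
    origin: np.ndarray  # (n, m) int8: 0 common / 1 het / 2 founder
    gmap: GeneticMap
    panel: FounderPanel | None = None

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def families(self) -> list[str]:
        return list(self.family_founder)

    def family_rows(self, fam: str) -> np.ndarray:
        return np.flatnonzero((self.family == fam).to_numpy())

    def heterozygosity(self) -> float:
        """Mean fraction of origin-heterozygous loci per line."""
        return float(np.mean(self.origin == ORIGIN_HET))


@dataclass
class TrialDesign:
    """Plot-level layout of a multi-environment augmented sets trial.

    ``plots`` columns: environment, set, block, entry, role
    (ril/parent/check), planting_date (Julian day).  A block is one set grown
    in one environment.
    """

    plots: pd.DataFrame
    set_members: dict[str, list[str]]

    def n_sets(self) -> int:
        return len(self.set_members)

    def environments(self) -> list[str]:
        return list(dict.fromkeys(self.plots["environment"]))


@dataclass
class PlotTable:
    """Observed plot values: one row per plot, one column per trait."""

    table: pd.DataFrame
    traits: list[str]

    def __post_init__(self) -> None:
        req = {"plot", "entry", "environment", "block", "planting_date", "role"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"plot table missing columns {sorted(missing)}")
        if "lodging" in self.traits:
            v = self.table["lodging"].dropna()
            if ((v < 1) | (v > 5)).any():
                raise ValueError("lodging scores must lie in [1, 5]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_map(
    n_chromosomes: int,
    cm_length: float | Sequence[float],
    n_markers: int | Sequence[int],
    bp_model: Mapping | None = None,
    seed: int | None = None,
    spacing: str = "uniform",
) -> GeneticMap:
    """Build a synthetic genetic map with consistent bp and cM coordinates.

    ``bp_model``: ``{"kind": "linear", "bp_per_cM": 1e6}`` (default) or
    ``{"kind": "piecewise", "n_knots": k, "rate_sd": s}`` for a random
    monotone piecewise-linear bp<->cM warp.  ``spacing`` is "uniform" (even
    grid, endpoints at 0 and cm_length) or "random" (sorted uniform interior
    positions, endpoints pinned).
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    lengths = np.broadcast_to(np.asarray(cm_length, dtype=float), (n_chromosomes,))
    counts = np.broadcast_to(np.asarray(n_markers, dtype=int), (n_chromosomes,))
    if (lengths <= 0).any() or (counts < 2).any():
        raise ValueError("chromosome length must be positive and n_markers >= 2")
    bp_model = dict(bp_model or {"kind": "linear"})
    kind = bp_model.get("kind", "linear")
    rng = np.random.default_rng(seed)

    rows = []
    for c in range(n_chromosomes):
        L, m = float(lengths[c]), int(counts[c])
        if spacing == "uniform":
            cm = np.linspace(0.0, L, m)
        elif spacing == "random":
            cm = np.concatenate([[0.0], np.sort(rng.uniform(0, L, m - 2)), [L]])
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        if kind == "linear":
            rate = float(bp_model.get("bp_per_cM", 1e6))
            bp = np.round(cm * rate).astype(np.int64) + 1
        elif kind == "piecewise":
            n_knots = int(bp_model.get("n_knots", 4))
            rate_sd = float(bp_model.get("rate_sd", 0.5))
            knots = np.linspace(0.0, L, n_knots + 1)
            rates = 1e6 * np.exp(rng.normal(0.0, rate_sd, n_knots))
            knot_bp = np.concatenate([[0.0], np.cumsum(np.diff(knots) * rates)])
            bp = np.round(np.interp(cm, knots, knot_bp)).astype(np.int64) + 1
        else:
            raise ValueError(f"unknown bp model {kind!r}")
        # enforce strict bp increase after rounding
        bp = np.maximum.accumulate(bp + np.arange(m))
        chrom = f"chr{c + 1:02d}"
        for j in range(m):
            rows.append((f"{chrom}_m{j + 1:04d}", chrom, int(bp[j]), float(cm[j])))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))


def simulate_founders(
    gmap: GeneticMap,
    group_counts: Mapping[str, int] | None = None,
    allele_freq: float | Mapping = 0.5,
    seed: int | None = None,
    common_id: str = "common",
) -> FounderPanel:
    """Draw a homozygous founder panel around an all-reference common parent.

    Each founder carries the alternate allele at marker j with probability
    f_j; ``allele_freq`` is a scalar or ``{"kind": "uniform", "low", "high"}``
    for per-marker frequencies.
    """
    group_counts = dict(group_counts or DEFAULT_GROUP_COUNTS)
    for g, k in group_counts.items():
        if g not in FOUNDER_GROUPS:
            raise ValueError(f"unknown founder group {g!r}")
        if k < 1:
            raise ValueError("group counts must be positive")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    if isinstance(allele_freq, Mapping):
        if allele_freq.get("kind") != "uniform":
            raise ValueError("allele_freq mapping must have kind='uniform'")
        freqs = rng.uniform(allele_freq["low"], allele_freq["high"], m)
    else:
        freqs = np.full(m, float(allele_freq))
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")

    ids = [common_id]
    groups = {common_id: COMMON_GROUP}
    haplos = [np.zeros(m, dtype=np.int8)]
    for g in FOUNDER_GROUPS:
        for i in range(group_counts.get(g, 0)):
            fid = f"{g}{i + 1:02d}"
            ids.append(fid)
            groups[fid] = g
            haplos.append((rng.random(m) < freqs).astype(np.int8))
    return FounderPanel(ids, groups, np.vstack(haplos), gmap, common_id=common_id)


def _meiosis_paths(rng, n: int, r: np.ndarray) -> np.ndarray:
    """n gamete origin paths over one chromosome: 0/1 choice of parental
    haplotype at each marker, switching between adjacent markers with the
    interval's recombination fraction (Markov chain, no interference)."""
    m = len(r) + 1
    start = rng.random((n, 1)) < 0.5
    switches = rng.random((n, m - 1)) < r[None, :]
    steps = np.concatenate([start, switches], axis=1)
    return (np.cumsum(steps, axis=1) % 2).astype(np.int8)


def simulate_gametes(gmap: GeneticMap, n: int, seed=None) -> np.ndarray:
    """Origin labels (0/1) of n gametes from a fully heterozygous F1,
    concatenated over chromosomes.  Exposed for map-consistency checks."""
    rng = np.random.default_rng(seed)
    cols = []
    for chrom in gmap.chromosomes():
        cols.append(_meiosis_paths(rng, n, gmap.recomb_fractions(chrom)))
    return np.concatenate(cols, axis=1)


def derive_rils(
    panel: FounderPanel,
    matings: Sequence[str],
    n_per_family: int,
    final_generation: int = 5,
    seed: int | None = None,
    family_ids: Sequence[str] | None = None,
) -> RILPopulation:
    """Advance each common x founder mating to F_{final_generation} RILs by
    single-seed descent: one random F2 per line, selfed forward with a single
    offspring per generation.

    Origin labels per marker record whether the line carries common, founder
    or (residually) heterozygous material; allele doses follow from the
    founder haplotype (the common parent is all-reference).
    """
    if final_generation < 2:
        raise ValueError("final_generation must be >= 2 (F2 is the first selfed generation)")
    if n_per_family < 1:
        raise ValueError("n_per_family must be positive")
    gmap = panel.gmap
    if family_ids is None:
        family_ids = [f"F{i + 1:02d}" for i in range(len(matings))]
    ss = np.random.SeedSequence(seed)
    fam_seeds = ss.spawn(len(matings))

    chrom_idx = [gmap.chrom_indices(c) for c in gmap.chromosomes()]
    rfracs = [gmap.recomb_fractions(c) for c in gmap.chromosomes()]

    all_orig = []
    fam_labels = []
    ril_ids = []
    family_founder = {}
    for fam, founder, fs in zip(family_ids, matings, fam_seeds):
        if founder not in panel.ids:
            raise ValueError(f"founder {founder!r} not in panel")
        if founder == panel.common_id:
            raise ValueError("matings must pair the common parent with a distinct founder")
        family_founder[fam] = founder
        rng = np.random.default_rng(fs)
        orig_chunks = []
        for idx, r in zip(chrom_idx, rfracs):
            # F1 haplotypes are pure common (0) / pure founder (1); an F2
            # genome is two independent F1 gametes, then each selfing draws
            # two gametes from the current individual.
            h1 = _meiosis_paths(rng, n_per_family, r)
            h2 = _meiosis_paths(rng, n_per_family, r)
            for _ in range(final_generation - 2):
                p1 = _meiosis_paths(rng, n_per_family, r)
                p2 = _meiosis_paths(rng, n_per_family, r)
                g1 = np.where(p1 == 0, h1, h2)
                g2 = np.where(p2 == 0, h1, h2)
                h1, h2 = g1, g2
            orig_chunks.append((h1 + h2).astype(np.int8))  # founder-allele count
        all_orig.append(np.concatenate(orig_chunks, axis=1))
        fam_labels.extend([fam] * n_per_family)
        ril_ids.extend([f"{fam}_R{i + 1:03d}" for i in range(n_per_family)])

    founder_count = np.vstack(all_orig)  # copies of founder-origin material
    fam_founder_hap = np.vstack(
        [panel.haplotype(family_founder[f]) for f in fam_labels]
    )
    geno = (founder_count * fam_founder_hap).astype(np.int8)
    origin = founder_count  # 0 common / 1 het / 2 founder by construction
    family = pd.Series(fam_labels, index=ril_ids, name="family")
    return RILPopulation(ril_ids, family, family_founder, geno, origin, gmap, panel)


def assign_trait_architecture(
    gmap: GeneticMap,
    panel: FounderPanel,
    n_qtl: Mapping[str, int] | int,
    group_effects: Mapping[str, Mapping[str, float]],
    polygenic_var: Mapping[str, float] | float = 0.0,
    pleiotropy: Sequence[Mapping] | None = None,
    traits: Sequence[str] = TRAITS,
    seed: int | None = None,
) -> TraitArchitecture:
    """Sample QTL positions and group-structured founder effects per trait.

    ``group_effects`` maps founder group -> {"mean": mu, "sd": s} in trait
    units (homozygous substitution relative to the common parent).  A
    pleiotropy entry ``{"traits": [a, b], "n_shared": k, "correlation": rho}``
    makes k QTL positions common to the listed traits with effects drawn at
    the given correlation (1.0 -> identical effects).
    """
    if not group_effects:
        raise ValueError("group_effects config is empty")
    traits = list(traits)
    if isinstance(n_qtl, int):
        n_qtl = {t: n_qtl for t in traits}
    for t in traits:
        if n_qtl[t] > gmap.n_markers:
            raise ValueError("more QTL requested than markers on map")
    rng = np.random.default_rng(seed)
    founders = panel.founder_ids
    fgroups = np.array([panel.groups[f] for f in founders])

    def draw_effects(k: int) -> np.ndarray:
        out = np.zeros((len(founders), k))
        for g, cfg in group_effects.items():
            rowmask = fgroups == g
            out[rowmask] = rng.normal(cfg.get("mean", 0.0), cfg.get("sd", 0.0),
                                      (int(rowmask.sum()), k))
        return out

    qtl: dict[str, list[str]] = {t: [] for t in traits}
    eff: dict[str, list[np.ndarray]] = {t: [] for t in traits}

    markers = list(gmap.markers)
    for entry in pleiotropy or []:
        shared_traits = list(entry["traits"])
        k = int(entry.get("n_shared", 1))
        rho = float(entry.get("correlation", 1.0))
        pos = list(rng.choice(markers, size=k, replace=False))
        base = draw_effects(k)
        for j, t in enumerate(shared_traits):
            if rho >= 1.0 or j == 0:
                e = base
            else:
                # mix with an independent draw from the same group model
                e = rho * base + np.sqrt(max(0.0, 1 - rho**2)) * draw_effects(k)
            qtl[t].extend(pos)
            eff[t].append(np.array(e))

    for t in traits:
        k = n_qtl[t] - len(qtl[t])
        if k < 0:
            raise ValueError(f"pleiotropy spec exceeds n_qtl for trait {t}")
        if k > 0:
            avail = [m for m in markers if m not in set(qtl[t])]
            qtl[t].extend(rng.choice(avail, size=k, replace=False))
            eff[t].append(draw_effects(k))

    if isinstance(polygenic_var, Mapping):
        pg = {t: float(polygenic_var.get(t, 0.0)) for t in traits}
    else:
        pg = {t: float(polygenic_var) for t in traits}
    if any(v < 0 for v in pg.values()):
        raise ValueError("polygenic variance must be non-negative")

    effects = {
        t: pd.DataFrame(
            np.concatenate(eff[t], axis=1) if eff[t] else np.zeros((len(founders), 0)),
            index=founders, columns=qtl[t],
        )
        for t in traits
    }
    return TraitArchitecture(qtl={t: list(q) for t, q in qtl.items()},
                             effects=effects, polygenic_var=pg)


def genetic_values(
    pop: RILPopulation,
    arch: TraitArchitecture,
    seed: int | None = None,
    polygenic_mode: str = "iid",
    kinship: np.ndarray | None = None,
) -> pd.DataFrame:
    """True genotypic value per RIL and trait.

    value = sum_q effect(founder of the RIL's family, q) * dose_q / 2 plus a
    polygenic deviate.  ``polygenic_mode`` "iid" draws independent normals;
    "genomic" draws from N(0, sigma2 * K) using ``kinship`` (computed from the
    population's own markers when not supplied), giving a background that is
    correlated with realized relatedness.
    """
    midx = pop.gmap.marker_index()
    fam_founders = pop.family.map(pop.family_founder)
    rng = np.random.default_rng(seed)
    out = {}
    chol = None
    for t in arch.traits():
        qtl = arch.qtl[t]
        if any(q not in midx.index for q in qtl):
            raise ValueError(f"architecture QTL absent from population map for {t}")
        vals = np.zeros(pop.n_rils)
        if qtl:
            cols = midx[qtl].to_numpy()
            dose = pop.geno[:, cols].astype(float)
            dose[dose == MISSING] = 0.0
            emat = arch.effects[t]  # founders x qtl
            per_ril_eff = emat.loc[fam_founders.to_numpy(), :].to_numpy()
            vals = np.sum(per_ril_eff * dose / 2.0, axis=1)
        pv = arch.polygenic_var[t]
        if pv > 0:
            z = rng.standard_normal(pop.n_rils)
            if polygenic_mode == "iid":
                vals = vals + np.sqrt(pv) * z
            elif polygenic_mode == "genomic":
                if chol is None:
                    if kinship is None:
                        from .kinship import vanraden_kinship
                        kinship = vanraden_kinship(pop.geno).values
                    chol = np.linalg.cholesky(
                        kinship + 1e-6 * np.eye(len(kinship)))
                vals = vals + np.sqrt(pv) * (chol @ z)
            else:
                raise ValueError(f"unknown polygenic_mode {polygenic_mode!r}")
        out[t] = vals
    return pd.DataFrame(out, index=pop.ril_ids)


def founder_parent_values(panel: FounderPanel, arch: TraitArchitecture) -> pd.DataFrame:
    """Genotypic values of the homozygous parents themselves (no polygene)."""
    midx = panel.gmap.marker_index()
    out = {}
    for t in arch.traits():
        qtl = arch.qtl[t]
        cols = midx[qtl].to_numpy() if qtl else np.array([], dtype=int)
        vals = []
        for line in panel.ids:
            hap = panel.haplotypes[panel.ids.index(line), cols] if qtl else np.array([])
            if line == panel.common_id:
                vals.append(0.0)
            else:
                e = arch.effects[t].loc[line].to_numpy() if qtl else np.array([])
                vals.append(float(np.sum(e * hap)))
        out[t] = vals
    return pd.DataFrame(out, index=panel.ids)


def design_trial(
    pop: RILPopulation,
    checks: Sequence[str],
    n_environments: int,
    sets_evaluated: str | Sequence[int] = "all",
    planting_date_model: Mapping | None = None,
    seed: int | None = None,
    set_size: int = 35,
) -> TrialDesign:
    """Lay the population out in augmented 40-entry sets across environments.

    Each family's RILs are split into sets of ``set_size`` (35), padded with
    checks when a family does not divide evenly; every set is augmented with
    the family's two parents and three checks.  ``sets_evaluated`` is "all"
    (every set in every environment) or a per-environment count of randomly
    chosen sets, emulating unbalanced coverage.  Planting dates are drawn per
    environment from ``{"base_julian": 135, "spread_days": 28}``.
    """
    if len(checks) < 3:
        raise ValueError("at least 3 check varieties are required")
    pdm = dict(planting_date_model or {})
    base = int(pdm.get("base_julian", 135))
    spread = int(pdm.get("spread_days", 28))
    rng = np.random.default_rng(seed)
    common = pop.panel.common_id if pop.panel is not None else "common"

    set_members: dict[str, list[str]] = {}
    set_roles: dict[str, list[str]] = {}
    for fam in pop.families():
        rils = [pop.ril_ids[i] for i in pop.family_rows(fam)]
        founder = pop.family_founder[fam]
        n_sets_fam = int(np.ceil(len(rils) / set_size))
        for s in range(n_sets_fam):
            chunk = rils[s * set_size:(s + 1) * set_size]
            pad = [checks[i % len(checks)] for i in range(set_size - len(chunk))]
            members = chunk + pad + [common, founder] + list(checks[:3])
            roles = (["ril"] * len(chunk) + ["check"] * len(pad)
                     + ["parent", "parent"] + ["check"] * 3)
            sid = f"{fam}_S{s + 1}"
            set_members[sid] = members
            set_roles[sid] = roles

    set_ids = list(set_members)
    env_dates = base + rng.integers(0, spread + 1, n_environments)
    rows = []
    for e in range(n_environments):
        env = f"E{e + 1:02d}"
        if isinstance(sets_evaluated, str) and sets_evaluated == "all":
            chosen = set_ids
        else:
            k = min(int(np.asarray(sets_evaluated)[e]), len(set_ids))
            chosen = list(rng.choice(set_ids, size=k, replace=False))
        for sid in chosen:
            block = f"{env}:{sid}"
            order = rng.permutation(len(set_members[sid]))
            for j in order:
                rows.append((env, sid, block, set_members[sid][j],
                             set_roles[sid][j], int(env_dates[e])))
    plots = pd.DataFrame(rows, columns=["environment", "set", "block", "entry",
                                        "role", "planting_date"])
    return TrialDesign(plots, set_members)


def simulate_plots(
    design: TrialDesign,
    gvalues: pd.DataFrame,
    variance_components: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    grand_means: Mapping[str, float] | None = None,
    planting_slope: Mapping[str, float] | float = 0.0,
    check_values: Mapping[str, Mapping[str, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> PlotTable:
    """Realize plot phenotypes from the trial design and true genotypic values.

    plot value = grand mean + environment effect + block effect + entry
    genotypic value + slope * (planting date - mean date) + residual, with
    independent normal environment/block/residual effects.  Checks take fixed
    true values (``check_values``, default 0); lodging is clipped to [1, 5].
    Plots go missing completely at random at ``missing_rate`` per trait.
    """
    traits = list(gvalues.columns)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    def vc(trait: str, name: str) -> float:
        cfg = variance_components
        v = cfg[trait][name] if trait in cfg and isinstance(cfg[trait], Mapping) else cfg[name]
        v = float(v)
        if v < 0:
            raise ValueError(f"negative variance component {name} for {trait}")
        return v

    rng = np.random.default_rng(seed)
    plots = design.plots.copy()
    envs = design.environments()
    blocks = list(dict.fromkeys(plots["block"]))
    date_center = plots["planting_date"].mean()
    n = len(plots)
    out = plots.reset_index(drop=True)
    out.insert(0, "plot", [f"P{i + 1:06d}" for i in range(n)])

    env_codes = out["environment"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    blk_codes = out["block"].map({b: i for i, b in enumerate(blocks)}).to_numpy()
    slope_map = (planting_slope if isinstance(planting_slope, Mapping)
                 else {t: float(planting_slope) for t in traits})
    cvals = check_values or {}

    for t in traits:
        env_eff = rng.normal(0, np.sqrt(vc(t, "env")), len(envs))
        blk_eff = rng.normal(0, np.sqrt(vc(t, "block")), len(blocks))
        resid = rng.normal(0, np.sqrt(vc(t, "residual")), n)
        gm = float((grand_means or {}).get(t, 0.0))
        entry_g = np.array([
            gvalues.at[e, t] if e in gvalues.index
            else float(cvals.get(e, {}).get(t, 0.0))
            for e in out["entry"]
        ])
        y = (gm + env_eff[env_codes] + blk_eff[blk_codes] + entry_g
             + slope_map.get(t, 0.0) * (out["planting_date"] - date_center).to_numpy()
             + resid)
        if t == "lodging":
            y = np.clip(y, 1.0, 5.0)
        if missing_rate > 0:
            y = np.where(rng.random(n) < missing_rate, np.nan, y)
        out[t] = y
    return PlotTable(out, traits)
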