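import numpy as np
import pandas as pd
import pytest

from soynam import simulate
from soynam.simulate import (GeneticMap, ORIGIN_FOUNDER, ORIGIN_HET,
                             TraitArchitecture, haldane_r)


class TestSimulateMap:
    def test_uniform_grid(self):
        m = simulate.simulate_map(1, 100.0, 11)
        assert m.frame["cM"].tolist() == [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]

    def test_minimal_two_marker_map(self):
        m = simulate.simulate_map(1, 50.0, 2)
        assert m.frame["cM"].tolist() == [0.0, 50.0]

    def test_piecewise_bp_strictly_increasing(self):
        m = simulate.simulate_map(2, 100.0, 100,
                                  bp_model={"kind": "piecewise", "n_knots": 5},
                                  seed=1, spacing="random")
        for chrom in m.chromosomes():
            bp = m.frame.loc[m.chrom_indices(chrom), "bp"].to_numpy()
            # exhaustive adjacent-pair scan
            assert all(bp[i] < bp[i + 1] for i in range(len(bp) - 1))

    @pytest.mark.parametrize("kwargs", [
        dict(n_chromosomes=0, cm_length=100, n_markers=10),
        dict(n_chromosomes=1, cm_length=-5, n_markers=10),
        dict(n_chromosomes=1, cm_length=100, n_markers=1),
    ])
    def test_rejects_bad_dimensions(self, kwargs):
        with pytest.raises(ValueError):
            simulate.simulate_map(**kwargs)

    def test_map_invariant_validation(self):
        bad = pd.DataFrame({"marker": ["a", "b"], "chrom": ["c1", "c1"],
                            "bp": [200, 100], "cM": [0.0, 1.0]})
        with pytest.raises(ValueError, match="strictly increasing"):
            GeneticMap(bad)


class TestSimulateFounders:
    def test_reference_panel_counts(self, small_map):
        panel = simulate.simulate_founders(small_map, seed=1)
        assert len(panel.ids) == 41  # one hub parent + 40 founders
        groups = pd.Series(panel.groups)
        assert (groups == "EL").sum() == 17
        assert (groups == "BX").sum() == 15
        assert (groups == "PI").sum() == 8

    def test_zero_frequency_degenerates_to_common(self, small_map):
        panel = simulate.simulate_founders(small_map, allele_freq=0.0, seed=2)
        assert not panel.haplotypes.any()

    def test_allele_sharing_matches_binomial(self):
        m = simulate.simulate_map(1, 100.0, 10_000)
        panel = simulate.simulate_founders(m, {"EL": 1, "BX": 1, "PI": 1},
                                           allele_freq=0.5, seed=3)
        for fid in panel.founder_ids:
            share = np.mean(panel.haplotype(fid) == panel.haplotype("common"))
            se = np.sqrt(0.25 / 10_000)
            assert abs(share - 0.5) < 3 * se


class TestDeriveRils:
    def test_heterozygosity_decay(self, small_panel):
        for gen, expect in [(2, 0.5), (3, 0.25), (5, 0.0625)]:
            pop = simulate.derive_rils(small_panel, small_panel.founder_ids[:3],
                                       150, final_generation=gen, seed=gen)
            n_loci = pop.n_rils * pop.gmap.n_markers
            se = np.sqrt(expect * (1 - expect) / n_loci)
            # loci are linked, hence positively correlated: allow a wide band
            assert abs(pop.heterozygosity() - expect) < 12 * se

    @pytest.mark.parametrize("d_cm", [1.0, 10.0, 50.0])
    def test_recombination_matches_haldane(self, d_cm):
        m = simulate.simulate_map(1, d_cm, 2)
        g = simulate.simulate_gametes(m, 20_000, seed=int(d_cm))
        r_hat = np.mean(g[:, 0] != g[:, 1])
        r = haldane_r(d_cm)
        se = np.sqrt(r * (1 - r) / 20_000)
        assert abs(r_hat - r) < 3.5 * se

    def test_genotype_consistent_with_origin(self, small_pop, small_panel):
        fam = small_pop.families()[0]
        rows = small_pop.family_rows(fam)
        fh = small_panel.haplotype(small_pop.family_founder[fam])
        expected = small_pop.origin[rows] * fh[None, :]
        np.testing.assert_array_equal(small_pop.geno[rows], expected)

    def test_reproducible_bit_identical(self, small_panel):
        a = simulate.derive_rils(small_panel, small_panel.founder_ids[:2], 30, seed=9)
        b = simulate.derive_rils(small_panel, small_panel.founder_ids[:2], 30, seed=9)
        np.testing.assert_array_equal(a.geno, b.geno)
        np.testing.assert_array_equal(a.origin, b.origin)

    def test_rejects_unknown_or_common_founder(self, small_panel):
        with pytest.raises(ValueError):
            simulate.derive_rils(small_panel, ["nope"], 5)
        with pytest.raises(ValueError):
            simulate.derive_rils(small_panel, [small_panel.common_id], 5)


class TestTraitArchitecture:
    def test_null_architecture_all_zero(self, small_map, small_panel):
        arch = simulate.assign_trait_architecture(
            small_map, small_panel, n_qtl=3,
            group_effects={g: {"mean": 0.0, "sd": 0.0} for g in ("EL", "BX", "PI")},
            traits=["t"], seed=1)
        assert (arch.effects["t"].to_numpy() == 0).all()

    def test_group_means_recovered(self):
        m = simulate.simulate_map(1, 100.0, 1200)
        panel = simulate.simulate_founders(m, {"EL": 5, "BX": 5, "PI": 5}, seed=4)
        arch = simulate.assign_trait_architecture(
            m, panel, n_qtl=1000,
            group_effects={"EL": {"mean": 5.0, "sd": 10.0},
                           "BX": {"mean": 0.0, "sd": 10.0},
                           "PI": {"mean": -50.0, "sd": 10.0}},
            traits=["t"], seed=5)
        eff = arch.effects["t"]
        for grp, mu in [("EL", 5.0), ("PI", -50.0)]:
            rows = [f for f in eff.index if panel.groups[f] == grp]
            draws = eff.loc[rows].to_numpy().ravel()
            se = 10.0 / np.sqrt(draws.size)
            assert abs(draws.mean() - mu) < 3 * se

    def test_pleiotropy_shares_positions_and_effects(self, small_map, small_panel):
        arch = simulate.assign_trait_architecture(
            small_map, small_panel, n_qtl=2,
            group_effects={g: {"mean": 1.0, "sd": 2.0} for g in ("EL", "BX", "PI")},
            pleiotropy=[{"traits": ["a", "b"], "n_shared": 1, "correlation": 1.0}],
            traits=["a", "b"], seed=6)
        shared = set(arch.qtl["a"]) & set(arch.qtl["b"])
        assert len(shared) == 1
        q = shared.pop()
        pd.testing.assert_series_equal(arch.effects["a"][q], arch.effects["b"][q],
                                       check_names=False)


class TestGeneticValues:
    def _arch(self, marker, founders, effect, pg=0.0):
        return TraitArchitecture(
            qtl={"t": [marker]},
            effects={"t": pd.DataFrame({marker: [effect] * len(founders)},
                                       index=founders)},
            polygenic_var={"t": pg})

    def test_null_architecture_gives_zero(self, small_pop):
        arch = TraitArchitecture(qtl={"t": []},
                                 effects={"t": pd.DataFrame(index=[])},
                                 polygenic_var={"t": 0.0})
        vals = simulate.genetic_values(small_pop, arch)
        assert (vals["t"] == 0).all()

    def test_homozygous_single_qtl_dose(self, small_pop, small_panel):
        # pick a segregating marker and a RIL homozygous for the founder allele
        fam = small_pop.families()[0]
        fh = small_panel.haplotype(small_pop.family_founder[fam])
        j = int(np.flatnonzero(fh == 1)[0])
        marker = str(small_pop.gmap.markers[j])
        rows = small_pop.family_rows(fam)
        hom = rows[small_pop.geno[rows, j] == 2]
        arch = self._arch(marker, small_panel.founder_ids, 10.0)
        vals = simulate.genetic_values(small_pop, arch)
        assert np.allclose(vals["t"].iloc[hom], 10.0)

    def test_matches_bruteforce_summation(self, small_pop, small_panel):
        rng = np.random.default_rng(7)
        markers = list(rng.choice(small_pop.gmap.markers, 4, replace=False))
        eff = pd.DataFrame(rng.normal(0, 5, (len(small_panel.founder_ids), 4)),
                           index=small_panel.founder_ids, columns=markers)
        arch = TraitArchitecture(qtl={"t": markers}, effects={"t": eff},
                                 polygenic_var={"t": 0.0})
        vals = simulate.genetic_values(small_pop, arch)["t"]
        midx = small_pop.gmap.marker_index()
        for i in rng.choice(small_pop.n_rils, 50, replace=False):
            rid = small_pop.ril_ids[i]
            founder = small_pop.family_founder[small_pop.family[rid]]
            total = 0.0
            for mk in markers:
                total += eff.at[founder, mk] * small_pop.geno[i, midx[mk]] / 2.0
            assert vals[rid] == pytest.approx(total, abs=1e-12)


class TestDesignTrial:
    def test_every_set_has_40_entries(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 2, seed=1)
        assert all(len(m) == 40 for m in d.set_members.values())

    def test_every_ril_in_exactly_one_set(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 1, seed=2)
        counts = {}
        for members in d.set_members.values():
            for e in members:
                counts[e] = counts.get(e, 0) + 1
        assert all(counts[r] == 1 for r in small_pop.ril_ids)

    def test_block_entries_come_from_one_set(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 2, seed=3)
        per_block = d.plots.groupby("block")["set"].nunique()
        assert (per_block == 1).all()
        per_block_env = d.plots.groupby("block")["environment"].nunique()
        assert (per_block_env == 1).all()

    def test_sets_evaluated_counts_echoed(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 3,
                                  sets_evaluated=[6, 2, 4], seed=4)
        counts = d.plots.groupby("environment")["set"].nunique()
        assert counts.tolist() == [6, 2, 4]

    def test_requires_three_checks(self, small_pop):
        with pytest.raises(ValueError, match="3 check"):
            simulate.design_trial(small_pop, ["C1", "C2"], 1)


class TestSimulatePlots:
    @pytest.fixture()
    def design_and_values(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 2, seed=5)
        g = pd.DataFrame({"t": np.arange(small_pop.n_rils, dtype=float)},
                         index=small_pop.ril_ids)
        # parents appear as entries too; give them fixed values via the table
        for fam, founder in small_pop.family_founder.items():
            g.loc[founder] = -1.0
        g.loc["common"] = 0.0
        return d, g

    def test_noiseless_reproduces_genotypic_values(self, design_and_values):
        d, g = design_and_values
        pt = simulate.simulate_plots(
            d, g, {"env": 0.0, "block": 0.0, "residual": 0.0},
            grand_means={"t": 100.0}, seed=6)
        rils = pt.table[pt.table["role"] == "ril"]
        expected = 100.0 + g.loc[rils["entry"], "t"].to_numpy()
        np.testing.assert_allclose(rils["t"].to_numpy(), expected)

    def test_planting_date_covariate_exact(self, small_pop):
        d = simulate.design_trial(small_pop, ["C1", "C2", "C3"], 2,
                                  planting_date_model={"base_julian": 130,
                                                       "spread_days": 20},
                                  seed=7)
        g = pd.DataFrame({"t": np.zeros(small_pop.n_rils)},
                         index=small_pop.ril_ids)
        pt = simulate.simulate_plots(
            d, g, {"env": 0.0, "block": 0.0, "residual": 0.0},
            planting_slope=1.0, seed=8)
        sub = pt.table[pt.table["role"] == "ril"]
        by_env = sub.groupby("environment").agg(
            date=("planting_date", "first"), val=("t", "mean"))
        if len(by_env) == 2:
            ddate = by_env["date"].iloc[1] - by_env["date"].iloc[0]
            dval = by_env["val"].iloc[1] - by_env["val"].iloc[0]
            assert dval == pytest.approx(float(ddate), abs=1e-9)

    def test_variance_components_recovered_by_moments(self):
        """Nested ANOVA moment estimators (plots within blocks within
        environments, balanced) recover the generating environment, block
        and residual variances within 10%, averaging two replicates to tame
        the environment-level sampling noise."""
        truth = {"env": 4.0, "block": 2.0, "residual": 1.0}
        m = simulate.simulate_map(1, 50.0, 5)
        panel = simulate.simulate_founders(m, {"EL": 1, "BX": 1, "PI": 1},
                                           seed=9)
        pop = simulate.derive_rils(panel, panel.founder_ids[:1], 70, seed=9)
        d = simulate.design_trial(pop, ["C1", "C2", "C3"], 400, seed=10)
        g = pd.DataFrame({"t": np.zeros(pop.n_rils)}, index=pop.ril_ids)
        ests = []
        for seed in (11, 12):
            df = simulate.simulate_plots(d, g, truth, seed=seed).table
            s2_res = df.groupby("block")["t"].var(ddof=1).mean()
            n_plot = df.groupby("block").size().iloc[0]
            blk_means = df.groupby(["environment", "block"])["t"].mean()
            s2_blk = (blk_means.groupby("environment").var(ddof=1).mean()
                      - s2_res / n_plot)
            env_means = df.groupby("environment")["t"].mean()
            n_blk = blk_means.groupby("environment").size().iloc[0]
            s2_env = (env_means.var(ddof=1) - s2_blk / n_blk
                      - s2_res / (n_blk * n_plot))
            ests.append((s2_env, s2_blk, s2_res))
        mean_est = np.mean(ests, axis=0)
        for est, (name, val) in zip(mean_est, truth.items()):
            assert est == pytest.approx(val, rel=0.10), name

    def test_rejects_negative_variance(self, design_and_values):
        d, g = design_and_values
        with pytest.raises(ValueError, match="negative variance"):
            simulate.simulate_plots(d, g, {"env": -1.0, "block": 0.0,
                                           "residual": 1.0})

    def test_missing_rate_drops_plots(self, design_and_values):
        d, g = design_and_values
        pt = simulate.simulate_plots(d, g, {"env": 0, "block": 0, "residual": 1},
                                     missing_rate=0.3, seed=12)
        frac = pt.table["t"].isna().mean()
        assert 0.2 < frac < 0.4

    def test_plot_table_reproducible(self, design_and_values):
        d, g = design_and_values
        kw = dict(variance_components={"env": 1, "block": 1, "residual": 1},
                  missing_rate=0.05, seed=13)
        a = simulate.simulate_plots(d, g, **kw)
        b = simulate.simulate_plots(d, g, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
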