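import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soynam import genoprep, simulate
from soynam.genoprep import (FLAG_IDENTICAL, FLAG_NON_PARENTAL, FLAG_PASS,
                             STATUS_LOW_MAF, STATUS_MONOMORPHIC,
                             STATUS_NO_DATA, STATUS_SEGREGATING)
from soynam.simulate import MISSING


def _toy_pop(doses_by_family: dict, panel):
    """Build a RILPopulation from explicit per-family dose matrices."""
    gmap = panel.gmap
    ril_ids, fams, genos = [], [], []
    family_founder = {}
    for k, (fam, doses) in enumerate(doses_by_family.items()):
        founder = panel.founder_ids[k]
        family_founder[fam] = founder
        doses = np.asarray(doses, dtype=np.int8)
        for i in range(len(doses)):
            ril_ids.append(f"{fam}_R{i}")
            fams.append(fam)
        genos.append(doses)
    geno = np.vstack(genos)
    origin = np.zeros_like(geno)
    return simulate.RILPopulation(
        ril_ids, pd.Series(fams, index=ril_ids), family_founder,
        geno, origin, gmap, panel)


@pytest.fixture(scope="module")
def tiny_panel():
    gmap = simulate.simulate_map(1, 10.0, 3)
    panel = simulate.simulate_founders(gmap, {"EL": 2, "BX": 1, "PI": 1},
                                       allele_freq=1.0, seed=1)
    return panel


class TestFilterMarkers:
    def test_monomorphic_marker_eliminated(self, tiny_panel):
        pop = _toy_pop({"F1": [[0, 0, 2], [0, 2, 0], [0, 2, 2]]}, tiny_panel)
        rep = genoprep.filter_markers(pop)
        row = rep.table[rep.table["marker"] == pop.gmap.markers[0]].iloc[0]
        assert row["status"] == STATUS_MONOMORPHIC
        assert pop.gmap.markers[0] in rep.eliminated

    def test_low_maf_from_explicit_counts(self, tiny_panel):
        # 91 RILs, 18 minor alleles of 182: MAF = 0.0989... < 0.10
        doses = np.zeros((91, 3), dtype=int)
        doses[:9, 0] = 2
        doses[:45, 1] = 2   # MAF 90/182... keep marker 2 segregating
        doses[:45, 2] = 1
        pop = _toy_pop({"F1": doses}, tiny_panel)
        rep = genoprep.filter_markers(pop, maf_threshold=0.10)
        row = rep.table[rep.table["marker"] == pop.gmap.markers[0]].iloc[0]
        assert row["MAF"] == pytest.approx(18 / 182)
        assert row["status"] == STATUS_LOW_MAF

    def test_maf_exactly_at_threshold_is_kept(self, tiny_panel):
        # 100 alleles, 10 minor -> MAF exactly 0.10: strictly-less-than rule
        doses = np.zeros((50, 3), dtype=int)
        doses[:5, :] = 2
        doses[5:25, 1] = 2
        doses[5:25, 2] = 2
        pop = _toy_pop({"F1": doses}, tiny_panel)
        rep = genoprep.filter_markers(pop, maf_threshold=0.10)
        row = rep.table[rep.table["marker"] == pop.gmap.markers[0]].iloc[0]
        assert row["MAF"] == pytest.approx(0.10)
        assert row["status"] == STATUS_SEGREGATING

    def test_family_with_no_data_reported_distinctly(self, tiny_panel):
        doses = np.full((4, 3), MISSING, dtype=int)
        doses[:, 1:] = 1
        pop = _toy_pop({"F1": doses}, tiny_panel)
        rep = genoprep.filter_markers(pop)
        row = rep.table[rep.table["marker"] == pop.gmap.markers[0]].iloc[0]
        assert row["status"] == STATUS_NO_DATA
        assert np.isnan(row["MAF"])

    def test_elimination_on_any_family_failure(self, tiny_panel):
        pop = _toy_pop({"F1": [[2, 0, 2], [0, 2, 0], [2, 2, 2], [0, 0, 0]],
                        "F2": [[1, 1, 0], [1, 1, 0], [1, 1, 0], [1, 1, 2]]},
                       tiny_panel)
        rep = genoprep.filter_markers(pop)
        # marker 0 segregates in F1 (MAF .5) but is distorted in F2? no:
        # F2 marker0 all dose 1 -> MAF 0.5; marker2 in F2: 3x0,1x2 -> MAF .25
        by = rep.table.set_index(["family", "marker"])["status"]
        m = pop.gmap.markers
        assert by[("F1", m[0])] == STATUS_SEGREGATING
        assert by[("F2", m[0])] == STATUS_SEGREGATING
        assert m[0] not in rep.eliminated

    def test_filtering_is_idempotent(self, small_pop):
        rep1 = genoprep.filter_markers(small_pop)
        filtered = genoprep.apply_marker_filter(small_pop, rep1)
        rep2 = genoprep.filter_markers(filtered)
        assert rep2.eliminated == []
        assert set(rep2.keep_markers()) == set(rep1.keep_markers())


class TestQcRils:
    def test_clone_of_common_parent_flagged(self, tiny_panel):
        pop = _toy_pop({"F1": [[0, 0, 0], [0, 2, 2]]}, tiny_panel)
        rep = genoprep.qc_rils(pop, tiny_panel)
        assert rep.flags["F1_R0"] == FLAG_IDENTICAL

    def test_non_parental_allele_flagged(self):
        gmap = simulate.simulate_map(1, 10.0, 3)
        panel = simulate.simulate_founders(gmap, {"EL": 1, "BX": 1, "PI": 1},
                                           allele_freq=0.0, seed=2)
        # founder identical to common everywhere: any alt dose is non-parental
        pop = _toy_pop({"F1": [[0, 2, 0], [0, 0, 0]]}, panel)
        rep = genoprep.qc_rils(pop, panel)
        assert rep.flags["F1_R0"] == FLAG_NON_PARENTAL
        # precedence: also identical at observed... R1 matches common exactly
        assert rep.flags["F1_R1"] == FLAG_IDENTICAL

    def test_simulated_clean_rils_pass(self):
        # dense multi-chromosome genome: fixation of a whole RIL genome to
        # one parent is then vanishingly rare, so clean lines all pass
        gmap = simulate.simulate_map(4, 100.0, 30)
        panel = simulate.simulate_founders(gmap, {"EL": 1, "BX": 1, "PI": 1},
                                           allele_freq=0.6, seed=7)
        pop = simulate.derive_rils(panel, panel.founder_ids, 40, seed=8)
        rep = genoprep.qc_rils(pop, panel)
        assert (rep.flags == FLAG_NON_PARENTAL).sum() == 0
        assert (rep.flags == FLAG_PASS).all()
        assert rep.families_to_remove == []

    def test_majority_bad_family_listed_for_removal(self):
        gmap = simulate.simulate_map(1, 10.0, 3)
        panel = simulate.simulate_founders(gmap, {"EL": 1, "BX": 1, "PI": 1},
                                           allele_freq=0.0, seed=3)
        pop = _toy_pop({"F1": [[2, 0, 0], [0, 2, 0], [2, 2, 0], [0, 0, 0]]},
                       panel)
        rep = genoprep.qc_rils(pop, panel)
        assert rep.family_fail_fraction["F1"] == pytest.approx(0.75)
        assert rep.families_to_remove == ["F1"]


class TestInterpolateCM:
    def test_midpoint(self):
        assert genoprep.interpolate_cM(150, [100, 200], [1.0, 2.0]) == 1.5

    def test_knot_identity(self):
        assert genoprep.interpolate_cM(100, [100, 200], [1.0, 2.0]) == 1.0

    def test_terminal_clamping(self):
        assert genoprep.interpolate_cM(50, [100, 200], [1.0, 2.0]) == 1.0
        assert genoprep.interpolate_cM(999, [100, 200], [1.0, 2.0]) == 2.0

    def test_matches_bruteforce_segment_search(self):
        rng = np.random.default_rng(4)
        bp = np.sort(rng.choice(np.arange(1, 10_000), 5, replace=False))
        cm = np.sort(rng.uniform(0, 50, 5))
        queries = rng.integers(1, 10_000, 100)
        got = genoprep.interpolate_cM(queries, bp, cm)
        for q, v in zip(queries, got):
            # independent piecewise-linear evaluation by segment scan
            if q <= bp[0]:
                expect = cm[0]
            elif q >= bp[-1]:
                expect = cm[-1]
            else:
                for k in range(len(bp) - 1):
                    if bp[k] <= q <= bp[k + 1]:
                        w = (q - bp[k]) / (bp[k + 1] - bp[k])
                        expect = cm[k] + w * (cm[k + 1] - cm[k])
                        break
            assert v == pytest.approx(expect, abs=1e-12)

    @given(
        knots=st.lists(st.tuples(st.integers(1, 10**6),
                                 st.floats(0, 200, allow_nan=False)),
                       min_size=2, max_size=8,
                       unique_by=lambda t: t[0]),
        queries=st.lists(st.integers(1, 10**6), min_size=2, max_size=40),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_bp(self, knots, queries):
        bp = sorted(k[0] for k in knots)
        cm = sorted(k[1] for k in knots)
        q = np.sort(np.asarray(queries))
        vals = genoprep.interpolate_cM(q, bp, cm)
        assert (np.diff(vals) >= -1e-12).all()

    def test_rejects_degenerate_frame(self):
        with pytest.raises(ValueError):
            genoprep.interpolate_cM(5, [100], [1.0])


class TestProjection:
    def _setup(self, seed=6, n_framework=21, n_dense=200, n_rils=60,
               cm_len=100.0):
        """Simulate at a combined dense+framework map, then hide the dense
        markers from the RILs so projection can be checked against truth."""
        full = simulate.simulate_map(1, cm_len, n_framework + n_dense,
                                     spacing="random", seed=seed)
        idx = np.sort(np.random.default_rng(seed).choice(
            full.n_markers, n_framework, replace=False))
        idx[0], idx[-1] = 0, full.n_markers - 1
        dense_idx = np.setdiff1d(np.arange(full.n_markers), idx)
        panel = simulate.simulate_founders(full, {"EL": 2, "BX": 1, "PI": 1},
                                           allele_freq=0.6, seed=seed + 1)
        pop_full = simulate.derive_rils(panel, panel.founder_ids[:3], n_rils,
                                        seed=seed + 2)
        fw_map = simulate.GeneticMap(full.frame.iloc[idx].reset_index(drop=True))
        dense_map = simulate.GeneticMap(full.frame.iloc[dense_idx].reset_index(drop=True))
        fw_panel = simulate.FounderPanel(panel.ids, panel.groups,
                                         panel.haplotypes[:, idx], fw_map,
                                         common_id=panel.common_id)
        pop = simulate.RILPopulation(
            pop_full.ril_ids, pop_full.family, pop_full.family_founder,
            pop_full.geno[:, idx], pop_full.origin[:, idx], fw_map, fw_panel)
        truth = pop_full.geno[:, dense_idx]
        dense_haplos = panel.haplotypes[:, dense_idx]
        return pop, dense_map, dense_haplos, truth, panel

    def test_concordant_interval_inherits_parent_genotype(self, tiny_panel):
        pop = _toy_pop({"F1": [[2, 0, 2]]}, tiny_panel)
        pop.origin[0] = [2, 0, 2]  # founder / common / founder
        dense_map = simulate.GeneticMap(pd.DataFrame({
            "marker": ["d1"], "chrom": [pop.gmap.frame["chrom"][0]],
            "bp": [int(pop.gmap.frame["bp"][0]) + 1], "cM": [0.5]}))
        dense_haplos = np.ones((len(tiny_panel.ids), 1), dtype=np.int8)
        dense_haplos[tiny_panel.ids.index("common"), 0] = 0
        out = genoprep.project_dense_markers(pop, dense_map, dense_haplos,
                                             tiny_panel)
        # flanks disagree (founder vs common) -> missing
        assert out.iloc[0, 0] == MISSING

    def test_recombinant_interval_projects_missing(self):
        pop, dense_map, dense_haplos, truth, panel = self._setup()
        out = genoprep.project_dense_markers(pop, dense_map, dense_haplos)
        mat = out.to_numpy()
        # conservation: projected alleles only from the two parents
        midx = {m: j for j, m in enumerate(dense_map.markers)}
        for fam in pop.families():
            rows = pop.family_rows(fam)
            fh = dense_haplos[panel.ids.index(pop.family_founder[fam])]
            ch = dense_haplos[panel.ids.index(panel.common_id)]
            sub = mat[rows]
            for j in range(dense_map.n_markers):
                vals = set(np.unique(sub[:, j])) - {MISSING}
                allowed = {2 * int(ch[j]), 2 * int(fh[j])}
                assert vals <= allowed

    def test_projection_accuracy_above_95pct(self):
        pop, dense_map, dense_haplos, truth, panel = self._setup()
        out = genoprep.project_dense_markers(pop, dense_map, dense_haplos).to_numpy()
        called = out != MISSING
        assert called.mean() > 0.5
        acc = np.mean(out[called] == truth[called])
        assert acc >= 0.95
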