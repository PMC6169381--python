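"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately use brute-force or closed-form routes
that never touch the implementation paths they are checking: explicit loops
for the VanRaden matrix, transitive-closure clustering for region binning,
and textbook balanced-design shrinkage formulas for the mixed models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from soynam import blup, simulate


@pytest.fixture(scope="session")
def small_map():
    return simulate.simulate_map(1, 100.0, 11)


@pytest.fixture(scope="session")
def small_panel(small_map):
    return simulate.simulate_founders(
        small_map, {"EL": 2, "BX": 2, "PI": 1}, allele_freq=0.6, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_panel):
    return simulate.derive_rils(small_panel, small_panel.founder_ids[:3], 40,
                                seed=12)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def vanraden_by_hand(geno: np.ndarray) -> np.ndarray:
    """Explicit-loop VanRaden matrix (no missing data) for tiny instances."""
    n, m = geno.shape
    p = np.array([sum(geno[i, j] for i in range(n)) / (2.0 * n) for j in range(m)])
    c = np.array([[geno[i, j] - 2.0 * p[j] for j in range(m)] for i in range(n)])
    s = sum(2.0 * p[j] * (1.0 - p[j]) for j in range(m))
    K = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            K[i, k] = sum(c[i, j] * c[k, j] for j in range(m)) / s
    return K


def cluster_by_closure(positions: np.ndarray, gap: float) -> list[frozenset]:
    """Brute-force transitive closure of the 'within gap' relation."""
    n = len(positions)
    adj = [[abs(positions[i] - positions[j]) <= gap for j in range(n)]
           for i in range(n)]
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        groups.append(frozenset(comp))
    return groups


def balanced_check_block_data(seed: int, n_blocks: int = 10, n_checks: int = 2,
                              reps: int = 3, s_blk: float = 2.0,
                              s_res: float = 1.0) -> pd.DataFrame:
    """Fully balanced check/block layout: every check replicated ``reps``
    times in every block, one planting date."""
    rng = np.random.default_rng(seed)
    blk_eff = rng.normal(0, s_blk, n_blocks)
    chk_eff = rng.normal(0, 3.0, n_checks)
    rows = []
    for b in range(n_blocks):
        for c in range(n_checks):
            for r in range(reps):
                rows.append({
                    "plot": f"{b}_{c}_{r}", "entry": f"CHK{c}",
                    "environment": "E1", "block": f"B{b:02d}",
                    "planting_date": 140, "role": "check",
                    "y": 10.0 + chk_eff[c] + blk_eff[b] + rng.normal(0, s_res),
                })
    return pd.DataFrame(rows)


def check_block_shrinkage_gap(seed: int) -> float:
    """Max |pi_hat - closed-form shrinkage| over blocks on a balanced toy.

    In the balanced design the BLUP of block b equals
    (s2blk / (s2blk + s2res/n_b)) * (block mean - grand mean) at the fitted
    variance components, with n_b observations per block.
    """
    df = balanced_check_block_data(seed)
    est = blup.fit_check_block_model(df, "y")
    n_b = df.groupby("block").size().iloc[0]
    shrink = est.sigma2_blk / (est.sigma2_blk + est.sigma2_res / n_b)
    grand = df["y"].mean()
    gaps = []
    for b, sub in df.groupby("block"):
        expected = shrink * (sub["y"].mean() - grand)
        gaps.append(abs(est.block_blups[b] - expected))
    return max(gaps)


def balanced_entry_data(seed: int, n_entries: int = 30, reps: int = 4,
                        s_g: float = 3.0, s_res: float = 1.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    g = rng.normal(0, s_g, n_entries)
    rows = []
    for i in range(n_entries):
        for r in range(reps):
            rows.append({"plot": f"{i}_{r}", "entry": f"G{i:03d}",
                         "environment": f"E{r}", "block": f"B{r}",
                         "planting_date": 140, "role": "ril",
                         "y": 5.0 + g[i] + rng.normal(0, s_res)})
    return pd.DataFrame(rows)


def entry_shrinkage_gap(seed: int) -> float:
    """Max |entry BLUP - closed-form balanced shrinkage| on a toy design."""
    df = balanced_entry_data(seed)
    fit = blup.fit_entry_model(df, "y", use_planting_date=False)
    reps = df.groupby("entry").size().iloc[0]
    shrink = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_res / reps)
    grand = df["y"].mean()
    gaps = []
    for e, sub in df.groupby("entry"):
        expected = shrink * (sub["y"].mean() - grand)
        gaps.append(abs(fit.blups[e] - expected))
    return max(gaps)
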