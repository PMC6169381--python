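"""Genomic relationship (VanRaden) matrices with marker exclusion.

K = C C' / s with C the column-centered dose matrix (dose - 2p) and
s = sum_j 2 p_j (1 - p_j).  Missing doses are mean-imputed column-wise for
K only.  ``KinshipBuilder`` precomputes the full cross-product so that the
per-marker linkage-window exclusions of the genome scan are cheap rank
updates rather than full recomputations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING


@dataclass
class KinshipMatrix:
    ids: list
    values: np.ndarray
    denom: float

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix not symmetric")

    def min_eigenvalue_ratio(self) -> float:
        w = np.linalg.eigvalsh(self.values)
        return float(w[0] / max(w[-1], 1e-300))


def _centered_doses(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, centered dose matrix and per-marker 2p(1-p) weights."""
    g = np.asarray(geno, dtype=float)
    g[np.asarray(geno) == MISSING] = np.nan
    means = np.nanmean(g, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(means, inds[1])
    p = means / 2.0
    return g - means[None, :], 2.0 * p * (1.0 - p)


class KinshipBuilder:
    """Precomputed machinery for window-excluded kinship matrices."""

    def __init__(self, geno: np.ndarray, ids: list | None = None):
        self.ids = list(ids) if ids is not None else list(range(len(geno)))
        self.C, self.w = _centered_doses(geno)
        self.M = self.C @ self.C.T
        self.s_total = float(self.w.sum())

    def kinship(self, exclude: np.ndarray | None = None) -> KinshipMatrix:
        if exclude is None or len(exclude) == 0:
            denom = self.s_total
            M = self.M
        else:
            exclude = np.asarray(exclude, dtype=int)
            Cw = self.C[:, exclude]
            M = self.M - Cw @ Cw.T
            denom = self.s_total - float(self.w[exclude].sum())
        if denom <= 0:
            raise ValueError("all informative markers excluded from kinship")
        return KinshipMatrix(self.ids, M / denom, denom)


def vanraden_kinship(geno: np.ndarray, ids: list | None = None,
                     exclude: np.ndarray | None = None) -> KinshipMatrix:
    """One-shot VanRaden matrix over all markers minus an excluded set."""
    return KinshipBuilder(geno, ids).kinship(exclude)
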