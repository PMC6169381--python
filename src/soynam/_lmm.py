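"""REML machinery for the two-variance-component marker-scan model.

The scan model for genotypic values v (one entry per line) is

    v = X b + W a + phi + eps,
    a ~ N(0, I s2a), phi ~ N(0, K s2p), eps ~ N(0, I s2e),

with W the family-nested marker design (q columns, one per segregating
family) and K a genomic relationship matrix.  Writing V = s2e * H with
H = I + lp*K + la*W W' (lp = s2p/s2e, la = s2a/s2e), the restricted
likelihood is profiled over s2e and the fixed effects and minimized over the
two log variance ratios.  K is eigendecomposed once per marker; the W term
is handled by a q x q Woodbury complement, so each likelihood evaluation is
O(n q + q^3) after the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_LOG_LO, _LOG_HI = -14.0, 14.0  # bounds on log variance ratios


@dataclass
class VCFit:
    """One fitted variance-component model (full or null)."""

    neg2_reml: float
    sigma2_e: float
    sigma2_phi: float
    sigma2_alpha: float
    beta: np.ndarray
    alpha: np.ndarray          # BLUPs of the q family marker effects
    alpha_sd: np.ndarray       # prediction-error SDs of alpha
    log_ratios: tuple


class _Rotated:
    """Inputs rotated into the eigenbasis of K."""

    def __init__(self, y: np.ndarray, X: np.ndarray, W: np.ndarray,
                 K: np.ndarray):
        d, U = np.linalg.eigh(K)
        self.U = U
        self.d = np.clip(d, 0.0, None)
        self.y = U.T @ y
        self.X = U.T @ X
        self.W = U.T @ W if W.size else np.zeros((len(y), 0))
        self.n, self.p = self.X.shape
        self.q = self.W.shape[1]

    def with_design(self, W: np.ndarray) -> "_Rotated":
        """Same rotated problem with a different random-effect design
        (reuses the eigendecomposition)."""
        new = object.__new__(_Rotated)
        new.U, new.d, new.y, new.X = self.U, self.d, self.y, self.X
        new.n, new.p = self.n, self.p
        new.W = self.U.T @ np.asarray(W, float) if W.size else np.zeros((self.n, 0))
        new.q = new.W.shape[1]
        return new


def rotate_problem(y, X, W, K) -> _Rotated:
    """One eigendecomposition serving both the null and the marker fit."""
    return _Rotated(np.asarray(y, float), np.atleast_2d(X),
                    np.asarray(W, float), K)


def _neg2_profile(rot: _Rotated, lam_phi: float, lam_alpha: float,
                  want_solution: bool = False):
    """Profiled -2 restricted log-likelihood at given variance ratios."""
    sig = 1.0 + lam_phi * rot.d
    logdet_h = float(np.sum(np.log(sig)))
    inv_sig = 1.0 / sig

    T = np.column_stack([rot.y, rot.X])        # n x (1+p)
    HiT = inv_sig[:, None] * T
    if rot.q and lam_alpha > 0.0:
        A = inv_sig[:, None] * rot.W           # Sigma^-1 W
        G = rot.W.T @ A                        # W' Sigma^-1 W
        Minner = G + np.eye(rot.q) / lam_alpha
        cho = linalg.cho_factor(Minner, lower=True)
        logdet_h += rot.q * np.log(lam_alpha) + 2.0 * float(
            np.sum(np.log(np.diag(cho[0]))))
        HiT = HiT - A @ linalg.cho_solve(cho, A.T @ T)
    Hiy, HiX = HiT[:, 0], HiT[:, 1:]

    XtHiX = rot.X.T @ HiX
    XtHiy = rot.X.T @ Hiy
    ytHiy = float(rot.y @ Hiy)
    sign, logdet_x = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return np.inf if not want_solution else (np.inf, None)
    beta = np.linalg.solve(XtHiX, XtHiy)
    quad = max(ytHiy - float(XtHiy @ beta), 1e-300)
    df = rot.n - rot.p
    sigma2_e = quad / df
    val = df * np.log(sigma2_e) + logdet_h + logdet_x + df
    if not want_solution:
        return val
    return val, (beta, sigma2_e, XtHiX, Hiy, HiX)


def _blups(rot: _Rotated, lam_phi: float, lam_alpha: float, beta, sigma2_e,
           XtHiX):
    """BLUPs of the family marker effects and their prediction-error SDs."""
    q = rot.q
    if q == 0 or lam_alpha <= 0.0:
        return np.zeros(q), np.zeros(q)
    sig = 1.0 + lam_phi * rot.d
    inv_sig = 1.0 / sig
    A = inv_sig[:, None] * rot.W
    G = rot.W.T @ A
    cho = linalg.cho_factor(G + np.eye(q) / lam_alpha, lower=True)

    def hinv(M):
        HiM = inv_sig[:, None] * M
        return HiM - A @ linalg.cho_solve(cho, A.T @ M)

    r = (rot.y - rot.X @ beta)[:, None]
    Hir = hinv(r)[:, 0]
    alpha = lam_alpha * (rot.W.T @ Hir)
    HiW = hinv(rot.W)
    WtHiW = rot.W.T @ HiW
    WtHiX = rot.W.T @ hinv(rot.X)
    WtPW = WtHiW - WtHiX @ np.linalg.solve(XtHiX, WtHiX.T)
    pev = sigma2_e * (lam_alpha * np.ones(q)
                      - lam_alpha**2 * np.diag(WtPW))
    return alpha, np.sqrt(np.clip(pev, 0.0, None))


def fit_polygenic_null(y=None, X=None, K=None, rot: _Rotated | None = None) -> VCFit:
    """REML fit of v = Xb + phi + eps (no marker term).

    Accepts either raw inputs or an already-rotated problem (whose W design,
    if any, is simply unused at lam_alpha = 0)."""
    if rot is None:
        rot = rotate_problem(y, X, np.zeros((len(y), 0)), K)

    def obj(lp):
        return _neg2_profile(rot, float(np.exp(lp)), 0.0)

    res = optimize.minimize_scalar(obj, bounds=(_LOG_LO, _LOG_HI),
                                   method="bounded",
                                   options={"xatol": 1e-5})
    lp = float(res.x)
    # boundary check: sigma2_phi = 0
    v0 = _neg2_profile(rot, 0.0, 0.0)
    if v0 <= res.fun:
        lp, best = -np.inf, v0
        lam_phi = 0.0
    else:
        best, lam_phi = float(res.fun), float(np.exp(lp))
    _, sol = _neg2_profile(rot, lam_phi, 0.0, want_solution=True)
    beta, sigma2_e, XtHiX, _, _ = sol
    return VCFit(best, sigma2_e, lam_phi * sigma2_e, 0.0, beta,
                 np.zeros(0), np.zeros(0), (lp, -np.inf))


def fit_marker_model(y=None, X=None, W=None, K=None,
                     null_fit: VCFit | None = None,
                     fix_lp: float | None = None,
                     rot: _Rotated | None = None) -> VCFit:
    """REML fit of the full family-nested marker model.

    The optimum is searched over (log lp, log la) by Nelder-Mead from the
    best of a coarse grid of marker-ratio starts (polygenic ratio
    warm-started at the null fit's value); the null point itself is always a
    candidate, so the restricted LRT against the no-marker model is
    non-negative by construction.  ``fix_lp`` pins the polygenic log-ratio
    at the null fit's value (approximate fixed-background mode: only the
    marker ratio is re-optimized).
    """
    if rot is None:
        rot = rotate_problem(y, X, W, K)
    if null_fit is None:
        null_fit = fit_polygenic_null(rot=rot)
    if rot.q == 0:
        return null_fit

    lp0 = null_fit.log_ratios[0]
    if not np.isfinite(lp0):
        lp0 = _LOG_LO

    best_x, best_v = None, np.inf
    if fix_lp is not None:
        lp_fixed = float(np.clip(fix_lp, _LOG_LO, _LOG_HI)) if np.isfinite(fix_lp) else _LOG_LO
        lam_p = float(np.exp(lp_fixed)) if np.isfinite(fix_lp) else 0.0

        res = optimize.minimize_scalar(
            lambda la: _neg2_profile(rot, lam_p,
                                     float(np.exp(np.clip(la, _LOG_LO, _LOG_HI)))),
            bounds=(_LOG_LO, _LOG_HI), method="bounded",
            options={"xatol": 1e-5})
        best_v = float(res.fun)
        best_x = np.array([lp_fixed, np.clip(res.x, _LOG_LO, _LOG_HI)])
    else:
        def obj(x):
            lp, la = np.clip(x, _LOG_LO, _LOG_HI)
            return _neg2_profile(rot, float(np.exp(lp)), float(np.exp(la)))

        starts = [(lp0, la0) for la0 in (-6.0, -3.0, 0.0, 3.0)]
        start_vals = [obj(np.array(s)) for s in starts]
        x0 = np.array(starts[int(np.argmin(start_vals))])
        res = optimize.minimize(obj, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-7,
                                         "maxiter": 250})
        best_v, best_x = float(res.fun), np.clip(res.x, _LOG_LO, _LOG_HI)
    if best_v >= null_fit.neg2_reml:  # boundary optimum: marker variance 0
        return VCFit(null_fit.neg2_reml, null_fit.sigma2_e,
                     null_fit.sigma2_phi, 0.0, null_fit.beta,
                     np.zeros(rot.q), np.zeros(rot.q),
                     (null_fit.log_ratios[0], -np.inf))
    lam_phi, lam_alpha = float(np.exp(best_x[0])), float(np.exp(best_x[1]))
    _, sol = _neg2_profile(rot, lam_phi, lam_alpha, want_solution=True)
    beta, sigma2_e, XtHiX, _, _ = sol
    alpha, alpha_sd = _blups(rot, lam_phi, lam_alpha, beta, sigma2_e, XtHiX)
    return VCFit(best_v, sigma2_e, lam_phi * sigma2_e, lam_alpha * sigma2_e,
                 beta, alpha, alpha_sd, tuple(best_x))


def boundary_lrt_pvalue(neg2_null: float, neg2_full: float) -> float:
    """p-value for H0: s2a = 0 from the restricted likelihood ratio under the
    boundary mixture null 0.5*chi2_0 + 0.5*chi2_1."""
    from scipy.stats import chi2

    lrt = max(0.0, neg2_null - neg2_full)
    if lrt <= 1e-10:
        return 1.0
    return float(0.5 * chi2.sf(lrt, df=1))
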