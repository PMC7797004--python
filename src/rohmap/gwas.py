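"""EMMAX-style mixed-model association.

The null model y = 1 mu + u + e with cov(u) = sigma2_g K is fitted once by
REML using the spectral decomposition of K (eigenvalues clipped at zero for
positive semi-definiteness); each marker is then tested by generalised
least squares with V = sigma2_g K + sigma2_e I held fixed, a two-sided
t-test on the marker coefficient with n - 2 degrees of freedom, and
Benjamini-Hochberg adjustment across markers.  The kinship matrix is the
pairwise IBS similarity by default, used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .panel import GenotypePanel


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GWASResult:
    table: pd.DataFrame = field(repr=False)   # chrom,pos,beta,se,p,fdr_p
    delta: float                              # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float

    def significant(self, alpha: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["fdr_p"] < alpha]


def _reml_delta(yt: np.ndarray, xt: np.ndarray, lam: np.ndarray):
    """Profile REML over delta on K-rotated data (X = intercept only)."""
    n = len(yt)

    def neg_restricted_ll(log_delta):
        d = np.exp(log_delta)
        w = lam + d                     # V = sigma2_g * diag(lam + delta)
        xv = (xt**2 / w).sum()
        beta = (xt * yt / w).sum() / xv
        r = yt - beta * xt
        rss = (r**2 / w).sum()
        s2g = rss / (n - 1)
        # -2 lR = (n-1)[log(2 pi s2g) + 1] + sum log w + log(X'V*^-1 X) - log(X'X)
        ll = -0.5 * (
            (n - 1) * (np.log(2 * np.pi * s2g) + 1.0) + np.log(w).sum()
            + np.log(xv) - np.log((xt**2).sum())
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_restricted_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_restricted_ll, bounds=(g0 - 1.5, g0 + 1.5),
                          method="bounded", options={"xatol": 1e-8})
    best = res.x if res.fun <= min(vals) else g0
    return float(np.exp(best)), float(-neg_restricted_ll(best))


def emmax_gwas(
    panel: GenotypePanel,
    blups: pd.Series,
    K: np.ndarray,
    fdr_alpha: float = 0.1,
    eig_tol: float = 1e-10,
) -> GWASResult:
    """Single-marker mixed-model scan of ``blups`` over the panel's markers.

    ``blups`` must be indexed by sample id; the panel is restricted to those
    samples.  Missing dosages are mean-imputed per marker so the fixed
    variance structure applies to every test.  Zero-variance markers are
    reported with NaN statistics.
    """
    ids = [s for s in panel.sample_ids if s in blups.index and pd.notna(blups[s])]
    sub = panel.subset_samples(ids)
    idx = panel.sample_index(ids)
    K = np.asarray(K, dtype=float)[np.ix_(idx, idx)]
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    y = blups.loc[ids].to_numpy(dtype=float)
    n = len(y)

    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    if lam.max() <= eig_tol:
        raise ValueError("kinship matrix is numerically zero after PSD clipping")

    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    delta, reml_ll = _reml_delta(yt, ones_t, lam)
    w = lam + delta
    # V = sigma2_g (K + delta I); sigma2_g from the profiled RSS
    xv = (ones_t**2 / w).sum()
    beta0 = (ones_t * yt / w).sum() / xv
    s2g = ((yt - beta0 * ones_t) ** 2 / w).sum() / (n - 1)
    s2e = s2g * delta

    # GLS per marker on whitened data
    sw = 1.0 / np.sqrt(w)
    yw = yt * sw
    x0w = ones_t * sw
    G = sub.dosages.astype(np.float64)
    called = sub.called
    p_freq = sub.allele_freq
    G = np.where(called, G, 2.0 * p_freq)
    Gw = (U.T @ G) * sw[:, None]

    # per-marker 2x2 normal equations with design [x0w, gw]
    a = x0w @ x0w
    b = x0w @ Gw
    c = (Gw**2).sum(axis=0)
    det = a * c - b**2
    xy0 = x0w @ yw
    xym = Gw.T @ yw
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (a * xym - b * xy0) / det
        alpha = (c * xy0 - b * xym) / det
    resid2 = (yw**2).sum() - alpha * xy0 - beta * xym
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = resid2 / df
        se = np.sqrt(s2 * a / det)
        tstat = beta / se
    zero_var = det <= 1e-12 * np.maximum(a * c, 1e-300)
    tstat = np.where(zero_var, np.nan, tstat)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    table = pd.DataFrame({
        "chrom": sub.markers["chrom"].to_numpy(),
        "pos": sub.markers["pos"].to_numpy(),
        "beta": np.where(zero_var, np.nan, beta),
        "se": np.where(zero_var, np.nan, se),
        "p": pvals,
    })
    ok = ~np.isnan(table["p"].to_numpy())
    fdr = np.full(len(table), np.nan)
    fdr[ok] = bh_fdr(table["p"].to_numpy()[ok])
    table["fdr_p"] = fdr
    table["significant"] = table["fdr_p"] < fdr_alpha
    return GWASResult(table=table, delta=delta, sigma2_g=float(s2g),
                      sigma2_e=float(s2e), reml_loglik=reml_ll)
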