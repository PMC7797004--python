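"""Multi-year phenotype modelling: REML variance components and BLUPs.

The model is an intercept-only linear mixed model with crossed random
genotype and year effects,

    y_ijk = mu + g_i + t_j + e_ijk,
    g ~ N(0, sigma2_G I),  t ~ N(0, sigma2_Y I),  e ~ N(0, sigma2_E I).

Variance components are estimated by direct maximisation of the restricted
log-likelihood (bounded quasi-Newton on the variance scale, so the
sigma2 = 0 boundary is attained exactly); genotype BLUPs are the
conditional means sigma2_G Z' V^{-1} (y - X beta_hat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class BLUPSet:
    trait: str
    blups: pd.Series                      # per genotype, mean ~ 0
    sigma2_g: float
    sigma2_y: float
    sigma2_e: float
    reml_loglik: float
    converged: bool
    intercept: float = 0.0
    year_blups: pd.Series | None = field(default=None, repr=False)


def _design(records: pd.DataFrame, trait: str):
    sub = records[records["trait"] == trait] if "trait" in records.columns else records
    sub = sub.dropna(subset=["value"])
    genotypes = pd.Index(sorted(sub["genotype"].unique()))
    years = pd.Index(sorted(sub["year"].unique()))
    if len(genotypes) < 2 or len(years) < 1:
        raise ValueError("BLUP model needs >= 2 genotypes and >= 1 year")
    y = sub["value"].to_numpy(dtype=float)
    Zg = np.zeros((len(y), len(genotypes)))
    Zg[np.arange(len(y)), genotypes.get_indexer(sub["genotype"])] = 1.0
    Zy = np.zeros((len(y), len(years)))
    Zy[np.arange(len(y)), years.get_indexer(sub["year"])] = 1.0
    return y, Zg, Zy, genotypes, years


def _neg2_reml(theta, y, Gg, Gy):
    s2g, s2y, s2e = theta
    n = len(y)
    V = s2g * Gg + s2y * Gy + s2e * np.eye(n)
    try:
        c, low = cho_factor(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = cho_solve((c, low), y)
    Vi_1 = cho_solve((c, low), np.ones(n))
    xvx = np.ones(n) @ Vi_1
    beta = (np.ones(n) @ Vi_y) / xvx
    resid = y - beta
    Vi_r = Vi_y - beta * Vi_1
    return logdet_v + np.log(xvx) + resid @ Vi_r


def fit_blup(records: pd.DataFrame, trait: str, tol: float = 1e-8) -> BLUPSet:
    """REML fit of the crossed genotype/year model; returns genotype BLUPs.

    ``records`` is long format with columns genotype, year, trait, value
    (or genotype, year, value when single-trait).  Deterministic given the
    data.  Raises on optimizer failure.
    """
    y, Zg, Zy, genotypes, years = _design(records, trait)
    Gg, Gy = Zg @ Zg.T, Zy @ Zy.T
    # a single year level is confounded with the intercept: pin sigma2_y at 0
    single_year = len(years) == 1
    if single_year:
        Gy = np.zeros_like(Gg)
    y_bound = (0.0, 0.0) if single_year else (0.0, None)
    vy = float(np.var(y, ddof=1)) or 1.0
    best = None
    for frac in ((0.4, 0.2, 0.4), (0.05, 0.05, 0.9), (0.8, 0.1, 0.1)):
        x0 = np.array(frac) * vy
        if single_year:
            x0[1] = 0.0
        res = minimize(
            _neg2_reml, x0, args=(y, Gg, Gy), method="L-BFGS-B",
            bounds=[(0.0, None), y_bound, (vy * 1e-10, None)],
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"REML failed to converge for trait {trait}: {best}")
    s2g, s2y, s2e = best.x
    n = len(y)
    V = s2g * Gg + s2y * Gy + s2e * np.eye(n)
    c, low = cho_factor(V)
    Vi_y = cho_solve((c, low), y)
    Vi_1 = cho_solve((c, low), np.ones(n))
    beta = (np.ones(n) @ Vi_y) / (np.ones(n) @ Vi_1)
    Vi_r = Vi_y - beta * Vi_1
    g_blup = s2g * (Zg.T @ Vi_r)
    t_blup = s2y * (Zy.T @ Vi_r)
    return BLUPSet(
        trait=trait,
        blups=pd.Series(g_blup, index=genotypes, name=trait),
        sigma2_g=float(s2g), sigma2_y=float(s2y), sigma2_e=float(s2e),
        reml_loglik=float(-0.5 * best.fun),
        converged=bool(best.success),
        intercept=float(beta),
        year_blups=pd.Series(t_blup, index=years, name=f"{trait}_year"),
    )


def ks_normality(values, use_lilliefors: bool = True) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean and sd.

    With ``use_lilliefors`` the p-value accounts for the estimation of the
    parameters; otherwise the plain KS p-value is returned.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 values for the normality test")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance")
    if use_lilliefors:
        stat, p = lilliefors(x, dist="norm")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)


def derive_shell(records: pd.DataFrame) -> pd.DataFrame:
    """Add shell = nut - seed rows to a long trait table (where absent)."""
    if "shell" in records["trait"].unique():
        return records
    wide = records.pivot_table(index=["genotype", "year"], columns="trait",
                               values="value").reset_index()
    if not {"nut", "seed"}.issubset(wide.columns):
        raise ValueError("need nut and seed traits to derive shell")
    shell = wide.dropna(subset=["nut", "seed"]).assign(
        trait="shell", value=lambda d: d["nut"] - d["seed"]
    )[["genotype", "year", "trait", "value"]]
    return pd.concat([records, shell], ignore_index=True)


def trait_relations(blups: pd.DataFrame) -> pd.DataFrame:
    """Pairwise OLS between trait BLUPs (columns = traits, rows = genotypes).

    Returns one row per ordered pair (y ~ x) with slope, adjusted R^2 and p;
    pairs with < 3 shared genotypes are skipped.
    """
    rows = []
    traits = list(blups.columns)
    for yi in traits:
        for xi in traits:
            if yi == xi:
                continue
            sub = blups[[yi, xi]].dropna()
            if len(sub) < 3:
                continue
            fit = sm.OLS(sub[yi].to_numpy(), sm.add_constant(sub[xi].to_numpy())).fit()
            rows.append({
                "y": yi, "x": xi, "slope": float(fit.params[1]),
                "adj_r2": float(fit.rsquared_adj), "p": float(fit.pvalues[1]),
                "n": len(sub),
            })
    return pd.DataFrame(rows)
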