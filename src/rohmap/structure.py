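"""Population structure and linkage disequilibrium.

Covers: pairwise composite (dosage) r^2 with pairwise-complete missing-data
handling, PLINK-style greedy LD pruning in sliding windows, genotype PCA
with 2p centring and sqrt(2p(1-p)) scaling, and genome-wide LD decay via
the Hill-Weir expectation

    E[r^2](C) = (10+C) / ((2+C)(11+C))
                * [1 + ((3+C)(12+12C+C^2)) / (n (2+C)(11+C))]

with C = rho * d for physical distance d and sample size n.  The mean
pairwise r^2 over within- and between-chromosome marker pairs serves as the
background threshold, and the decay distance is where the fitted curve
crosses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .panel import GenotypePanel


# ----------------------------------------------------------------- r^2 --

def _pairwise_corr_stats(G, M, idx_a, idx_b):
    """Elementwise pairwise-complete Pearson r for column pairs (a_k, b_k)."""
    Xa, Xb = G[:, idx_a], G[:, idx_b]
    Ma, Mb = M[:, idx_a], M[:, idx_b]
    Mab = Ma * Mb
    n = Mab.sum(axis=0)
    sx = (Xa * Mab).sum(axis=0)
    sy = (Xb * Mab).sum(axis=0)
    sxx = (Xa**2 * Mab).sum(axis=0)
    syy = (Xb**2 * Mab).sum(axis=0)
    sxy = (Xa * Xb * Mab).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var = (n * sxx - sx**2) * (n * syy - sy**2)
        r = np.where(var > 0, cov / np.sqrt(var), np.nan)
    return r, n


def ld_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared dosage correlation of markers i and j over shared calls.

    NaN when either marker has zero variance among the shared samples.
    """
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    r, n = _pairwise_corr_stats(G, M, np.array([i]), np.array([j]))
    if n[0] < 2:
        return float("nan")
    return float(r[0] ** 2)


def pairwise_r2_matrix(panel: GenotypePanel, idx: np.ndarray) -> np.ndarray:
    """Dense r^2 matrix for the given marker indices (pairwise-complete)."""
    idx = np.asarray(idx)
    w = len(idx)
    ii, jj = np.triu_indices(w, k=1)
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    r, _ = _pairwise_corr_stats(G, M, idx[ii], idx[jj])
    out = np.full((w, w), np.nan)
    out[ii, jj] = out[jj, ii] = r**2
    np.fill_diagonal(out, 1.0)
    return out


# --------------------------------------------------------------- pruning --

def ld_prune(
    panel: GenotypePanel, window: int = 50, step: int = 5, r2_max: float = 0.5
) -> GenotypePanel:
    """Greedy sliding-window LD pruning (PLINK --indep-pairwise style).

    Within each window of ``window`` markers (advanced by ``step``), every
    remaining pair with r^2 > ``r2_max`` drops its first marker.  Removal is
    deterministic; output markers are an order-preserving subset.
    """
    keep = np.ones(panel.n_markers, dtype=bool)
    for chrom, sub in panel.markers.groupby("chrom", sort=False):
        c_idx = sub.index.to_numpy()
        L = len(c_idx)
        for ws in range(0, max(L - 1, 1), step):
            win = c_idx[ws:ws + window]
            alive = win[keep[win]]
            if len(alive) < 2:
                continue
            r2 = pairwise_r2_matrix(panel, alive)
            local_alive = np.ones(len(alive), dtype=bool)
            for a in range(len(alive)):
                if not local_alive[a]:
                    continue
                for b in range(a + 1, len(alive)):
                    if local_alive[b] and r2[a, b] > r2_max:
                        local_alive[a] = False
                        break
            keep[alive[~local_alive]] = False
            if ws + window >= L:
                break
    return panel.subset(marker_idx=keep)


# ------------------------------------------------------------------- PCA --

@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray = field(repr=False)            # (n_samples, k)
    explained_variance_ratio: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca(panel: GenotypePanel, n_components: int = 5) -> PCAResult:
    """Genotype PCA with allele-frequency standardisation.

    Missing dosages are mean-imputed per marker; each marker is centred by
    2p and scaled by sqrt(2p(1-p)).  Scores are the projections onto the
    top right-singular directions of the standardised matrix.
    """
    if n_components >= panel.n_samples:
        raise ValueError("n_components must be smaller than the sample count")
    G = panel.dosages.astype(np.float64)
    called = panel.called
    p = panel.allele_freq
    mean = 2.0 * p
    G = np.where(called, G, mean)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    X = (G[:, ok] - mean[ok]) / scale[ok]
    X = X - X.mean(axis=0)  # centre samples so component scores average 0
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :n_components] * s[:n_components]
    return PCAResult(sample_ids=list(panel.sample_ids), scores=scores,
                     explained_variance_ratio=ratio[:n_components])


# ------------------------------------------------------------- LD decay --

def hill_weir_r2(d, rho: float, n: int) -> np.ndarray:
    """Expected r^2 at distance d for recombination scale rho and n samples."""
    C = rho * np.asarray(d, dtype=float)
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return base * corr


@dataclass
class DecayFit:
    rho: float
    n: int
    threshold_r2: float
    decay_distance: float | None
    pairs: pd.DataFrame = field(repr=False)           # distance, r2 (within-chrom)
    per_chrom_mean_r2: pd.Series = field(repr=False)


def _sample_within_pairs(markers: pd.DataFrame, max_dist: int, cap: int, rng):
    """(i, j) index pairs on the same chromosome with pos diff <= max_dist."""
    out_i, out_j = [], []
    for _, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        ii = np.concatenate([np.repeat(k, hi[k] - k - 1) for k in range(len(idx))]) \
            if len(idx) > 1 else np.array([], dtype=int)
        jj = np.concatenate([np.arange(k + 1, hi[k]) for k in range(len(idx))]) \
            if len(idx) > 1 else np.array([], dtype=int)
        if len(ii) > cap:
            sel = rng.choice(len(ii), size=cap, replace=False)
            ii, jj = ii[sel], jj[sel]
        out_i.append(idx[ii])
        out_j.append(idx[jj])
    return np.concatenate(out_i), np.concatenate(out_j)


def mean_background_r2(
    panel: GenotypePanel, n_pairs: int = 100_000, rng=None
) -> float:
    """Mean r^2 over random marker pairs within and between chromosomes."""
    rng = np.random.default_rng(rng)
    L = panel.n_markers
    i = rng.integers(0, L, size=n_pairs)
    j = rng.integers(0, L, size=n_pairs)
    ok = i != j
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    r, n = _pairwise_corr_stats(G, M, i[ok], j[ok])
    r2 = r[n >= 2] ** 2
    return float(np.nanmean(r2))


def per_chromosome_mean_r2(
    panel: GenotypePanel, max_pairs_per_chrom: int = 50_000, rng=None
) -> pd.Series:
    """Mean within-chromosome r^2, per chromosome (subsampled pairs)."""
    rng = np.random.default_rng(rng)
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    out = {}
    for chrom, sub in panel.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        if len(ii) > max_pairs_per_chrom:
            sel = rng.choice(len(ii), size=max_pairs_per_chrom, replace=False)
            ii, jj = ii[sel], jj[sel]
        r, n = _pairwise_corr_stats(G, M, idx[ii], idx[jj])
        out[chrom] = float(np.nanmean(r[n >= 2] ** 2))
    return pd.Series(out, name="mean_r2")


def fit_hill_weir(distances: np.ndarray, r2: np.ndarray, n: int,
                  bounds=(1e-6, 10.0)) -> float:
    """Least-squares rho for the Hill-Weir expectation, grid-initialised."""
    grid = np.geomspace(bounds[0], bounds[1], 60)
    sse = [np.sum((hill_weir_r2(distances, g, n) - r2) ** 2) for g in grid]
    rho0 = grid[int(np.argmin(sse))]
    res = least_squares(
        lambda rho: hill_weir_r2(distances, rho[0], n) - r2,
        x0=[rho0], bounds=([bounds[0]], [bounds[1]]),
    )
    if not res.success:
        return float(rho0)  # grid-search fallback
    return float(res.x[0])


def ld_decay(
    panel: GenotypePanel,
    max_dist: int = 100_000,
    pair_cap_per_chrom: int = 100_000,
    threshold_pairs: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> DecayFit:
    """Fit the genome-wide LD decay curve and its background threshold.

    Collects within-chromosome pairs up to ``max_dist`` apart (subsampled
    per chromosome), fits rho by nonlinear least squares, computes the mean
    background r^2 over random within+between pairs, and solves for the
    distance at which the fitted curve crosses it.
    """
    rng = np.random.default_rng(seed)
    i, j = _sample_within_pairs(panel.markers, max_dist, pair_cap_per_chrom, rng)
    if len(i) == 0:
        raise ValueError("no within-chromosome marker pairs within max_dist")
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    r, n_obs = _pairwise_corr_stats(G, M, i, j)
    dist = np.abs(panel.markers["pos"].to_numpy()[i] - panel.markers["pos"].to_numpy()[j])
    ok = (n_obs >= 2) & ~np.isnan(r)
    dist, r2 = dist[ok].astype(float), r[ok] ** 2
    n = panel.n_samples
    rho = fit_hill_weir(dist, r2, n)
    threshold = mean_background_r2(panel, n_pairs=threshold_pairs, rng=rng)
    f = lambda d: hill_weir_r2(d, rho, n) - threshold
    decay_distance: float | None = None
    if f(1e-3) > 0 and f(1e9) < 0:
        decay_distance = float(brentq(f, 1e-3, 1e9))
    pairs = pd.DataFrame({"distance": dist, "r2": r2})
    return DecayFit(
        rho=rho, n=n, threshold_r2=threshold, decay_distance=decay_distance,
        pairs=pairs, per_chrom_mean_r2=per_chromosome_mean_r2(panel, rng=rng),
    )
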