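"""Homozygosity mapping: ROH clusters, spectral boundary trimming, and
cluster-phenotype association.

A cluster of ROHs is a genomic region of at least ``min_length`` bp whose
detection markers lie inside ROHs of at least ``min_carriers`` phenotyped
samples.  Candidate boundaries are refined by repeated binary spectral
clustering of the marker columns of the ROH incidence matrix (Jaccard
similarity, normalised-Laplacian Fiedler vector), descending into the
denser block until the carrier rows are homogeneous.  Association is then
an OLS of the trait BLUP on the carrier indicator with principal-component
covariates, BH-adjusted across clusters per trait, plus a plain two-sample
t-test of carrier vs non-carrier BLUP means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import eigh

from .gwas import bh_fdr
from .panel import GenotypePanel


@dataclass
class ROHCluster:
    chrom: str
    start: int
    end: int
    carriers: frozenset[str]
    n_loci: int

    @property
    def id(self) -> str:
        return f"ROH_S{self.chrom}_{self.start}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _covering_samples(rohs: pd.DataFrame, chrom: str, start: int, end: int) -> frozenset[str]:
    """Samples with a single ROH spanning the whole [start, end] region."""
    sub = rohs[(rohs["chrom"] == chrom) & (rohs["start"] <= start) & (rohs["end"] >= end)]
    return frozenset(sub["sample"])


def roh_incidence(
    rohs: pd.DataFrame, detection_markers: pd.DataFrame, sample_ids: list[str]
) -> np.ndarray:
    """Boolean (samples x markers) matrix: marker inside that sample's ROH."""
    out = np.zeros((len(sample_ids), len(detection_markers)), dtype=bool)
    order = {s: i for i, s in enumerate(sample_ids)}
    pos = detection_markers["pos"].to_numpy()
    chrom_arr = detection_markers["chrom"].to_numpy()
    for chrom, sub in rohs.groupby("chrom", sort=False):
        in_chrom = np.flatnonzero(chrom_arr == chrom)
        if len(in_chrom) == 0:
            continue
        cpos = pos[in_chrom]
        for row in sub.itertuples():
            if row.sample not in order:
                continue
            lo = np.searchsorted(cpos, row.start, side="left")
            hi = np.searchsorted(cpos, row.end, side="right")
            out[order[row.sample], in_chrom[lo:hi]] = True
    return out


def build_roh_clusters(
    rohs: pd.DataFrame,
    detection_markers: pd.DataFrame,
    phenotyped_ids: list[str],
    min_carriers: int = 10,
    min_length: int = 100_000,
) -> list[dict]:
    """Candidate cluster regions before trimming.

    Per detection marker, counts phenotyped samples whose ROHs cover it;
    candidates are maximal runs of consecutive markers with count >=
    ``min_carriers`` spanning >= ``min_length`` bp.  Returns dicts with
    chrom/start/end/marker index span.
    """
    rohs = rohs[rohs["sample"].isin(set(phenotyped_ids))]
    inc = roh_incidence(rohs, detection_markers, list(phenotyped_ids))
    counts = inc.sum(axis=0)
    pos = detection_markers["pos"].to_numpy()
    chrom_arr = detection_markers["chrom"].to_numpy()
    candidates = []
    hot = counts >= min_carriers
    # break runs at chromosome boundaries
    boundary = np.r_[True, chrom_arr[1:] != chrom_arr[:-1]]
    run_start = None
    for k in range(len(hot) + 1):
        if k < len(hot) and hot[k] and (run_start is None):
            run_start = k
        elif run_start is not None and (k == len(hot) or not hot[k] or boundary[k]):
            a, b = run_start, k - 1
            run_start = k if (k < len(hot) and hot[k]) else None
            start, end = int(pos[a]), int(pos[b])
            if end - start + 1 >= min_length:
                candidates.append({
                    "chrom": str(chrom_arr[a]), "start": start, "end": end,
                    "marker_span": (a, b), "n_carriers_max": int(counts[a:b + 1].max()),
                })
    return candidates


def _fiedler_split(S: np.ndarray) -> np.ndarray:
    """Boolean partition of columns by the Fiedler vector sign of the
    normalised Laplacian of similarity matrix S."""
    d = S.sum(axis=1)
    d[d <= 0] = 1e-12
    Dh = 1.0 / np.sqrt(d)
    L = np.eye(len(S)) - (Dh[:, None] * S * Dh[None, :])
    w, v = eigh(L)
    fiedler = v[:, 1] if len(w) > 1 else v[:, 0]
    return fiedler >= 0


def trim_cluster(
    candidate: dict,
    incidence: np.ndarray,
    detection_markers: pd.DataFrame,
    rohs: pd.DataFrame,
    sample_ids: list[str],
    min_carriers: int = 10,
    min_length: int = 100_000,
    homogeneity: float = 0.8,
    max_depth: int = 20,
) -> ROHCluster | None:
    """Trim candidate boundaries by repeated binary spectral clustering.

    ``incidence`` is the full (samples x detection markers) ROH incidence
    matrix.  At each step the marker columns of the current block are
    bipartitioned by the Fiedler vector of the Jaccard-similarity graph and
    the recursion descends into the block with the higher mean incidence,
    stopping when the mean incidence among rows touching the block reaches
    ``homogeneity`` or a further split would violate ``min_length``.
    Returns None when the trimmed region loses the carrier or length rule.
    """
    a, b = candidate["marker_span"]
    pos = detection_markers["pos"].to_numpy()
    lo, hi = a, b

    def block_homogeneity(l, h):
        block = incidence[:, l:h + 1]
        rows = block.any(axis=1)
        return float(block[rows].mean()) if rows.any() else 0.0

    for _ in range(max_depth):
        if block_homogeneity(lo, hi) >= homogeneity:
            break
        cols = incidence[:, lo:hi + 1].astype(float)
        w = cols.shape[1]
        if w < 2:
            break
        inter = cols.T @ cols
        sizes = cols.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, inter / union, 0.0)
        side = _fiedler_split(S)
        if side.all() or (~side).all():
            break
        parts = []
        for mask in (side, ~side):
            kidx = np.flatnonzero(mask)
            l, h = lo + kidx.min(), lo + kidx.max()
            parts.append((float(incidence[:, l:h + 1].mean()), l, h))
        parts.sort(reverse=True)
        _, l, h = parts[0]
        if pos[h] - pos[l] + 1 < min_length or (l, h) == (lo, hi):
            break
        lo, hi = l, h

    chrom = candidate["chrom"]
    start, end = int(pos[lo]), int(pos[hi])
    carriers = _covering_samples(rohs, chrom, start, end) & set(sample_ids)
    if end - start + 1 < min_length or len(carriers) < min_carriers:
        return None
    return ROHCluster(chrom=chrom, start=start, end=end,
                      carriers=frozenset(carriers), n_loci=hi - lo + 1)


def find_clusters(
    rohs: pd.DataFrame,
    detection_markers: pd.DataFrame,
    phenotyped_ids: list[str],
    min_carriers: int = 10,
    min_length: int = 100_000,
    homogeneity: float = 0.8,
) -> list[ROHCluster]:
    """Candidate construction plus spectral trimming, end to end."""
    rohs = rohs[rohs["sample"].isin(set(phenotyped_ids))]
    candidates = build_roh_clusters(rohs, detection_markers, phenotyped_ids,
                                    min_carriers, min_length)
    incidence = roh_incidence(rohs, detection_markers, list(phenotyped_ids))
    out = []
    for cand in candidates:
        cl = trim_cluster(cand, incidence, detection_markers, rohs,
                          list(phenotyped_ids), min_carriers, min_length,
                          homogeneity)
        if cl is not None:
            out.append(cl)
    return out


def hm_test(
    clusters: list[ROHCluster],
    blups: pd.DataFrame,
    pcs: pd.DataFrame,
    n_pcs: int = 5,
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Cluster-trait association with principal-component covariates.

    For each cluster and trait column of ``blups``: OLS of the BLUP on the
    carrier indicator plus the top ``n_pcs`` PC scores, two-sided t-test on
    the carrier coefficient, BH adjustment across clusters within trait.
    """
    rows = []
    samples = blups.index
    P = pcs.loc[samples].iloc[:, :n_pcs].to_numpy()
    for trait in blups.columns:
        y_all = blups[trait]
        trait_rows = []
        for cl in clusters:
            carrier = np.array([s in cl.carriers for s in samples], dtype=float)
            ok = y_all.notna().to_numpy()
            n_car = int(carrier[ok].sum())
            n_non = int(ok.sum() - n_car)
            if n_car < 2 or n_non < 2:
                continue
            X = sm.add_constant(np.column_stack([carrier, P])[ok])
            fit = sm.OLS(y_all.to_numpy()[ok], X).fit()
            trait_rows.append({
                "trait": trait, "cluster": cl.id, "chrom": cl.chrom,
                "start": cl.start, "end": cl.end, "n_carriers": n_car,
                "beta": float(fit.params[1]), "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
            })
        if trait_rows:
            df = pd.DataFrame(trait_rows)
            df["fdr_p"] = bh_fdr(df["p"].to_numpy())
            df["significant"] = df["fdr_p"] < fdr_alpha
            rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["trait", "cluster", "chrom", "start", "end",
                                     "n_carriers", "beta", "se", "p", "fdr_p",
                                     "significant"])
    return pd.concat(rows, ignore_index=True)


def carrier_ttest(cluster: ROHCluster, blups: pd.Series) -> dict:
    """Carrier vs non-carrier BLUP means with a pooled-variance t-test."""
    blups = blups.dropna()
    is_car = blups.index.isin(cluster.carriers)
    car, non = blups[is_car], blups[~is_car]
    if len(car) == 0 or len(non) == 0:
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    out = {
        "cluster": cluster.id,
        "mean_carrier": float(car.mean()),
        "se_carrier": float(car.std(ddof=1) / np.sqrt(len(car))) if len(car) > 1 else np.nan,
        "mean_noncarrier": float(non.mean()),
        "se_noncarrier": float(non.std(ddof=1) / np.sqrt(len(non))) if len(non) > 1 else np.nan,
        "n_carrier": int(len(car)), "n_noncarrier": int(len(non)),
    }
    if len(car) > 1 and len(non) > 1:
        t, p = stats.ttest_ind(car, non, equal_var=True)
        out["t"], out["p"] = float(t), float(p)
    else:
        out["t"], out["p"] = np.nan, np.nan
    return out
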