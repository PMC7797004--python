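"""Runs of homozygosity and individual inbreeding.

A ROH is a maximal stretch of consecutive detection markers with no
heterozygous call for a sample (missing calls are allowed inside and
counted), broken at chromosome ends, heterozygous calls, and inter-marker
gaps larger than ``max_gap``.  Detection runs on the MAF > 0.15 marker
subset; runs are kept if they contain at least ``min_snps`` markers and
span at least ``min_length`` bp (endpoints at the outermost non-missing
homozygous calls).

The F_PLINK inbreeding coefficient is the excess of observed over expected
homozygosity, F = (O - E) / (L - E), with the per-locus expectation under
Hardy-Weinberg 1 - 2 p q * n/(n-1) (n = called genotypes at the locus),
computed on the LD-pruned marker set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import MISSING, GenotypePanel

ROH_COLUMNS = ["sample", "chrom", "start", "end", "length", "n_snps", "n_missing"]


def roh_marker_subset(panel: GenotypePanel, maf_min: float = 0.15) -> GenotypePanel:
    """Detection marker subset: MAF strictly above ``maf_min``."""
    keep = panel.maf > maf_min
    if not keep.any():
        raise ValueError(f"no markers with MAF > {maf_min}; cannot detect ROHs")
    return panel.subset(marker_idx=keep)


def _runs_for_sample(pos: np.ndarray, g: np.ndarray, max_gap: int):
    """Yield (i0, i1) index spans of maximal het-free stretches.

    Spans are trimmed to the outermost non-missing (homozygous) call.
    """
    n = len(pos)
    # break *between* j-1 and j when g[j-1] or g[j] is het, or the gap is too big
    het = g == 1
    breaks = np.zeros(n + 1, dtype=bool)
    breaks[0] = breaks[n] = True
    if n > 1:
        gap_break = np.diff(pos) > max_gap
        breaks[1:n] = het[:-1] | het[1:] | gap_break
    edges = np.flatnonzero(breaks)
    for a, b in zip(edges[:-1], edges[1:]):
        seg = np.arange(a, b)
        seg = seg[~het[seg]]
        if seg.size == 0:
            continue
        called = g[seg] != MISSING
        if not called.any():
            continue
        i0 = seg[np.argmax(called)]
        i1 = seg[len(seg) - 1 - np.argmax(called[::-1])]
        yield int(i0), int(i1)


def detect_rohs(
    panel: GenotypePanel,
    maf_min: float = 0.15,
    min_snps: int = 15,
    min_length: int = 100_000,
    max_gap: int = 1_000_000,
    max_missing_frac: float | None = None,
    subset_markers: bool = True,
) -> pd.DataFrame:
    """Detect ROHs for every sample; returns a table with ROH_COLUMNS.

    Set ``subset_markers=False`` when the panel already is the detection set.
    """
    det = roh_marker_subset(panel, maf_min) if subset_markers else panel
    rows = []
    for chrom, sub in det.markers.groupby("chrom", sort=False):
        m_idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        for s, sid in enumerate(det.sample_ids):
            g = det.dosages[s, m_idx]
            for i0, i1 in _runs_for_sample(pos, g, max_gap):
                n_snps = i1 - i0 + 1
                start, end = int(pos[i0]), int(pos[i1])
                length = end - start + 1
                n_missing = int((g[i0:i1 + 1] == MISSING).sum())
                if n_snps < min_snps or length < min_length:
                    continue
                if max_missing_frac is not None and n_missing > max_missing_frac * n_snps:
                    continue
                rows.append({
                    "sample": sid, "chrom": chrom, "start": start, "end": end,
                    "length": length, "n_snps": n_snps, "n_missing": n_missing,
                })
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


def f_plink(panel: GenotypePanel) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per sample.

    The input should be the LD-pruned panel.  Samples for which the called
    locus count equals the expected homozygosity (degenerate denominator)
    get NaN.
    """
    p = panel.allele_freq
    n_l = panel.n_called().astype(float)
    if np.any(n_l < 2):
        raise ValueError("markers with fewer than 2 called genotypes; filter first")
    e_l = 1.0 - 2.0 * p * (1.0 - p) * n_l / (n_l - 1.0)
    M = panel.called.astype(np.float64)
    L = M.sum(axis=1)
    O = (((panel.dosages == 0) | (panel.dosages == 2)) & panel.called).sum(axis=1)
    E = M @ e_l
    denom = L - E
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    return pd.Series(f, index=panel.sample_ids, name="F_PLINK")


def inbreeding_summary(rohs: pd.DataFrame, f: pd.Series) -> pd.DataFrame:
    """Per-sample ROH count, total length and F, for all samples in ``f``."""
    counts = rohs.groupby("sample").size() if len(rohs) else pd.Series(dtype=int)
    lengths = rohs.groupby("sample")["length"].sum() if len(rohs) else pd.Series(dtype=int)
    out = pd.DataFrame({
        "roh_count": counts.reindex(f.index).fillna(0).astype(int),
        "roh_total_length": lengths.reindex(f.index).fillna(0).astype(np.int64),
        "F_PLINK": f,
    })
    return out.sort_values("roh_count", ascending=False)


def inbreeding_report(rohs: pd.DataFrame, f: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Summary table plus OLS of ROH count (and total length) on F.

    Regressions report slope and adjusted R^2; skipped with < 3 samples.
    """
    summary = inbreeding_summary(rohs, f)
    stats: dict = {}
    valid = summary.dropna(subset=["F_PLINK"])
    if len(valid) >= 3:
        X = sm.add_constant(valid["F_PLINK"].to_numpy())
        for col in ("roh_count", "roh_total_length"):
            fit = sm.OLS(valid[col].to_numpy(dtype=float), X).fit()
            stats[col] = {
                "slope": float(fit.params[1]),
                "adj_r2": float(fit.rsquared_adj),
                "p": float(fit.pvalues[1]),
            }
    return summary, stats
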