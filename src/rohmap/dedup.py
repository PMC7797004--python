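"""Clonal deduplication from pairwise identity-by-state similarity.

Biological replicates of the same accession calibrate an IBS threshold
(mean - 3 sd of replicate-pair IBS); samples joined by IBS at or above the
threshold form clonal groups (connected components, i.e. single linkage),
and each group is represented by its highest-call-rate member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .panel import GenotypePanel


@dataclass
class IBSMatrix:
    """Pairwise IBS similarity (fraction of shared alleles) in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)       # (n, n), NaN where undefined
    n_shared: np.ndarray = field(repr=False)     # loci non-missing in both

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def ibs_matrix(panel: GenotypePanel) -> IBSMatrix:
    """Mean fraction of alleles identical by state, per sample pair.

    For loci called in both samples, a pair shares ``2 - |g_i - g_j|``
    alleles of the two compared; the similarity is the total shared over
    ``2 * L_pair``.  Pairs with no shared called locus get NaN.
    """
    if panel.n_samples < 2:
        raise ValueError("IBS matrix requires at least 2 samples")
    G = panel.dosages.astype(np.float64)
    M = panel.called.astype(np.float64)
    Gm = np.where(panel.called, G, 0.0)
    n_shared = M @ M.T
    # sum over shared loci of |gi - gj| via indicator algebra:
    # |gi-gj| in {0,1,2}; count pairs at distance 2 (opposite homozygotes)
    # and distance 1 (hom vs het) using class indicator matmuls.
    H = [((panel.dosages == k) & panel.called).astype(np.float64) for k in (0, 1, 2)]
    ibs2 = sum(Hk @ Hk.T for Hk in H)
    ibs0 = H[0] @ H[2].T + H[2] @ H[0].T
    ibs1 = n_shared - ibs2 - ibs0
    shared_alleles = 2.0 * ibs2 + ibs1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_shared > 0, shared_alleles / (2.0 * n_shared), np.nan)
    np.fill_diagonal(values, 1.0)
    return IBSMatrix(sample_ids=list(panel.sample_ids), values=values,
                     n_shared=n_shared.astype(np.int64))


@dataclass
class ClonalGrouping:
    threshold: float
    groups: list[list[str]]            # size >= 2, members sorted
    representatives: list[str]         # one per group
    singletons: list[str]

    @property
    def deduplicated_ids(self) -> list[str]:
        return sorted(self.representatives + self.singletons)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, (members, rep) in enumerate(zip(self.groups, self.representatives), 1):
            for m in members:
                rows.append({"group": f"CG{g}", "sample": m, "representative": rep})
        return pd.DataFrame(rows, columns=["group", "sample", "representative"])


def replicate_ibs_threshold(ibs: IBSMatrix, replicate_pairs) -> float:
    """mean - 3*sd (ddof=1) of IBS over known replicate pairs."""
    vals = np.array([ibs.pair(a, b) for a, b in replicate_pairs], dtype=float)
    if vals.size == 0 or np.isnan(vals).any():
        raise ValueError("replicate pairs missing or with undefined IBS")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(vals.mean() - 3.0 * sd)


def clonal_groups(
    ibs: IBSMatrix,
    replicate_pairs: list[tuple[str, str]] | None,
    call_rates: dict[str, float],
    threshold: float | None = None,
) -> ClonalGrouping:
    """Form clonal groups by single linkage at the replicate-derived threshold.

    ``replicate_pairs`` are pairs of sample ids known to be biological
    replicates of the same accession; they calibrate the threshold and are
    always merged.  Without replicate pairs an explicit ``threshold`` must
    be supplied.  The representative of each group is the member with the
    highest call rate (ties broken lexicographically).
    """
    if threshold is None:
        if not replicate_pairs:
            raise ValueError(
                "no replicate pairs given: supply threshold= explicitly "
                "to declare clonal groups"
            )
        threshold = replicate_ibs_threshold(ibs, replicate_pairs)

    ids = ibs.sample_ids
    n = len(ids)
    adj = np.nan_to_num(ibs.values, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, False)
    if replicate_pairs:
        idx = {s: i for i, s in enumerate(ids)}
        for a, b in replicate_pairs:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    groups, reps, singles = [], [], []
    for c in range(n_comp):
        members = sorted(ids[i] for i in np.flatnonzero(labels == c))
        if len(members) == 1:
            singles.append(members[0])
        else:
            groups.append(members)
            reps.append(min(members, key=lambda s: (-call_rates[s], s)))
    # stable group order: by first member
    order = np.argsort([g[0] for g in groups])
    groups = [groups[i] for i in order]
    reps = [reps[i] for i in order]
    return ClonalGrouping(threshold=threshold, groups=groups,
                          representatives=reps, singletons=sorted(singles))


def deduplicate(panel: GenotypePanel, grouping: ClonalGrouping) -> GenotypePanel:
    """Panel restricted to group representatives plus singletons."""
    keep = [s for s in panel.sample_ids if s in set(grouping.deduplicated_ids)]
    return panel.subset_samples(keep)
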