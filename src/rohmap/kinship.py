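"""Method-of-moments estimation of pairwise IBD sharing (PLINK-style).

For each pair, observed counts of loci at IBS state 0/1/2 (both calls
present) are equated to their expectations under the probabilities
(Z0, Z1, Z2) of sharing 0/1/2 alleles identical by descent.  With p the
alternate-allele frequency at a locus and q = 1 - p, the per-locus
conditional probabilities are

    P(IBS0|Z0) = 2 p^2 q^2           P(IBS1|Z0) = 4 p^3 q + 4 p q^3
    P(IBS2|Z0) = p^4 + q^4 + 4 p^2 q^2
    P(IBS1|Z1) = 2 p^2 q + 2 p q^2   P(IBS2|Z1) = p^3 + q^3 + p^2 q + p q^2
    P(IBS2|Z2) = 1

and the system is solved sequentially: Z0 from the IBS0 count, Z1 from the
IBS1 count net of the Z0 contribution, Z2 = 1 - Z0 - Z1.  Estimates are
truncated to [0, 1] and renormalised; PI_HAT = Z2 + Z1/2.  No finite-sample
bias correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class KinshipEstimate:
    """Pairwise IBD-sharing probabilities and PI_HAT for all sample pairs."""

    sample_ids: list[str]
    Z0: np.ndarray = field(repr=False)
    Z1: np.ndarray = field(repr=False)
    Z2: np.ndarray = field(repr=False)
    pi_hat: np.ndarray = field(repr=False)
    n_shared: np.ndarray = field(repr=False)
    min_shared: int = 100

    def pair(self, a: str, b: str) -> dict:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return {
            "Z0": float(self.Z0[i, j]), "Z1": float(self.Z1[i, j]),
            "Z2": float(self.Z2[i, j]), "PI_HAT": float(self.pi_hat[i, j]),
            "n_shared": int(self.n_shared[i, j]),
            "reliable": bool(self.n_shared[i, j] >= self.min_shared),
        }

    def to_frame(self) -> pd.DataFrame:
        """Long pair table (i < j), sorted by descending PI_HAT."""
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "id1": self.sample_ids[i], "id2": self.sample_ids[j],
                    "Z0": self.Z0[i, j], "Z1": self.Z1[i, j], "Z2": self.Z2[i, j],
                    "PI_HAT": self.pi_hat[i, j],
                    "n_shared_loci": int(self.n_shared[i, j]),
                    "reliable": bool(self.n_shared[i, j] >= self.min_shared),
                })
        return (pd.DataFrame(rows)
                .sort_values("PI_HAT", ascending=False)
                .reset_index(drop=True))


def ibd_mom(
    panel: GenotypePanel,
    allele_freq: np.ndarray | None = None,
    min_shared: int = 100,
) -> KinshipEstimate:
    """Method-of-moments (Z0, Z1, Z2, PI_HAT) for every sample pair.

    ``allele_freq`` overrides the panel's sample frequencies (e.g. with
    known population frequencies in simulations).  Monomorphic loci must be
    filtered out beforehand.  Pairs sharing fewer than ``min_shared`` called
    loci are flagged unreliable.
    """
    p = panel.allele_freq if allele_freq is None else np.asarray(allele_freq, float)
    if p.shape != (panel.n_markers,):
        raise ValueError("allele_freq length must match marker count")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic loci present; filter markers before ibd_mom")
    q = 1.0 - p
    e0_z0 = 2 * p**2 * q**2
    e1_z0 = 4 * p**3 * q + 4 * p * q**3
    e1_z1 = 2 * p**2 * q + 2 * p * q**2

    M = panel.called.astype(np.float64)
    n_shared = M @ M.T
    # pairwise sums of per-locus expectations over loci called in both
    E0_Z0 = (M * e0_z0) @ M.T
    E1_Z0 = (M * e1_z0) @ M.T
    E1_Z1 = (M * e1_z1) @ M.T

    H = [((panel.dosages == k) & panel.called).astype(np.float64) for k in (0, 1, 2)]
    N2 = sum(Hk @ Hk.T for Hk in H)
    N0 = H[0] @ H[2].T + H[2] @ H[0].T
    N1 = n_shared - N0 - N2

    with np.errstate(invalid="ignore", divide="ignore"):
        Z0 = N0 / E0_Z0
        Z1 = (N1 - Z0 * E1_Z0) / E1_Z1
    Z2 = 1.0 - Z0 - Z1
    Z0, Z1, Z2 = (np.clip(Z, 0.0, 1.0) for Z in (Z0, Z1, Z2))
    total = Z0 + Z1 + Z2
    with np.errstate(invalid="ignore", divide="ignore"):
        Z0, Z1, Z2 = Z0 / total, Z1 / total, Z2 / total
    pi_hat = Z2 + 0.5 * Z1
    for Z in (Z0, Z1, Z2, pi_hat):
        np.fill_diagonal(Z, np.nan)
    return KinshipEstimate(
        sample_ids=list(panel.sample_ids), Z0=Z0, Z1=Z1, Z2=Z2,
        pi_hat=pi_hat, n_shared=n_shared.astype(np.int64), min_shared=min_shared,
    )
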