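"""Genotype panel container: samples x markers dosage matrix with a marker map.

The panel is the in-memory currency of the whole pipeline.  Dosages are
alternate-allele counts in {0, 1, 2}; missing calls are stored as -1.
Allele frequencies are always computed on the non-missing calls of the
current panel, so any subsetting automatically refreshes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypePanel:
    """SNP dosage matrix with sample labels and a physical marker map.

    Parameters
    ----------
    sample_ids:
        Ordered sample labels, one per dosage row.
    markers:
        DataFrame with columns ``chrom`` (string label), ``pos`` (1-based bp,
        strictly increasing within each chromosome) and optionally
        ``is_snp`` (False for multiallelic/indel records slated for removal
        by marker QC; defaults to True).
    dosages:
        ``(n_samples, n_markers)`` int8 array of alternate-allele counts,
        ``MISSING`` (-1) where the genotype call is absent.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) == 0:
            raise ValueError("panel must contain at least one sample")
        if len(self.markers) == 0:
            raise ValueError("panel must contain at least one marker")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.markers = self.markers.reset_index(drop=True)
        if "is_snp" not in self.markers.columns:
            self.markers = self.markers.assign(is_snp=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def called(self) -> np.ndarray:
        """Boolean (samples x markers) mask of non-missing calls."""
        return self.dosages != MISSING

    # -- per-marker / per-sample statistics -----------------------------
    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, over non-missing calls."""
        called = self.called
        n = called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def marker_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called.mean(axis=1)

    def n_called(self) -> np.ndarray:
        """Non-missing genotype count per marker (n_l)."""
        return self.called.sum(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypePanel":
        """Return a new panel restricted to the given sample/marker indices.

        Indices may be integer arrays or boolean masks; marker order must be
        preserved (the map stays position-sorted).
        """
        s_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        if m_idx.dtype == bool:
            m_idx = np.flatnonzero(m_idx)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in s_idx],
            markers=self.markers.iloc[m_idx],
            dosages=self.dosages[np.ix_(s_idx, m_idx)],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypePanel":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in order]
        if missing:
            raise KeyError(f"samples not in panel: {missing}")
        return self.subset(sample_idx=np.array([order[s] for s in ids]))

    def sample_index(self, ids) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([order[s] for s in ids])
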