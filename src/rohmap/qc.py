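"""Marker and sample quality control.

Marker filters keep biallelic SNPs with minor allele frequency strictly
above ``maf_min`` and call rate strictly above ``call_min``; sample
filtering keeps samples with overall call rate strictly above
``sample_call_min``.  Filters are applied markers-first, and allele
frequencies are recomputed after every subsetting step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel


@dataclass
class QCReport:
    """Bookkeeping for one filtering step (counts reconcile exactly)."""

    markers_in: int
    markers_out: int
    samples_in: int
    samples_out: int
    removed_sample_ids: list[str] = field(default_factory=list)
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.markers_out <= self.markers_in
        assert self.samples_out <= self.samples_in
        assert self.samples_in - self.samples_out == len(self.removed_sample_ids)


def filter_markers(
    panel: GenotypePanel, maf_min: float = 0.05, call_min: float = 0.7
) -> tuple[GenotypePanel, QCReport]:
    """Keep biallelic SNP markers with MAF > maf_min and call rate > call_min."""
    is_snp = panel.markers["is_snp"].to_numpy(dtype=bool)
    maf_ok = panel.maf > maf_min
    call_ok = panel.marker_call_rate() > call_min
    keep = is_snp & maf_ok & call_ok
    if not keep.any():
        n_maf = int((is_snp & ~maf_ok).sum())
        n_call = int((is_snp & ~call_ok).sum())
        stricter = "maf_min" if n_maf >= n_call else "call_min"
        raise ValueError(
            f"marker filtering removed all {panel.n_markers} markers "
            f"(strictest filter: {stricter}; maf fails {n_maf}, call-rate fails {n_call})"
        )
    out = panel.subset(marker_idx=keep)
    report = QCReport(
        markers_in=panel.n_markers,
        markers_out=out.n_markers,
        samples_in=panel.n_samples,
        samples_out=out.n_samples,
        filter_params={"maf_min": maf_min, "marker_call_min": call_min},
    )
    return out, report


def filter_samples(
    panel: GenotypePanel, sample_call_min: float = 0.6
) -> tuple[GenotypePanel, QCReport]:
    """Keep samples with overall SNP call rate > sample_call_min."""
    keep = panel.sample_call_rate() > sample_call_min
    if not keep.any():
        raise ValueError(
            f"sample filtering removed all {panel.n_samples} samples "
            f"(sample_call_min={sample_call_min})"
        )
    removed = [s for s, k in zip(panel.sample_ids, keep) if not k]
    out = panel.subset(sample_idx=keep)
    report = QCReport(
        markers_in=panel.n_markers,
        markers_out=out.n_markers,
        samples_in=panel.n_samples,
        samples_out=out.n_samples,
        removed_sample_ids=removed,
        filter_params={"sample_call_min": sample_call_min},
    )
    return out, report


def qc_pipeline(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    call_min: float = 0.7,
    sample_call_min: float = 0.6,
) -> tuple[GenotypePanel, list[QCReport]]:
    """Markers first, then samples (fixed order); reports for both steps."""
    p1, r1 = filter_markers(panel, maf_min=maf_min, call_min=call_min)
    p2, r2 = filter_samples(p1, sample_call_min=sample_call_min)
    return p2, [r1, r2]
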