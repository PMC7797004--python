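"""VCF input/output for genotype panels.

Reading goes through cyvcf2; writing emits a minimal GT-only VCF 4.2 text
file so that a filtered panel can be fed back into any downstream tool.
Chromosome labels are normalised to bare "1".."8"; records on other contigs
are dropped with a warning (the downstream homozygosity analyses are defined
on the eight nuclear chromosomes only).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

VALID_CHROMS = tuple(str(c) for c in range(1, 9))
_SNP_ALLELES = {"A", "C", "G", "T"}


def _normalize_chrom(label: str) -> str | None:
    """Map contig names like 'chr2', 'Pd02' or '2' onto '1'..'8'."""
    m = re.search(r"(\d+)$", label)
    if m is None:
        return None
    c = str(int(m.group(1)))
    return c if c in VALID_CHROMS else None


def read_vcf(path: str) -> GenotypePanel:
    """Read a multi-sample VCF into a :class:`GenotypePanel`.

    Biallelic SNP records become dosage columns (alternate-allele counts);
    multiallelic and indel records are kept but flagged ``is_snp=False`` so
    that marker QC removes them.  Phased and unphased calls are treated
    identically; half-missing diploid calls count as missing.
    """
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    chroms: list[str] = []
    positions: list[int] = []
    is_snp: list[bool] = []
    rows: list[np.ndarray] = []
    n_dropped_contig = 0
    for v in vcf:
        chrom = _normalize_chrom(v.CHROM)
        if chrom is None:
            n_dropped_contig += 1
            continue
        alts = [a for a in v.ALT if a not in (None, ".")]
        snp = (
            len(alts) == 1
            and v.REF in _SNP_ALLELES
            and alts[0] in _SNP_ALLELES
        )
        gt = np.asarray(v.genotype.array())  # (n_samples, ploidy+1); last col = phased
        alleles = gt[:, :2]
        dos = (alleles == 1).sum(axis=1).astype(np.int8)
        dos[(alleles < 0).any(axis=1)] = MISSING  # half-missing -> missing
        chroms.append(chrom)
        positions.append(v.POS)
        is_snp.append(snp)
        rows.append(dos)
    vcf.close()
    if n_dropped_contig:
        logger.warning("dropped %d records on contigs outside 1-8", n_dropped_contig)
    if not rows:
        raise ValueError(f"{path}: no usable records on chromosomes 1-8")

    markers = pd.DataFrame({"chrom": chroms, "pos": positions, "is_snp": is_snp})
    dosages = np.stack(rows, axis=1)
    # enforce position sorting within chromosome, preserving chromosome order
    order = np.lexsort((markers["pos"].to_numpy(),
                        markers["chrom"].astype(int).to_numpy()))
    markers = markers.iloc[order]
    dosages = dosages[:, order]
    return GenotypePanel(sample_ids=samples, markers=markers, dosages=dosages)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as a GT-only VCF 4.2 text file.

    Alleles are synthesised as REF=A, ALT=C (dosage semantics only); a
    read/write round trip reproduces the dosage matrix exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohmap\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(set(panel.markers["chrom"]), key=int):
            length = int(panel.markers.loc[panel.markers["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_markers):
            chrom = panel.markers.at[j, "chrom"]
            pos = panel.markers.at[j, "pos"]
            calls = "\t".join(_GT_STR[int(g)] for g in panel.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\tS{chrom}_{pos}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")
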