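"""End-to-end pipeline: QC -> dedup -> structure/LD -> kinship -> ROH ->
BLUP -> homozygosity mapping -> GWAS, with a manifest for reproducibility.

Every stage writes plain TSV (or VCF) files into the output directory so
any stage can be re-run standalone; the manifest records each file's SHA256
together with the full parameter set actually used.  Stages can be toggled
off; a stage whose inputs are missing (because its producer was disabled)
is skipped with a log message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dedup as dedup_mod
from . import gwas as gwas_mod
from . import hm as hm_mod
from . import io as io_mod
from . import phenotypes as phe_mod
from . import qc as qc_mod
from . import roh as roh_mod
from . import structure as struct_mod

logger = logging.getLogger(__name__)

STAGES = ("qc", "dedup", "structure", "kinship", "roh", "blup", "hm", "gwas")


@dataclass
class PipelineConfig:
    vcf: str = ""
    phenotypes: str = ""               # long CSV/TSV: genotype,year,trait,value
    replicates: str = ""               # TSV: id1,id2 per known replicate pair
    out_dir: str = "rohmap_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # QC
    maf_min: float = 0.05
    marker_call_min: float = 0.7
    sample_call_min: float = 0.6
    # pruning / PCA / LD decay
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.5
    n_pcs: int = 5
    ld_max_dist: int = 100_000
    ld_pair_cap: int = 100_000
    # ROH / clusters
    roh_maf_min: float = 0.15
    roh_min_snps: int = 15
    roh_min_length: int = 100_000
    roh_max_gap: int = 1_000_000
    cluster_min_carriers: int = 10
    # association
    fdr_alpha: float = 0.1
    ibs_threshold: float | None = None  # dedup fallback without replicates

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.stages = {**{s: True for s in STAGES}, **cfg.stages}
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Out:
    def __init__(self, out_dir: Path):
        self.dir = out_dir
        self.files: dict[str, str] = {}

    def tsv(self, name: str, df: pd.DataFrame, stage: str, index=False):
        path = self.dir / name
        df.to_csv(path, sep="\t", index=index)
        self.files[name] = stage

    def path(self, name: str, stage: str) -> Path:
        self.files[name] = stage
        return self.dir / name


def load_phenotypes(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = {"genotype", "year", "trait", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(need)}")
    return df


def load_replicate_pairs(path: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    out = _Out(Path(cfg.out_dir))
    out.dir.mkdir(parents=True, exist_ok=True)
    on = {s: cfg.stages.get(s, True) for s in STAGES}
    state: dict = {}

    try:
        if on["qc"]:
            panel = io_mod.read_vcf(cfg.vcf)
            panel, reports = qc_mod.qc_pipeline(
                panel, cfg.maf_min, cfg.marker_call_min, cfg.sample_call_min)
            io_mod.write_vcf(panel, out.path("filtered.vcf", "qc"))
            out.tsv("qc_report.tsv", pd.DataFrame(
                [dataclasses.asdict(r) for r in reports]), "qc")
            state["panel"] = panel

        if on["dedup"] and "panel" in state:
            panel = state["panel"]
            ibs = dedup_mod.ibs_matrix(panel)
            out.tsv("ibs_matrix.tsv", ibs.to_frame(), "dedup", index=True)
            state["ibs"] = ibs
            reps = load_replicate_pairs(cfg.replicates) if cfg.replicates else None
            if reps or cfg.ibs_threshold is not None:
                call = dict(zip(panel.sample_ids, panel.sample_call_rate()))
                grouping = dedup_mod.clonal_groups(
                    ibs, reps, call, threshold=cfg.ibs_threshold)
                out.tsv("clonal_groups.tsv", grouping.to_frame(), "dedup")
                panel = dedup_mod.deduplicate(panel, grouping)
                ibs = dedup_mod.ibs_matrix(panel)
                state.update(panel=panel, ibs=ibs, grouping=grouping)
            else:
                logger.info("dedup: no replicate file or threshold; panel unchanged")

        if on["structure"] and "panel" in state:
            panel = state["panel"]
            pruned = struct_mod.ld_prune(
                panel, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
            io_mod.write_vcf(pruned, out.path("pruned.vcf", "structure"))
            pcs = struct_mod.pca(pruned, n_components=min(cfg.n_pcs,
                                                          panel.n_samples - 1))
            out.tsv("pcs.tsv", pcs.to_frame(), "structure", index=True)
            decay = struct_mod.ld_decay(
                panel, max_dist=cfg.ld_max_dist,
                pair_cap_per_chrom=cfg.ld_pair_cap,
                threshold_pairs=cfg.ld_pair_cap, seed=cfg.seed)
            out.tsv("ld_decay_pairs.tsv", decay.pairs, "structure")
            out.tsv("ld_per_chrom_r2.tsv",
                    decay.per_chrom_mean_r2.rename_axis("chrom").reset_index(),
                    "structure")
            out.tsv("ld_decay_fit.tsv", pd.DataFrame([{
                "rho": decay.rho, "n": decay.n,
                "threshold_r2": decay.threshold_r2,
                "decay_distance": decay.decay_distance}]), "structure")
            state.update(pruned=pruned, pcs=pcs, decay=decay)

        if on["kinship"] and "pruned" in state:
            from . import kinship as kin_mod
            kin = kin_mod.ibd_mom(state["pruned"])
            out.tsv("kinship_pairs.tsv", kin.to_frame(), "kinship")
            out.tsv("pi_hat_matrix.tsv",
                    pd.DataFrame(kin.pi_hat, index=kin.sample_ids,
                                 columns=kin.sample_ids), "kinship", index=True)
            state["kinship"] = kin

        if on["roh"] and "panel" in state:
            panel = state["panel"]
            det = roh_mod.roh_marker_subset(panel, cfg.roh_maf_min)
            rohs = roh_mod.detect_rohs(
                det, min_snps=cfg.roh_min_snps, min_length=cfg.roh_min_length,
                max_gap=cfg.roh_max_gap, subset_markers=False)
            out.tsv("roh.tsv", rohs, "roh")
            bed = rohs.assign(start0=rohs["start"] - 1)[
                ["chrom", "start0", "end", "sample", "n_snps", "n_missing"]]
            out.tsv("roh.bed", bed, "roh")
            f = roh_mod.f_plink(state.get("pruned", panel))
            summary, stats = roh_mod.inbreeding_report(rohs, f)
            out.tsv("inbreeding.tsv", summary, "roh", index=True)
            out.tsv("inbreeding_regressions.tsv",
                    pd.DataFrame(stats).T.rename_axis("response").reset_index(),
                    "roh")
            state.update(rohs=rohs, detection_markers=det.markers, f_plink=f)

        if on["blup"] and cfg.phenotypes:
            records = phe_mod.derive_shell(load_phenotypes(cfg.phenotypes))
            blups, comps = {}, []
            for trait in sorted(records["trait"].unique()):
                fit = phe_mod.fit_blup(records, trait)
                blups[trait] = fit.blups
                ks_stat, ks_p = phe_mod.ks_normality(fit.blups.to_numpy())
                comps.append({
                    "trait": trait, "sigma2_g": fit.sigma2_g,
                    "sigma2_y": fit.sigma2_y, "sigma2_e": fit.sigma2_e,
                    "reml_loglik": fit.reml_loglik, "converged": fit.converged,
                    "ks_stat": ks_stat, "ks_p": ks_p})
            blup_df = pd.DataFrame(blups)
            out.tsv("blups.tsv", blup_df, "blup", index=True)
            out.tsv("variance_components.tsv", pd.DataFrame(comps), "blup")
            out.tsv("trait_relations.tsv", phe_mod.trait_relations(blup_df), "blup")
            state["blups"] = blup_df

        if on["hm"] and {"rohs", "blups", "pcs"} <= state.keys():
            blup_df = state["blups"]
            pheno_ids = [s for s in state["panel"].sample_ids
                         if s in blup_df.index]
            clusters = hm_mod.find_clusters(
                state["rohs"], state["detection_markers"], pheno_ids,
                min_carriers=cfg.cluster_min_carriers,
                min_length=cfg.roh_min_length)
            out.tsv("roh_clusters.tsv", pd.DataFrame([{
                "cluster": c.id, "chrom": c.chrom, "start": c.start,
                "end": c.end, "n_carriers": len(c.carriers),
                "n_loci": c.n_loci} for c in clusters]), "hm")
            assoc = hm_mod.hm_test(
                clusters, blup_df.loc[pheno_ids],
                state["pcs"].to_frame(), n_pcs=cfg.n_pcs,
                fdr_alpha=cfg.fdr_alpha)
            out.tsv("hm_association.tsv", assoc, "hm")
            ttests = []
            for c in clusters:
                for trait in blup_df.columns:
                    row = hm_mod.carrier_ttest(c, blup_df.loc[pheno_ids, trait])
                    row["trait"] = trait
                    ttests.append(row)
            out.tsv("hm_group_means.tsv", pd.DataFrame(ttests), "hm")
            state.update(clusters=clusters, hm=assoc)

        if on["gwas"] and {"blups", "ibs"} <= state.keys():
            blup_df = state["blups"]
            K = state["ibs"].values
            for trait in blup_df.columns:
                res = gwas_mod.emmax_gwas(
                    state["panel"], blup_df[trait], K, fdr_alpha=cfg.fdr_alpha)
                out.tsv(f"gwas_{trait}.tsv", res.table, "gwas")
                state[f"gwas_{trait}"] = res
    except Exception:
        logger.exception("pipeline halted; partial outputs kept in %s", out.dir)
        raise

    manifest = {
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "files": {name: {"stage": stage, "sha256": _sha256(out.dir / name)}
                  for name, stage in sorted(out.files.items())},
    }
    with open(out.dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
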