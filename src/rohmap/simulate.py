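"""Seeded simulation of germplasm panels and multi-year phenotypes.

The generator emulates the statistical structure a GBS germplasm panel
presents to the pipeline: several differentiated subpopulations (founder
allele frequencies via the Balding-Nichols construction), a pedigree layer
(parent-offspring pairs, full sibs, lines selfed for g generations carrying
long autozygous tracts), clonal replicates with genotyping error, GBS-like
heterozygote under-calling, missingness, additive QTLs for nut and seed
weight (shell = nut - seed), and crossed genotype/year phenotype records.

All randomness flows from a single seed; truth tables (pedigree F,
relationships, QTL positions, subpopulation and clone labels) are returned
alongside the panel for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class QTL:
    trait: str
    chrom: str
    rel_pos: float      # position along the chromosome in (0, 1)
    effect: float       # additive effect per alternate allele, grams


@dataclass
class SimConfig:
    seed: int = 0
    # genome / markers
    n_chrom: int = 8
    markers_per_chrom: int = 500
    chrom_length: int = 25_000_000
    # population
    n_founders: int = 100
    n_subpops: int = 4
    fst: float = 0.1
    # pedigree layer
    n_parent_offspring: int = 8
    n_full_sib_pairs: int = 4
    selfing_generations: tuple[int, ...] = (2, 3, 3, 4, 5, 5)
    # clonal replicates (one group of 3 plus groups of 2, as in GBS panels
    # that include repeated accessions)
    clone_group_sizes: tuple[int, ...] = (3, 2, 2, 2, 2, 2)
    # genotyping artifacts
    genotype_error_rate: float = 0.005
    het_undercall_rate: float = 0.0
    missing_rate: float = 0.1
    # recombination
    crossovers_per_chrom: float = 1.0
    poisson_crossovers: bool = False
    # phenotypes
    years: tuple[int, ...] = (2006, 2007, 2009, 2012)
    trait_means: dict = field(default_factory=lambda: {"nut": 4.5, "seed": 1.2})
    variances: dict = field(default_factory=lambda: {
        "nut": (1.0, 0.3, 0.2), "seed": (0.06, 0.02, 0.01)})
    qtls: tuple[QTL, ...] = (
        QTL("nut", "1", 0.45, 0.6), QTL("nut", "2", 0.60, 0.5),
        QTL("nut", "7", 0.35, 0.4),
        QTL("seed", "1", 0.10, 0.15), QTL("seed", "6", 0.80, 0.12),
    )

    def validate(self) -> None:
        for r in (self.fst, self.genotype_error_rate, self.het_undercall_rate,
                  self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.fst <= 0.5:
            raise ValueError("fst must lie in [0, 0.5]")
        if self.n_subpops < 1 or self.n_founders < self.n_subpops:
            raise ValueError("need at least one founder per subpopulation")


def tiny_config(seed: int = 0) -> SimConfig:
    """20 samples x 2,000 markers: smoke-test preset."""
    return SimConfig(seed=seed, markers_per_chrom=250, n_founders=14,
                     n_subpops=2, n_parent_offspring=2, n_full_sib_pairs=1,
                     selfing_generations=(3,), clone_group_sizes=(2,))


def study_like_config(seed: int = 0) -> SimConfig:
    """~130 distinct samples x 50,000 markers: full-scale preset."""
    return SimConfig(seed=seed, markers_per_chrom=6250, n_founders=110,
                     n_subpops=4)


@dataclass
class TruthTables:
    samples: pd.DataFrame      # id, subpop, pedigree_f, clone_of
    pairs: pd.DataFrame        # id1, id2, relation
    qtls: pd.DataFrame         # trait, chrom, pos, marker_index, effect
    genetic_values: pd.DataFrame | None = None   # per sample x trait


# ------------------------------------------------------------ genotypes --

def _marker_map(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        pos = np.sort(rng.choice(
            np.arange(1, cfg.chrom_length), size=cfg.markers_per_chrom,
            replace=False))
        rows.append(pd.DataFrame({"chrom": str(c), "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def _chrom_slices(markers: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    out = []
    for _, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        out.append((slice(idx[0], idx[-1] + 1), sub["pos"].to_numpy()))
    return out


def _gamete(haps: np.ndarray, chrom_slices, cfg: SimConfig, rng) -> np.ndarray:
    """One meiotic product of a (2, L) haplotype pair."""
    L = haps.shape[1]
    out = np.empty(L, dtype=np.int8)
    for sl, pos in chrom_slices:
        k = (rng.poisson(cfg.crossovers_per_chrom) if cfg.poisson_crossovers
             else int(round(cfg.crossovers_per_chrom)))
        cuts = np.sort(rng.uniform(1, cfg.chrom_length, size=k))
        phase = int(rng.integers(2))
        source = (phase + np.searchsorted(cuts, pos)) % 2
        seg = haps[:, sl]
        out[sl] = seg[source, np.arange(sl.stop - sl.start)]
    return out


def simulate_panel(cfg: SimConfig) -> tuple[GenotypePanel, TruthTables]:
    """Generate the genotype panel and its truth tables (deterministic per seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    L = len(markers)
    chrom_slices = _chrom_slices(markers)

    # Balding-Nichols subpopulation frequencies around a shared ancestral pool
    p_anc = rng.uniform(0.1, 0.9, size=L)
    if cfg.fst > 0:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        p_sub = np.clip(rng.beta(a, b, size=(cfg.n_subpops, L)), 0.01, 0.99)
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    haplos: dict[str, np.ndarray] = {}
    sample_rows = []
    pair_rows = []

    def add(sid, haps, subpop, pedigree_f=0.0, clone_of=""):
        haplos[sid] = haps
        sample_rows.append({"id": sid, "subpop": subpop,
                            "pedigree_f": pedigree_f, "clone_of": clone_of})

    founders_by_pop: list[list[str]] = [[] for _ in range(cfg.n_subpops)]
    for i in range(cfg.n_founders):
        pop = i % cfg.n_subpops
        sid = f"FND{i:03d}"
        haps = (rng.random((2, L)) < p_sub[pop]).astype(np.int8)
        add(sid, haps, pop)
        founders_by_pop[pop].append(sid)

    # parent-offspring: child of two random founders from the same subpop
    for i in range(cfg.n_parent_offspring):
        pop = i % cfg.n_subpops
        pa, pb = rng.choice(founders_by_pop[pop], size=2, replace=False)
        sid = f"PO{i:02d}"
        child = np.stack([
            _gamete(haplos[pa], chrom_slices, cfg, rng),
            _gamete(haplos[pb], chrom_slices, cfg, rng),
        ])
        add(sid, child, pop)
        pair_rows.append({"id1": pa, "id2": sid, "relation": "parent_offspring"})
        pair_rows.append({"id1": pb, "id2": sid, "relation": "parent_offspring"})

    # full-sib pairs: two children of the same founder couple
    for i in range(cfg.n_full_sib_pairs):
        pop = i % cfg.n_subpops
        pa, pb = rng.choice(founders_by_pop[pop], size=2, replace=False)
        sibs = []
        for k in range(2):
            sid = f"SIB{i:02d}{'AB'[k]}"
            child = np.stack([
                _gamete(haplos[pa], chrom_slices, cfg, rng),
                _gamete(haplos[pb], chrom_slices, cfg, rng),
            ])
            add(sid, child, pop)
            sibs.append(sid)
            pair_rows.append({"id1": pa, "id2": sid, "relation": "parent_offspring"})
            pair_rows.append({"id1": pb, "id2": sid, "relation": "parent_offspring"})
        pair_rows.append({"id1": sibs[0], "id2": sibs[1], "relation": "full_sib"})

    # selfed lines: g generations of selfing from one founder
    for i, g in enumerate(cfg.selfing_generations):
        pop = i % cfg.n_subpops
        base = rng.choice(founders_by_pop[pop])
        cur = haplos[base]
        for _ in range(g):
            cur = np.stack([
                _gamete(cur, chrom_slices, cfg, rng),
                _gamete(cur, chrom_slices, cfg, rng),
            ])
        add(f"INB{i:02d}g{g}", cur, pop, pedigree_f=1.0 - 0.5**g)

    # clonal replicates copy an existing accession's genotype
    non_clone_ids = [r["id"] for r in sample_rows]
    sources = rng.choice(non_clone_ids, size=len(cfg.clone_group_sizes),
                         replace=False)
    for src, size in zip(sources, cfg.clone_group_sizes):
        reps = [src]
        for k in range(1, size):
            sid = f"{src}rep{k}"
            add(sid, haplos[src].copy(),
                next(r["subpop"] for r in sample_rows if r["id"] == src),
                clone_of=src)
            reps.append(sid)
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                pair_rows.append({"id1": reps[a], "id2": reps[b],
                                  "relation": "replicate"})

    ids = [r["id"] for r in sample_rows]
    dosages = np.stack([haplos[s].sum(axis=0) for s in ids]).astype(np.int8)

    # genotyping artifacts: random dosage errors, het under-calling, missingness
    if cfg.genotype_error_rate > 0:
        err = rng.random(dosages.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=dosages.shape)
        dosages = np.where(err, (dosages + shift) % 3, dosages).astype(np.int8)
    if cfg.het_undercall_rate > 0:
        flip = (dosages == 1) & (rng.random(dosages.shape) < cfg.het_undercall_rate)
        hom = rng.integers(0, 2, size=dosages.shape) * 2
        dosages = np.where(flip, hom, dosages).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = MISSING

    qtl_rows = []
    for q in cfg.qtls:
        sub = markers[markers["chrom"] == q.chrom]
        target = int(q.rel_pos * cfg.chrom_length)
        m_idx = int(sub.index[np.argmin(np.abs(sub["pos"].to_numpy() - target))])
        qtl_rows.append({"trait": q.trait, "chrom": q.chrom,
                         "pos": int(markers.at[m_idx, "pos"]),
                         "marker_index": m_idx, "effect": q.effect})

    panel = GenotypePanel(sample_ids=ids, markers=markers, dosages=dosages)
    truth = TruthTables(
        samples=pd.DataFrame(sample_rows),
        pairs=pd.DataFrame(pair_rows, columns=["id1", "id2", "relation"]),
        qtls=pd.DataFrame(qtl_rows,
                          columns=["trait", "chrom", "pos", "marker_index", "effect"]),
    )
    return panel, truth


# ----------------------------------------------------------- phenotypes --

def simulate_phenotypes(
    panel: GenotypePanel, truth: TruthTables, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format records (genotype, year, trait, value); shell = nut - seed.

    The genetic value of a sample is the sum of its QTL dosage effects plus
    a polygenic N(0, sigma2_G) term; clonal replicates inherit the genetic
    value of their source.  Each yearly record adds a year effect
    N(0, sigma2_Y) and a residual N(0, sigma2_E).  Clone replicate copies
    themselves are not phenotyped (records are clone means per accession).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    clone_of = dict(zip(truth.samples["id"], truth.samples["clone_of"]))
    pheno_ids = [s for s in panel.sample_ids if not clone_of.get(s, "")]
    idx = panel.sample_index(pheno_ids)

    records = []
    gv_rows = {}
    for trait in cfg.trait_means:
        if trait not in cfg.variances:
            raise ValueError(f"no variance specification for trait {trait}")
        s2g, s2y, s2e = cfg.variances[trait]
        qtls = truth.qtls[truth.qtls["trait"] == trait]
        gv = np.zeros(len(pheno_ids))
        for q in qtls.itertuples():
            d = panel.dosages[idx, q.marker_index].astype(float)
            d[d == MISSING] = np.nan
            # truth uses the error-free mean-imputed dosage for missing calls
            d = np.where(np.isnan(d), np.nanmean(d), d)
            gv += q.effect * d
        gv += rng.normal(0.0, np.sqrt(s2g), size=len(pheno_ids))
        gv_rows[trait] = pd.Series(gv, index=pheno_ids)
        year_eff = rng.normal(0.0, np.sqrt(s2y), size=len(cfg.years))
        for yi, year in enumerate(cfg.years):
            resid = rng.normal(0.0, np.sqrt(s2e), size=len(pheno_ids))
            vals = cfg.trait_means[trait] + gv + year_eff[yi] + resid
            for s, v in zip(pheno_ids, vals):
                records.append({"genotype": s, "year": year,
                                "trait": trait, "value": float(v)})
    df = pd.DataFrame(records)
    # shell is defined as the within-record difference nut - seed
    wide = df.pivot_table(index=["genotype", "year"], columns="trait",
                          values="value").reset_index()
    if {"nut", "seed"}.issubset(wide.columns):
        shell = wide.assign(trait="shell", value=wide["nut"] - wide["seed"])
        df = pd.concat(
            [df, shell[["genotype", "year", "trait", "value"]]],
            ignore_index=True)
    truth.genetic_values = pd.DataFrame(gv_rows)
    return df.sort_values(["trait", "genotype", "year"]).reset_index(drop=True)


# ------------------------------------------------- unlinked pair cohorts --

def simulate_unlinked_pairs(
    n_pairs: int = 100,
    n_loci: int = 500,
    relation: str = "parent_offspring",
    freq_low: float = 0.1,
    freq_high: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypePanel, np.ndarray, list[tuple[str, str]]]:
    """Cohort of independent pairs at unlinked loci with known frequencies.

    ``relation`` is one of parent_offspring, full_sib, half_sib, unrelated
    or duplicate.  Returns the panel, the true allele frequencies, and the
    list of (id1, id2) pairs.  No genotyping error or missingness.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(freq_low, freq_high, size=n_loci)

    def hap():
        return (rng.random((n_pairs, n_loci)) < p).astype(np.int8)

    def transmit(h1, h2):
        """One allele per locus from a parent's two haplotypes."""
        pick = rng.integers(2, size=(n_pairs, n_loci))
        return np.where(pick == 0, h1, h2)

    pa1, pa2 = hap(), hap()           # parent/founder A
    pb1, pb2 = hap(), hap()           # parent/founder B
    if relation == "parent_offspring":
        g1 = pa1 + pa2
        g2 = transmit(pa1, pa2) + hap()  # other allele drawn from the pool
    elif relation == "full_sib":
        g1 = transmit(pa1, pa2) + transmit(pb1, pb2)
        g2 = transmit(pa1, pa2) + transmit(pb1, pb2)
    elif relation == "half_sib":
        g1 = transmit(pa1, pa2) + hap()
        g2 = transmit(pa1, pa2) + hap()
    elif relation == "unrelated":
        g1 = pa1 + pa2
        g2 = pb1 + pb2
    elif relation == "duplicate":
        g1 = pa1 + pa2
        g2 = g1.copy()
    else:
        raise ValueError(f"unknown relation {relation!r}")

    ids, rows, pairs = [], [], []
    for k in range(n_pairs):
        a, b = f"P{k:03d}a", f"P{k:03d}b"
        ids += [a, b]
        rows += [g1[k], g2[k]]
        pairs.append((a, b))
    markers = pd.DataFrame({
        "chrom": "1", "pos": (np.arange(n_loci) + 1) * 2_000_000})
    panel = GenotypePanel(sample_ids=ids, markers=markers,
                          dosages=np.stack(rows).astype(np.int8))
    return panel, p, pairs
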