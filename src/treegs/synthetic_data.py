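"""Synthetic two-generation, multi-site breeding populations.

The generator emulates the structure of a conifer progeny-trial study: a
small founder pool (P0) crossed into ~37 full-sib F1 families replicated
over three sites, a subset of F1 individuals reused as parents of an F2
progeny trial on a fourth site, biallelic SNP genotypes, and phenotypes for
a juvenile-height trait (measured in both generations) plus a mature-height
trait (F1 only) carrying the full variance structure of the evaluation
model: additive, site x additive, block-within-site, site x family, family
and per-site residual components.

Because reusing a ~30-founder pool across 37 crosses concentrates
coancestry, the F1 group has a status-number effective population size near
20 — the low-Ne regime in which marker-based prediction is driven by
relatedness rather than marker-QTL linkage disequilibrium.  Markers are
unlinked by default and the causal loci (QTL) are *not* in the marker panel,
making relatedness the only usable signal; an optional block-LD mode places
loci on linked blocks (founder haplotypes drawn from a small per-block pool,
crossovers between adjacent loci) so that marker density experiments have
genuine LD to exploit.

Juvenile and mature height share QTL with correlated effect sizes
(default genetic correlation 0.7), emulating an imperfect age-age
relationship.

A single master seed fans out to named sub-streams (founders, gene drop,
effects, design, noise) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_founders",
    "drop_genes",
    "assign_qtl_effects",
    "true_breeding_values",
    "simulate_phenotypes",
    "build_study_bundle",
    "build_two_cluster_bundle",
]


@dataclass
class SimulationConfig:
    """Parameters of the simulated breeding study.

    Defaults mirror the emulated design: 37 F1 full-sib families from a
    30-founder pool planted on 3 sites (449/441/431 trees), 42 F2 families
    from 17 F1 parents on one site (247 trees, 136 genotyped), per-site
    juvenile-height heritabilities of 0.19/0.22/0.13 (F1) and 0.39 (F2).
    Variance components are in squared trait units (cm^2).
    """

    n_founders: int = 30
    n_f1_families: int = 37
    f1_site_sizes: tuple = (449, 441, 431)
    n_f2_families: int = 42
    n_f2_parents: int = 17
    f2_size: int = 247
    f2_genotyped: int = 136
    n_markers: int = 2000
    n_qtl: int = 100
    qtl_observed: bool = False       # True: QTL loci are part of the marker panel
    maf_range: tuple = (0.05, 0.5)
    sigma_a2: float = 400.0          # additive variance (sd 20 cm)
    ratio_site_additive: float = 0.3   # variances relative to sigma_a2
    ratio_block: float = 0.2
    ratio_site_family: float = 0.2
    ratio_family: float = 0.1
    h2_f1_sites: tuple = (0.19, 0.22, 0.13)
    h2_f2_site: float = 0.39
    h2_ht35: float = 0.25
    age_age_corr: float = 0.7        # genetic correlation juvenile vs mature height
    blocks_per_site: int = 10
    site_means_htj: tuple = (650.0, 640.0, 660.0)
    f2_site_mean_htj: float = 350.0
    mean_ht35: float = 2500.0
    beta_age: float = 30.0           # cm per year around age 10
    age_f1: float = 13.0
    age_f2: float = 7.0
    age_ht35: float = 35.0
    missing_rate: float = 0.01
    ld_blocks: int | None = None     # block-LD mode: number of linked blocks
    ld_haplotypes_per_block: int = 8
    recomb_rate: float = 0.02        # crossover prob between adjacent loci
    seed: int = 0

    @property
    def n_loci(self) -> int:
        return self.n_markers if self.qtl_observed else self.n_markers + self.n_qtl

    def validate(self) -> None:
        if not (0 < self.n_qtl <= self.n_loci):
            raise ValueError("n_qtl must be in (0, n_loci]")
        if any(not 0 < h < 1 for h in (*self.h2_f1_sites, self.h2_f2_site, self.h2_ht35)):
            raise ValueError("target h2 must be in (0, 1)")
        if min(*self.f1_site_sizes, self.f2_size) <= 0:
            raise ValueError("site sizes must be positive")
        if self.n_f2_parents < 2 or self.n_founders < 2:
            raise ValueError("parent pools must have at least two members")


def _streams(seed: int) -> dict:
    names = ["founders", "gene_drop", "effects", "design", "noise"]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ------------------------------------------------------------------ genotypes

def simulate_founders(config: SimulationConfig, rng: np.random.Generator):
    """Founder haplotypes: (n_founders, n_loci, 2) int8 alleles, plus the
    per-locus allele frequencies they were drawn from.

    Independent loci: each allele is Bernoulli(MAF_k) with
    MAF_k ~ Uniform over ``maf_range``.  In block-LD mode each block's
    founder haplotypes are copies of a small pool of ancestral haplotypes,
    which is what creates marker-marker and marker-QTL LD.
    """
    L = config.n_loci
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=L)
    n = config.n_founders
    if config.ld_blocks:
        H = np.empty((n, L, 2), dtype=np.int8)
        bounds = _block_bounds(L, config.ld_blocks)
        npool = config.ld_haplotypes_per_block
        for b0, b1 in bounds:
            pool = (rng.random((npool, b1 - b0)) < freqs[b0:b1]).astype(np.int8)
            pick = rng.integers(0, npool, size=(n, 2))
            H[:, b0:b1, 0] = pool[pick[:, 0]]
            H[:, b0:b1, 1] = pool[pick[:, 1]]
    else:
        H = (rng.random((n, L, 2)) < freqs[None, :, None]).astype(np.int8)
    return H, freqs


def _block_bounds(L: int, n_blocks: int):
    edges = np.linspace(0, L, n_blocks + 1).astype(int)
    return list(zip(edges[:-1], edges[1:]))


def drop_genes(
    parent_haplotypes: np.ndarray,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> np.ndarray:
    """Mendelian transmission: one gamete per parent per offspring.

    Unlinked mode samples each locus independently from the parent's two
    haplotypes; block-LD mode runs a two-state Markov chain along each block
    (switch probability = ``recomb_rate`` between adjacent loci).
    """
    if np.any(sire_idx < 0) or np.any(dam_idx < 0):
        raise ValueError("drop_genes: every offspring needs two genotyped parents")
    H = parent_haplotypes
    n_off = len(sire_idx)
    L = H.shape[1]
    out = np.empty((n_off, L, 2), dtype=np.int8)
    for which, pidx in ((0, sire_idx), (1, dam_idx)):
        if config.ld_blocks:
            state = _linked_gamete_states(n_off, L, config, rng)
        else:
            state = (rng.random((n_off, L)) < 0.5).astype(np.int8)
        ph = H[pidx]                          # (n_off, L, 2)
        out[:, :, which] = np.where(state == 0, ph[:, :, 0], ph[:, :, 1])
    return out


def _linked_gamete_states(n: int, L: int, config, rng) -> np.ndarray:
    state = np.empty((n, L), dtype=np.int8)
    for b0, b1 in _block_bounds(L, config.ld_blocks):
        w = b1 - b0
        switches = (rng.random((n, w)) < config.recomb_rate).astype(np.int8)
        switches[:, 0] = rng.integers(0, 2, size=n)  # independent start per block
        state[:, b0:b1] = np.cumsum(switches, axis=1) % 2
    return state


# ------------------------------------------------------------------ effects

def assign_qtl_effects(config: SimulationConfig, freqs: np.ndarray,
                       rng: np.random.Generator):
    """Sample QTL positions and bivariate (juvenile, mature) effect sizes.

    Effects are bivariate normal with correlation ``age_age_corr`` and are
    scaled so the expected additive variance ``sum_k 2 p_k q_k a_k^2`` equals
    ``sigma_a2`` for each trait.
    """
    L = len(freqs)
    qtl_idx = np.sort(rng.choice(L, size=config.n_qtl, replace=False))
    rho = config.age_age_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=config.n_qtl)
    w = 2.0 * freqs[qtl_idx] * (1.0 - freqs[qtl_idx])
    for t in range(2):
        var = float(np.sum(w * eff[:, t] ** 2))
        eff[:, t] *= np.sqrt(config.sigma_a2 / var)
    return qtl_idx, eff


def true_breeding_values(counts: np.ndarray, freqs: np.ndarray,
                         qtl_idx: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """TBV = sum over QTL of (allele count - 2p) x effect (per trait column)."""
    centered = counts[:, qtl_idx] - 2.0 * freqs[qtl_idx]
    return centered @ effects


# ------------------------------------------------------------------ phenotypes

def _pedigree_structured_effect(pedigree: Pedigree, sigma2: float,
                                rng: np.random.Generator) -> dict:
    """An additive-structured random effect over all pedigree members.

    Founders draw N(0, s2); offspring receive the parent average plus a
    Mendelian-sampling deviation of variance s2/2 (inbreeding ignored for
    this nuisance component).  Used for the site x additive interaction,
    which shares the pedigree covariance within each site.
    """
    values: dict = {}
    for r in pedigree.records.itertuples(index=False):
        parents = [values[p] for p in (r.sire, r.dam) if p is not None]
        if not parents:
            values[r.id] = rng.normal(0.0, np.sqrt(sigma2))
        else:
            pa = np.mean(parents) if len(parents) == 2 else 0.5 * parents[0]
            values[r.id] = pa + rng.normal(0.0, np.sqrt(sigma2 / 2.0))
    return values


def simulate_phenotypes(
    tbv: np.ndarray,
    design: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    h2_by_site: dict,
    site_means: dict,
    age_by_site: dict,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Phenotypes under the evaluation model's variance structure.

    ``design`` has columns id, site, block, family; one row per tree.  The
    residual variance of each site is solved from its target h2 under the
    heritability convention h2 = s2_a / (s2_a + s2_sa + s2_sf + s2_f + s2_e),
    so the block variance does not influence the target.  When a pedigree is
    supplied, the site x additive deviations are drawn with the pedigree's
    additive covariance within each site (independent across sites);
    otherwise they are iid.
    """
    s2a = config.sigma_a2
    s2sa = config.ratio_site_additive * s2a
    s2b = config.ratio_block * s2a
    s2sf = config.ratio_site_family * s2a
    s2f = config.ratio_family * s2a
    non_resid = s2a + s2sa + s2sf + s2f

    df = design.copy()
    n = len(df)
    y = np.asarray(tbv, dtype=float).copy()

    fam_levels = df["family"].unique()
    fam_eff = dict(zip(fam_levels, rng.normal(0, np.sqrt(s2f), len(fam_levels))))
    sf_levels = (df["site"] + "|" + df["family"]).unique()
    sf_eff = dict(zip(sf_levels, rng.normal(0, np.sqrt(s2sf), len(sf_levels))))
    blk_levels = (df["site"] + "|" + df["block"].astype(str)).unique()
    blk_eff = dict(zip(blk_levels, rng.normal(0, np.sqrt(s2b), len(blk_levels))))

    y += df["family"].map(fam_eff).to_numpy()
    y += (df["site"] + "|" + df["family"]).map(sf_eff).to_numpy()
    y += (df["site"] + "|" + df["block"].astype(str)).map(blk_eff).to_numpy()
    if s2sa > 0:
        if pedigree is not None:
            for site in df["site"].unique():
                vals = _pedigree_structured_effect(pedigree, s2sa, rng)
                mask = (df["site"] == site).to_numpy()
                y[mask] += np.array([vals[i] for i in df.loc[mask, "id"]])
        else:
            y += rng.normal(0, np.sqrt(s2sa), n)

    ages = df["site"].map(age_by_site).astype(float)
    y += df["site"].map(site_means).astype(float).to_numpy()
    y += config.beta_age * (ages.to_numpy() - 10.0)

    resid = np.empty(n)
    for site, h2 in h2_by_site.items():
        s2e = s2a / h2 - non_resid
        if s2e < 0:
            raise ValueError(
                f"target h2={h2} infeasible for site {site!r} given variance ratios"
            )
        mask = (df["site"] == site).to_numpy()
        resid[mask] = rng.normal(0, np.sqrt(s2e), mask.sum()) if s2e > 0 else 0.0
    y += resid

    out = df[["id", "site", "block", "family"]].copy()
    out["age"] = ages.to_numpy()
    out["trait"] = y
    return out


# ------------------------------------------------------------------ the bundle

@dataclass
class StudyBundle:
    """Everything the downstream pipeline needs, in memory."""

    config: SimulationConfig
    pedigree: Pedigree
    phenotypes_htj: pd.DataFrame      # F1 (3 sites) + F2 (1 site)
    phenotypes_ht35: pd.DataFrame     # F1 only
    genotypes_f1: pd.DataFrame        # raw counts, NaN = missing
    genotypes_f2: pd.DataFrame
    truth: pd.DataFrame               # id, generation, tbv/ms per trait, genotyped
    qtl: pd.DataFrame                 # locus, effects (hidden loci unless observed)
    f1_ids: list = field(default_factory=list)          # genotyped F1
    f2_ids: list = field(default_factory=list)          # genotyped F2 (validation)
    f2_parents: list = field(default_factory=list)

    @property
    def marker_names(self) -> list:
        return list(self.genotypes_f1.columns)


def build_study_bundle(config: SimulationConfig | None = None) -> StudyBundle:
    """Simulate the full two-generation study from a config.

    P0 founders -> 37 F1 full-sib families over 3 sites -> 17 F1 individuals
    chosen as F2 parents -> 42 F2 families on one site.  Genotypes cover all
    F1 trees and a subset of F2; juvenile height is phenotyped everywhere,
    mature height only in F1.
    """
    config = config or SimulationConfig()
    config.validate()
    rngs = _streams(config.seed)

    founders_H, freqs = simulate_founders(config, rngs["founders"])
    nP = config.n_founders
    p0_ids = [f"P{i + 1:03d}" for i in range(nP)]

    # --- F1 crossing plan: unique random founder pairs
    design_rng = rngs["design"]
    pairs = _unique_pairs(nP, config.n_f1_families, design_rng)
    fam_names = [f"FAM{i + 1:02d}" for i in range(config.n_f1_families)]

    # F1 trees per site, families cycled so each family appears on each site
    f1_rows = []
    k = 0
    site_names = [f"F1-S{i + 1}" for i in range(len(config.f1_site_sizes))]
    for site, size in zip(site_names, config.f1_site_sizes):
        fam_seq = np.tile(np.arange(config.n_f1_families),
                          int(np.ceil(size / config.n_f1_families)))[:size]
        design_rng.shuffle(fam_seq)
        for fi in fam_seq:
            k += 1
            f1_rows.append((f"F1_{k:04d}", fi, site))
    f1_ids = [r[0] for r in f1_rows]
    f1_fam_idx = np.array([r[1] for r in f1_rows])
    f1_site = [r[2] for r in f1_rows]
    f1_sire = pairs[f1_fam_idx, 0]
    f1_dam = pairs[f1_fam_idx, 1]

    H_f1 = drop_genes(founders_H, f1_sire, f1_dam, rngs["gene_drop"], config)

    # --- F2 parents: one individual from each of 17 distinct F1 families
    fam_choice = design_rng.choice(config.n_f1_families, config.n_f2_parents,
                                   replace=False)
    f2_parents = []
    for fi in fam_choice:
        members = np.flatnonzero(f1_fam_idx == fi)
        f2_parents.append(int(design_rng.choice(members)))
    f2_parent_ids = [f1_ids[i] for i in f2_parents]

    f2_pairs = _unique_pairs(config.n_f2_parents, config.n_f2_families, design_rng)
    f2_fam_names = [f"F2F{i + 1:02d}" for i in range(config.n_f2_families)]
    sizes = _spread(config.f2_size, config.n_f2_families)
    f2_fam_idx = np.repeat(np.arange(config.n_f2_families), sizes)
    f2_ids_all = [f"F2_{i + 1:04d}" for i in range(config.f2_size)]
    f2_sire = np.array([f2_parents[p] for p in f2_pairs[f2_fam_idx, 0]])
    f2_dam = np.array([f2_parents[p] for p in f2_pairs[f2_fam_idx, 1]])
    H_f2 = drop_genes(H_f1, f2_sire, f2_dam, rngs["gene_drop"], config)

    # --- pedigree
    ped_rows = [(i, None, None) for i in p0_ids]
    gens = ["P0"] * nP
    for i, idx in enumerate(f1_ids):
        ped_rows.append((idx, p0_ids[f1_sire[i]], p0_ids[f1_dam[i]]))
        gens.append("F1")
    for i, idx in enumerate(f2_ids_all):
        ped_rows.append((idx, f1_ids[f2_sire[i]], f1_ids[f2_dam[i]]))
        gens.append("F2")
    pedigree = Pedigree.from_records(ped_rows, generations=gens)

    # --- true breeding values (all individuals)
    qtl_idx, eff = assign_qtl_effects(config, freqs, rngs["effects"])
    counts_all = np.concatenate(
        [founders_H.sum(axis=2), H_f1.sum(axis=2), H_f2.sum(axis=2)]
    ).astype(float)
    all_ids = p0_ids + f1_ids + f2_ids_all
    tbv = true_breeding_values(counts_all, freqs, qtl_idx, eff)
    tbv_map = {i: tbv[k] for k, i in enumerate(all_ids)}

    # Mendelian sampling deviations
    pm = pedigree.parent_map()
    ms = np.zeros_like(tbv)
    for k, i in enumerate(all_ids):
        s, d = pm[i]
        pa = 0.5 * (tbv_map.get(s, np.zeros(2))[0:2] + tbv_map.get(d, np.zeros(2))[0:2]) \
            if (s or d) else np.zeros(2)
        ms[k] = tbv[k] - pa

    # --- phenotypes
    f2_site = "F2-S1"
    design_f1 = pd.DataFrame({
        "id": f1_ids,
        "site": f1_site,
        "block": design_rng.integers(1, config.blocks_per_site + 1, len(f1_ids)),
        "family": [fam_names[i] for i in f1_fam_idx],
    })
    design_f2 = pd.DataFrame({
        "id": f2_ids_all,
        "site": f2_site,
        "block": design_rng.integers(1, config.blocks_per_site + 1, config.f2_size),
        "family": [f2_fam_names[i] for i in f2_fam_idx],
    })
    design_all = pd.concat([design_f1, design_f2], ignore_index=True)

    idx_of = {i: k for k, i in enumerate(all_ids)}
    tbv_htj = np.array([tbv[idx_of[i]][0] for i in design_all["id"]])
    h2_by_site = dict(zip(site_names, config.h2_f1_sites))
    h2_by_site[f2_site] = config.h2_f2_site
    site_means = dict(zip(site_names, config.site_means_htj))
    site_means[f2_site] = config.f2_site_mean_htj
    age_by_site = {s: config.age_f1 for s in site_names}
    age_by_site[f2_site] = config.age_f2
    phen_htj = simulate_phenotypes(
        tbv_htj, design_all, config, rngs["noise"], h2_by_site, site_means,
        age_by_site, pedigree=pedigree,
    )

    tbv_ht35 = np.array([tbv[idx_of[i]][1] for i in design_f1["id"]])
    phen_ht35 = simulate_phenotypes(
        tbv_ht35, design_f1, config, rngs["noise"],
        {s: config.h2_ht35 for s in site_names},
        {s: config.mean_ht35 for s in site_names},
        {s: config.age_ht35 for s in site_names},
        pedigree=pedigree,
    )

    # --- genotype tables (markers exclude hidden QTL loci)
    marker_mask = np.ones(config.n_loci, dtype=bool)
    if not config.qtl_observed:
        marker_mask[qtl_idx] = False
    marker_names = [f"SNP{j + 1:05d}" for j in range(int(marker_mask.sum()))]
    geno_f1 = _geno_frame(H_f1.sum(axis=2)[:, marker_mask], f1_ids, marker_names,
                          config.missing_rate, rngs["noise"])
    f2_gen_pick = np.sort(design_rng.choice(config.f2_size, config.f2_genotyped,
                                            replace=False))
    f2_ids_gen = [f2_ids_all[i] for i in f2_gen_pick]
    geno_f2 = _geno_frame(H_f2.sum(axis=2)[f2_gen_pick][:, marker_mask], f2_ids_gen,
                          marker_names, config.missing_rate, rngs["noise"])

    genotyped = set(f1_ids) | set(f2_ids_gen)
    truth = pd.DataFrame({
        "id": all_ids,
        "generation": gens,
        "tbv_htj": tbv[:, 0],
        "tbv_ht35": tbv[:, 1],
        "ms_htj": ms[:, 0],
        "ms_ht35": ms[:, 1],
        "genotyped": [i in genotyped for i in all_ids],
    })
    qtl_table = pd.DataFrame({
        "locus": qtl_idx,
        "freq": freqs[qtl_idx],
        "effect_htj": eff[:, 0],
        "effect_ht35": eff[:, 1],
    })
    return StudyBundle(
        config=config,
        pedigree=pedigree,
        phenotypes_htj=phen_htj,
        phenotypes_ht35=phen_ht35,
        genotypes_f1=geno_f1,
        genotypes_f2=geno_f2,
        truth=truth,
        qtl=qtl_table,
        f1_ids=list(f1_ids),
        f2_ids=f2_ids_gen,
        f2_parents=f2_parent_ids,
    )


def _unique_pairs(n_pool: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Random distinct unordered pairs (as index rows) from a pool."""
    import itertools
    all_pairs = list(itertools.combinations(range(n_pool), 2))
    if n_pairs > len(all_pairs):
        raise ValueError(
            f"parent pool of {n_pool} supports at most {len(all_pairs)} distinct "
            f"families; {n_pairs} requested"
        )
    pick = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return np.array([all_pairs[i] for i in pick])


def _spread(total: int, k: int) -> np.ndarray:
    base = np.full(k, total // k)
    base[: total % k] += 1
    return base


def _geno_frame(counts, ids, markers, missing_rate, rng) -> pd.DataFrame:
    Z = counts.astype(float)
    if missing_rate > 0:
        mask = rng.random(Z.shape) < missing_rate
        Z[mask] = np.nan
    return pd.DataFrame(Z, index=pd.Index(ids, name="id"), columns=markers)


def build_two_cluster_bundle(seed: int = 0, shift: float = 160.0,
                             family_size: int = 60, f2_family_size: int = 60):
    """A deliberately pathological two-family fixture.

    Two F1 full-sib families with disjoint founder parents; F2 families bred
    strictly within each F1 family; and a heritable mean offset ``shift``
    (trait units) separating the two lineages.  Overall prediction
    correlations are dominated by the between-cluster gap while within a
    cluster the markers carry almost no usable signal — the clustering
    artifact the validation module's sub-analysis is designed to expose.

    Returns (bundle, cluster_labels) where the labels map genotyped F2 ids
    to 0 (low lineage) or 1 (high lineage).
    """
    cfg = SimulationConfig(
        n_founders=4,
        n_f1_families=2,
        f1_site_sizes=(2 * family_size,),
        h2_f1_sites=(0.25,),
        n_f2_families=2,
        n_f2_parents=4,
        f2_size=2 * f2_family_size,
        f2_genotyped=2 * f2_family_size,
        n_markers=600,
        n_qtl=40,
        seed=seed,
    )
    cfg.validate()
    rngs = _streams(cfg.seed)
    founders_H, freqs = simulate_founders(cfg, rngs["founders"])
    p0_ids = [f"P{i + 1:03d}" for i in range(4)]
    # lineage 0: founders 0x1; lineage 1: founders 2x3 (disjoint)
    pairs = np.array([[0, 1], [2, 3]])
    fam_names = ["FAM01", "FAM02"]
    n1 = 2 * family_size
    f1_fam_idx = np.repeat([0, 1], family_size)
    f1_ids = [f"F1_{i + 1:04d}" for i in range(n1)]
    f1_sire, f1_dam = pairs[f1_fam_idx, 0], pairs[f1_fam_idx, 1]
    H_f1 = drop_genes(founders_H, f1_sire, f1_dam, rngs["gene_drop"], cfg)

    # F2: sib crosses within each lineage
    design_rng = rngs["design"]
    f2_parents = [0, 1, family_size, family_size + 1]
    f2_fam_idx = np.repeat([0, 1], f2_family_size)
    f2_sire = np.where(f2_fam_idx == 0, f2_parents[0], f2_parents[2])
    f2_dam = np.where(f2_fam_idx == 0, f2_parents[1], f2_parents[3])
    f2_ids = [f"F2_{i + 1:04d}" for i in range(2 * f2_family_size)]
    H_f2 = drop_genes(H_f1, f2_sire, f2_dam, rngs["gene_drop"], cfg)

    ped_rows = [(i, None, None) for i in p0_ids]
    gens = ["P0"] * 4
    for i, idx in enumerate(f1_ids):
        ped_rows.append((idx, p0_ids[f1_sire[i]], p0_ids[f1_dam[i]]))
        gens.append("F1")
    for i, idx in enumerate(f2_ids):
        ped_rows.append((idx, f1_ids[f2_sire[i]], f1_ids[f2_dam[i]]))
        gens.append("F2")
    pedigree = Pedigree.from_records(ped_rows, generations=gens)

    qtl_idx, eff = assign_qtl_effects(cfg, freqs, rngs["effects"])
    counts_all = np.concatenate(
        [founders_H.sum(axis=2), H_f1.sum(axis=2), H_f2.sum(axis=2)]
    ).astype(float)
    all_ids = p0_ids + f1_ids + f2_ids
    tbv = true_breeding_values(counts_all, freqs, qtl_idx, eff)

    # heritable lineage offset: founders of lineage 1 carry +shift, transmitted
    # as the parent average (pure family-mean separation, no segregation)
    offset = {p0_ids[0]: 0.0, p0_ids[1]: 0.0, p0_ids[2]: shift, p0_ids[3]: shift}
    pm = pedigree.parent_map()
    for i in f1_ids + f2_ids:
        s, d = pm[i]
        offset[i] = 0.5 * (offset[s] + offset[d])
    tbv[:, 0] += np.array([offset[i] for i in all_ids])

    design = pd.DataFrame({
        "id": f1_ids + f2_ids,
        "site": ["F1-S1"] * n1 + ["F2-S1"] * len(f2_ids),
        "block": design_rng.integers(1, 6, n1 + len(f2_ids)),
        "family": [fam_names[i] for i in f1_fam_idx]
                  + [f"F2F{i + 1:02d}" for i in f2_fam_idx],
    })
    idx_of = {i: k for k, i in enumerate(all_ids)}
    tbv_htj = np.array([tbv[idx_of[i]][0] for i in design["id"]])
    phen = simulate_phenotypes(
        tbv_htj, design, cfg, rngs["noise"],
        {"F1-S1": 0.25, "F2-S1": 0.3},
        {"F1-S1": 650.0, "F2-S1": 350.0},
        {"F1-S1": cfg.age_f1, "F2-S1": cfg.age_f2},
        pedigree=pedigree,
    )
    marker_mask = np.ones(cfg.n_loci, dtype=bool)
    marker_mask[qtl_idx] = False
    marker_names = [f"SNP{j + 1:05d}" for j in range(int(marker_mask.sum()))]
    geno_f1 = _geno_frame(H_f1.sum(axis=2)[:, marker_mask], f1_ids, marker_names,
                          0.0, rngs["noise"])
    geno_f2 = _geno_frame(H_f2.sum(axis=2)[:, marker_mask], f2_ids, marker_names,
                          0.0, rngs["noise"])
    truth = pd.DataFrame({
        "id": all_ids,
        "generation": gens,
        "tbv_htj": tbv[:, 0],
        "tbv_ht35": tbv[:, 1],
        "ms_htj": np.nan,
        "ms_ht35": np.nan,
        "genotyped": [i in set(f1_ids) | set(f2_ids) for i in all_ids],
    })
    bundle = StudyBundle(
        config=cfg, pedigree=pedigree,
        phenotypes_htj=phen,
        phenotypes_ht35=phen.iloc[0:0],
        genotypes_f1=geno_f1, genotypes_f2=geno_f2,
        truth=truth,
        qtl=pd.DataFrame({"locus": qtl_idx, "freq": freqs[qtl_idx],
                          "effect_htj": eff[:, 0], "effect_ht35": eff[:, 1]}),
        f1_ids=f1_ids, f2_ids=f2_ids,
        f2_parents=[f1_ids[i] for i in f2_parents],
    )
    labels = {i: int(k >= f2_family_size) for k, i in enumerate(f2_ids)}
    return bundle, labels
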