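"""Synthetic pooled-droplet and cell-atlas data with known ground truth.

Emulates the structure of a two-species pooled snRNA-seq study: six
replicate 10x pools each containing four samples (two species x two
sexes), ~20,000 droplets per pool with a ~9% doublet rate, and a
cluster-structured gene count matrix over ~50 clusters with planted
abundance and expression fold changes. Everything downstream of read
mapping and background filtering is generated: per-droplet reads to the
two genomes (with mismapping leakage), per-droplet SNP allele counts tied
to the pooled samples' genotypes, and NB-distributed gene counts.

Every quantity derives from a single root seed through named child
streams, so identical configs produce bit-identical outputs and each
stage can be regenerated independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .demux import DropletProfile

__all__ = [
    "SimConfig",
    "PoolTruth",
    "AtlasTruth",
    "simulate_genotypes",
    "simulate_pooled_run",
    "simulate_cluster_assignments",
    "simulate_atlas_counts",
]

SPECIES = ("A", "B")
SEXES = ("F", "M")

#: marker genes used for inhibitory/excitatory cluster classing
MARKERS = ("Gad1", "Gad2", "Slc17a6")
FEMALE_MARKER = "Xist"


def child_rng(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-operation child stream from the root seed."""
    digests = [int.from_bytes(hashlib.sha256(k.encode()).digest()[:4], "little")
               for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *digests]))


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the profiled experiment: 6 replicate pools of 4 samples
    (2 species x 2 sexes), ~20,000 droplets per pool with a 9% doublet
    rate, ~50 clusters. ``abundance_effects`` entries are
    ``(cluster, covariate, fold)`` with the fold applied to species "B" or
    sex "M" (the second covariate level); ``expression_effects`` entries
    are ``(gene, cluster, covariate, fold)`` with the same convention, and
    ``cluster=None`` meaning all clusters.
    """

    n_replicates: int = 6
    samples_per_pool: int = 4
    n_droplets_per_pool: int = 20000
    multiplet_rate: float = 0.09
    mismap_rate: float = 0.01
    read_depth_law: tuple[float, float] = (np.log(10000.0), 0.6)  # lognormal meanlog/sdlog
    n_snps: int = 200
    maf: float = 0.3
    snp_read_rate: float = 0.002  # Poisson thinning of total reads into SNP reads
    snp_error: float = 0.001
    n_genes: int = 2000
    n_clusters: int = 50
    n_cells_per_sample: int = 500
    cells_per_sample_sdlog: float = 0.2  # samples never yield identical cell numbers
    composition_sdlog: float = 0.1  # animal-to-animal jitter of cluster proportions
    mean_cell_depth: float = 2500.0
    abundance_effects: list = field(default_factory=list)
    expression_effects: list = field(default_factory=list)
    category_map: dict | None = None
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.multiplet_rate <= 1:
            raise ValueError("multiplet_rate must be in [0, 1]")
        if not 0 <= self.mismap_rate <= 1:
            raise ValueError("mismap_rate must be in [0, 1]")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.samples_per_pool != len(SPECIES) * len(SEXES):
            raise ValueError("samples_per_pool must be 4 (2 species x 2 sexes)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for n in (self.n_replicates, self.n_droplets_per_pool, self.n_snps,
                  self.n_genes, self.n_clusters, self.n_cells_per_sample):
            if n <= 0:
                raise ValueError("all sizes must be positive")
        for eff in self.abundance_effects:
            if len(eff) != 3 or eff[2] <= 0:
                raise ValueError(f"bad abundance effect {eff!r}")
        for eff in self.expression_effects:
            if len(eff) != 4 or eff[3] <= 0:
                raise ValueError(f"bad expression effect {eff!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{sp}{sx}" for sp in SPECIES for sx in SEXES]

    def cluster_names(self) -> list[str]:
        return [f"c{k:02d}" for k in range(self.n_clusters)]

    def gene_names(self) -> list[str]:
        names = [f"g{j:04d}" for j in range(self.n_genes)]
        # three class markers replace mid-expression genes; Xist is appended
        for i, m in enumerate(MARKERS):
            names[self.n_genes // 4 + i] = m
        names.append(FEMALE_MARKER)
        return names


@dataclass
class PoolTruth:
    """Ground truth for one simulated pool (one row per droplet)."""

    table: pd.DataFrame  # barcode, sample_1, sample_2, is_multiplet, is_cross_species, total_reads
    genotypes: dict[str, pd.DataFrame]  # per species: samples x SNP ids


@dataclass
class AtlasTruth:
    """Ground truth for the simulated atlas."""

    base_proportions: pd.Series  # per-cluster baseline composition
    abundance_effects: list
    expression_effects: list
    cluster_class: pd.Series  # inhibitory/excitatory per cluster
    cluster_label: pd.Series  # true reference label per cluster


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n_samples: int, n_snps: int, maf: float,
                       seed: int = 0, max_retries: int = 100) -> pd.DataFrame:
    """Hardy-Weinberg genotypes (alt dosage 0/1/2) for pooled samples.

    Per-SNP alt-allele frequencies are Beta-distributed around ``maf``;
    dosages are Binomial(2, freq). The table is resampled until every pair
    of samples differs at >= 1 SNP; if the retry budget is exhausted the
    panel cannot discriminate the samples and an error is raised.
    """
    if n_samples < 2 or n_snps < 1:
        raise ValueError("need >= 2 samples and >= 1 SNP")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = child_rng(seed, "genotypes")
    conc = 30.0
    for _ in range(max_retries):
        freqs = rng.beta(maf * conc, (1 - maf) * conc, size=n_snps)
        g = rng.binomial(2, freqs[None, :], size=(n_samples, n_snps))
        diffs = (g[:, None, :] != g[None, :, :]).any(axis=2)
        if diffs[np.triu_indices(n_samples, k=1)].all():
            return pd.DataFrame(g, index=[f"s{i}" for i in range(n_samples)],
                                columns=[f"snp{j:04d}" for j in range(n_snps)])
    raise RuntimeError(
        f"could not discriminate {n_samples} samples with {n_snps} SNPs "
        f"after {max_retries} attempts")


# ---------------------------------------------------------------------------
# Pooled droplets
# ---------------------------------------------------------------------------

def simulate_pooled_run(config: SimConfig, replicate: int = 0
                        ) -> tuple[list[DropletProfile], PoolTruth]:
    """One pooled 10x run: droplet read counts and SNP allele counts.

    Singlets carry one sample's nucleus; doublets carry two distinct
    samples with reads split Binomial(total, 1/2). Each nucleus's reads map
    to its own species' genome except a ``mismap_rate`` fraction leaking to
    the other genome; primary + secondary reads always sum to the drawn
    total depth. SNP reads are Poisson-thinned from total reads and scored
    against the contributing nucleus's genotype.
    """
    rng = child_rng(config.seed, "pool", f"rep{replicate}")
    n = config.n_droplets_per_pool
    samples = config.sample_ids
    genotypes: dict[str, pd.DataFrame] = {}
    for sp in SPECIES:
        g = simulate_genotypes(len(SEXES), config.n_snps, config.maf,
                               seed=config.seed + 13 * replicate + ord(sp))
        g.index = [f"{sp}{sx}" for sx in SEXES]
        g.columns = [f"{sp}:{c}" for c in g.columns]
        genotypes[sp] = g

    meanlog, sdlog = config.read_depth_law
    total = np.maximum(rng.lognormal(meanlog, sdlog, size=n).round().astype(np.int64), 10)

    is_mult = rng.random(n) < config.multiplet_rate
    s1 = rng.integers(0, len(samples), size=n)
    shift = rng.integers(1, len(samples), size=n)
    s2 = np.where(is_mult, (s1 + shift) % len(samples), s1)

    r1 = np.where(is_mult, rng.binomial(total, 0.5), total)
    r2 = total - r1

    sp1 = np.array([s // len(SEXES) for s in s1])  # 0 = A, 1 = B
    sp2 = np.array([s // len(SEXES) for s in s2])

    # genome mapping with leakage
    own1 = rng.binomial(r1, 1.0 - config.mismap_rate) if config.mismap_rate > 0 else r1
    own2 = np.where(is_mult, rng.binomial(r2, 1.0 - config.mismap_rate), 0) \
        if config.mismap_rate > 0 else np.where(is_mult, r2, 0)
    reads_a = np.where(sp1 == 0, own1, r1 - own1) + np.where(is_mult,
                       np.where(sp2 == 0, own2, r2 - own2), 0)
    reads_b = total - reads_a

    # SNP reads: Poisson thinning of total depth, attributed to nuclei by
    # their read share, spread uniformly over the nucleus's species panel
    n_snp_reads = rng.poisson(config.snp_read_rate * total)
    with np.errstate(invalid="ignore"):
        share1 = np.where(total > 0, r1 / total, 1.0)
    reads_n1 = rng.binomial(n_snp_reads, share1)
    reads_n2 = n_snp_reads - reads_n1

    dosage = {sp: genotypes[sp].to_numpy() for sp in SPECIES}  # (2 sexes, n_snps)
    p_alt_tab = {sp: np.array([config.snp_error, 0.5, 1.0 - config.snp_error])[dosage[sp]]
                 for sp in SPECIES}

    uniform = np.full(config.n_snps, 1.0 / config.n_snps)
    cov1 = rng.multinomial(reads_n1, uniform)
    cov2 = rng.multinomial(reads_n2, uniform)
    sex1 = s1 % len(SEXES)
    sex2 = s2 % len(SEXES)
    p1 = np.stack([p_alt_tab[SPECIES[sp1[i]]][sex1[i]] for i in range(n)])
    alt1 = rng.binomial(cov1, p1)
    alt2 = np.zeros_like(cov2)
    mult_idx = np.flatnonzero(is_mult & (reads_n2 > 0))
    if mult_idx.size:
        p2 = np.stack([p_alt_tab[SPECIES[sp2[i]]][sex2[i]] for i in mult_idx])
        alt2[mult_idx] = rng.binomial(cov2[mult_idx], p2)

    snp_ids = {sp: list(genotypes[sp].columns) for sp in SPECIES}
    profiles: list[DropletProfile] = []
    barcodes = [f"r{replicate}-bc{i:06d}" for i in range(n)]
    for i in range(n):
        alleles: dict[str, tuple[int, int]] = {}
        for cov, alt, spi in ((cov1[i], alt1[i], sp1[i]), (cov2[i], alt2[i], sp2[i])):
            if cov.sum() == 0:
                continue
            ids = snp_ids[SPECIES[spi]]
            for j in np.flatnonzero(cov):
                ref_ct, alt_ct = int(cov[j] - alt[j]), int(alt[j])
                prev = alleles.get(ids[j], (0, 0))
                alleles[ids[j]] = (prev[0] + ref_ct, prev[1] + alt_ct)
            if not is_mult[i]:
                break
        profiles.append(DropletProfile(barcodes[i], int(reads_a[i]),
                                       int(reads_b[i]), alleles))

    truth = pd.DataFrame({
        "barcode": barcodes,
        "sample_1": [samples[k] for k in s1],
        "sample_2": [samples[k] if m else "" for k, m in zip(s2, is_mult)],
        "is_multiplet": is_mult,
        "is_cross_species": is_mult & (sp1 != sp2),
        "total_reads": total,
    })
    return profiles, PoolTruth(table=truth, genotypes=genotypes)


# ---------------------------------------------------------------------------
# Atlas counts
# ---------------------------------------------------------------------------

def _sample_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for rep in range(config.n_replicates):
        for sp in SPECIES:
            for sx in SEXES:
                rows.append({
                    "sample": f"r{rep}_{sp}{sx}",
                    "replicate": f"r{rep}",
                    "species": sp,
                    "sex": sx,
                })
    return pd.DataFrame(rows).set_index("sample")


def _base_proportions(config: SimConfig) -> np.ndarray:
    rng = child_rng(config.seed, "atlas", "proportions")
    sizes = np.sort(rng.lognormal(0.0, 1.0, size=config.n_clusters))[::-1]
    return sizes / sizes.sum()


def simulate_cluster_assignments(config: SimConfig) -> tuple[pd.DataFrame, AtlasTruth]:
    """Per-cell metadata (sample, replicate, species, sex, cluster, label).

    Cluster membership is multinomial per sample from lognormal baseline
    proportions (sorted so cluster c00 is the largest), with planted
    abundance fold-changes multiplying the affected covariate level's
    proportion before renormalization. Per-sample cell totals vary
    lognormally around ``n_cells_per_sample`` — samples never profile the
    same number of neurons, which is what the TMM offsets downstream are
    for. Cheap to call on its own when only composition (not expression)
    is under test.
    """
    clusters = config.cluster_names()
    base = _base_proportions(config)
    for eff in config.abundance_effects:
        if eff[0] not in clusters:
            raise ValueError(f"abundance effect references unknown cluster {eff[0]!r}")

    # alternate inhibitory/excitatory classes; each cluster gets a reference label
    classes = pd.Series(["inhibitory" if k % 2 == 0 else "excitatory"
                         for k in range(config.n_clusters)], index=clusters)
    labels = pd.Series([f"i{k}:Gaba" if k % 2 == 0 else f"e{k}:Glut"
                        for k in range(config.n_clusters)], index=clusters)

    meta = _sample_meta(config)
    rng = child_rng(config.seed, "atlas", "cells")
    rows = []
    for sample, sm in meta.iterrows():
        props = base.copy()
        for clu, cov, fold in config.abundance_effects:
            level = {"species": "B", "sex": "M"}[cov]
            if sm[cov] == level:
                props[clusters.index(clu)] *= fold
        if config.composition_sdlog > 0:
            props = props * rng.lognormal(0.0, config.composition_sdlog,
                                          size=props.size)
        props = props / props.sum()
        n_cells = max(1, int(round(rng.lognormal(
            np.log(config.n_cells_per_sample), config.cells_per_sample_sdlog))))
        counts = rng.multinomial(n_cells, props)
        for k, c in enumerate(counts):
            rows.extend([(sample, clusters[k])] * int(c))
    obs = pd.DataFrame(rows, columns=["sample", "cluster"])
    obs = obs.join(meta, on="sample")
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]

    # transferred reference labels: true label w.p. 0.8, else a random label
    # of the same class (transfer never crosses the inhibitory/excitatory split)
    lab_pool = {cl: labels[classes == cl].to_numpy() for cl in ("inhibitory", "excitatory")}
    true_lab = labels[obs["cluster"]].to_numpy()
    true_cls = classes[obs["cluster"]].to_numpy()
    noisy = rng.random(len(obs)) >= 0.8
    drawn = np.array([rng.choice(lab_pool[c]) for c in true_cls[noisy]]) \
        if noisy.any() else np.array([], dtype=object)
    lab = true_lab.copy()
    lab[noisy] = drawn
    obs["transferred_label"] = lab

    truth = AtlasTruth(
        base_proportions=pd.Series(base, index=clusters),
        abundance_effects=list(config.abundance_effects),
        expression_effects=list(config.expression_effects),
        cluster_class=classes,
        cluster_label=labels,
    )
    return obs, truth


def simulate_atlas_counts(config: SimConfig) -> tuple[ad.AnnData, AtlasTruth]:
    """Cluster-structured NB gene counts for the full 24-sample design.

    Gene baseline abundances are lognormal (sorted, so g0000 is the most
    expressed); each cluster perturbs them lognormally to create cluster
    structure, and class markers (Gad1/Gad2 vs Slc17a6) are boosted in
    their own class. Planted expression effects multiply the affected
    (gene, cluster, covariate-level) mean. Counts are Gamma-Poisson
    (i.e. NB) with dispersion ``config.dispersion`` at the cell level; the
    female marker gene is structurally zero in male cells.
    """
    genes = config.gene_names()
    n_genes_tot = len(genes)
    obs, truth = simulate_cluster_assignments(config)
    clusters = config.cluster_names()
    for eff in config.expression_effects:
        g, clu = eff[0], eff[1]
        if g not in genes:
            raise ValueError(f"expression effect references unknown gene {g!r}")
        if clu is not None and clu not in clusters:
            raise ValueError(f"expression effect references unknown cluster {clu!r}")

    rng = child_rng(config.seed, "atlas", "expression")
    base = np.sort(rng.lognormal(0.0, 1.2, size=config.n_genes))[::-1]
    base = np.append(base, np.quantile(base, 0.85))  # Xist baseline (females only)
    profile = base[:, None] * rng.lognormal(0.0, 0.3, size=(n_genes_tot, config.n_clusters))

    gidx = {g: j for j, g in enumerate(genes)}
    cls = truth.cluster_class
    for m in ("Gad1", "Gad2"):
        profile[gidx[m], :] *= np.where(cls.to_numpy() == "inhibitory", 5.0, 0.05)
    profile[gidx["Slc17a6"], :] *= np.where(cls.to_numpy() == "excitatory", 5.0, 0.05)

    # per-(cluster, covariate-level) multipliers for planted effects
    eff_mult = {}  # (gene_idx, cluster or None, covariate) -> fold
    for g, clu, cov, fold in config.expression_effects:
        eff_mult[(gidx[g], clu, cov)] = fold

    depth_rng = child_rng(config.seed, "atlas", "depth")
    depths = depth_rng.lognormal(np.log(config.mean_cell_depth), 0.4, size=len(obs))

    count_rng = child_rng(config.seed, "atlas", "counts")
    blocks = []
    order = []
    xist = gidx[FEMALE_MARKER]
    group_iter = obs.groupby(["sample", "cluster"], sort=True, observed=True)
    for (sample, cluster), grp in group_iter:
        k = clusters.index(cluster)
        mu_rel = profile[:, k].copy()
        sm = grp.iloc[0]
        for (gj, clu, cov), fold in eff_mult.items():
            if clu is not None and clu != cluster:
                continue
            level = {"species": "B", "sex": "M"}[cov]
            if sm[cov] == level:
                mu_rel[gj] *= fold
        if sm["sex"] == "M":
            mu_rel[xist] = 0.0
        mu_rel = mu_rel / mu_rel.sum()
        mu = depths[obs.index.get_indexer(grp.index)][:, None] * mu_rel[None, :]
        if config.dispersion > 0:
            lam = count_rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
            counts = count_rng.poisson(lam)
        else:
            counts = count_rng.poisson(mu)
        blocks.append(sparse.csr_matrix(counts.astype(np.int32)))
        order.extend(grp.index)

    X = sparse.vstack(blocks, format="csr")
    obs_ordered = obs.loc[order]
    adata = ad.AnnData(X=X, obs=obs_ordered,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["categories"] = _category_frame(config, genes)
    return adata, truth


def _category_frame(config: SimConfig, genes: list[str]) -> pd.DataFrame:
    if config.category_map is not None:
        rows = [(g, c) for g, cats in config.category_map.items()
                for c in (cats if isinstance(cats, (list, tuple)) else [cats])]
    else:
        rng = child_rng(config.seed, "atlas", "categories")
        picks = rng.choice(config.n_genes, size=60, replace=False)
        rows = [(genes[j], "neuropeptide") for j in picks[:30]]
        rows += [(genes[j], "random_set") for j in picks[30:]]
    return pd.DataFrame(rows, columns=["gene", "category"])
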