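"""Pseudobulk differential expression per cluster.

Gene counts are summed over all cells sharing a (cluster, sample) pair —
exact integer conservation — and each cluster's genes x samples table is
analysed with the NB GLM engine. Two designs are run: species differences
with replicate + sex + species covariates over all 24 samples, and sex
differences within one species with replicate + sex covariates over that
species' 12 samples. FDR is applied within each cluster's gene family
(matching the per-cluster DE-count presentation; a global family is a
switch away) at the 0.05 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .glm import nb_glm_table

__all__ = ["PseudobulkTable", "pseudobulk", "de_species",
           "de_sex_within_species", "de_summary", "PseudobulkDEModel"]

DEFAULT_DE_FDR = 0.05


@dataclass
class PseudobulkTable:
    """Genes x (cluster, sample) summed counts with sample covariates."""

    counts: pd.DataFrame  # genes x MultiIndex (cluster, sample)
    sample_meta: pd.DataFrame  # samples x (replicate, species, sex)

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.columns.get_level_values("cluster").unique())

    def cluster_counts(self, cluster: str) -> pd.DataFrame:
        sub = self.counts.xs(cluster, axis=1, level="cluster")
        return sub


def pseudobulk(adata: ad.AnnData, cluster_key: str = "cluster",
               sample_key: str = "sample") -> PseudobulkTable:
    """Sum cell counts within each (cluster, sample) group."""
    for key in (cluster_key, sample_key):
        if key not in adata.obs or adata.obs[key].isna().any():
            raise ValueError(f"every cell needs a {key!r} label")
    groups = adata.obs.groupby([cluster_key, sample_key], sort=True, observed=True)
    X = adata.X if sparse.issparse(adata.X) else np.asarray(adata.X)
    cols = {}
    for (clu, sample), grp in groups:
        idx = adata.obs.index.get_indexer(grp.index)
        sub = X[idx]
        total = np.asarray(sub.sum(axis=0)).ravel()
        cols[(clu, sample)] = total.astype(np.int64)
    counts = pd.DataFrame(cols, index=adata.var_names)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["cluster", "sample"])
    meta_cols = [c for c in ("replicate", "species", "sex") if c in adata.obs]
    sample_meta = (adata.obs[[sample_key] + meta_cols]
                   .drop_duplicates().set_index(sample_key).sort_index())
    return PseudobulkTable(counts=counts, sample_meta=sample_meta)


def _per_cluster_tables(pb: PseudobulkTable, meta_mask, covariates, coef,
                        fdr: float, min_total: int) -> dict[str, pd.DataFrame]:
    out = {}
    for clu in pb.clusters:
        sub = pb.cluster_counts(clu)
        meta = pb.sample_meta.loc[sub.columns]
        if meta_mask is not None:
            keep = meta_mask(meta)
            sub, meta = sub.loc[:, keep], meta[keep]
        sub = sub.loc[:, sub.sum(axis=0) > 0]  # drop empty sample columns
        meta = meta.loc[sub.columns]
        # genes never seen in this cluster leave the family before BH
        sub = sub[sub.sum(axis=1) > 0]
        # clusters absent from part of the design (e.g. a whole covariate
        # level unobserved) cannot be tested
        testable = not sub.empty and all(
            meta[c].nunique() >= 2 for c in covariates)
        if not testable:
            out[clu] = pd.DataFrame(columns=["log2_fold_change", "p_value", "fdr",
                                             "significant", "direction"])
            continue
        tab = nb_glm_table(sub, meta, covariates=covariates,
                           test_coefs=(coef,), min_total=min_total)[coef]
        tab["significant"] = tab["fdr"] < fdr
        tab["direction"] = np.where(tab["log2_fold_change"] > 0, "up_in_second_level",
                                    "up_in_first_level")
        out[clu] = tab
    return out


def de_species(pb: PseudobulkTable, fdr: float = DEFAULT_DE_FDR,
               min_total: int = 10) -> dict[str, pd.DataFrame]:
    """Species DE per cluster: replicate + sex + species design, 24 samples.

    Positive log2 fold changes are species-B-biased (treatment coding on
    the sorted species levels).
    """
    return _per_cluster_tables(pb, None, ("replicate", "sex", "species"),
                               "species", fdr, min_total)


def de_sex_within_species(pb: PseudobulkTable, species: str,
                          fdr: float = DEFAULT_DE_FDR,
                          min_total: int = 10) -> dict[str, pd.DataFrame]:
    """Sex DE per cluster within one species: replicate + sex design.

    Positive log2 fold changes are male-biased (levels sorted F < M).
    """
    if species not in set(pb.sample_meta["species"]):
        raise ValueError(f"unknown species {species!r}")
    return _per_cluster_tables(pb, lambda m: m["species"] == species,
                               ("replicate", "sex"), "sex", fdr, min_total)


def shared_sex_bias(tables_sp1: dict[str, pd.DataFrame],
                    tables_sp2: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes sex-biased in the same cluster with the same direction in both
    species."""
    rows = []
    for clu in set(tables_sp1) & set(tables_sp2):
        t1, t2 = tables_sp1[clu], tables_sp2[clu]
        if t1.empty or t2.empty:
            continue
        t1 = t1[t1["significant"].astype(bool)]
        t2 = t2[t2["significant"].astype(bool)]
        common = t1.index.intersection(t2.index)
        for g in common:
            if t1.loc[g, "direction"] == t2.loc[g, "direction"]:
                rows.append({"gene": g, "cluster": clu,
                             "direction": t1.loc[g, "direction"]})
    return pd.DataFrame(rows, columns=["gene", "cluster", "direction"])


def de_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-cluster DE counts split by direction, plus the unique-gene union."""
    rows = []
    union: set[str] = set()
    for clu, tab in tables.items():
        sig = tab[tab.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
        union |= set(sig.index)
        rows.append({
            "cluster": clu,
            "n_de": int(len(sig)),
            "n_up_second": int((sig["direction"] == "up_in_second_level").sum()) if len(sig) else 0,
            "n_up_first": int((sig["direction"] == "up_in_first_level").sum()) if len(sig) else 0,
        })
    out = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    out.attrs["n_unique_genes"] = len(union)
    return out


class PseudobulkDEModel:
    """Model-object spelling of the pseudobulk DE stage."""

    def __init__(self, adata: ad.AnnData, fdr: float = DEFAULT_DE_FDR,
                 min_total: int = 10):
        self.pb = pseudobulk(adata)
        self.fdr = fdr
        self.min_total = min_total

    def fit(self) -> "PseudobulkDEResults":
        species_tabs = de_species(self.pb, self.fdr, self.min_total)
        sexes = {}
        for sp in sorted(set(self.pb.sample_meta["species"])):
            sexes[sp] = de_sex_within_species(self.pb, sp, self.fdr, self.min_total)
        return PseudobulkDEResults(self, species_tabs, sexes)


@dataclass
class PseudobulkDEResults:
    model: PseudobulkDEModel
    species_tables: dict[str, pd.DataFrame]
    sex_tables: dict[str, dict[str, pd.DataFrame]]

    def summary(self) -> pd.DataFrame:
        parts = [de_summary(self.species_tables).assign(analysis="species")]
        for sp, tabs in self.sex_tables.items():
            parts.append(de_summary(tabs).assign(analysis=f"sex_{sp}"))
        return pd.concat(parts, ignore_index=True)

    def shared_sex_biased(self) -> pd.DataFrame:
        sps = sorted(self.sex_tables)
        if len(sps) != 2:
            raise ValueError("shared sex-bias needs exactly two species")
        return shared_sex_bias(self.sex_tables[sps[0]], self.sex_tables[sps[1]])
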