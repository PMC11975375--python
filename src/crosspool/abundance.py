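"""Differential cell-type abundance across species and sex.

Cell counts are cross-tabulated into a cluster x sample matrix and treated
as count data: TMM normalization over cluster sizes absorbs the different
numbers of neurons profiled per sample, and a negative-binomial GLM with
replicate, sex and species covariates is fitted per cluster. Both the
species and sex coefficients are tested from the single joint fit and
BH-corrected; the lenient default FDR cutoff of 0.3 flags candidate
clusters for downstream validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .glm import nb_glm_table

__all__ = ["AbundanceMatrix", "build_abundance_matrix", "differential_abundance",
           "DifferentialAbundanceModel"]

DEFAULT_ABUNDANCE_FDR = 0.3
LOW_CONFIDENCE_CELLS = 20


@dataclass
class AbundanceMatrix:
    """Cluster x sample cell counts plus per-sample covariates."""

    counts: pd.DataFrame  # clusters x samples
    meta: pd.DataFrame    # samples x (replicate, species, sex)

    def __post_init__(self):
        if not self.counts.columns.equals(self.meta.index):
            raise ValueError("count columns and metadata rows must align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative cell counts")


def build_abundance_matrix(cell_metadata: pd.DataFrame,
                           sample_meta: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Exact cross-tabulation of cells into cluster x sample counts.

    ``cell_metadata`` needs ``cluster`` and ``sample`` columns plus the
    per-sample covariates (replicate, species, sex), unless ``sample_meta``
    supplies the covariates directly. Unobserved (cluster, sample) pairs
    are zero.
    """
    for col in ("cluster", "sample"):
        if col not in cell_metadata.columns or cell_metadata[col].isna().any():
            raise ValueError(f"every cell needs a {col!r} label")
    counts = pd.crosstab(cell_metadata["cluster"], cell_metadata["sample"])
    if sample_meta is None:
        sample_meta = (cell_metadata[["sample", "replicate", "species", "sex"]]
                       .drop_duplicates().set_index("sample"))
    unknown = set(counts.columns) - set(sample_meta.index)
    if unknown:
        raise ValueError(f"samples without metadata: {sorted(unknown)}")
    sample_meta = sample_meta.loc[counts.columns]
    counts = counts.reindex(columns=sample_meta.index, fill_value=0)
    return AbundanceMatrix(counts=counts, meta=sample_meta)


def differential_abundance(matrix: AbundanceMatrix,
                           fdr_threshold: float = DEFAULT_ABUNDANCE_FDR) -> pd.DataFrame:
    """Species and sex differential-abundance tests for every cluster.

    Returns a tidy table with one row per (cluster, contrast):
    log2_fold_change, p_value, BH fdr within each contrast, a candidate
    flag at ``fdr_threshold``, and a low-confidence flag for clusters with
    fewer than 20 cells in total.
    """
    for cov in ("species", "sex"):
        if matrix.meta[cov].value_counts().min() < 2:
            raise ValueError(f"need >= 2 samples per {cov} level")
    tables = nb_glm_table(matrix.counts, matrix.meta,
                          covariates=("replicate", "sex", "species"),
                          test_coefs=("species", "sex"), min_total=0)
    out = []
    totals = matrix.counts.sum(axis=1)
    for contrast, tab in tables.items():
        tab = tab.copy()
        tab["contrast"] = contrast
        tab["candidate"] = tab["fdr"] < fdr_threshold
        tab["low_confidence"] = totals.reindex(tab.index) < LOW_CONFIDENCE_CELLS
        out.append(tab.reset_index().rename(columns={"feature": "cluster"}))
    return pd.concat(out, ignore_index=True)


class DifferentialAbundanceModel:
    """Model-object spelling: build from cell metadata, ``fit`` to a table."""

    def __init__(self, cell_metadata: pd.DataFrame,
                 fdr_threshold: float = DEFAULT_ABUNDANCE_FDR):
        self.matrix = build_abundance_matrix(cell_metadata)
        self.fdr_threshold = fdr_threshold

    def fit(self) -> "DifferentialAbundanceResults":
        return DifferentialAbundanceResults(self, differential_abundance(
            self.matrix, self.fdr_threshold))


@dataclass
class DifferentialAbundanceResults:
    model: DifferentialAbundanceModel
    table: pd.DataFrame

    def candidates(self) -> pd.DataFrame:
        return self.table[self.table["candidate"]]

    def summary(self) -> pd.DataFrame:
        t = self.table
        return (t.groupby("contrast")
                 .agg(n_clusters=("cluster", "nunique"),
                      n_candidates=("candidate", "sum"),
                      min_fdr=("fdr", "min"))
                 .reset_index())
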