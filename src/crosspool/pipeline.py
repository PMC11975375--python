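"""End-to-end orchestration: simulate -> demux -> abundance -> DE ->
annotation -> enrichment, with one root seed, a parameter echo and a
deterministic JSON run report.

The demultiplexing stages consume the simulated pooled runs; the
abundance/DE/annotation/enrichment stages consume the simulated atlas
(clustering and label transfer are upstream of this package, so the
generator's cluster and transferred-label columns stand in for them).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import io as cio
from .abundance import DifferentialAbundanceModel
from .demux import demux_pool
from .enrichment import MatchedEnrichmentTest
from .pseudobulk import PseudobulkDEModel
from .simulate import SimConfig, simulate_atlas_counts, simulate_pooled_run

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline thresholds (defaults are the study's stated values) and toggles."""

    sim: SimConfig = field(default_factory=SimConfig)
    bin_width: int = 500
    min_prop: float = 0.15
    abundance_fdr: float = 0.3
    de_fdr: float = 0.05
    enrichment_resamples: int = 5000
    stages: tuple[str, ...] = ("simulate", "demux", "abundance", "de",
                               "annotate", "enrich")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"},
                  **({"stages": tuple(raw["stages"])} if "stages" in raw else {}))
        if sim_kw:
            cfg.sim = SimConfig(**sim_kw)
        if "seed" in raw:
            cfg.sim.seed = cfg.seed
        return cfg


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the enabled stages in dependency order and write all outputs.

    Returns the run report (also written to ``report.json``); identical
    configs produce byte-identical reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed if config.sim.seed == 0 else config.sim.seed
    report: dict = {"parameters": {
        "bin_width": config.bin_width,
        "min_prop": config.min_prop,
        "abundance_fdr": config.abundance_fdr,
        "de_fdr": config.de_fdr,
        "enrichment_resamples": config.enrichment_resamples,
        "seed": config.seed,
        "sim": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config.sim).items()},
    }}
    stages = set(config.stages)

    pools = None
    adata = truth = None
    if "simulate" in stages:
        pools = [simulate_pooled_run(config.sim, replicate=r)
                 for r in range(config.sim.n_replicates)]
        adata, truth = simulate_atlas_counts(config.sim)
        cio.write_10x_mtx(adata, out / "atlas")
        for r, (profiles, ptruth) in enumerate(pools):
            pdir = out / f"pool{r}"
            cio.write_droplet_tables(profiles, pdir)
            ptruth.table.to_csv(pdir / "truth.tsv", sep="\t", index=False)
            for sp, g in ptruth.genotypes.items():
                cio.write_vcf(g, pdir / f"genotypes_{sp}.vcf")
        report["simulate"] = {
            "n_pools": config.sim.n_replicates,
            "n_droplets_per_pool": config.sim.n_droplets_per_pool,
            "n_cells": int(adata.n_obs),
            "n_genes": int(adata.n_vars),
        }

    if "demux" in stages:
        if pools is None:
            raise FileNotFoundError("demux requires the simulate stage outputs")
        demux_rows = []
        for r, (profiles, ptruth) in enumerate(pools):
            calls, res = demux_pool(profiles, ptruth.genotypes,
                                    bin_width=config.bin_width)
            calls.to_csv(out / f"pool{r}" / "calls.tsv", sep="\t", index=False)
            cio.dump_json(res.to_json_dict(), out / f"pool{r}" / "demux_model.json")
            demux_rows.append({
                "pool": r,
                "droplets": len(calls),
                "singlets": int((calls["status"] == "singlet").sum()),
                "species_multiplets": int((calls["status"] == "species_multiplet").sum()),
                "sample_multiplets": int((calls["status"] == "sample_multiplet").sum()),
                "ambiguous": int((calls["status"] == "ambiguous").sum()),
            })
        for row in demux_rows:
            row["removed_multiplets"] = row["species_multiplets"] + row["sample_multiplets"]
            assert row["singlets"] + row["removed_multiplets"] + row["ambiguous"] == row["droplets"]
        report["demux"] = demux_rows

    if "abundance" in stages:
        if adata is None:
            raise FileNotFoundError("abundance requires the simulate stage outputs")
        da = DifferentialAbundanceModel(adata.obs, config.abundance_fdr).fit()
        da.table.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        report["abundance"] = {
            contrast: int(n) for contrast, n in
            da.table.groupby("contrast")["candidate"].sum().items()
        }

    de_res = None
    if "de" in stages:
        if adata is None:
            raise FileNotFoundError("de requires the simulate stage outputs")
        de_res = PseudobulkDEModel(adata, fdr=config.de_fdr).fit()
        de_res.summary().to_csv(out / "de_summary.tsv", sep="\t", index=False)
        report["de"] = {
            "species_de_total": int(sum(t["significant"].sum()
                                        for t in de_res.species_tables.values())),
            "sex_de_total": {sp: int(sum(t["significant"].sum() for t in tabs.values()))
                             for sp, tabs in de_res.sex_tables.items()},
            "shared_sex_biased": int(len(de_res.shared_sex_biased())),
        }

    if "annotate" in stages:
        if adata is None:
            raise FileNotFoundError("annotate requires the simulate stage outputs")
        props = ann.label_proportion_matrix(adata.obs)
        assignments = ann.assign_homology(props, min_prop=config.min_prop)
        tab = ann.homology_table(assignments)
        tab.to_csv(out / "homology.tsv", sep="\t", index=False)
        report["annotate"] = {
            "n_clusters": int(props.shape[0]),
            "n_mapped": int(sum(a.mapped for a in assignments)),
        }

    if "enrich" in stages:
        if de_res is None:
            raise FileNotFoundError("enrich requires the de stage outputs")
        pb = de_res.model.pb
        per_cluster_cpm = _per_cluster_cpm(pb)
        fg, fg_cpm = _foreground_from_de(de_res.species_tables, per_cluster_cpm)
        cats = adata.uns["categories"].groupby("category")["gene"].apply(set).to_dict()
        if fg:
            test = MatchedEnrichmentTest(fg, cats, per_cluster_cpm.max(axis=1),
                                         foreground_cpm=fg_cpm)
            res = test.fit(B=config.enrichment_resamples, seed=config.seed)
            summ = res.summary()
            summ.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["enrich"] = summ.drop(columns=["p_display"]).to_dict(orient="records")
        else:
            report["enrich"] = []

    cio.dump_json(report, out / "report.json")
    return report


def _per_cluster_cpm(pb) -> pd.DataFrame:
    """Genes x clusters CPM from the pooled per-cluster pseudobulk."""
    sums = pb.counts.T.groupby(level="cluster").sum().T
    return sums / sums.sum(axis=0) * 1e6


def _foreground_from_de(species_tables, per_cluster_cpm):
    """DE gene union with the highest-expression rule for multi-cluster genes."""
    from .enrichment import resolve_foreground_expression

    de_in: dict[str, list[str]] = {}
    for clu, tab in species_tables.items():
        for g in tab.index[tab["significant"]]:
            de_in.setdefault(g, []).append(clu)
    fg = sorted(de_in)
    fg_cpm = pd.Series({g: resolve_foreground_expression(g, per_cluster_cpm, de_in[g])
                        for g in fg})
    return fg, fg_cpm
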