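"""Readers and writers for the pipeline's on-disk formats.

10x-style triplet matrices go through scipy's Matrix Market support with
the usual barcodes.tsv / features.tsv sidecars; genotypes travel as a
minimal GT-only VCF (written directly, read back with cyvcf2); everything
else is plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

__all__ = ["write_10x_mtx", "read_10x_mtx", "write_vcf", "read_vcf",
           "write_droplet_tables", "read_droplet_tables"]


def write_10x_mtx(adata: ad.AnnData, outdir) -> Path:
    """matrix.mtx (features x cells, 10x orientation) + barcodes/features."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    scio.mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")
    return outdir


def read_10x_mtx(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(indir / "matrix.mtx").T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs,
                      var=pd.DataFrame(index=pd.Index(features, name="gene")))


def write_vcf(genotypes: pd.DataFrame, path) -> Path:
    """Minimal GT-only VCF for a samples x SNPs dosage table ({0,1,2}).

    SNPs become biallelic A/G records on a synthetic contig in column
    order; sample columns carry unphased genotypes.
    """
    path = Path(path)
    samples = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=sim,length=%d>\n" % (len(genotypes.columns) + 1))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, snp in enumerate(genotypes.columns, start=1):
            gts = "\t".join(gt_map[int(genotypes.loc[s, snp])] for s in samples)
            fh.write(f"sim\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def read_vcf(path) -> pd.DataFrame:
    """Samples x SNPs alt-dosage table from a GT-only VCF."""
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = list(v.samples)
    ids, rows = [], []
    for var in v:
        ids.append(var.ID)
        rows.append([a + b for a, b, *_ in var.genotypes])
    return pd.DataFrame(np.array(rows).T, index=samples, columns=ids)


def write_droplet_tables(profiles, outdir) -> Path:
    """reads.tsv (barcode, reads_a, reads_b) + alleles.tsv (long form)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = pd.DataFrame({
        "barcode": [p.barcode for p in profiles],
        "reads_a": [p.reads_species_a for p in profiles],
        "reads_b": [p.reads_species_b for p in profiles],
    })
    reads.to_csv(outdir / "reads.tsv", sep="\t", index=False)
    rows = [(p.barcode, snp, ref, alt)
            for p in profiles for snp, (ref, alt) in sorted(p.allele_counts.items())]
    pd.DataFrame(rows, columns=["barcode", "snp_id", "ref", "alt"]).to_csv(
        outdir / "alleles.tsv", sep="\t", index=False)
    return outdir


def read_droplet_tables(reads_path, alleles_path):
    from .demux import DropletProfile

    reads = pd.read_csv(reads_path, sep="\t")
    alleles = pd.read_csv(alleles_path, sep="\t")
    by_bc: dict[str, dict] = {bc: {} for bc in reads["barcode"]}
    for bc, snp, ref, alt in alleles.itertuples(index=False):
        by_bc.setdefault(bc, {})[snp] = (int(ref), int(alt))
    return [DropletProfile(r.barcode, int(r.reads_a), int(r.reads_b),
                           by_bc.get(r.barcode, {}))
            for r in reads.itertuples(index=False)]


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
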