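# crosspool

Demultiplexing and differential analysis for **cross-species pooled
single-nucleus RNA-seq**.

When nuclei from two closely related species (here, two deer-mouse species
profiled in the hypothalamic preoptic area) are pooled into the same 10x
runs — two species x two sexes per pool, across replicate pools — every
downstream comparison rests on a chain of bespoke statistics:

1. **Species demultiplexing.** Each droplet's reads are mapped to both
   genomes; the majority species is "primary". Binning droplets by primary
   reads (500-read increments), fitting the within-bin secondary-read
   distribution with a two-Gaussian mixture (EM), finding each bin's
   density crossing point, and regressing the crossings on the bin centers
   yields a threshold line that flags cross-species multiplets.
2. **Sample demultiplexing.** Within the called species, a genotype
   likelihood over per-droplet SNP allele counts (alt-read probability
   eps / 0.5 / 1-eps by dosage) calls the pooled sample, flags 50/50
   genotype mixtures as sample multiplets, and leaves uninformative
   droplets unassigned.
3. **Differential cell-type abundance.** Cluster x sample cell counts are
   treated as count data: TMM normalization, NB GLM with
   log mu = replicate + sex + species + offset, likelihood-ratio tests per
   contrast, BH FDR with a deliberately lenient 0.3 candidate cutoff.
4. **Pseudobulk differential expression.** Gene counts summed per
   (cluster, sample); the same GLM engine tests species (24 samples) and,
   separately per species, sex (12 samples) at FDR 0.05.
5. **Homology mapping.** Clusters are classed inhibitory/excitatory by
   Gad1/Gad2 vs Slc17a6 and mapped to reference cell-type labels wherever
   at least 15% of a cluster shares a transferred label.
6. **Expression-matched enrichment.** DE genes are compared against
   backgrounds resampled from 0.5-log10(CPM) expression bins (B = 5000);
   enrichment score = foreground count / mean background count, with
   empirical p-values floored at the 1/B resolution bound.

A built-in synthetic-data generator reproduces the study's structure
(6 pools x 4 samples, ~20,000 droplets/pool at a 9% doublet rate,
~50 clusters, planted fold changes) with known ground truth, so every
stage is testable end to end without any download. See `docs/methods.md`
for models, assumptions, and numerical choices.

## Worked example

```python
import logging; logging.disable(logging.WARNING)
from crosspool.simulate import SimConfig, simulate_pooled_run, simulate_cluster_assignments
from crosspool.demux import SpeciesDemuxModel
from crosspool.abundance import DifferentialAbundanceModel

cfg = SimConfig(seed=1, abundance_effects=[("c00", "species", 1.6)])

# stage 1: flag cross-species multiplets in one 20,000-droplet pool
profiles, truth = simulate_pooled_run(cfg)
res = SpeciesDemuxModel.from_profiles(profiles).fit()
line = res.threshold_line
print(f"threshold: secondary = {line.slope:.3f} x primary + {line.intercept:.1f}")
print(res.calls["status"].value_counts().to_string())

# stage 3: recover a planted 1.6x species abundance effect
obs, _ = simulate_cluster_assignments(cfg)
da = DifferentialAbundanceModel(obs).fit()
row = da.table.query("cluster == 'c00' and contrast == 'species'").iloc[0]
print(f"c00 species log2FC = {row.log2_fold_change:.3f} "
      f"(fold {2**row.log2_fold_change:.2f}), FDR = {row.fdr:.2e}")
```

prints

```
threshold: secondary = 0.083 x primary + -124.5
status
singlet              18749
species_multiplet     1251
c00 species log2FC = 0.590 (fold 1.51), FDR = 5.41e-03
```

The 1,251 flagged droplets are 6.3% of the pool — the detectable
(cross-species) share of the 9% doublet rate, since only 4 of the 6
possible sample pairings span species. The planted 1.6x effect on the
largest cluster is recovered as a 1.51-fold estimate, significant far
below the 0.3 candidate cutoff; the 49 null clusters yield no species
candidates and the sex contrast none at all.

The same workflow is available from the shell:

```bash
crosspool all --seed 1 --out-dir runs/demo          # full synthetic pipeline
crosspool demux --reads reads.tsv --alleles alleles.tsv \
    --vcf-a genoA.vcf --vcf-b genoB.vcf --bin-width 500 --out calls.tsv
```

Subcommands `simulate`, `demux`, `abundance`, `de`, `annotate`, `enrich`
and `all` consume/produce plain TSV, Matrix Market and GT-only VCF, and
every run writes a deterministic `report.json` keyed to one root seed.

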