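# Methods

`crosspool` implements the bespoke computational stages of a two-species
pooled single-nucleus RNA-seq comparison: droplet demultiplexing by species
and pooled sample, count-GLM tests of differential cell-type abundance and
pseudobulk differential expression, inhibitory/excitatory classing with
proportion-threshold homology mapping, and an expression-matched
permutation test for gene-category enrichment. This note records the
models, their assumptions, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Species and sample demultiplexing

Two species are nuclei-pooled in each 10x run, so every droplet carries
reads mapped against both genomes. A droplet's **primary species** is the
majority vote of the two read counts; ties (measure-zero in practice) go to
species A with a logged warning, on the expectation that a genuinely tied
droplet is a multiplet and will be flagged anyway.

Cross-species multiplets are separated from singlets geometrically.
Droplets are binned by primary-genome reads in half-open 500-read
increments. Within each bin, the distribution of *secondary*-genome reads
is bimodal: a dense component near zero (singlets whose secondary reads are
mismapping noise) and a sparse component near the bin center (doublets
whose two nuclei split the total depth roughly evenly). Each bin is fitted
with a two-component univariate Gaussian mixture by EM:

- deterministic initialization at the 25th/75th within-bin percentiles with
  pooled SD and equal weights — no seed sensitivity on the common path;
- relative log-likelihood tolerance 1e-6, at most 500 iterations, with the
  trace recorded (it is asserted non-decreasing in the tests);
- a variance floor of (1e-6 x data range)^2 prevents collapse onto a point;
- components are reported in canonical order mu1 < mu2.

The **crossing point** of the two weighted densities is the root of the
quadratic obtained by equating the two log densities, taking the root
strictly between the means. An ordinary least-squares line through the
(bin center, crossing) points is the classification threshold: a droplet is
a species multiplet iff its secondary reads exceed the line at its primary
reads.

Two stability rules decide which bins contribute a crossing. Bins with
fewer than 50 droplets are skipped (mixture fits on tiny bins are
unstable). Additionally, a fitted bin only contributes when both components
are genuinely supported — each carries at least 15 effective droplets
(weight x bin size), neither SD sits at the variance floor, and the means
separate by more than twice the summed SDs. Without the second rule, bins
containing zero-to-a-couple true multiplets produce EM artifacts (a
component collapsed onto one outlier, or a split of the singlet cloud)
whose "crossings" sit near the bin center and destroy the regression; with
it, species-multiplet precision and recall both exceed 0.9 on synthetic
pools across seeds.

Within the called species, the pooled sample of origin is inferred from SNP
allele counts with a count-level genotype likelihood (a deliberately
simple, documented stand-in for external genotype-demultiplexing tools; no
ambient-RNA or per-base-quality modeling). For candidate sample s with alt
dosage g at a covered SNP, alt reads are Binomial with success probability
eps (g=0), 0.5 (g=1) or 1-eps (g=2), eps = 0.01. Every single sample and
every 50/50 two-sample mixture is scored; a mixture beating all singletons
by more than delta = 2 natural-log units is a sample multiplet, top
singletons within delta of each other are ambiguous, otherwise the best
singleton is called. Droplets with no informative SNP coverage are
ambiguous/UNASSIGNED. Multiplets flagged at either stage (the union) are
excluded from all downstream counting.

## The count-GLM engine

Both differential abundance and differential expression reduce to the same
sample-level model: counts y (cluster cell counts, or pseudobulk gene
counts) follow NB(mu, phi) with log mu = X beta + offset, where X holds an
intercept plus treatment-coded indicators for replicate, sex and species
(levels sorted; the reported log2 fold change is therefore second level
over first: B/A for species, M/F for sex), and the offset is log(library
size x TMM factor).

**TMM factors** follow the trimmed-mean-of-M-values definition: against a
reference sample (upper-quartile rule), M- and A-values of doubly-nonzero
features are two-sided-trimmed (30% on M, 5% on A), the surviving M-values
averaged with delta-method precision weights, exponentiated, and the
factors rescaled to geometric mean one. The implementation reproduces
edgeR's calcNormFactors to ~1e-6 on spiked toys (frozen value in the
tests).

**Dispersion** is estimated per feature by maximizing the Cox-Reid adjusted
profile likelihood — NB log-likelihood at the IRLS fit minus half the log
determinant of the weighted information X'WX — on a 36-point log grid from
1e-6 to ~16, refined by parabolic interpolation in log space. Each
feature's APL is combined with the pooled mean APL weighted 10/n (a prior
worth ten samples), shrinking noisy per-feature estimates toward the
common value. Method-of-moments-scale grids and warm-started IRLS keep the
whole grid pass vectorized across features. All-zero features get NaN.

**Fitting** is iteratively reweighted least squares, vectorized across all
features sharing a design: weights mu/(1 + phi mu), convergence at 1e-8
relative deviance change, at most 100 iterations, coefficients capped at
+/-30 on the natural-log scale. A fit reaching the cap (a design cell with
all zeros) is flagged *separated* and its tests return NaN. statsmodels'
NB GLM serves as an independent oracle in the test suite, never as the
implementation.

**Coefficient tests** drop one column and compare deviances. The
likelihood-ratio statistic is referred to F(1, residual df + 10) in the
table-level drivers rather than chi-square(1): at 24 samples the asymptotic
chi-square reference rejects true nulls at 5.8-7.0% for a nominal 5% even
when the dispersion is known, and the F denominator credits the residual
degrees of freedom plus the dispersion prior's worth of samples (the same
convention quasi-likelihood testing uses). Null simulations at the study's
design land at 3.8-5.7% across seeds with this reference; it converges to
the chi-square as samples grow. The single-fit API keeps the asymptotic
chi-square default with an opt-in `denom_df`.

**FDR** is Benjamini-Hochberg step-up with NaNs excluded from the family
size. Features with fewer than 10 total counts are filtered before testing
(configurable).

## Differential abundance

Cells are cross-tabulated into a cluster x sample count matrix (exact;
unobserved pairs are zero). TMM over cluster sizes plus library-size
offsets absorb the differing numbers of neurons profiled per sample — the
normalization assumes cluster-size composition is broadly comparable across
samples, which is a known caveat of this design. One joint NB GLM per
cluster (replicate + sex + species) supplies both contrasts without
refitting. The default candidate threshold is the deliberately lenient
FDR < 0.3, intended to nominate clusters for independent (e.g. histological)
validation rather than to be a final claim. Clusters with fewer than 20
cells in total are reported but flagged low-confidence.

## Pseudobulk differential expression

Gene counts are summed over all cells of each (cluster, sample) pair —
integer-exact, asserted as an identity in the tests. Two designs run per
cluster: species differences with replicate + sex + species over all 24
samples, and sex differences within each species with replicate + sex over
that species' 12 samples. Genes with zero counts in a cluster leave that
cluster's family before BH; FDR (cutoff 0.05) is applied within each
cluster's gene family, matching the per-cluster presentation of DE counts
(a global family is one switch away). Shared sex bias across species
requires the same gene, same cluster and same direction in both species.
Because library-size offsets normalize pseudobulk totals, cell-type
abundance is controlled for without any per-cell-count scaling; a direct
consequence, reproduced in the tests, is that a cluster's DE-gene count
grows with its abundance (detection power tracks cells sequenced).

## Homology mapping

Clusters are classed inhibitory or excitatory by comparing the mean of the
two inhibitory markers (Gad1, Gad2) against Slc17a6 on normalized mean
expression; "mean" is a choice (the comparison rule is stated only as
"higher expression"), switchable to "max". Exact ties or all-zero markers
are unassigned. Transferred reference labels — produced upstream,
class-restricted by construction — are cross-tabulated per cluster and
row-normalized. Reference labels known to map indiscriminately (default
exclusion list: e1:Glut, i1:Gaba, i7:Gaba, i9:Gaba, i11:Gaba, i13:Gaba,
i12:Gaba, i15:Gaba, i39:Gaba) are removed before thresholding, then every
remaining label covering at least 15% of a cluster is accepted; a cluster
may map to several labels, or to none (unmapped). The 15% threshold is
taken as given; no data-driven selection is implemented. Accepted pairs are
monotone non-increasing in the threshold (property-tested).

## Expression-matched enrichment

Highly expressed genes are more accurately quantified and hence more likely
to reach significance, so category enrichment among DE genes is tested
against expression-matched backgrounds. All genes are binned by
floor(log10 CPM / 0.5) (half-open bins; zero-CPM genes occupy a dedicated
bin that participates like any other). A gene DE in several clusters is
matched at its highest expression among them; universe genes are binned at
their maximum per-cluster CPM for consistency with that rule. Each of
B = 5000 background lists replaces every foreground gene with an
independent uniform draw from its bin — the entire dataset participates,
foreground genes included, and repeats across positions are possible. The
empirical p-value is k/B, where k counts lists whose category hit count is
*equal or higher* than the foreground's; k = 0 reports the resolution
bound 1/B (2e-4 at B = 5000) rather than a smoothed estimator, because the
bound is what a resampling test can honestly state. The enrichment score is
the foreground count over the mean background count (+inf flagged when the
mean is zero), and BH FDR runs across the tested categories.

## Synthetic data generator

The generator emulates the deposited study's structure: 6 replicate pools x
4 samples (2 species x 2 sexes), 20,000 droplets per pool, a 9% doublet
rate, ~50 clusters, and planted effects at the magnitudes the study
reports (e.g. 1.6x / 3.4x abundance shifts, 2x expression shifts). Choices
the source data do not pin down are stated assumptions, fixed once:

- per-droplet total reads LogNormal(log 10000, 0.6);
- doublets are pairs only, splitting reads Binomial(total, 1/2) — the
  threshold separates two clusters and higher orders add nothing testable;
- a 1% mismap rate leaks singlet reads to the other genome;
- SNP reads are Poisson-thinned from total reads at rate 0.002 over a
  200-SNP panel per species (MAF Beta-distributed around 0.3, resampled
  until every sample pair is discriminable), with a 1e-3 base error;
- per-sample cell totals LogNormal around 500 (sdlog 0.2) and per-sample
  cluster proportions jittered lognormally (sdlog 0.1): replicate animals
  never yield identical compositions, and without that variability cluster
  counts conditioned on totals would be sub-Poisson — a regime real
  replicated data does not occupy and the NB model cannot represent;
- gene baselines LogNormal (sorted descending), per-cluster lognormal
  perturbation (sdlog 0.3), class markers boosted 5x in their own class
  and suppressed in the other, cell depths LogNormal around 2500, and
  NB(mu, phi = 0.1) counts at the cell level via Gamma-Poisson mixing;
- a female marker gene ("Xist") is structurally zero in male cells;
- expression is compositional per cell (relative abundances renormalized),
  so planting a strong effect in some genes induces small opposite shifts
  in the rest — as in real sequencing.

All randomness flows from one root seed through named, hash-derived child
streams, so identical configs give bit-identical outputs and stages can be
regenerated independently. What the generator does **not** emulate:
ambient RNA, empty droplets, UMI collisions (background filtering is
upstream and out of scope), batch chemistry effects, doublets of more than
two nuclei, and clustering/label-transfer errors beyond a flat 20% label
noise within the correct neuronal class. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative model, not that the pipeline is robust to every artifact
of real droplet data.

## Problem sizes in the test suite

The suite exercises the study's sample design (24 samples) throughout.
Null-calibration runs use 2,000 features per contrast (one 2,000-gene
pseudobulk table; 40 composition draws x 50 clusters for abundance); power
runs use 20 seeds at 12-vs-12 samples with effects planted in mid-expression
genes of the largest cluster (where the study-scale power the pipeline
promises is actually attainable); demultiplexing recovery runs on one full
20,000-droplet pool, with ten 6,000-droplet pools behind the invariant
checks. These sizes were chosen as the smallest that make the binomial
acceptance bands meaningful.

## Known limitations

- The coefficient test is an NB likelihood-ratio test with an F-calibrated
  reference, not the quasi-likelihood F-test; bit-level agreement with
  edgeR outputs is a non-goal (contract-level equivalence — calibrated
  type-I error, consistent effect estimates — is what the tests assert).
- TMM on cluster-size matrices inherits the minimal-composition-change
  assumption; no compositional alternative is implemented.
- The genotype assigner is count-level only and assumes the pool's
  genotypes are known and correct.
- Exact invariance of coefficients to rescaling a *single* sample's counts
  and library does not hold for any count GLM (the sample's information
  weight changes); the engine guarantees exact absorption of joint scaling
  and near-invariance (<1e-3 in log2FC on well-populated features) for
  single-sample scaling.
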