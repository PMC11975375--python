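"""Species and sample demultiplexing of pooled droplets.

Two pooled species are separated per droplet by majority vote of reads
mapped to each genome. Cross-species multiplets are then flagged with the
binned mixture threshold: droplets are binned by reads to the *primary*
genome in 500-read increments, the within-bin distribution of reads to the
*secondary* genome is fitted with a two-component Gaussian mixture by EM,
the crossing point of the two weighted densities is found per bin, and an
ordinary least-squares line through the (bin center, crossing) points is
the singlet/multiplet threshold. Within the called species, samples are
assigned by a count-level genotype likelihood: each candidate sample (and
each 50/50 two-sample mixture) gives a binomial probability of alt reads
at every covered SNP; the winner by a log-likelihood margin is called.

``SpeciesDemuxModel`` bundles the threshold stage statsmodels-style:
construct from per-droplet read counts, ``fit()`` returns a results object
carrying the per-bin mixture fits, the threshold line, per-droplet calls
and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DropletProfile",
    "MixtureFit",
    "ThresholdLine",
    "SampleCall",
    "assign_primary_species",
    "bin_by_primary_reads",
    "fit_two_gaussian_mixture",
    "gaussian_crossing",
    "fit_threshold_line",
    "classify_species_multiplets",
    "assign_sample_by_genotype",
    "SpeciesDemuxModel",
    "SpeciesDemuxResults",
    "demux_pool",
]

DEFAULT_BIN_WIDTH = 500
MIN_BIN_DROPLETS = 50
#: a bin's crossing enters the line fit only when both mixture components
#: have at least this many effective droplets behind them
MIN_COMPONENT_DROPLETS = 15
#: ... and the means are separated by this many pooled SDs (otherwise the
#: EM has split a single cloud, or collapsed onto an outlier, and the
#: "crossing" is an artifact of a degenerate fit)
MIN_SEPARATION_SDS = 2.0


@dataclass
class DropletProfile:
    """Per-droplet evidence used for demultiplexing.

    ``allele_counts`` maps SNP id -> (ref_count, alt_count).
    """

    barcode: str
    reads_species_a: int
    reads_species_b: int
    allele_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.reads_species_a < 0 or self.reads_species_b < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture fitted within one bin."""

    bin_index: int
    bin_center_reads: float
    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    n_droplets: int
    converged: bool
    loglik_trace: list[float]
    crossing_point: float | None = None


@dataclass
class ThresholdLine:
    """OLS line through (bin center, mixture crossing) points."""

    slope: float
    intercept: float
    n_points: int

    def __call__(self, primary_reads):
        return self.slope * np.asarray(primary_reads, dtype=float) + self.intercept


@dataclass
class SampleCall:
    barcode: str
    species: str
    sample_id: str  # "UNASSIGNED" when not callable
    status: str  # singlet | species_multiplet | sample_multiplet | ambiguous
    logliks: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage 1: species majority vote and mixture threshold
# ---------------------------------------------------------------------------

def assign_primary_species(profile: DropletProfile) -> tuple[str, int, int]:
    """Majority-rule species call; returns (species, primary, secondary).

    Ties go to species A with a logged warning; a tied droplet is normally
    a multiplet and gets flagged downstream anyway.
    """
    a, b = profile.reads_species_a, profile.reads_species_b
    if a + b == 0:
        raise ValueError(f"droplet {profile.barcode}: zero mapped reads")
    if a == b:
        logger.warning("droplet %s: tied read counts (%d); assigning species A",
                       profile.barcode, a)
        return "A", a, b
    return ("A", a, b) if a > b else ("B", b, a)


def bin_by_primary_reads(primary_reads, width: int = DEFAULT_BIN_WIDTH):
    """Half-open read-count bins: index = floor(primary / width)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return np.floor_divide(np.asarray(primary_reads, dtype=np.int64), int(width))


def fit_two_gaussian_mixture(values, tol: float = 1e-6, max_iter: int = 500,
                             seed: int | None = None, bin_index: int = 0,
                             bin_center: float = 0.0) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to one bin's values.

    Initialization is deterministic (components at the 25th/75th
    percentiles, pooled SD, equal weights), so ``seed`` is accepted for
    API symmetry but does not influence the common path. Components are
    returned in canonical order mu1 < mu2; the log-likelihood trace is
    recorded and is non-decreasing up to floating-point noise.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate bin: all values identical")
    rng = x.max() - x.min()
    var_floor = (1e-6 * rng) ** 2

    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()], dtype=float)
    sd = np.full(2, max(x.std(), math.sqrt(var_floor)))
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step in log space for stability
        logp = (np.log(w)[:, None]
                - 0.5 * np.log(2 * np.pi * sd[:, None] ** 2)
                - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2)
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)

        if trace and abs(ll - trace[-1]) <= tol * (abs(trace[-1]) + 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ (x ** 2)) / nk - mu ** 2
        sd = np.sqrt(np.maximum(var, var_floor))

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    return MixtureFit(
        bin_index=bin_index,
        bin_center_reads=bin_center,
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        n_droplets=int(x.size),
        converged=converged,
        loglik_trace=trace,
    )


def gaussian_crossing(fit: MixtureFit) -> float:
    """x in (mu1, mu2) where the two weighted component densities cross.

    Setting w1*phi(x; mu1, s1) = w2*phi(x; mu2, s2) and taking logs gives a
    quadratic in x; the root strictly between the means is returned.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if not m1 < m2:
        raise ValueError("no interior crossing: component means coincide")
    A = 0.5 / s2 ** 2 - 0.5 / s1 ** 2
    B = m1 / s1 ** 2 - m2 / s2 ** 2
    C = (math.log(w1 * s2 / (w2 * s1))
         - m1 ** 2 / (2 * s1 ** 2) + m2 ** 2 / (2 * s2 ** 2))
    if abs(A) < 1e-300 * max(1.0, abs(B)):
        if B == 0:
            raise ValueError("no interior crossing")
        roots = [-C / B]
    else:
        disc = B ** 2 - 4 * A * C
        if disc < 0:
            raise ValueError("no interior crossing")
        sq = math.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    interior = [r for r in roots if m1 < r < m2]
    if not interior:
        raise ValueError("no interior crossing between component means")
    return float(interior[0])


def fit_threshold_line(points) -> ThresholdLine:
    """OLS fit of crossing point on bin center over all usable bins."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("insufficient bins: need >= 2 crossing points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("insufficient bins: degenerate bin centers")
    slope, intercept = np.polyfit(x, y, 1)
    return ThresholdLine(slope=float(slope), intercept=float(intercept),
                         n_points=int(pts.shape[0]))


def _usable_mixture(fit: MixtureFit, values: np.ndarray) -> bool:
    """True when the fit describes two genuinely supported components.

    Bins where one component rests on a handful of droplets (EM collapse
    onto an outlier, sd at the variance floor) or where the means are not
    separated relative to the spreads (EM split a single cloud) yield
    crossing points that are fit artifacts, not a singlet/multiplet
    boundary, and are kept out of the threshold-line regression.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    n = fit.n_droplets
    if min(w1, w2) * n < MIN_COMPONENT_DROPLETS:
        return False
    floor = 1e-6 * np.ptp(values)
    if min(s1, s2) <= 3 * floor:
        return False
    return (m2 - m1) > MIN_SEPARATION_SDS * (s1 + s2)


def classify_species_multiplets(primary_reads, secondary_reads,
                                line: ThresholdLine) -> np.ndarray:
    """'species_multiplet' where secondary reads exceed the line, else 'singlet'."""
    sec = np.asarray(secondary_reads, dtype=float)
    above = sec > line(primary_reads)
    return np.where(above, "species_multiplet", "singlet")


# ---------------------------------------------------------------------------
# Stage 2: genotype-likelihood sample assignment
# ---------------------------------------------------------------------------

def _alt_probs(genotype_row: pd.Series, eps: float) -> pd.Series:
    table = {0: eps, 1: 0.5, 2: 1.0 - eps}
    return genotype_row.map(table)


def assign_sample_by_genotype(profile: DropletProfile, genotypes: pd.DataFrame,
                              species: str, eps: float = 0.01,
                              delta: float = 2.0) -> SampleCall:
    """Call the pooled sample of origin from SNP allele counts.

    ``genotypes`` is samples x SNP ids with alt-allele dosages {0, 1, 2}.
    Observed alt reads at a SNP are Binomial with success probability eps,
    0.5 or 1-eps for dosage 0/1/2. Every single sample and every 50/50
    two-sample mixture is scored; a mixture beating all singletons by more
    than ``delta`` log-units is a sample_multiplet, top singletons within
    ``delta`` of each other are ambiguous, otherwise the best singleton.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    snps = [s for s in profile.allele_counts if s in genotypes.columns]
    ref = np.array([profile.allele_counts[s][0] for s in snps], dtype=float)
    alt = np.array([profile.allele_counts[s][1] for s in snps], dtype=float)
    covered = (ref + alt) > 0
    if not snps or not covered.any():
        return SampleCall(profile.barcode, species, "UNASSIGNED", "ambiguous")
    ref, alt = ref[covered], alt[covered]
    cols = [s for s, c in zip(snps, covered) if c]

    p_by_sample = {s: _alt_probs(genotypes.loc[s, cols], eps).to_numpy(dtype=float)
                   for s in genotypes.index}

    def loglik(p):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(alt * np.log(p) + ref * np.log1p(-p)))

    singles = {s: loglik(p) for s, p in p_by_sample.items()}
    mixtures = {}
    samples = list(genotypes.index)
    for i, s in enumerate(samples):
        for t in samples[i + 1:]:
            mixtures[f"{s}+{t}"] = loglik(0.5 * (p_by_sample[s] + p_by_sample[t]))

    best_s = max(singles, key=singles.get)
    ranked = sorted(singles.values(), reverse=True)
    logliks = {**singles, **mixtures}
    if mixtures:
        best_m = max(mixtures, key=mixtures.get)
        if mixtures[best_m] - singles[best_s] > delta:
            return SampleCall(profile.barcode, species, "UNASSIGNED",
                              "sample_multiplet", logliks)
    if len(ranked) > 1 and ranked[0] - ranked[1] < delta:
        return SampleCall(profile.barcode, species, "UNASSIGNED", "ambiguous", logliks)
    return SampleCall(profile.barcode, species, best_s, "singlet", logliks)


# ---------------------------------------------------------------------------
# Model/Results wrapper for the threshold stage
# ---------------------------------------------------------------------------

class SpeciesDemuxModel:
    """Binned-mixture species demultiplexer for one pooled 10x run.

    Parameters
    ----------
    reads : DataFrame with columns barcode, reads_a, reads_b
        Per-droplet read counts mapped to each species' genome.
    bin_width : primary-read bin width (500-read increments by default).
    min_bin_droplets : bins with fewer droplets contribute no crossing.
    """

    def __init__(self, reads: pd.DataFrame, bin_width: int = DEFAULT_BIN_WIDTH,
                 min_bin_droplets: int = MIN_BIN_DROPLETS):
        req = {"barcode", "reads_a", "reads_b"}
        if not req.issubset(reads.columns):
            raise ValueError(f"reads table needs columns {sorted(req)}")
        self.reads = reads.reset_index(drop=True)
        self.bin_width = int(bin_width)
        self.min_bin_droplets = int(min_bin_droplets)

    @classmethod
    def from_profiles(cls, profiles, **kw) -> "SpeciesDemuxModel":
        df = pd.DataFrame({
            "barcode": [p.barcode for p in profiles],
            "reads_a": [p.reads_species_a for p in profiles],
            "reads_b": [p.reads_species_b for p in profiles],
        })
        return cls(df, **kw)

    def fit(self) -> "SpeciesDemuxResults":
        a = self.reads["reads_a"].to_numpy(dtype=np.int64)
        b = self.reads["reads_b"].to_numpy(dtype=np.int64)
        if np.any(a + b == 0):
            raise ValueError("droplets with zero mapped reads present")
        primary = np.maximum(a, b)
        secondary = np.minimum(a, b)
        species = np.where(a >= b, "A", "B")
        n_ties = int(np.sum(a == b))
        if n_ties:
            logger.warning("%d droplets with tied read counts assigned species A", n_ties)

        bins = bin_by_primary_reads(primary, self.bin_width)
        fits: list[MixtureFit] = []
        points: list[tuple[float, float]] = []
        for k in np.unique(bins):
            vals = secondary[bins == k]
            if vals.size < self.min_bin_droplets:
                continue
            center = (k + 0.5) * self.bin_width
            try:
                fit = fit_two_gaussian_mixture(vals, bin_index=int(k), bin_center=center)
            except ValueError:
                continue
            if not fit.converged or not _usable_mixture(fit, vals):
                fits.append(fit)
                continue
            try:
                fit.crossing_point = gaussian_crossing(fit)
                points.append((center, fit.crossing_point))
            except ValueError:
                pass
            fits.append(fit)
        line = fit_threshold_line(points)
        status = classify_species_multiplets(primary, secondary, line)
        calls = pd.DataFrame({
            "barcode": self.reads["barcode"],
            "species": species,
            "primary_reads": primary,
            "secondary_reads": secondary,
            "bin": bins,
            "status": status,
        })
        return SpeciesDemuxResults(self, fits, line, calls)


@dataclass
class SpeciesDemuxResults:
    """Fitted threshold model: per-bin mixtures, line, per-droplet calls."""

    model: SpeciesDemuxModel
    mixture_fits: list[MixtureFit]
    threshold_line: ThresholdLine
    calls: pd.DataFrame

    @property
    def n_multiplets(self) -> int:
        return int((self.calls["status"] == "species_multiplet").sum())

    def summary(self) -> pd.DataFrame:
        rows = [{
            "bin": f.bin_index,
            "bin_center": f.bin_center_reads,
            "n": f.n_droplets,
            "w1": f.weights[0], "w2": f.weights[1],
            "mu1": f.means[0], "mu2": f.means[1],
            "sd1": f.sds[0], "sd2": f.sds[1],
            "converged": f.converged,
            "crossing": f.crossing_point,
        } for f in self.mixture_fits]
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "bin_width": self.model.bin_width,
            "threshold_line": {
                "slope": self.threshold_line.slope,
                "intercept": self.threshold_line.intercept,
                "n_points": self.threshold_line.n_points,
            },
            "bins": self.summary().to_dict(orient="records"),
        }


def demux_pool(profiles, genotypes_by_species: dict[str, pd.DataFrame],
               bin_width: int = DEFAULT_BIN_WIDTH, eps: float = 0.01,
               delta: float = 2.0,
               min_bin_droplets: int = MIN_BIN_DROPLETS) -> tuple[pd.DataFrame, SpeciesDemuxResults]:
    """Two-stage demultiplexing of one pool.

    Species multiplets are flagged first by the mixture threshold; sample
    assignment by genotype then runs on the remaining droplets within their
    called species. Droplets flagged at either stage are multiplets and are
    excluded from downstream counting. Returns (calls table, stage-1 results).
    """
    model = SpeciesDemuxModel.from_profiles(profiles, bin_width=bin_width,
                                            min_bin_droplets=min_bin_droplets)
    res = model.fit()
    by_barcode = {p.barcode: p for p in profiles}
    rows = []
    for _, rec in res.calls.iterrows():
        bc, sp, status = rec["barcode"], rec["species"], rec["status"]
        if status == "species_multiplet":
            rows.append((bc, sp, "UNASSIGNED", "species_multiplet"))
            continue
        call = assign_sample_by_genotype(by_barcode[bc], genotypes_by_species[sp],
                                         sp, eps=eps, delta=delta)
        rows.append((bc, sp, call.sample_id, call.status))
    calls = pd.DataFrame(rows, columns=["barcode", "species", "sample", "status"])
    return calls, res
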