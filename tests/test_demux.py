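"""Species/sample demultiplexing: mixture EM, crossings, threshold line,
genotype-likelihood assignment."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from crosspool.demux import (
    DropletProfile,
    MixtureFit,
    SpeciesDemuxModel,
    assign_primary_species,
    assign_sample_by_genotype,
    bin_by_primary_reads,
    classify_species_multiplets,
    fit_threshold_line,
    fit_two_gaussian_mixture,
    gaussian_crossing,
)


def profile(a, b, alleles=None, bc="bc1"):
    return DropletProfile(bc, a, b, alleles or {})


class TestPrimarySpecies:
    @pytest.mark.parametrize("a, b, expected", [
        (900, 100, ("A", 900, 100)),
        (100, 900, ("B", 900, 100)),
    ])
    def test_majority_rule(self, a, b, expected):
        assert assign_primary_species(profile(a, b)) == expected

    def test_tie_goes_to_a_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="crosspool.demux"):
            assert assign_primary_species(profile(500, 500)) == ("A", 500, 500)
        assert "tied" in caplog.text

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            assign_primary_species(profile(0, 0))


class TestBinning:
    @pytest.mark.parametrize("reads, expected", [(250, 0), (500, 1), (1249, 2)])
    def test_half_open_bins(self, reads, expected):
        assert bin_by_primary_reads(reads, 500) == expected

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            bin_by_primary_reads(100, 0)


class TestMixtureEM:
    def test_two_component_recovery_over_seeds(self):
        """Means of Normal(50, 5) + Normal(400, 30) halves recovered within
        +/- 5 across 10 seeds."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.r_[r.normal(50, 5, 1000), r.normal(400, 30, 1000)]
            fit = fit_two_gaussian_mixture(x)
            assert fit.converged
            assert fit.means[0] == pytest.approx(50, abs=5)
            assert fit.means[1] == pytest.approx(400, abs=5)

    def test_symmetric_sample_gives_equal_weights(self):
        r = np.random.default_rng(3)
        half = r.normal(0, 1, 1500)
        x = np.r_[half + 10, -half - 10 + 20]  # exact mirror around 10
        fit = fit_two_gaussian_mixture(x)
        assert abs(fit.weights[0] - 0.5) < 0.05

    def test_degenerate_bin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_two_gaussian_mixture(np.full(100, 7.0))

    def test_loglik_trace_non_decreasing(self):
        r = np.random.default_rng(4)
        x = np.r_[r.normal(10, 2, 300), r.normal(60, 8, 100)]
        fit = fit_two_gaussian_mixture(x)
        t = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(t) >= -1e-7 * np.abs(t[:-1]))

    def test_canonical_component_order(self):
        r = np.random.default_rng(5)
        x = np.r_[r.normal(100, 5, 500), r.normal(20, 3, 500)]
        fit = fit_two_gaussian_mixture(x)
        assert fit.means[0] < fit.means[1]
        assert abs(sum(fit.weights) - 1) < 1e-9

    def test_agrees_with_sklearn_em(self):
        """Independent EM oracle: scikit-learn's GaussianMixture lands on
        the same two components."""
        from sklearn.mixture import GaussianMixture

        r = np.random.default_rng(6)
        x = np.r_[r.normal(30, 4, 800), r.normal(250, 25, 200)]
        ours = fit_two_gaussian_mixture(x)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        sk_means = np.sort(gm.means_.ravel())
        assert np.allclose(ours.means, sk_means, atol=2.0)


def make_fit(w, mu, sd):
    return MixtureFit(0, 0.0, tuple(w), tuple(mu), tuple(sd), 100, True, [])


class TestCrossing:
    def test_symmetric_case_is_midpoint(self):
        fit = make_fit((0.5, 0.5), (0.0, 4.0), (1.0, 1.0))
        assert gaussian_crossing(fit) == pytest.approx(2.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        fit = make_fit((0.5, 0.5), (0.0, 3.0), (1.0, 2.0))
        x = np.linspace(0, 3, 300001)
        d1 = 0.5 / (1.0 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * x ** 2)
        d2 = 0.5 / (2.0 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - 3) / 2) ** 2)
        grid_root = x[np.argmin(np.abs(d1 - d2))]
        assert gaussian_crossing(fit) == pytest.approx(grid_root, abs=1e-4)

    def test_equal_means_rejected(self):
        fit = make_fit((0.5, 0.5), (2.0, 2.0), (1.0, 1.0))
        with pytest.raises(ValueError, match="crossing"):
            gaussian_crossing(fit)


class TestThresholdLine:
    def test_exact_collinear_points(self):
        line = fit_threshold_line([(0, 0), (1, 1), (2, 2)])
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    def test_two_points_interpolated_exactly(self):
        line = fit_threshold_line([(100, 10), (300, 50)])
        assert line(100) == pytest.approx(10)
        assert line(300) == pytest.approx(50)

    def test_matches_normal_equations(self, rng):
        x = np.arange(10, dtype=float)
        y = 3 * x + 2 + rng.normal(0, 0.5, 10)
        line = fit_threshold_line(np.c_[x, y])
        X = np.c_[x, np.ones(10)]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert line.slope == pytest.approx(beta[0], abs=1e-10)
        assert line.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_threshold_line([(1, 1)])


class TestClassification:
    def test_relative_to_line(self):
        line = fit_threshold_line([(0, 100), (1000, 100)])  # flat at 100
        status = classify_species_multiplets([500, 500], [5, 500], line)
        assert list(status) == ["singlet", "species_multiplet"]


class TestGenotypeAssignment:
    @pytest.fixture
    def genotypes(self):
        # sample s1 homozygous-alt, s2 homozygous-ref at 10 SNPs
        return pd.DataFrame({f"snp{j}": [2, 0] for j in range(10)},
                            index=["s1", "s2"])

    def test_discriminating_reads_call_singlet_with_margin(self, genotypes):
        eps = 0.01
        alleles = {f"snp{j}": (0, 1) for j in range(10)}  # 10 alt reads
        call = assign_sample_by_genotype(profile(900, 5, alleles), genotypes,
                                         "A", eps=eps)
        assert call.status == "singlet" and call.sample_id == "s1"
        margin = call.logliks["s1"] - call.logliks["s2"]
        assert margin >= 10 * math.log((1 - eps) / eps) - 1e-9

    def test_no_coverage_is_unassigned(self, genotypes):
        call = assign_sample_by_genotype(profile(900, 5, {}), genotypes, "A")
        assert call.status == "ambiguous" and call.sample_id == "UNASSIGNED"

    def test_even_mixture_called_sample_multiplet(self, genotypes):
        # half the SNPs support s1's alt allele, half s2's ref allele, deeply
        alleles = {f"snp{j}": ((0, 8) if j < 5 else (8, 0)) for j in range(10)}
        call = assign_sample_by_genotype(profile(900, 5, alleles), genotypes, "A")
        assert call.status == "sample_multiplet"


class TestEndToEnd:
    def test_scale_equivariance(self):
        """Multiplying every read count by c scales fitted means, sds,
        crossings and the line intercept by c and preserves calls."""
        from crosspool.simulate import SimConfig, simulate_pooled_run

        cfg = SimConfig(seed=11, n_droplets_per_pool=6000)
        profiles, _ = simulate_pooled_run(cfg)
        c = 3
        scaled = [DropletProfile(p.barcode, c * p.reads_species_a,
                                 c * p.reads_species_b, p.allele_counts)
                  for p in profiles]
        r1 = SpeciesDemuxModel.from_profiles(profiles).fit()
        r2 = SpeciesDemuxModel.from_profiles(
            scaled, bin_width=c * 500).fit()
        f1 = {f.bin_index: f for f in r1.mixture_fits if f.crossing_point}
        f2 = {f.bin_index: f for f in r2.mixture_fits if f.crossing_point}
        shared = sorted(set(f1) & set(f2))
        assert len(shared) >= 5
        for k in shared[:10]:
            assert f2[k].means[0] == pytest.approx(c * f1[k].means[0], rel=0.01)
            assert f2[k].crossing_point == pytest.approx(
                c * f1[k].crossing_point, rel=0.02)
        assert r2.threshold_line.intercept == pytest.approx(
            c * r1.threshold_line.intercept, rel=0.05, abs=5.0)
        assert r2.threshold_line.slope == pytest.approx(
            r1.threshold_line.slope, rel=0.05, abs=0.01)
        assert (r1.calls["status"] == r2.calls["status"]).mean() > 0.995

    def test_multiplet_detection_on_synthetic_pool(self, default_pool):
        """Balanced accuracy >= 0.95 against ground truth on a default pool."""
        profiles, truth = default_pool
        res = SpeciesDemuxModel.from_profiles(profiles).fit()
        t = truth.table
        pred = (res.calls["status"] == "species_multiplet").to_numpy()
        cross = t["is_cross_species"].to_numpy()
        recall = (pred & cross).sum() / cross.sum()
        spec = (~pred & ~cross).sum() / (~cross).sum()
        assert (recall + spec) / 2 >= 0.95
        assert (pred & cross).sum() / pred.sum() >= 0.90  # precision
        assert recall >= 0.90
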