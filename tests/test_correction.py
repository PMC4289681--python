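import numpy as np
import pytest
from scipy import integrate, stats

import admixpop as ap
from admixpop.correction import AlphaBin


class TestFitAdmixtureDistribution:
    def test_all_zero_is_pure_point_mass(self):
        dist = ap.fit_admixture_distribution(np.zeros(100))
        assert dist.p0 == 1.0
        assert dist.interior_mass == 0.0
        assert dist.a is None and dist.b is None

    def test_half_zero_half_one(self):
        alphas = np.r_[np.zeros(50), np.ones(50)]
        dist = ap.fit_admixture_distribution(alphas)
        assert dist.p0 == pytest.approx(0.5)
        assert dist.p1 == pytest.approx(0.5)

    def test_near_boundary_values_join_point_masses(self):
        alphas = np.r_[np.full(10, 5e-4), np.full(10, 0.9999), np.full(20, 0.3),
                       np.full(20, 0.5)]
        dist = ap.fit_admixture_distribution(alphas, eps=1e-3)
        assert dist.p0 == pytest.approx(10 / 60)
        assert dist.p1 == pytest.approx(10 / 60)

    def test_single_interior_point_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            ap.fit_admixture_distribution(np.r_[np.zeros(10), [0.4]])

    def test_monte_carlo_recovery(self):
        """Parameters of (p0=0.3, Beta(2,5), p1=0.1) recovered at n=2000."""
        alphas = ap.draw_admixture_proportions(
            2000, p0=0.3, a=2, b=5, p1=0.1, seed=17).column("EUR")
        dist = ap.fit_admixture_distribution(alphas)
        assert dist.p0 == pytest.approx(0.3, abs=0.03)
        assert dist.p1 == pytest.approx(0.1, abs=0.03)
        assert dist.a == pytest.approx(2.0, abs=0.3)
        assert dist.b == pytest.approx(5.0, abs=0.7)

    def test_model_mean_tracks_empirical_mean(self):
        alphas = ap.draw_admixture_proportions(
            2000, p0=0.2, a=2, b=5, p1=0.05, seed=23).column("EUR")
        dist = ap.fit_admixture_distribution(alphas)
        assert dist.model_mean == pytest.approx(dist.empirical_mean, abs=0.01)


class TestDiscretize:
    def test_pure_point_mass_at_zero(self):
        dist = ap.fit_admixture_distribution(np.zeros(10))
        bins = ap.discretize_distribution(dist, 10)
        assert bins[0].alpha == 0.0
        assert bins[0].prob == pytest.approx(1.0)
        assert sum(b.prob for b in bins[1:]) == pytest.approx(0.0)

    def test_uniform_beta_gives_equal_bins_at_midpoints(self):
        dist = ap.AdmixtureDistribution(p0=0.0, p1=0.0, a=1.0, b=1.0, n=100,
                                        empirical_mean=0.5)
        bins = ap.discretize_distribution(dist, 10)
        for i, b in enumerate(bins):
            assert b.prob == pytest.approx(0.1)
            assert b.alpha == pytest.approx(0.05 + 0.1 * i)

    def test_masses_match_quadrature(self):
        """Bin masses agree with numeric integration of the mixture density."""
        dist = ap.AdmixtureDistribution(p0=0.3, p1=0.1, a=2.0, b=5.0, n=1000,
                                        empirical_mean=0.0)
        bins = ap.discretize_distribution(dist, 10)
        interior = 0.6
        edges = np.linspace(0, 1, 11)
        for i, b in enumerate(bins):
            mass, _ = integrate.quad(lambda x: stats.beta.pdf(x, 2.0, 5.0),
                                     edges[i], edges[i + 1])
            expected = interior * mass + (0.3 if i == 0 else 0) + (0.1 if i == 9 else 0)
            assert b.prob == pytest.approx(expected, abs=1e-6)
        assert sum(b.prob for b in bins) == pytest.approx(1.0, abs=1e-9)

    def test_bin_count_validation(self):
        dist = ap.fit_admixture_distribution(np.zeros(10))
        with pytest.raises(ValueError):
            ap.discretize_distribution(dist, 1)


class TestCorrectedFrequency:
    def test_no_admixture_is_identity(self):
        bins = [AlphaBin(0.0, 1.0)]
        f, clamped = ap.corrected_allele_frequency(0.37, 0.9, bins)
        assert f == pytest.approx(0.37)
        assert not clamped

    def test_single_bin_direct_evaluation(self):
        """alpha=0.5, f_G=0.5, f_D=0.3: (0.5 - 0.5*0.3)/0.5 = 0.7."""
        bins = [AlphaBin(0.5, 1.0)]
        f, _ = ap.corrected_allele_frequency(0.5, 0.3, bins)
        assert f == pytest.approx(0.7)

    def test_equal_frequencies_collapse_for_any_bins(self):
        """With p1=0 and f_D = f_G the formula returns f_G exactly."""
        dist = ap.AdmixtureDistribution(p0=0.4, p1=0.0, a=2.0, b=3.0, n=100,
                                        empirical_mean=0.0)
        bins = ap.discretize_distribution(dist, 10)
        for fg in (0.0, 0.2, 0.9):
            f, _ = ap.corrected_allele_frequency(fg, fg, bins)
            assert f == pytest.approx(fg, abs=1e-12)

    def test_alpha_one_bins_excluded_with_renormalization(self):
        bins = [AlphaBin(0.0, 0.5), AlphaBin(1.0, 0.5)]
        f, _ = ap.corrected_allele_frequency(0.4, 0.1, bins)
        assert f == pytest.approx(0.4)  # the alpha=1 bin is uninformative
        with pytest.raises(ValueError):
            ap.corrected_allele_frequency(0.4, 0.1, [AlphaBin(1.0, 1.0)])

    def test_clamped_flag(self):
        bins = [AlphaBin(0.9, 1.0)]
        f, clamped = ap.corrected_allele_frequency(0.05, 0.9, bins)
        assert f == 0.0 and clamped

    def test_matches_analytic_expectation_of_formula(self):
        """On a wide admixture distribution the bin-averaged corrector
        converges to its own analytic expectation
        f_I (1-abar) A + f_D (abar A - (A-1)), A = sum_b Pr_b/(1-alpha_b),
        which can sit far from the true ancestral frequency."""
        f_i, f_d = 0.4, 0.1
        al = ap.draw_admixture_proportions(2000, p0=0.5, a=2, b=2, p1=0, seed=31)
        dist = ap.fit_admixture_distribution(al.column("EUR"))
        bins = ap.discretize_distribution(dist, 10)
        n_sites = 500
        freqs = np.column_stack([np.full(n_sites, f_d), np.full(n_sites, f_i)])
        gm = ap.simulate_admixed_genotypes(al, freqs, seed=32)
        fc, _ = ap.corrected_allele_frequency(
            gm.allele_frequencies(), np.full(n_sites, f_d), bins)
        a_vec = np.array([b.alpha for b in bins])
        p_vec = np.array([b.prob for b in bins])
        big_a = (p_vec / (1 - a_vec)).sum()
        abar = al.column("EUR").mean()
        expected = f_i * (1 - abar) * big_a + f_d * (abar * big_a - (big_a - 1))
        assert fc.mean() == pytest.approx(expected, abs=0.02)

    def test_recovery_under_concentrated_admixture(self):
        """When the admixture distribution is tightly concentrated the
        corrector is an unbiased estimate of the ancestral frequency
        (|bias| < 0.01)."""
        n, n_sites = 2000, 500
        f_i, f_d = 0.4, 0.1
        al = ap.draw_admixture_proportions(n, p0=0, a=250, b=750, p1=0, seed=36)
        freqs = np.column_stack([np.full(n_sites, f_d), np.full(n_sites, f_i)])
        gm = ap.simulate_admixed_genotypes(al, freqs, seed=33)
        dist = ap.fit_admixture_distribution(al.column("EUR"))
        bins = ap.discretize_distribution(dist, 10)
        fc, _ = ap.corrected_allele_frequency(
            gm.allele_frequencies(), np.full(n_sites, f_d), bins)
        assert abs(fc.mean() - f_i) < 0.01

    def test_moment_corrector_unbiased_under_wide_admixture(self):
        """The moment-based inversion recovers the ancestral frequency even
        when admixture proportions are widely dispersed."""
        f_i, f_d = 0.4, 0.1
        al = ap.draw_admixture_proportions(2000, p0=0.5, a=2, b=2, p1=0, seed=34)
        dist = ap.fit_admixture_distribution(al.column("EUR"))
        bins = ap.discretize_distribution(dist, 10)
        n_sites = 500
        freqs = np.column_stack([np.full(n_sites, f_d), np.full(n_sites, f_i)])
        gm = ap.simulate_admixed_genotypes(al, freqs, seed=35)
        fm, _ = ap.corrected_allele_frequency_moment(
            gm.allele_frequencies(), np.full(n_sites, f_d), bins)
        assert abs(fm.mean() - f_i) < 0.02

    def test_table_output(self):
        bins = [AlphaBin(0.25, 1.0)]
        tbl = ap.correct_frequency_table([0.3, 0.5], [0.1, 0.2], bins)
        assert list(tbl.columns) == ["f_observed", "f_reference",
                                     "f_corrected", "clamped"]
        assert tbl["f_corrected"].iloc[0] == pytest.approx((0.3 - 0.25 * 0.1) / 0.75)
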