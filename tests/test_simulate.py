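import numpy as np
import pytest
from scipy import stats

import admixpop as ap


class TestDrawAdmixtureProportions:
    def test_all_point_mass_at_zero(self):
        alphas = ap.draw_admixture_proportions(100, p0=1.0, a=2, b=2, p1=0.0, seed=1)
        assert np.all(alphas.column("EUR") == 0.0)
        assert np.all(alphas.column("INUIT") == 1.0)

    def test_uniform_interior_mean(self):
        """Beta(1,1) interior: empirical mean within 3 SE of 1/2."""
        n = 10_000
        alphas = ap.draw_admixture_proportions(n, p0=0, a=1, b=1, p1=0, seed=2)
        se = np.sqrt(1 / 12 / n)
        assert abs(alphas.column("EUR").mean() - 0.5) < 3 * se

    def test_point_mass_fractions(self):
        n = 10_000
        alphas = ap.draw_admixture_proportions(n, p0=0.3, a=2, b=5, p1=0.1, seed=3)
        a = alphas.column("EUR")
        se0 = np.sqrt(0.3 * 0.7 / n)
        se1 = np.sqrt(0.1 * 0.9 / n)
        assert abs((a == 0).mean() - 0.3) < 3 * se0
        assert abs((a == 1).mean() - 0.1) < 3 * se1

    def test_seed_reproducible(self):
        a = ap.draw_admixture_proportions(50, seed=9).proportions
        b = ap.draw_admixture_proportions(50, seed=9).proportions
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ap.draw_admixture_proportions(10, p0=0.7, p1=0.5)
        with pytest.raises(ValueError):
            ap.draw_admixture_proportions(10, a=-1)


class TestFrequencyTree:
    def test_zero_drift_returns_root(self):
        tree = ap.FrequencyTree(0, 0, 0, 0, 0, 0)
        f = ap.simulate_ancestral_frequencies(tree, 100, seed=4)
        np.testing.assert_array_equal(f["H1"], f["H4"])
        np.testing.assert_array_equal(f["H2"], f["H3"])

    def test_symmetric_drift_zero_mean_difference(self):
        tree = ap.FrequencyTree(c_h1=0.1, c_h2=0.1)
        f = ap.simulate_ancestral_frequencies(tree, 20_000, seed=5)
        diff = (f["H1"] - f["H2"]).to_numpy()
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(diff.size)

    def test_drift_matches_weir_cockerham_fst(self):
        """Two leaves both drifted c from their ancestor show F_ST ~ c."""
        c = 0.12
        tree = ap.FrequencyTree(c_h1=c, c_h2=c, c_h3=0, c_h4=0,
                                c_internal1=0, c_internal2=0)
        f = ap.simulate_ancestral_frequencies(tree, 5000, seed=6)
        al = ap.AdmixtureProportionSet(np.ones((500, 1)), ("POP",))
        groups = {}
        genos = []
        for pop in ("H1", "H2"):
            gm = ap.simulate_admixed_genotypes(
                al, f[pop].to_numpy()[:, None], seed=7 if pop == "H1" else 8)
            genos.append(gm.genotypes)
            groups.update({f"{pop}_{i}": pop for i in range(500)})
        merged = ap.GenotypeMatrix(
            np.vstack(genos),
            [f"{p}_{i}" for p in ("H1", "H2") for i in range(500)],
            gm.sites)
        est = ap.weir_cockerham_fst(merged, groups)
        # realized infinite-sample WC theta from the drawn frequencies
        f1, f2 = f["H1"].to_numpy(), f["H2"].to_numpy()
        pbar = (f1 + f2) / 2
        s2 = (f1 - f2) ** 2 / 2
        realized = s2.sum() / (s2 / 2 + pbar * (1 - pbar)).sum()
        assert est.fst == pytest.approx(realized, abs=0.01)


class TestSimulateGenotypes:
    def test_zero_frequencies_give_zero_genotypes(self):
        al = ap.draw_admixture_proportions(20, seed=1)
        gm = ap.simulate_admixed_genotypes(al, np.zeros((50, 2)), seed=2)
        assert np.all(gm.genotypes == 0)

    def test_full_inbreeding_removes_heterozygotes(self):
        al = ap.AdmixtureProportionSet(np.tile([0.5, 0.5], (10, 1)))
        freqs = np.full((2000, 2), 0.5)
        gm = ap.simulate_admixed_genotypes(al, freqs, inbreeding=1.0, seed=3)
        assert np.mean(gm.genotypes == 1) == 0.0

    def test_unadmixed_outbred_matches_hwe(self):
        """alpha=(1,0), f=0.3, F=0: genotype frequencies within 3 SE of
        (0.49, 0.42, 0.09)."""
        n_sites = 10_000
        al = ap.AdmixtureProportionSet(np.array([[1.0, 0.0]]))
        freqs = np.column_stack([np.full(n_sites, 0.3), np.full(n_sites, 0.9)])
        gm = ap.simulate_admixed_genotypes(al, freqs, seed=4)
        g = gm.genotypes[0]
        for val, p in ((0, 0.49), (1, 0.42), (2, 0.09)):
            se = np.sqrt(p * (1 - p) / n_sites)
            assert abs((g == val).mean() - p) < 3 * se

    def test_binomial_sampling_chi_square(self):
        """K=1, F=0 reduces to binomial(2, f) sampling (GOF at alpha=0.01)."""
        n_sites = 10_000
        al = ap.AdmixtureProportionSet(np.ones((1, 1)), ("POP",))
        gm = ap.simulate_admixed_genotypes(al, np.full((n_sites, 1), 0.37), seed=5)
        obs = np.bincount(gm.genotypes[0], minlength=3)
        exp = n_sites * np.array([0.63 ** 2, 2 * 0.37 * 0.63, 0.37 ** 2])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_expected_mean_is_twice_weighted_frequency(self):
        al = ap.AdmixtureProportionSet(np.array([[0.3, 0.7]]))
        n_sites = 20_000
        freqs = np.column_stack([np.full(n_sites, 0.1), np.full(n_sites, 0.6)])
        gm = ap.simulate_admixed_genotypes(al, freqs, seed=6)
        fstar = 0.3 * 0.1 + 0.7 * 0.6
        se = np.sqrt(2 * fstar * (1 - fstar) / n_sites)  # conservative
        assert abs(gm.genotypes[0].mean() - 2 * fstar) < 3 * 2 * se


class TestSimulatePairs:
    def test_fixed_haplotype_gives_fixed_genotypes(self):
        al = ap.draw_admixture_proportions(30, seed=1)
        p = np.array([[1.0, 1.0], [0, 0], [0, 0], [0, 0]])
        gm = ap.simulate_admixed_genotype_pairs(al, p, n_pairs=3, seed=2)
        assert np.all(gm.genotypes == 2)

    def test_unadmixed_haplotype_counts(self):
        """Haplotype counts in an unadmixed cohort are multinomial around p."""
        n = 4000
        p = np.array([0.4, 0.2, 0.1, 0.3])[:, None]
        al = ap.AdmixtureProportionSet(np.ones((n, 1)), ("POP",))
        gm = ap.simulate_admixed_genotype_pairs(al, p, n_pairs=1, seed=3)
        g = gm.genotypes
        # AB...ab counts are identifiable from unambiguous genotype classes:
        # p_AB estimated from P(g=(2,2)) = p_AB^2
        for hap, (g1, g2) in ((0, (2, 2)), (3, (0, 0))):
            frac = np.mean((g[:, 0] == g1) & (g[:, 1] == g2))
            expected = p[hap, 0] ** 2
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 3 * se

    def test_mixture_r2_between_ancestral_values(self):
        """A 50/50 mix of perfect-LD and equilibrium ancestries has naive
        genotype r^2 strictly between 0 and 1."""
        n = 2000
        P = np.column_stack([[0.5, 0, 0, 0.5], [0.25, 0.25, 0.25, 0.25]])
        al = ap.draw_admixture_proportions(n, p0=0, a=2, b=2, p1=0, seed=4)
        gm = ap.simulate_admixed_genotype_pairs(al, P, n_pairs=5, seed=5)
        r2s = [ap.genotype_r2(gm.genotypes[:, 2 * i], gm.genotypes[:, 2 * i + 1])
               for i in range(5)]
        assert 0.05 < np.mean(r2s) < 0.95

    def test_column_sum_validation(self):
        al = ap.draw_admixture_proportions(5, seed=1)
        with pytest.raises(ValueError):
            ap.simulate_admixed_genotype_pairs(al, np.full((4, 2), 0.3), 1)


class TestSimulateTracts:
    def test_no_admixture_no_admixed_tracts(self):
        ts = ap.simulate_ancestry_tracts(0.0, 1.3e-8, 25, [10**7], 5, seed=1)
        assert (ts.tracts["ancestry"] == "EUR").sum() == 0

    def test_mean_admixed_tract_length(self):
        """Mean admixed tract length ~ 1/lambda1 = 3.374e6 bp at
        (m=0.05, t=25, r=1.3e-8)."""
        m, r, t = 0.05, 1.3e-8, 25
        lam1 = (1 - m) * r * (t - 1)
        ts = ap.simulate_ancestry_tracts(m, r, t, [10**9], 40, seed=2, ploidy=2)
        eur = ts.tracts[ts.tracts["ancestry"] == "EUR"]
        # drop censored tracts touching chromosome ends
        interior = eur[(eur["start_bp"] > 0) & (eur["end_bp"] < 10**9)]
        lengths = (interior["end_bp"] - interior["start_bp"]).to_numpy()
        assert len(lengths) > 1000
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 1 / lam1) < 3 * se

    def test_admixed_fraction_near_m(self):
        m = 0.05
        ts = ap.simulate_ancestry_tracts(m, 1.3e-8, 25, [5 * 10**8], 100,
                                         seed=3, ploidy=1)
        eur_bp = ts.filter_ancestry("EUR").lengths_bp().sum()
        total = ts.lengths_bp().sum()
        frac = eur_bp / total
        assert abs(frac - m) < 0.01

    def test_haplotypes_tile_each_chromosome(self):
        ts = ap.simulate_ancestry_tracts(0.3, 1e-8, 10, {"chr1": 10**6}, 3, seed=4)
        for _, grp in ts.tracts.groupby(["individual", "haplotype"]):
            g = grp.sort_values("start_bp")
            assert g["start_bp"].iloc[0] == 0
            assert g["end_bp"].iloc[-1] == 10**6
            assert np.all(g["end_bp"].to_numpy()[:-1] == g["start_bp"].to_numpy()[1:])

    def test_time_validation(self):
        with pytest.raises(ValueError):
            ap.simulate_ancestry_tracts(0.1, 1e-8, 1.0, [10**6], 1)
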