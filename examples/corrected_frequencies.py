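"""Admixture-corrected allele frequencies.

Observed allele frequencies in an admixed cohort mix the ancestral
(e.g. Inuit) frequency with the donor (European) one. This script fits
the point-mass/beta/point-mass distribution of admixture proportions,
discretizes it into ten bins, and applies the bin-averaged correction;
it also prints the moment-based inversion, which stays unbiased when the
admixture distribution is wide.
"""
import numpy as np

import admixpop as ap

TRUE_ANCESTRAL, DONOR = 0.4, 0.1

alphas = ap.draw_admixture_proportions(2000, p0=0.4, a=2, b=5, p1=0.0, seed=1)
dist = ap.fit_admixture_distribution(alphas.column("EUR"))
print("fitted admixture distribution:")
print(f"  P(alpha=0) = {dist.p0:.3f}   P(alpha=1) = {dist.p1:.3f}   "
      f"Beta(a={dist.a:.2f}, b={dist.b:.2f})")
print(f"  model mean {dist.model_mean:.4f} vs empirical mean "
      f"{dist.empirical_mean:.4f}")

bins = ap.discretize_distribution(dist, 10)
print("\nten-bin discretization (alpha_b, Pr):")
print("  " + "  ".join(f"({b.alpha:.2f}, {b.prob:.3f})" for b in bins))

n_sites = 500
freqs = np.column_stack([np.full(n_sites, DONOR),
                         np.full(n_sites, TRUE_ANCESTRAL)])
gm = ap.simulate_admixed_genotypes(alphas, freqs, seed=2)
f_obs = gm.allele_frequencies()
f_bin, _ = ap.corrected_allele_frequency(f_obs, np.full(n_sites, DONOR), bins)
f_mom, _ = ap.corrected_allele_frequency_moment(f_obs, np.full(n_sites, DONOR),
                                                bins)
print(f"\ntrue ancestral frequency:        {TRUE_ANCESTRAL}")
print(f"observed cohort frequency (mean): {f_obs.mean():.4f}")
print(f"bin-averaged correction (mean):   {f_bin.mean():.4f}")
print(f"moment-based correction (mean):   {f_mom.mean():.4f}")
print("\nBoth correctors pull the observed frequency back toward the "
      "ancestral value; the bin-averaged form overshoots slightly when "
      "the admixture distribution is dispersed (see docs/methods.md).")
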