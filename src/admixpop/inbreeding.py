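"""Maximum-likelihood inbreeding coefficients with admixture-aware
allele frequencies.

For one individual with ancestry proportions ``alpha`` and per-ancestry
allele frequencies ``f_sk``, the chance of carrying the allele at site
``s`` is the ancestry-weighted frequency ``f*_s = sum_k alpha_k f_sk``.
With inbreeding coefficient ``F`` (the probability the two alleles are
identical by descent) the genotype probabilities are a mixture of the
Hardy-Weinberg and the single-allele distribution:

    Pr(g=0 | F) = (1 - f*)^2 (1 - F) + (1 - f*) F
    Pr(g=1 | F) = 2 f* (1 - f*) (1 - F)
    Pr(g=2 | F) = f*^2 (1 - F) + f* F

and ``F`` is estimated by maximizing the composite log-likelihood over
sites (between-site LD is ignored). Using pooled cohort frequencies
instead of the ancestry-weighted ``f*`` mistakes admixture for
inbreeding and inflates the estimate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import MISSING, AdmixtureProportionSet, GenotypeMatrix


@dataclass
class InbreedingEstimate:
    individual_id: str
    f_hat: float
    log_likelihood: float
    n_sites: int


def genotype_prob_f(g, f_star, f):
    """Pr(genotype | F) under the admixture-aware inbreeding model.

    Broadcasts over array inputs; ``f_star`` must lie strictly inside
    (0, 1). For every (f*, F) the three genotype probabilities sum to 1.
    """
    g = np.asarray(g)
    fs = np.asarray(f_star, dtype=float)
    F = np.asarray(f, dtype=float)
    if np.any(fs <= 0) or np.any(fs >= 1):
        raise ValueError("f_star must lie strictly inside (0, 1)")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("F must lie in [0, 1]")
    hwe = np.select([g == 0, g == 1, g == 2],
                    [(1 - fs) ** 2, 2 * fs * (1 - fs), fs ** 2])
    ibd = np.select([g == 0, g == 1, g == 2], [1 - fs, 0.0 * fs, fs])
    return hwe * (1 - F) + ibd * F


def _profile_loglik(a_hwe: np.ndarray, b_ibd: np.ndarray):
    """Return vectorized loglik(F) for per-site HWE/IBD genotype probabilities."""

    def loglik(f):
        f = np.asarray(f, dtype=float)
        p = a_hwe * (1 - f[..., None]) + b_ibd * f[..., None]
        return np.log(np.maximum(p, 1e-300)).sum(axis=-1)

    return loglik


def estimate_inbreeding(genotypes, f_star, f_eps: float = 0.005,
                        min_sites: int = 50, grid_size: int = 101,
                        individual_id: str = "") -> InbreedingEstimate:
    """ML inbreeding coefficient for one individual from genotypes and
    per-site allele probabilities ``f_star``.

    Sites with a missing genotype, or with ``f_star`` within ``f_eps``
    of a boundary (near-monomorphic, where the log-likelihood is
    numerically fragile), are dropped; at least ``min_sites`` must
    remain. The likelihood is scanned on a ``grid_size``-point grid over
    [0, 1] and refined by bounded scalar optimization between the
    neighbours of the best grid point.
    """
    g = np.asarray(genotypes)
    fs = np.asarray(f_star, dtype=float)
    if g.shape != fs.shape:
        raise ValueError("genotypes and f_star must align")
    keep = (g != MISSING) & (fs >= f_eps) & (fs <= 1.0 - f_eps)
    g = g[keep]
    fs = fs[keep]
    if g.size < min_sites:
        raise ValueError(f"only {g.size} usable sites (< {min_sites})")
    a_hwe = np.select([g == 0, g == 1, g == 2],
                      [(1 - fs) ** 2, 2 * fs * (1 - fs), fs ** 2])
    b_ibd = np.select([g == 0, g == 1, g == 2], [1 - fs, 0.0 * fs, fs])
    loglik = _profile_loglik(a_hwe, b_ibd)
    grid = np.linspace(0.0, 1.0, grid_size)
    ll = loglik(grid)
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    best_f, best_ll = grid[i], ll[i]
    if hi > lo:
        res = minimize_scalar(lambda x: -loglik(np.array(x)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        if -res.fun > best_ll:
            best_f, best_ll = float(np.clip(res.x, 0, 1)), float(-res.fun)
    return InbreedingEstimate(individual_id, float(best_f), float(best_ll),
                              int(g.size))


def estimate_inbreeding_admixture_aware(genotypes, alpha, ancestral_freqs,
                                        **kwargs) -> InbreedingEstimate:
    """Estimate F using ancestry-weighted frequencies f* = sum_k alpha_k f_sk."""
    freqs = np.asarray(ancestral_freqs, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != alpha.size:
        raise ValueError("ancestral_freqs must be (n_sites, K)")
    return estimate_inbreeding(genotypes, freqs @ alpha, **kwargs)


def estimate_inbreeding_cohort(gm: GenotypeMatrix,
                               alphas: AdmixtureProportionSet,
                               ancestral_freqs, **kwargs) -> pd.DataFrame:
    """Per-individual admixture-aware inbreeding estimates for a cohort."""
    if alphas.n_individuals != gm.n_individuals:
        raise ValueError("cohort sizes disagree")
    rows = []
    for i, ind in enumerate(gm.individual_ids):
        est = estimate_inbreeding_admixture_aware(
            gm.genotypes[i], alphas.proportions[i], ancestral_freqs,
            individual_id=ind, **kwargs)
        rows.append((est.individual_id, est.f_hat, est.n_sites, est.log_likelihood))
    return pd.DataFrame(rows, columns=["individual", "f_hat", "n_sites",
                                       "log_likelihood"])
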