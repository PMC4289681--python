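"""Ancestry-specific two-locus haplotype frequencies and LD from unphased
genotypes of admixed individuals.

Admixture distorts LD measured naively on a mixed cohort. Given each
individual's ancestry proportions ``alpha_i`` over K ancestral
populations, the two haplotypes of an individual are modeled as drawn
independently: first an ancestry ``k ~ alpha_i``, then a haplotype
``j ~ p_{.k}``, where ``p_{jk}`` is the frequency of two-locus haplotype
``j in {AB, Ab, aB, ab}`` in ancestry ``k`` (a haplotype keeps a single
ancestry across both sites, which is reasonable for nearby SNPs). The
likelihood of ``p`` given unphased genotype pairs sums over the
haplotype pairs consistent with each genotype and over the latent
ancestries; it is maximized by an EM algorithm whose M-step is the
standard ratio of expected haplotype counts,

    p*_{jk} = E[# haplotypes of type j and ancestry k] /
              E[# haplotypes of ancestry k],

which keeps each ancestry's four frequencies on the simplex and never
decreases the likelihood. Per-ancestry r^2 then follows from the fitted
haplotype frequencies exactly as in a phased sample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, AdmixtureProportionSet, GenotypeMatrix
from .qc import genotype_r2

#: Two-locus haplotype order used throughout; A/B are the alt alleles.
HAPLOTYPES = ("AB", "Ab", "aB", "ab")
#: Alt-allele dosage of each haplotype at the first / second site.
HAP_ALLELE1 = np.array([1, 1, 0, 0])
HAP_ALLELE2 = np.array([1, 0, 1, 0])

#: Minimum summed admixture proportion for an ancestry to be estimable.
MIN_EFFECTIVE_ALPHA = 0.5


def _compat_table() -> np.ndarray:
    """(9, 4, 4) indicator: ordered haplotype pair (h1, h2) consistent with
    genotype class g1 * 3 + g2."""
    table = np.zeros((9, 4, 4), dtype=bool)
    for g1 in range(3):
        for g2 in range(3):
            for h1 in range(4):
                for h2 in range(4):
                    ok = (HAP_ALLELE1[h1] + HAP_ALLELE1[h2] == g1
                          and HAP_ALLELE2[h1] + HAP_ALLELE2[h2] == g2)
                    table[g1 * 3 + g2, h1, h2] = ok
    return table


_COMPAT = _compat_table()


@dataclass
class PairHaplotypeFrequencies:
    """EM-fitted 4 x K ancestry-specific haplotype frequencies for one SNP pair."""

    p: np.ndarray                 # (4, K), columns sum to 1
    ancestries: tuple
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    resolved: np.ndarray          # (K,) bool; False when sum(alpha_k) too small
    n_individuals: int

    def r_squared(self) -> np.ndarray:
        """Per-ancestry r^2; NaN for unresolved or monomorphic ancestries."""
        out = np.full(self.p.shape[1], np.nan)
        for k in range(self.p.shape[1]):
            if self.resolved[k]:
                out[k] = r_squared_from_haplotypes(self.p[:, k])
        return out


def r_squared_from_haplotypes(p_column) -> float:
    """r^2 = D^2 / (pA qA pB qB) from four haplotype frequencies.

    Returns NaN (an undefined, not erroneous, result) when either locus
    is monomorphic in the given ancestry.
    """
    p = np.asarray(p_column, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected four haplotype frequencies")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    p_a = p[0] + p[1]
    p_b = p[0] + p[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return float("nan")
    d = p[0] - p_a * p_b
    return float(d * d / denom)


def _em_run(classes: np.ndarray, alphas: np.ndarray, p0: np.ndarray,
            tol: float, max_iter: int):
    """Run EM from one start. Returns (p, loglik_trace, n_iter, converged)."""
    compat = _COMPAT[classes]          # (n, 4, 4)
    p = p0.copy()
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b = alphas @ p.T               # (n, 4): B[i,h] = sum_k p[h,k] alpha[i,k]
        partner = np.einsum("nhg,ng->nh", compat, b)
        lik = np.maximum((b * partner).sum(axis=1), 1e-300)
        trace.append(float(np.log(lik).sum()))
        w = partner / lik[:, None]     # (n, 4)
        counts = p * (w.T @ alphas)    # (4, K) expected haplotype counts / 2
        p_new = counts / counts.sum(axis=0, keepdims=True)
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break
    # log-likelihood at the final parameters
    b = alphas @ p.T
    partner = np.einsum("nhg,ng->nh", compat, b)
    lik = np.maximum((b * partner).sum(axis=1), 1e-300)
    trace.append(float(np.log(lik).sum()))
    return p, np.array(trace), it, converged


def estimate_pair_haplotype_frequencies(
    genotype_pairs, alphas: AdmixtureProportionSet, tol: float = 1e-6,
    n_starts: int = 5, max_iter: int = 2000, seed=None,
) -> PairHaplotypeFrequencies:
    """Maximum-likelihood ancestry-specific haplotype frequencies for one
    SNP pair from unphased genotypes.

    Parameters
    ----------
    genotype_pairs
        ``(n, 2)`` genotypes at the two sites; individuals missing either
        genotype are dropped.
    alphas
        Ancestry proportions for the same ``n`` individuals.
    tol
        EM stops when no parameter moves by more than ``tol``.
    n_starts
        Uniform-random restarts; the best final likelihood wins, ties
        going to the earlier start.

    Ancestries whose summed proportion over retained individuals is at
    most :data:`MIN_EFFECTIVE_ALPHA` are flagged unresolved: their column
    is still returned but carries essentially no information.
    """
    g = np.asarray(genotype_pairs)
    if g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("genotype_pairs must be an (n, 2) array")
    if g.shape[0] != alphas.n_individuals:
        raise ValueError("genotypes and ancestry proportions disagree on n")
    ok = (g[:, 0] != MISSING) & (g[:, 1] != MISSING)
    if not ok.any():
        raise ValueError("no individuals with complete genotypes at the pair")
    g = g[ok].astype(int)
    a = alphas.proportions[ok]
    k = alphas.n_ancestries
    classes = g[:, 0] * 3 + g[:, 1]
    resolved = a.sum(axis=0) > MIN_EFFECTIVE_ALPHA

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        p0 = rng.random((4, k))
        p0 /= p0.sum(axis=0, keepdims=True)
        p, trace, n_iter, conv = _em_run(classes, a, p0, tol, max_iter)
        if best is None or trace[-1] > best[1][-1]:
            best = (p, trace, n_iter, conv)
    p, trace, n_iter, conv = best
    return PairHaplotypeFrequencies(
        p=p, ancestries=alphas.ancestries, log_likelihood=float(trace[-1]),
        n_iterations=n_iter, converged=conv, loglik_trace=trace,
        resolved=resolved, n_individuals=int(ok.sum()),
    )


def ld_decay_curve(gm: GenotypeMatrix, alphas: AdmixtureProportionSet,
                   distance_bins, maf_min: float = 0.05,
                   max_pairs_per_bin: int = 50, tol: float = 1e-6,
                   n_starts: int = 5, seed=None) -> pd.DataFrame:
    """Mean naive and per-ancestry r^2 as a function of physical distance.

    Sites are filtered at ``maf_min``; within each chromosome, SNP pairs
    whose bp distance falls in each ``[lo, hi)`` bin of ``distance_bins``
    (a monotone sequence of bp edges) are sampled uniformly without
    replacement up to ``max_pairs_per_bin``. For every sampled pair the
    composite genotype r^2 and the EM-based per-ancestry r^2 are
    computed; bin means are reported with pair counts. Empty bins are
    simply absent from the output.
    """
    from .qc import filter_sites

    edges = np.asarray(distance_bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("distance_bins must be increasing bp edges")
    rng = np.random.default_rng(seed)
    gmf = filter_sites(gm, maf_min=maf_min, miss_max=1.0)
    pos = gmf.sites["pos"].to_numpy()
    chroms = gmf.sites["chrom"].to_numpy()
    rows = []
    anc_cols = [f"r2_{a}" for a in alphas.ancestries]
    for lo, hi in zip(edges[:-1], edges[1:]):
        cand = []
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            p = pos[idx]
            for ii, site_i in enumerate(idx):
                j_lo = max(int(np.searchsorted(p, p[ii] + lo, side="left")), ii + 1)
                j_hi = int(np.searchsorted(p, p[ii] + hi, side="left"))
                cand.extend((site_i, idx[j]) for j in range(j_lo, j_hi))
        if not cand:
            continue
        if len(cand) > max_pairs_per_bin:
            take = rng.choice(len(cand), size=max_pairs_per_bin, replace=False)
            cand = [cand[i] for i in sorted(take)]
        naive = []
        per_anc = []
        for i, j in cand:
            naive.append(genotype_r2(gmf.genotypes[:, i], gmf.genotypes[:, j]))
            fit = estimate_pair_haplotype_frequencies(
                gmf.genotypes[:, [i, j]], alphas, tol=tol,
                n_starts=n_starts, seed=rng.integers(2**31),
            )
            per_anc.append(fit.r_squared())
        per_anc = np.asarray(per_anc)
        row = {"bin_lo_bp": lo, "bin_hi_bp": hi, "n_pairs": len(cand),
               "r2_naive": float(np.mean(naive))}
        with np.errstate(invalid="ignore"):
            means = np.nanmean(per_anc, axis=0)
        row.update({c: float(v) for c, v in zip(anc_cols, means)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["bin_lo_bp", "bin_hi_bp", "n_pairs",
                                       "r2_naive", *anc_cols])
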