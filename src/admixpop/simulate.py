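"""Synthetic admixed cohorts with the statistical structure the
estimators assume.

Every generator here is the exact generative counterpart of one
estimator in the package: admixture proportions follow the point-mass /
beta / point-mass mixture fitted by
:func:`admixpop.correction.fit_admixture_distribution`; genotypes follow
the ancestry-weighted inbreeding model of :mod:`admixpop.inbreeding`;
two-locus genotype pairs follow the haplotype-mixture model of
:mod:`admixpop.ancestral_ld`; ancestry tracts follow the two-state
Markov process of :mod:`admixpop.tracts`; and four-population allele
frequencies drift along a fixed tree under the Balding-Nichols model,
providing nulls for the D statistic. Fixing ``seed`` makes every
generator bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestral_ld import HAP_ALLELE1, HAP_ALLELE2
from .containers import AdmixtureProportionSet, GenotypeMatrix, TractSet, TRACT_COLUMNS
from .tracts import tract_rates


def _site_table(n_sites: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": chrom,
        "pos": 1 + spacing * np.arange(n_sites),
        "ref": "A",
        "alt": "C",
    })


def draw_admixture_proportions(n: int, p0: float = 0.2, a: float = 2.0,
                               b: float = 5.0, p1: float = 0.0, seed=None,
                               ancestries=("EUR", "INUIT")) -> AdmixtureProportionSet:
    """Draw first-ancestry proportions from the point-mass/beta mixture.

    Each proportion is 0 with probability ``p0``, 1 with probability
    ``p1`` and otherwise ``Beta(a, b)``. The defaults emulate a cohort in
    which ~80% of individuals carry some European ancestry and the
    cohort-average European fraction is ~25%.
    """
    if not (0 <= p0 <= 1 and 0 <= p1 <= 1 and p0 + p1 <= 1):
        raise ValueError("need 0 <= p0, p1 and p0 + p1 <= 1")
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    alpha = np.empty(n)
    lo = u < p0
    hi = u >= 1.0 - p1
    mid = ~lo & ~hi
    alpha[lo] = 0.0
    alpha[hi] = 1.0
    alpha[mid] = rng.beta(a, b, size=int(mid.sum()))
    return AdmixtureProportionSet(np.column_stack([alpha, 1.0 - alpha]), ancestries)


@dataclass
class FrequencyTree:
    """Rooted four-leaf drift tree (((H1,H2),H3),H4) with per-branch
    Balding-Nichols drift parameters ``c`` in [0, 1).

    ``c_internal1`` is the branch root -> ancestor(H1,H2,H3) and
    ``c_internal2`` the branch down to ancestor(H1,H2). The ancestral
    root frequency of each site is uniform on
    ``(root_low, root_high)``.
    """

    c_h1: float = 0.05
    c_h2: float = 0.05
    c_h3: float = 0.05
    c_h4: float = 0.05
    c_internal1: float = 0.05
    c_internal2: float = 0.05
    root_low: float = 0.05
    root_high: float = 0.95
    leaves: tuple = ("H1", "H2", "H3", "H4")

    def __post_init__(self) -> None:
        for c in (self.c_h1, self.c_h2, self.c_h3, self.c_h4,
                  self.c_internal1, self.c_internal2):
            if not 0 <= c < 1:
                raise ValueError("drift parameters must lie in [0, 1)")
        if len(set(self.leaves)) != 4:
            raise ValueError("leaves must carry four unique labels")


def _drift(f: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols step: child ~ Beta(f(1-c)/c, (1-f)(1-c)/c)."""
    if c == 0:
        return f.copy()
    scale = (1.0 - c) / c
    out = rng.beta(f * scale, (1.0 - f) * scale)
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def simulate_ancestral_frequencies(tree: FrequencyTree, n_sites: int,
                                   seed=None) -> pd.DataFrame:
    """Per-leaf allele frequencies drifted along the tree; one row per site."""
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(seed)
    root = rng.uniform(tree.root_low, tree.root_high, size=n_sites)
    anc123 = _drift(root, tree.c_internal1, rng)
    anc12 = _drift(anc123, tree.c_internal2, rng)
    data = {
        tree.leaves[0]: _drift(anc12, tree.c_h1, rng),
        tree.leaves[1]: _drift(anc12, tree.c_h2, rng),
        tree.leaves[2]: _drift(anc123, tree.c_h3, rng),
        tree.leaves[3]: _drift(root, tree.c_h4, rng),
    }
    return pd.DataFrame(data)


def _draw_ancestries(alpha_cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: ancestry index per (individual, site)."""
    return (u[..., None] > alpha_cum[:, None, :]).sum(axis=-1)


def simulate_admixed_genotypes(alphas: AdmixtureProportionSet,
                               ancestral_freqs, inbreeding=None, seed=None,
                               chrom: str = "1",
                               pos_spacing: int = 1000) -> GenotypeMatrix:
    """Draw unphased genotypes for an admixed, possibly inbred cohort.

    For individual ``i`` at site ``s``: with probability ``F_i`` a single
    (ancestry, allele) draw is duplicated (the two alleles are identical
    by descent); otherwise two independent draws are made, each picking
    an ancestry ``k ~ alpha_i`` and then an allele with probability
    ``f_sk``. Inbreeding therefore acts independently per site, matching
    the composite likelihood of the inbreeding estimator rather than
    producing realistic runs of homozygosity.
    """
    f = np.asarray(ancestral_freqs, dtype=float)
    if f.ndim != 2 or f.shape[1] != alphas.n_ancestries:
        raise ValueError("ancestral_freqs must be (n_sites, K)")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("ancestral frequencies must lie in [0, 1]")
    n = alphas.n_individuals
    s = f.shape[0]
    if inbreeding is None:
        inbreeding = np.zeros(n)
    fvec = np.broadcast_to(np.asarray(inbreeding, dtype=float), (n,))
    if np.any(fvec < 0) or np.any(fvec > 1):
        raise ValueError("inbreeding coefficients must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha_cum = np.cumsum(alphas.proportions, axis=1)
    sites_idx = np.arange(s)

    k1 = _draw_ancestries(alpha_cum, rng.random((n, s)))
    a1 = rng.random((n, s)) < f[sites_idx, k1]
    k2 = _draw_ancestries(alpha_cum, rng.random((n, s)))
    a2 = rng.random((n, s)) < f[sites_idx, k2]
    ibd = rng.random((n, s)) < fvec[:, None]
    a1 = a1.astype(np.int8)
    a2 = a2.astype(np.int8)
    geno = np.where(ibd, 2 * a1, a1 + a2)
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(geno, ids, _site_table(s, chrom, pos_spacing))


def simulate_admixed_genotype_pairs(alphas: AdmixtureProportionSet,
                                    pair_hap_freqs, n_pairs: int = 1,
                                    seed=None) -> GenotypeMatrix:
    """Draw unphased genotypes at SNP pairs from ancestry-specific
    haplotype frequencies.

    ``pair_hap_freqs`` is the (4, K) haplotype-frequency matrix in the
    order AB, Ab, aB, ab (columns must each sum to 1). Per individual and
    pair, two haplotypes are drawn independently (ancestry ``k ~
    alpha_i`` then haplotype ``j ~ p_{.k}``) and phase is discarded:
    the output holds the per-site allele sums, two adjacent sites per
    pair on one chromosome.
    """
    p = np.asarray(pair_hap_freqs, dtype=float)
    if p.shape != (4, alphas.n_ancestries):
        raise ValueError("pair_hap_freqs must be (4, K)")
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=0) - 1.0) > 1e-9):
        raise ValueError("each ancestry's haplotype frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    n = alphas.n_individuals
    alpha_cum = np.cumsum(alphas.proportions, axis=1)
    p_cum = np.cumsum(p, axis=0)  # (4, K)

    geno = np.empty((n, 2 * n_pairs), dtype=np.int8)
    k = _draw_ancestries(alpha_cum, rng.random((n, 2 * n_pairs)))  # 2 haplotypes per pair
    k = k.reshape(n, n_pairs, 2)
    u = rng.random((n, n_pairs, 2))
    thresh = np.moveaxis(p_cum[:, k], 0, -1)        # (n, n_pairs, 2, 4)
    hap = (u[..., None] > thresh).sum(axis=-1)       # (n, n_pairs, 2)
    g1 = HAP_ALLELE1[hap].sum(axis=-1)
    g2 = HAP_ALLELE2[hap].sum(axis=-1)
    geno[:, 0::2] = g1
    geno[:, 1::2] = g2
    ids = [f"ind{i}" for i in range(n)]
    # pairs sit 1 bp apart and 100 bp from the next pair, so within-pair
    # and between-pair distances are cleanly separable
    base = 100 * np.repeat(np.arange(n_pairs), 2)
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": base + np.tile([1, 2], n_pairs),
        "ref": "A",
        "alt": "C",
    })
    return GenotypeMatrix(geno, ids, sites)


def simulate_ancestry_tracts(m: float, r: float, t: float, chrom_lengths_bp,
                             n_individuals: int, seed=None, ploidy: int = 2,
                             labels=("EUR", "INUIT")) -> TractSet:
    """Simulate alternating ancestry tracts under the two-state Markov model.

    Each haplotype starts in the admixed state (``labels[0]``) with
    probability ``m`` and alternates between geometrically distributed
    segment lengths with per-bp exit rates ``lambda1`` (admixed) and
    ``lambda2`` (unadmixed). Tract cM lengths use the uniform rate:
    ``cM = bp * r * 100``.
    """
    lam1, lam2, _ = tract_rates(m, r, t)
    if isinstance(chrom_lengths_bp, dict):
        chrom_items = list(chrom_lengths_bp.items())
    else:
        chrom_items = [(str(i + 1), int(l)) for i, l in enumerate(np.atleast_1d(chrom_lengths_bp))]
    rng = np.random.default_rng(seed)
    rows = []
    for ind in range(n_individuals):
        for hap in range(ploidy):
            for chrom, length in chrom_items:
                pos = 0
                admixed = bool(rng.random() < m)
                while pos < length:
                    lam = lam1 if admixed else lam2
                    seg = int(rng.geometric(lam)) if lam > 0 else length - pos
                    end = min(pos + seg, length)
                    rows.append((f"ind{ind}", hap, chrom, pos, end,
                                 labels[0] if admixed else labels[1],
                                 (end - pos) * r * 100.0))
                    pos = end
                    admixed = not admixed
    df = pd.DataFrame(rows, columns=list(TRACT_COLUMNS))
    return TractSet(df)
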