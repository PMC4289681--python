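"""Site/individual QC filters and windowed LD pruning.

Defaults follow common SNP-chip practice: sites are dropped below 5%
minor allele frequency or above 1% missingness; individuals are dropped
above 2% missingness assessed at sites with MAF above 1%; pruning removes
one SNP of each pair with r^2 > 0.3 in 50-SNP windows slid by 5 SNPs.
Missing genotypes are excluded pairwise throughout.
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import MISSING, GenotypeMatrix


def filter_sites(gm: GenotypeMatrix, maf_min: float = 0.05,
                 miss_max: float = 0.01) -> GenotypeMatrix:
    """Keep sites with MAF >= ``maf_min`` and missing fraction <= ``miss_max``."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0 <= miss_max <= 1:
        raise ValueError("miss_max must lie in [0, 1]")
    maf = gm.minor_allele_frequencies()
    miss = gm.site_missingness()
    with np.errstate(invalid="ignore"):
        keep = (maf >= maf_min) & (miss <= miss_max)
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("all sites removed by filter_sites", stacklevel=2)
    return gm.take_sites(np.flatnonzero(keep))


def filter_individuals(gm: GenotypeMatrix, miss_max: float = 0.02,
                       maf_floor: float = 0.01) -> GenotypeMatrix:
    """Keep individuals with missingness <= ``miss_max`` at sites with MAF > ``maf_floor``."""
    maf = gm.minor_allele_frequencies()
    with np.errstate(invalid="ignore"):
        assessed = np.flatnonzero(maf > maf_floor)
    if assessed.size == 0:
        return gm.take_individuals(np.arange(gm.n_individuals))
    frac = (gm.genotypes[:, assessed] == MISSING).mean(axis=1)
    keep = frac <= miss_max
    if not keep.any():
        warnings.warn("all individuals removed by filter_individuals", stacklevel=2)
    return gm.take_individuals(np.flatnonzero(keep))


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 dosages (composite LD).

    Missing calls are dropped pairwise. Returns 0.0 when fewer than two
    complete pairs remain or either column is constant.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.3, window: int = 50,
             step: int = 5) -> GenotypeMatrix:
    """Windowed LD pruning, keeping the earlier SNP of each offending pair.

    Windows of ``window`` SNPs are slid left to right by ``step`` SNPs
    within each chromosome; whenever two retained SNPs in a window show
    genotype r^2 > ``r2_max``, the later one is removed. Output column
    order is a subset of the input order and the scan is deterministic.
    """
    if window < 2:
        raise ValueError("window must span at least 2 SNPs")
    if not window > step >= 1:
        raise ValueError("require window > step >= 1")
    keep = np.ones(gm.n_sites, dtype=bool)
    geno = gm.genotypes
    chroms = gm.sites["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):  # preserves order of appearance
        idx = np.flatnonzero(chroms == chrom)
        n = idx.size
        if n < 2:
            continue
        start = 0
        while True:
            w = idx[start:start + window]
            for a_i, a in enumerate(w):
                if not keep[a]:
                    continue
                for b in w[a_i + 1:]:
                    if keep[b] and genotype_r2(geno[:, a], geno[:, b]) > r2_max:
                        keep[b] = False
            if start + window >= n:
                break
            start += step
    return gm.take_sites(np.flatnonzero(keep))
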