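"""Population allele frequencies, D statistics with weighted block
jackknife, and Weir-Cockerham F_ST.

The D statistic for the rooted topology (((H1, H2), H3), H4) is the
frequency-based ratio of sums

    D = sum_i (f_iH3 - f_iH4)(f_iH1 - f_iH2)
        ---------------------------------------------------------
        sum_i (f_iH3 + f_iH4 - 2 f_iH3 f_iH4)(f_iH1 + f_iH2 - 2 f_iH1 f_iH2)

over sites informative in all four populations; under treeness its
expectation is 0. Standard errors come from a delete-m jackknife for
unequal m over contiguous genomic blocks (default 5 Mb), weighted by the
number of SNPs in each block.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


def population_allele_frequencies(gm: GenotypeMatrix, groups) -> pd.DataFrame:
    """Per-population alt-allele frequencies (sites x populations).

    ``groups`` maps every individual id to a population label.
    Frequencies are allele counts over twice the non-missing individuals;
    a site with no calls in a population is NaN (absent) there.
    """
    labels = [groups[i] for i in gm.individual_ids]
    pops = list(dict.fromkeys(labels))
    out = {}
    for pop in pops:
        rows = np.array([l == pop for l in labels])
        if not rows.any():
            raise ValueError(f"population {pop!r} has no individuals")
        sub = gm.genotypes[rows]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(n > 0, alt / (2.0 * n), np.nan)
    return pd.DataFrame(out)


def _d_site_terms(f1, f2, f3, f4):
    """Per-site numerator/denominator terms and the inclusion mask.

    A site is included when all four frequencies are present and its
    denominator term is nonzero (sites monomorphic in both pairs carry
    no information and would contribute 0/0).
    """
    f1, f2, f3, f4 = (np.asarray(f, dtype=float) for f in (f1, f2, f3, f4))
    num = (f3 - f4) * (f1 - f2)
    den = (f3 + f4 - 2 * f3 * f4) * (f1 + f2 - 2 * f1 * f2)
    present = np.isfinite(f1) & np.isfinite(f2) & np.isfinite(f3) & np.isfinite(f4)
    mask = present & (den != 0)
    return num, den, mask


def d_statistic(f1, f2, f3, f4) -> float:
    """D for the topology (((H1, H2), H3), H4) from per-site frequencies."""
    num, den, mask = _d_site_terms(f1, f2, f3, f4)
    if not mask.any():
        raise ValueError("no informative sites for the D statistic")
    return float(num[mask].sum() / den[mask].sum())


def assign_blocks(chroms, positions, block_size_bp: float = 5e6) -> np.ndarray:
    """Contiguous genomic block labels, anchored at each chromosome's
    first site position."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=float)
    labels = np.empty(chroms.size, dtype=int)
    nxt = 0
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        local = np.floor((positions[idx] - positions[idx[0]]) / block_size_bp).astype(int)
        # renumber to global consecutive labels, skipping empty windows
        _, dense = np.unique(local, return_inverse=True)
        labels[idx] = dense + nxt
        nxt = labels[idx].max() + 1
    return labels


@dataclass
class JackknifeResult:
    estimate: float
    estimate_jackknife: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    block_sizes: np.ndarray


def block_jackknife(stat_fn, chroms, positions,
                    block_size_bp: float = 5e6) -> JackknifeResult:
    """Weighted delete-m jackknife over genomic blocks of unequal SNP count.

    ``stat_fn`` maps a boolean site-inclusion mask to the statistic.
    With g blocks of sizes m_j (n = sum m_j) and leave-one-block-out
    estimates theta_{-j}, the weights are h_j = n / m_j and

        tau_j   = h_j * theta - (h_j - 1) * theta_{-j}
        theta_J = g * theta - sum_j (1 - m_j / n) * theta_{-j}
        Var     = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    With equal block sizes this reduces to the ordinary delete-m
    jackknife, and with one SNP per block to the classic delete-1.
    """
    labels = assign_blocks(chroms, positions, block_size_bp)
    blocks, sizes = np.unique(labels, return_counts=True)
    g = blocks.size
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    n = int(sizes.sum())
    theta = float(stat_fn(np.ones(n, dtype=bool)))
    theta_mj = np.array([stat_fn(labels != j) for j in blocks])
    h = n / sizes
    tau = h * theta - (h - 1.0) * theta_mj
    theta_j = g * theta - ((1.0 - sizes / n) * theta_mj).sum()
    if np.all(theta_mj == theta):  # constant statistic: exactly zero variance
        var = 0.0
    else:
        var = float(((tau - theta_j) ** 2 / (h - 1.0)).sum() / g)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = float(theta / se) if se > 0 else (np.inf * np.sign(theta) if theta else np.nan)
    return JackknifeResult(theta, float(theta_j), float(se), z, n, g, sizes)


@dataclass
class DStatResult:
    d: float
    z: float
    se: float
    n_sites: int
    n_blocks: int
    block_sizes: np.ndarray


def d_statistic_test(f1, f2, f3, f4, chroms, positions,
                     block_size_bp: float = 5e6) -> DStatResult:
    """D with weighted-block-jackknife SE and Z score.

    Frequencies, chromosome labels and positions are per-site arrays of
    equal length; only sites informative in all four populations enter.
    """
    num, den, mask = _d_site_terms(f1, f2, f3, f4)
    if not mask.any():
        raise ValueError("no informative sites for the D statistic")
    num = num[mask]
    den = den[mask]
    chroms = np.asarray(chroms)[mask]
    positions = np.asarray(positions)[mask]

    def stat(include):
        return num[include].sum() / den[include].sum()

    jk = block_jackknife(stat, chroms, positions, block_size_bp)
    return DStatResult(jk.estimate, jk.z, jk.se, jk.n_sites, jk.n_blocks,
                       jk.block_sizes)


@dataclass
class FstResult:
    fst: float       # NaN when every site is monomorphic (undefined)
    n_sites: int


def weir_cockerham_fst(gm: GenotypeMatrix, groups) -> FstResult:
    """Two-population Weir-Cockerham (1984) F_ST, ratio-of-sums form.

    Per site the variance components a (between populations), b (between
    individuals within populations) and c (within individuals) are
    computed from sample sizes, allele frequencies and observed
    heterozygosity; F_ST = sum(a) / sum(a + b + c) over usable sites.
    """
    labels = [groups[i] for i in gm.individual_ids]
    pops = list(dict.fromkeys(labels))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    r = 2
    stats = []
    for pop in pops:
        rows = np.array([l == pop for l in labels])
        sub = gm.genotypes[rows]
        called = sub != MISSING
        n_i = called.sum(axis=0).astype(float)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, np.where(called, sub == 1, False).sum(axis=0) / n_i, np.nan)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    usable = (n1 > 0) & (n2 > 0)
    n1, p1, h1, n2, p2, h2 = (x[usable] for x in (n1, p1, h1, n2, p2, h2))
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    finite = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = a[finite], b[finite], c[finite]
    denom = (a + b + c).sum()
    fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstResult(fst, int(finite.sum()))
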