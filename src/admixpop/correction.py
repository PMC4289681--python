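"""Fitting the distribution of admixture proportions and computing
admixture-corrected allele frequencies.

The distribution of individual admixture proportions in a cohort is
modeled as a mixture of a point mass at 0, a beta density on the
interior, and a point mass at 1 (ancestry-estimation software emits many
exact-boundary values). The fitted distribution is discretized into B
bins {(alpha_b, Pr(alpha_b))} and the allele frequency of the unadmixed
ancestral component is estimated from the observed cohort frequency
``f_G`` and a reference (donor) population frequency ``f_D`` as

    f'_G = sum_b Pr(alpha_b) * (f_G - alpha_b * f_D) / (1 - alpha_b),

the per-bin inversion of ``f_G = (1 - alpha) f_I + alpha f_D`` averaged
over the admixture distribution. Bins with ``alpha_b = 1`` carry no
information about the ancestral frequency and are excluded with weight
renormalization. Note the bin-averaged inversion is exact only when the
admixture distribution is concentrated; see ``docs/methods.md`` for its
bias under wide distributions, and :func:`corrected_allele_frequency_moment`
for the moment-based alternative that is exact in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AlphaBin:
    """One bin of the discretized admixture distribution."""

    alpha: float
    prob: float


@dataclass
class AdmixtureDistribution:
    """Fitted point-mass(0) / Beta(a, b) / point-mass(1) mixture.

    ``a``/``b`` are None when the interior carries no mass.
    """

    p0: float
    p1: float
    a: float | None
    b: float | None
    n: int
    empirical_mean: float

    @property
    def interior_mass(self) -> float:
        return 1.0 - self.p0 - self.p1

    @property
    def model_mean(self) -> float:
        """Mean of the fitted mixture, for comparison with the empirical mean."""
        mean = self.p1
        if self.interior_mass > 0 and self.a is not None:
            mean += self.interior_mass * self.a / (self.a + self.b)
        return mean


def fit_admixture_distribution(alphas, eps: float = 1e-3) -> AdmixtureDistribution:
    """Maximum-likelihood fit of the admixture-proportion mixture.

    Values within ``eps`` of a boundary are assigned to the point masses
    (ancestry software reports near-zero rather than exact-zero values);
    the beta shapes are MLE-fitted to the interior values from a
    moment-matching start.
    """
    alpha = np.asarray(alphas, dtype=float).ravel()
    if alpha.size < 3:
        raise ValueError("need at least 3 admixture proportions")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("admixture proportions must lie in [0, 1]")
    at0 = alpha <= eps
    at1 = alpha >= 1.0 - eps
    interior = alpha[~at0 & ~at1]
    p0 = float(at0.mean())
    p1 = float(at1.mean())
    if interior.size == 0:
        return AdmixtureDistribution(p0, p1, None, None, alpha.size, float(alpha.mean()))
    if interior.size < 2:
        raise ValueError("interior mass present but fewer than 2 interior points")
    mean = interior.mean()
    var = interior.var()
    if var <= 0:
        raise ValueError(f"degenerate interior sample (all values {mean:.4f}); "
                         "cannot fit beta shapes")
    common = mean * (1 - mean) / var - 1.0
    a0 = max(mean * common, 1e-3)
    b0 = max((1 - mean) * common, 1e-3)
    a, b, _, _ = stats.beta.fit(interior, a0, b0, floc=0, fscale=1)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise ValueError(f"degenerate beta fit (a={a}, b={b}) from start "
                         f"(a0={a0:.3f}, b0={b0:.3f}), n_interior={interior.size}")
    return AdmixtureDistribution(p0, p1, float(a), float(b), alpha.size,
                                 float(alpha.mean()))


def discretize_distribution(dist: AdmixtureDistribution, n_bins: int = 10) -> list:
    """Discretize the fitted mixture into ``n_bins`` equal-width bins on [0, 1].

    A bin's probability is the beta mass it contains plus any point mass
    at its boundary (0 goes to the first bin, 1 to the last); its
    representative ``alpha_b`` is the probability-weighted mean of the
    bin's content. Empty bins get the bin midpoint as representative.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mass = np.zeros(n_bins)
    moment = np.zeros(n_bins)
    w = dist.interior_mass
    if w > 0:
        cdf = stats.beta.cdf(edges, dist.a, dist.b)
        mass += w * np.diff(cdf)
        # first moment over each bin: E[alpha; bin] via Beta(a+1, b)
        cdf1 = stats.beta.cdf(edges, dist.a + 1.0, dist.b)
        moment += w * (dist.a / (dist.a + dist.b)) * np.diff(cdf1)
    mass[0] += dist.p0
    mass[-1] += dist.p1
    moment[-1] += dist.p1 * 1.0
    total = mass.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"bin masses sum to {total}, not 1")
    mass /= total
    mids = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_b = np.where(mass > 0, moment / np.maximum(mass * total, 1e-300), mids)
    return [AlphaBin(float(a), float(p)) for a, p in zip(alpha_b, mass)]


def _bin_arrays(bins) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.array([b.alpha for b in bins])
    prob = np.array([b.prob for b in bins])
    included = alpha < 1.0 - 1e-9
    if not included.any():
        raise ValueError("all bins sit at alpha = 1; correction undefined")
    prob = prob[included] / prob[included].sum()
    return alpha[included], prob


def corrected_allele_frequency(f_g, f_d, bins):
    """Admixture-corrected allele frequency(ies), clamped to [0, 1].

    Parameters
    ----------
    f_g, f_d
        Observed admixed-cohort and reference-donor frequencies
        (scalars or equal-length arrays).
    bins
        Discretized admixture distribution from
        :func:`discretize_distribution`.

    Returns
    -------
    (corrected, clamped)
        Corrected frequency(ies) and a flag marking values that were
        clamped into the unit interval (the raw formula can exit it when
        the input frequencies are noisy).
    """
    alpha, prob = _bin_arrays(bins)
    fg = np.atleast_1d(np.asarray(f_g, dtype=float))
    fd = np.atleast_1d(np.asarray(f_d, dtype=float))
    if np.any((fg < 0) | (fg > 1)) or np.any((fd < 0) | (fd > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    raw = ((fg[..., None] - alpha * fd[..., None]) / (1.0 - alpha) * prob).sum(axis=-1)
    corrected = np.clip(raw, 0.0, 1.0)
    clamped = raw != corrected
    if np.isscalar(f_g) or np.ndim(f_g) == 0:
        return float(corrected[0]), bool(clamped[0])
    return corrected, clamped


def corrected_allele_frequency_moment(f_g, f_d, bins):
    """Moment-based corrector ``(f_G - E[alpha] f_D) / (1 - E[alpha])``.

    Unlike the bin-averaged form this inverts the expectation of the
    mixing identity directly, so it is unbiased for the ancestral
    frequency under any admixture distribution with ``E[alpha] < 1``.
    """
    alpha, prob = _bin_arrays(bins)
    abar = float((alpha * prob).sum())
    fg = np.asarray(f_g, dtype=float)
    fd = np.asarray(f_d, dtype=float)
    raw = (fg - abar * fd) / (1.0 - abar)
    corrected = np.clip(raw, 0.0, 1.0)
    clamped = raw != corrected
    if np.ndim(f_g) == 0:
        return float(corrected), bool(clamped)
    return corrected, clamped


def correct_frequency_table(f_g, f_d, bins) -> pd.DataFrame:
    """Per-site table of observed, reference and corrected frequencies."""
    corrected, clamped = corrected_allele_frequency(f_g, f_d, bins)
    return pd.DataFrame({
        "f_observed": np.asarray(f_g, dtype=float),
        "f_reference": np.asarray(f_d, dtype=float),
        "f_corrected": corrected,
        "clamped": clamped,
    })
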