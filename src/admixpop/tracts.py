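"""Two-state Markov model of ancestry-tract lengths, tract binning, and
ancestry-proportion matching.

Along a chromosome of an admixed individual, ancestry alternates between
"admixed" (introgressed) and "unadmixed" segments. Treating each base
pair as one step of a two-state Markov chain, a single admixture pulse of
proportion ``m`` occurring ``t`` generations ago with a uniform
recombination rate ``r`` (Morgans per bp) gives per-bp transition rates

    lambda1 = (1 - m) * r * (t - 1)   (admixed -> unadmixed)
    lambda2 = m * r * (t - 1)         (unadmixed -> admixed)

with stationary probability ``pi2 = 1 - m`` of the unadmixed state. The
probability that a given site initiates an admixed run of at least ``k``
sites is ``R = pi2 * lambda2 * (1 - lambda1)**(k - 1)``; over a genome of
``S`` sites with ``R`` small the number of such runs is approximately
Poisson and the probability of seeing none is ``exp(-R * S)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TractSet


def tract_rates(m: float, r: float, t: float) -> tuple[float, float, float]:
    """Per-bp transition rates (lambda1, lambda2) and stationary pi2 = 1 - m."""
    if not 0 <= m <= 1:
        raise ValueError("admixture proportion m must lie in [0, 1]")
    if r <= 0:
        raise ValueError("recombination rate r must be positive")
    if t <= 1:
        raise ValueError("admixture time t must exceed 1 generation")
    lam1 = (1.0 - m) * r * (t - 1.0)
    lam2 = m * r * (t - 1.0)
    if lam1 >= 1 or lam2 >= 1:
        raise ValueError("per-bp transition rates must be below 1; "
                         "r * (t - 1) is too large")
    return lam1, lam2, 1.0 - m


@dataclass
class TractModel:
    """Markov tract-length model: admixture proportion ``m``, uniform
    recombination rate ``r`` (Morgans/bp), admixture time ``t``
    (generations), genome size ``s`` (bp)."""

    m: float
    r: float
    t: float
    s: float

    def __post_init__(self) -> None:
        tract_rates(self.m, self.r, self.t)  # validates
        if self.s <= 0:
            raise ValueError("genome size must be positive")

    @property
    def lambda1(self) -> float:
        return tract_rates(self.m, self.r, self.t)[0]

    @property
    def lambda2(self) -> float:
        return tract_rates(self.m, self.r, self.t)[1]

    @property
    def pi2(self) -> float:
        return 1.0 - self.m

    def prob_no_tract_at_least(self, length_cm: float) -> float:
        return prob_no_tract_at_least(self.m, self.r, self.t, self.s, length_cm)

    def prob_at_least_one(self, length_cm: float) -> float:
        return prob_at_least_one(self.m, self.r, self.t, self.s, length_cm)


def _run_threshold_sites(length_cm: float, r: float) -> int:
    # one bp == one Markov site; a tract of L cM spans (L/100)/r sites
    k = round((length_cm / 100.0) / r)
    if k < 1:
        raise ValueError("tract-length threshold shorter than one site")
    return k


def prob_no_tract_at_least(m: float, r: float, t: float, s: float,
                           length_cm: float) -> float:
    """Probability that a genome of ``s`` bp carries no admixed tract of at
    least ``length_cm`` cM, i.e. ``exp(-R*S)``.

    ``(1 - lambda1)**(k-1)`` is evaluated in log space so genome-scale
    ``k`` does not underflow.
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    lam1, lam2, pi2 = tract_rates(m, r, t)
    k = _run_threshold_sites(length_cm, r)
    log_r = math.log(pi2 * lam2) if pi2 * lam2 > 0 else -math.inf
    log_r += (k - 1) * math.log1p(-lam1)
    return math.exp(-math.exp(log_r) * s) if log_r > -math.inf else 1.0


def prob_at_least_one(m: float, r: float, t: float, s: float,
                      length_cm: float) -> float:
    """Companion probability ``1 - exp(-R*S)`` of at least one long tract."""
    return 1.0 - prob_no_tract_at_least(m, r, t, s, length_cm)


def bin_tract_lengths(ts: TractSet, bin_cm: float = 5.0,
                      ancestry: str | None = None,
                      groups=None) -> pd.DataFrame:
    """Summarize tract lengths into ``[i*bin, (i+1)*bin)`` cM bins.

    Parameters
    ----------
    ts
        Tract set; must be non-empty.
    bin_cm
        Bin width in cM (default 5).
    ancestry
        If given, only tracts of this ancestry are counted.
    groups
        Optional mapping individual -> population label; counts and
        within-population frequencies are reported per population.

    Returns a DataFrame with columns ``population, bin_lo_cm, bin_hi_cm,
    count, frequency``; frequencies sum to 1 within each population.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    if ts.n_tracts == 0:
        raise ValueError("empty tract set")
    df = ts.tracts
    if ancestry is not None:
        df = df[df["ancestry"] == ancestry]
    if len(df) == 0:
        return pd.DataFrame(columns=["population", "bin_lo_cm", "bin_hi_cm",
                                     "count", "frequency"])
    if groups is None:
        pop = pd.Series("all", index=df.index)
    else:
        pop = df["individual"].map(lambda i: groups[i])
    n_bins = int(np.floor(df["length_cm"].max() / bin_cm)) + 1
    edges = np.arange(n_bins + 1) * bin_cm
    out = []
    for label in pd.unique(pop):
        lengths = df.loc[pop == label, "length_cm"].to_numpy()
        counts, _ = np.histogram(lengths, bins=edges)
        out.append(pd.DataFrame({
            "population": label,
            "bin_lo_cm": edges[:-1],
            "bin_hi_cm": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }))
    return pd.concat(out, ignore_index=True)


@dataclass
class MatchResult:
    """Ancestry-matched index pairs between two cohorts."""

    pairs: list  # (index_in_a, index_in_b), original indices
    total_abs_diff: float


def match_by_ancestry(props_a, props_b, min_prop: float = 0.05) -> MatchResult:
    """Match two cohorts on an ancestry proportion as closely as possible.

    Individuals below ``min_prop`` are excluded on both sides, then
    ``min(n_a, n_b)`` one-to-one pairs are chosen to minimize the total
    absolute difference in ancestry proportion (optimal assignment, so
    the pairing is deterministic and its total difference is a global
    minimum). Pairs are returned sorted by index in A.
    """
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(props_a, dtype=float)
    b = np.asarray(props_b, dtype=float)
    ia = np.flatnonzero(a >= min_prop)
    ib = np.flatnonzero(b >= min_prop)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("one cohort is empty after the min_prop filter")
    cost = np.abs(a[ia][:, None] - b[ib][None, :])
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted((int(ia[i]), int(ib[j])) for i, j in zip(rows, cols))
    total = float(cost[rows, cols].sum())
    return MatchResult(pairs, total)
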