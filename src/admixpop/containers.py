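"""Core in-memory containers shared across the toolkit.

The three containers mirror the three kinds of input the estimators
consume: unphased biallelic genotypes (:class:`GenotypeMatrix`),
per-individual ancestry proportions (:class:`AdmixtureProportionSet`),
and local-ancestry tract tables (:class:`TractSet`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call.
MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")
TRACT_COLUMNS = ("individual", "haplotype", "chrom", "start_bp", "end_bp",
                 "ancestry", "length_cm")


def _check_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    sites = sites.reset_index(drop=True)
    if (sites["ref"].astype(str) == sites["alt"].astype(str)).any():
        raise ValueError("ref and alt alleles must differ at every site")
    pos = sites["pos"].to_numpy()
    for _, idx in sites.groupby("chrom", sort=False).indices.items():
        if np.any(np.diff(pos[idx]) <= 0):
            raise ValueError("positions must be strictly increasing within a chromosome")
    return sites


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes coded as alt-allele counts.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` integer array with values in
        ``{0, 1, 2}``; missing calls are :data:`MISSING` (-1).
    individual_ids
        Unique sample labels, one per row.
    sites
        Site table with columns ``chrom``, ``pos`` (1-based bp), ``ref``
        and ``alt``, one row per column of ``genotypes``. Positions must
        be strictly increasing within each chromosome.
    """

    genotypes: np.ndarray
    individual_ids: list = field(default_factory=list)
    sites: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals x sites array")
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if len(self.individual_ids) != self.genotypes.shape[0]:
            raise ValueError("individual_ids length does not match genotype rows")
        if self.sites is None:
            raise ValueError("a site table is required")
        self.sites = _check_site_table(self.sites)
        if len(self.sites) != self.genotypes.shape[1]:
            raise ValueError("site table rows do not match genotype columns")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be in {0, 1, 2} or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency from non-missing calls (NaN if none)."""
        called = self.genotypes != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def site_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.genotypes[:, index], list(self.individual_ids),
                              self.sites.iloc[index].reset_index(drop=True))

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.genotypes[index], [self.individual_ids[i] for i in index],
                              self.sites.copy())


@dataclass
class AdmixtureProportionSet:
    """Per-individual ancestry proportion vectors over K ancestral populations.

    Rows must lie in ``[0, 1]`` and sum to one within 1e-6 (the reader in
    :mod:`admixpop.io` renormalizes small deviations before building this).
    """

    proportions: np.ndarray
    ancestries: tuple = ("EUR", "INUIT")
    individual_ids: list | None = None

    def __post_init__(self) -> None:
        self.proportions = np.atleast_2d(np.asarray(self.proportions, dtype=float))
        self.ancestries = tuple(str(a) for a in self.ancestries)
        if self.proportions.shape[1] != len(self.ancestries):
            raise ValueError("ancestry labels do not match proportion columns")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValueError("ancestry proportions must lie in [0, 1]")
        if np.any(np.abs(self.proportions.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each row of ancestry proportions must sum to 1")
        if self.individual_ids is not None:
            self.individual_ids = [str(i) for i in self.individual_ids]
            if len(self.individual_ids) != self.proportions.shape[0]:
                raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_ancestries(self) -> int:
        return self.proportions.shape[1]

    def column(self, ancestry: str) -> np.ndarray:
        return self.proportions[:, self.ancestries.index(ancestry)]

    def take(self, index) -> "AdmixtureProportionSet":
        index = np.asarray(index)
        ids = None if self.individual_ids is None else [self.individual_ids[i] for i in index]
        return AdmixtureProportionSet(self.proportions[index], self.ancestries, ids)


@dataclass
class TractSet:
    """Local-ancestry tracts in half-open 0-based [start_bp, end_bp) coordinates.

    ``tracts`` holds one row per tract with columns
    ``individual, haplotype, chrom, start_bp, end_bp, ancestry, length_cm``.
    Tracts on one (individual, haplotype, chromosome) must not overlap.
    """

    tracts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACT_COLUMNS if c not in self.tracts.columns]
        if missing:
            raise ValueError(f"tract table lacks columns {missing}")
        self.tracts = self.tracts.reset_index(drop=True)
        if len(self.tracts) == 0:
            return
        t = self.tracts
        if (t["end_bp"].to_numpy() <= t["start_bp"].to_numpy()).any():
            raise ValueError("tract end_bp must exceed start_bp")
        if (t["length_cm"].to_numpy() <= 0).any():
            raise ValueError("tract length_cm must be positive")
        for _, grp in t.groupby(["individual", "haplotype", "chrom"], sort=False):
            g = grp.sort_values("start_bp")
            if (g["start_bp"].to_numpy()[1:] < g["end_bp"].to_numpy()[:-1]).any():
                raise ValueError("overlapping tracts on one haplotype")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def lengths_bp(self) -> np.ndarray:
        return (self.tracts["end_bp"] - self.tracts["start_bp"]).to_numpy()

    def filter_ancestry(self, ancestry: str) -> "TractSet":
        return TractSet(self.tracts[self.tracts["ancestry"] == ancestry].reset_index(drop=True))
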