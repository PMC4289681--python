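"""Readers and writers for the toolkit's text formats.

Supported formats: VCF (GT field only, read via cyvcf2), a tab-separated
genotype matrix dialect that round-trips exactly, ADMIXTURE-style Q
matrices, and BED-like local-ancestry tract tables.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (MISSING, SITE_COLUMNS, TRACT_COLUMNS,
                         AdmixtureProportionSet, GenotypeMatrix, TractSet)

logger = logging.getLogger(__name__)

_TSV_MISSING = "NA"


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read diploid genotypes as alt-allele counts.

    VCF records that are not biallelic SNPs (indels, multiallelics) are
    skipped; the skipped count is logged. Missing GT calls become
    :data:`~admixpop.containers.MISSING`.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    cols, rows, skipped = [], [], 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            skipped += 1
            continue
        cols.append(code[v.gt_types])
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    vcf.close()
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    return GenotypeMatrix(np.column_stack(cols), ids, sites)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:4]) != list(SITE_COLUMNS):
        raise ValueError(f"genotype TSV must start with columns {SITE_COLUMNS}")
    ids = list(df.columns[4:])
    sites = df[list(SITE_COLUMNS)].copy()
    sites["pos"] = sites["pos"].astype(int)
    if len(df) == 0:
        geno = np.empty((len(ids), 0), dtype=np.int8)
    else:
        raw = df[ids].to_numpy(dtype="U8")
        geno = np.where(raw == _TSV_MISSING, str(MISSING), raw).astype(np.int8).T
    if geno.shape[1] == 0:
        raise ValueError(f"no usable sites in {path}")
    return GenotypeMatrix(geno, ids, sites)


def write_genotypes(gm: GenotypeMatrix, path, format: str = "tsv") -> None:
    """Write a genotype matrix; the tsv dialect round-trips bit-exactly."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(gm, path)
    elif format == "vcf":
        _write_vcf(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(list(SITE_COLUMNS) + gm.individual_ids) + "\n")
        geno = gm.genotypes
        for s in range(gm.n_sites):
            row = gm.sites.iloc[s]
            calls = [_TSV_MISSING if g == MISSING else str(int(g)) for g in geno[:, s]]
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{row.ref}\t{row.alt}\t" + "\t".join(calls) + "\n")


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixpop\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids) + "\n")
        for s in range(gm.n_sites):
            row = gm.sites.iloc[s]
            calls = "\t".join(_VCF_GT[int(g)] for g in gm.genotypes[:, s])
            fh.write(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{calls}\n")


def read_admixture_q(path, ancestries=("EUR", "INUIT"),
                     individual_ids=None) -> AdmixtureProportionSet:
    """Read an ADMIXTURE-style Q matrix (whitespace-separated, K columns).

    Rows whose sum deviates from 1 by at most 1e-3 are renormalized;
    larger deviations raise ``ValueError``.
    """
    q = np.loadtxt(path, dtype=float, ndmin=2)
    if q.shape[1] != len(ancestries):
        raise ValueError(f"expected {len(ancestries)} columns, found {q.shape[1]}")
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} of Q matrix sums to {sums[bad]:.6f}, not 1")
    q = q / sums[:, None]
    return AdmixtureProportionSet(q, ancestries, individual_ids)


def write_admixture_q(alphas: AdmixtureProportionSet, path) -> None:
    np.savetxt(path, alphas.proportions, fmt="%.6f")


def read_tracts(path, rate_morgans_per_bp: float | None = None,
                ancestries=None) -> TractSet:
    """Read a BED-like tract table (half-open [start, end) bp coordinates).

    The table must carry columns ``chrom start end individual haplotype
    ancestry`` and either a ``length_cm`` column or a uniform
    ``rate_morgans_per_bp`` from which cM lengths are derived as
    ``bp * rate * 100``.
    """
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return TractSet(pd.DataFrame(columns=list(TRACT_COLUMNS)))
    required = ["chrom", "start", "end", "individual", "haplotype", "ancestry"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"tract table lacks columns {missing}")
    if ancestries is not None:
        unknown = set(df["ancestry"].astype(str)) - set(map(str, ancestries))
        if unknown:
            raise ValueError(f"unknown ancestry labels {sorted(unknown)}")
    out = pd.DataFrame({
        "individual": df["individual"].astype(str),
        "haplotype": df["haplotype"],
        "chrom": df["chrom"].astype(str),
        "start_bp": df["start"].astype(int),
        "end_bp": df["end"].astype(int),
        "ancestry": df["ancestry"].astype(str),
    })
    if "length_cm" in df.columns:
        out["length_cm"] = df["length_cm"].astype(float)
    else:
        if rate_morgans_per_bp is None:
            raise ValueError("need a length_cm column or rate_morgans_per_bp")
        out["length_cm"] = (out["end_bp"] - out["start_bp"]) * rate_morgans_per_bp * 100.0
    return TractSet(out)


def write_tracts(ts: TractSet, path) -> None:
    df = ts.tracts.rename(columns={"start_bp": "start", "end_bp": "end"})
    cols = ["chrom", "start", "end", "individual", "haplotype", "ancestry", "length_cm"]
    df[cols].to_csv(path, sep="\t", index=False)
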