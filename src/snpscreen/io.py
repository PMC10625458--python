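"""Readers and writers for phenotype tables, PLINK 1 binary triplets and VCF.

Subject alignment between genotype and phenotype sources is always by
sample id intersection, never positional.  The PLINK .bed codec implements
the v1.0 SNP-major layout (magic 6C 1B 01; two bits per genotype packed
four samples per byte: 00 = homozygous A1, 01 = missing, 10 = heterozygous,
11 = homozygous A2).  Internally genotypes are alt-allele counts with A1
as the alternate allele.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import GenotypeMatrix
from .survival import CohortData

log = logging.getLogger("snpscreen")

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "align",
    "write_results",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit bed code -> alt-allele count (A1 = alt)
_BED_TO_GENO = np.array([2, -1, 1, 0], dtype=np.int8)
_GENO_TO_BED = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def read_phenotypes(path: str | Path) -> CohortData:
    """Load a CSV/TSV phenotype table into a cohort.

    Requires columns ``id``, ``time``, ``event``; every remaining column is
    treated as a numeric covariate in file order.  The delimiter (comma or
    tab) is auto-detected.  Rows missing time or event are dropped with a
    per-row report; duplicate ids and non-numeric covariate cells raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"phenotype file {path} is missing required column '{col}'")
    bad = df["time"].isna() | df["event"].isna()
    if bad.any():
        for i in df.index[bad]:
            log.warning("dropping row %d (id=%s): missing time/event", i, df.loc[i, "id"])
        df = df[~bad]
    dup = df["id"][df["id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate subject ids: {dup.tolist()}")
    cov_cols = [c for c in df.columns if c not in ("id", "time", "event")]
    try:
        cov = df[cov_cols].astype(float).to_numpy() if cov_cols else np.empty((len(df), 0))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric covariate cell in {path}: {exc}") from exc
    return CohortData(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        covariates=cov,
        subject_ids=df["id"].astype(str).to_numpy(),
        covariate_names=cov_cols,
    )


def write_phenotypes(cohort: CohortData, path: str | Path) -> None:
    """Write a cohort as a TSV phenotype table (inverse of read_phenotypes)."""
    df = pd.DataFrame({"id": cohort.subject_ids, "time": cohort.time, "event": cohort.event})
    for j, name in enumerate(cohort.covariate_names):
        df[name] = cohort.covariates[:, j]
    df.to_csv(path, sep="\t", index=False)


# --- PLINK 1 binary ---------------------------------------------------------

def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam (SNP-major v1.0) for a genotype matrix."""
    prefix = Path(prefix)
    n, m = geno.n, geno.n_snps
    samples = geno.sample_ids if geno.sample_ids is not None else [f"S{i+1}" for i in range(n)]
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    chrom = geno.chrom if geno.chrom is not None else np.ones(m, int)
    pos = geno.pos if geno.pos is not None else np.arange(1, m + 1)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            ref, alt = geno.alleles[j]
            fh.write(f"{chrom[j]}\t{geno.snp_ids[j]}\t0\t{pos[j]}\t{alt}\t{ref}\n")
    nbytes = math.ceil(n / 4)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(nbytes, dtype=np.uint8)
        for j in range(m):
            buf[:] = 0
            col = geno.genotypes[:, j]
            for i in range(n):
                buf[i // 4] |= _GENO_TO_BED[int(col[i])] << ((i % 4) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet (SNP-major v1.0)."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str)
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad magic bytes (not PLINK bed v1.0 SNP-major)")
    nbytes = math.ceil(n / 4)
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != nbytes * m:
        raise ValueError(f"{prefix.with_suffix('.bed')}: size mismatch for n={n}, m={m}")
    body = body.reshape(m, nbytes)
    # unpack 2-bit fields, sample-fastest within byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    G = _BED_TO_GENO[codes].T  # (n, m)
    return GenotypeMatrix(
        genotypes=G,
        snp_ids=bim["snp"].tolist(),
        alleles=[(a2, a1) for a1, a2 in zip(bim["a1"], bim["a2"])],
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].astype(int).to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid biallelic GT calls from a VCF; multiallelic sites are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    cols, ids, alleles, chroms, poss = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1).astype(np.int8)
        cols.append(col)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if n_multi:
        log.info("skipped %d multiallelic site(s) in %s", n_multi, path)
    if not cols:
        raise ValueError(f"no usable biallelic sites in {path}")
    return GenotypeMatrix(
        genotypes=np.column_stack(cols),
        snp_ids=ids,
        alleles=alleles,
        chrom=np.asarray(chroms),
        pos=np.asarray(poss),
        sample_ids=samples,
    )


def read_genotypes(path_or_prefix: str | Path) -> GenotypeMatrix:
    """Dispatch to the VCF or PLINK reader based on the path."""
    p = Path(path_or_prefix)
    if p.suffix in {".vcf", ".gz"} or str(p).endswith(".vcf.gz"):
        return read_vcf(p)
    return read_plink(p)


def align(cohort: CohortData, geno: GenotypeMatrix):
    """Intersect cohort and genotype samples by id, in cohort order.

    Returns (cohort, genotypes, report) restricted to the shared subjects;
    the report counts subjects present on only one side.
    """
    if geno.sample_ids is None:
        raise ValueError("genotype matrix carries no sample ids; cannot align")
    geno_ids = [str(s) for s in geno.sample_ids]
    pheno_ids = [str(s) for s in cohort.subject_ids]
    geno_pos = {s: i for i, s in enumerate(geno_ids)}
    shared = [s for s in pheno_ids if s in geno_pos]
    if not shared:
        raise ValueError("zero overlapping subjects between phenotype and genotype files")
    report = {
        "n_shared": len(shared),
        "n_pheno_only": len(pheno_ids) - len(shared),
        "n_geno_only": len(geno_ids) - len(shared),
    }
    keep_p = [i for i, s in enumerate(pheno_ids) if s in geno_pos]
    keep_g = [geno_pos[s] for s in shared]
    sub_cohort = CohortData(
        cohort.time[keep_p], cohort.event[keep_p], cohort.covariates[keep_p],
        subject_ids=cohort.subject_ids[keep_p],
        covariate_names=list(cohort.covariate_names),
    )
    sub_geno = GenotypeMatrix(
        genotypes=geno.genotypes[keep_g],
        snp_ids=geno.snp_ids, alleles=geno.alleles,
        chrom=geno.chrom, pos=geno.pos,
        sample_ids=np.asarray(shared),
    )
    return sub_cohort, sub_geno, report


def write_results(results: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a deterministic TSV of screen results, sorted and with stable columns."""
    df = results.sort_values(
        [c for c in ("snp_id", "pass", "method") if c in results.columns], kind="stable"
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV (skipping provenance comment lines)."""
    return pd.read_csv(path, sep="\t", comment="#")
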