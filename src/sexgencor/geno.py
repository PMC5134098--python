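"""SNP quality control and genomic relatedness matrix (GRM) construction.

The GRM is the SNP-derived estimate of realized genetic relatedness,

    A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with ``x`` an allele dosage in {0, 1, 2} and ``p_i`` the sample frequency of
the counted allele at SNP ``i``.  Missing dosages are mean-imputed per SNP
(equivalently contribute zero after centering).  The sex partition of the GRM
supplies the male block ``A_m``, the female block ``A_f`` and the cross block
``A_mf`` that parameterize the covariance of the bivariate mixed model.

SNP QC follows the standard panel filters: minor allele frequency >= 0.01 and
Hardy-Weinberg exact test p >= 1e-6 by default.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRMPartition",
    "SexBlocks",
    "compute_maf",
    "hwe_exact_test",
    "filter_snps",
    "compute_grm",
    "partition_by_sex",
    "normalize_sex",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_bed",
    "write_bed",
    "read_grm_bin",
    "write_grm_bin",
    "write_grm_text",
]

DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_MIN = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n samples x M SNPs of minor-allele dosages with per-SNP metadata.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing.
    ``snp_meta`` columns: snp_id, chromosome, position, a1, a2, maf.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GRMPartition:
    """Symmetric n x n SNP relatedness with optional per-sample sex labels."""

    values: np.ndarray
    ids: np.ndarray
    m_snps: int
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square and match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM entries must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.ids)


@dataclass
class SexBlocks:
    """Views of a GRM partitioned by sex: A_m (m x m), A_f (f x f), A_mf (m x f)."""

    A_m: np.ndarray
    A_f: np.ndarray
    A_mf: np.ndarray
    male_ids: np.ndarray
    female_ids: np.ndarray


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def compute_maf(dosages: Sequence[float]) -> float:
    """Minor-allele frequency of one SNP; missing dosages excluded."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all dosages missing")
    freq = d[ok].sum() / (2.0 * ok.sum())
    return float(min(freq, 1.0 - freq))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one (the plain,
    not mid-p, exact test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # count one allele; symmetry makes the choice moot
    n_minor = min(n_a, 2 * n - n_a)

    # log P(het = h | allele counts), up to a shared constant
    def logprob(h: int) -> float:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            h * math.log(2.0)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_major + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (n_Aa - n_minor % 2) // 2
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _snp_qc_table(G: GenotypeMatrix) -> pd.DataFrame:
    mafs = np.empty(G.n_snps)
    hwe = np.empty(G.n_snps)
    for j in range(G.n_snps):
        col = G.dosages[:, j]
        ok = ~np.isnan(col)
        mafs[j] = compute_maf(col)
        c = col[ok]
        hwe[j] = hwe_exact_test(
            int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
        )
    return pd.DataFrame(
        {"snp_id": G.snp_meta["snp_id"].to_numpy(), "maf": mafs, "hwe_p": hwe}
    )


def filter_snps(
    G: GenotypeMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_min: float = DEFAULT_HWE_MIN,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the MAF and HWE filters; returns the retained panel and a report.

    The report has one row per input SNP with columns snp_id, maf, hwe_p,
    kept, reason (one of ``low_maf``, ``hwe_fail``, ``ok``).
    """
    report = _snp_qc_table(G)
    low_maf = report["maf"].to_numpy() < maf_min
    hwe_fail = report["hwe_p"].to_numpy() < hwe_min
    kept = ~(low_maf | hwe_fail)
    reason = np.where(low_maf, "low_maf", np.where(hwe_fail, "hwe_fail", "ok"))
    report["kept"] = kept
    report["reason"] = reason
    keep_idx = np.flatnonzero(kept)
    out = GenotypeMatrix(
        dosages=G.dosages[:, keep_idx],
        snp_meta=G.snp_meta.iloc[keep_idx].reset_index(drop=True),
        sample_ids=G.sample_ids,
    )
    return out, report


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(G: GenotypeMatrix) -> GRMPartition:
    """GCTA-style GRM from standardized dosages.

    Allele frequencies are estimated from the analysis sample.  Raises on
    monomorphic SNPs (zero variance under HWE scaling).
    """
    if G.n_snps < 1:
        raise ValueError("need at least one SNP")
    X = G.dosages.copy()
    ok = ~np.isnan(X)
    p = np.nansum(X, axis=0) / (2.0 * ok.sum(axis=0))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNP encountered; filter before GRM")
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[~ok] = 0.0  # mean imputation after centering
    A = (Z @ Z.T) / G.n_snps
    A = (A + A.T) / 2.0
    return GRMPartition(values=A, ids=G.sample_ids.copy(), m_snps=G.n_snps)


def normalize_sex(sex: Sequence) -> np.ndarray:
    """Map assorted encodings to the canonical {'male', 'female'} labels."""
    mapping = {
        "male": "male", "m": "male", "1": "male", 1: "male",
        "female": "female", "f": "female", "2": "female", 2: "female",
    }
    out = []
    for s in sex:
        key = s.lower() if isinstance(s, str) else s
        if key not in mapping:
            raise ValueError(f"unknown sex label: {s!r}")
        out.append(mapping[key])
    return np.asarray(out, dtype=object)


def partition_by_sex(
    grm: GRMPartition, sex: Sequence | Mapping[str, str]
) -> SexBlocks:
    """Partition the GRM into the A_m, A_f and A_mf blocks of the V matrix.

    ``sex`` is either an array aligned with ``grm.ids`` or a mapping
    id -> label, so the blocks are invariant to sample ordering.
    """
    if isinstance(sex, Mapping):
        labels = normalize_sex([sex[i] for i in grm.ids])
    else:
        if len(sex) != grm.n_samples:
            raise ValueError("sex labels must cover all samples")
        labels = normalize_sex(sex)
    grm.sex = labels
    male = labels == "male"
    female = labels == "female"
    A = grm.values
    return SexBlocks(
        A_m=A[np.ix_(male, male)],
        A_f=A[np.ix_(female, female)],
        A_mf=A[np.ix_(male, female)],
        male_ids=grm.ids[male],
        female_ids=grm.ids[female],
    )


# ---------------------------------------------------------------------------
# genotype I/O: dosage TSV and the bed/bim/fam binary triplet
# ---------------------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        G.dosages.T, index=G.snp_meta["snp_id"].to_numpy(), columns=G.sample_ids
    )
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(
    path: str | Path, snp_meta: pd.DataFrame | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    dosages = df.to_numpy(dtype=float).T
    if snp_meta is None:
        m = len(df.index)
        snp_meta = pd.DataFrame(
            {
                "snp_id": df.index.to_numpy(),
                "chromosome": np.ones(m, dtype=int),
                "position": np.arange(1, m + 1),
                "a1": ["A"] * m,
                "a2": ["B"] * m,
                "maf": [compute_maf(dosages[:, j]) for j in range(m)],
            }
        )
    return GenotypeMatrix(
        dosages=dosages,
        snp_meta=snp_meta,
        sample_ids=np.asarray(df.columns, dtype=object),
    )


_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit codes, per pair of bits: 0=hom A1 (dosage 2), 1=missing, 2=het, 3=hom A2
_CODE_FOR_DOSAGE = {2.0: 0, 1.0: 2, 0.0: 3}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_bed(G: GenotypeMatrix, prefix: str | Path, sex: Sequence | None = None) -> None:
    """Write the standard binary genotype triplet (<prefix>.bed/.bim/.fam)."""
    prefix = Path(prefix)
    n = G.n_samples
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        nbytes = (n + 3) // 4
        for j in range(G.n_snps):
            buf = bytearray(nbytes)
            col = G.dosages[:, j]
            for i in range(n):
                code = 1 if np.isnan(col[i]) else _CODE_FOR_DOSAGE[col[i]]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))
    bim = G.snp_meta
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in bim.iterrows():
            fh.write(
                f"{row['chromosome']}\t{row['snp_id']}\t0\t{row['position']}"
                f"\t{row['a1']}\t{row['a2']}\n"
            )
    sex_codes = (
        ["1" if s == "male" else "2" for s in normalize_sex(sex)]
        if sex is not None
        else ["0"] * n
    )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, sc in zip(G.sample_ids, sex_codes):
            fh.write(f"{sid}\t{sid}\t0\t0\t{sc}\t-9\n")


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chromosome", "snp_id", "cm", "position", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep="\t",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major bed file")
    nbytes = (n + 3) // 4
    body = raw[3:].reshape(m, nbytes)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    dosages = _DOSAGE_FOR_CODE[codes].T
    meta = bim[["snp_id", "chromosome", "position", "a1", "a2"]].copy()
    meta["maf"] = [compute_maf(dosages[:, j]) for j in range(m)]
    return GenotypeMatrix(
        dosages=dosages,
        snp_meta=meta,
        sample_ids=fam["iid"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# GRM I/O: GCTA binary dialect and gzipped text
# ---------------------------------------------------------------------------

def write_grm_bin(grm: GRMPartition, prefix: str | Path) -> None:
    """Lower-triangle float32 stream + id file + per-pair SNP-count file."""
    prefix = Path(prefix)
    n = grm.n_samples
    tri = np.concatenate([grm.values[i, : i + 1] for i in range(n)])
    tri.astype("<f4").tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, grm.m_snps, dtype="<f4").tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for sid in grm.ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_bin(prefix: str | Path) -> GRMPartition:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None)[1].to_numpy(object)
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    A = np.zeros((n, n))
    k = 0
    for i in range(n):
        A[i, : i + 1] = tri[k : k + i + 1]
        k += i + 1
    A = A + np.tril(A, -1).T
    return GRMPartition(values=A, ids=ids, m_snps=int(round(float(counts[0]))))


def write_grm_text(grm: GRMPartition, path: str | Path) -> None:
    """Gzipped text GRM: one line per pair i j m_snps a_ij (1-based, j <= i)."""
    with gzip.open(path, "wt") as fh:
        for i in range(grm.n_samples):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.values[i, j]:.6f}\n")
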