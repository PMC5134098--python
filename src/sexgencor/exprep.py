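"""Expression preprocessing and probe filtering.

Covers the standard microarray hygiene ahead of the genetic analysis:
quantile normalization across samples, rank-based inverse-normal transform
within sex-by-cohort groups, least-squares residualization on covariates or
expression principal components (with a per-PC sex t-test so that a PC that
captures sex is never regressed out), the sex-chromosome cross-hybridisation
rule for 50-mer probes, and the probe retention filter (autosomal, unflagged,
heritability strictly above the threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProbeRecord",
    "AlignmentHit",
    "quantile_normalize",
    "rank_inverse_normal",
    "residualize",
    "expression_pcs",
    "pc_sex_check",
    "classify_cross_hybridising",
    "filter_probes",
    "read_alignment_hits",
    "EXCLUSION_ORDER",
]

SEX_CHROMOSOMES = {"X", "Y"}
EXCLUSION_ORDER = (
    "cross_hybridising",
    "low_heritability",
    "background_fail",
    "uncharacterised",
    "chr_x",
    "chr_y",
)


@dataclass
class ProbeRecord:
    """Annotation and filter state for one expression probe."""

    probe_id: str
    chromosome: str
    position: int
    gene_symbol: str
    cross_hybridising: bool = False
    low_heritability: bool = False
    background_fail: bool = False
    uncharacterised: bool = False
    h2_estimate: float = float("nan")

    @property
    def sex_chromosome(self) -> bool:
        return str(self.chromosome).upper() in SEX_CHROMOSOMES

    @property
    def retained(self) -> bool:
        return not (
            self.cross_hybridising
            or self.low_heritability
            or self.background_fail
            or self.uncharacterised
            or self.sex_chromosome
        )


@dataclass
class AlignmentHit:
    """One probe-vs-genome alignment record (50-mer expression platform)."""

    probe_id: str
    identity: float
    matched_bp: int
    probe_length: int = 50
    gaps: int = 0
    target_chromosome: str = "X"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0, 1]")
        if self.matched_bp > self.probe_length:
            raise ValueError("matched_bp cannot exceed probe_length")
        if min(self.matched_bp, self.probe_length, self.gaps) < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize a samples x features matrix across samples.

    Every sample's sorted values are replaced by the cross-sample mean of the
    order statistics; ties within a sample receive the mean of the reference
    values they span.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    n, p = X.shape
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        # average rank handles ties: interpolate the reference at rank - 1
        ranks = stats.rankdata(X[i], method="average")
        out[i] = np.interp(ranks - 1.0, np.arange(p), reference)
    return out


def rank_inverse_normal(
    v: Sequence[float], groups: Sequence | None = None
) -> np.ndarray:
    """Rank-based inverse-normal transform, within groups if given.

    Within each group, value -> Phi^{-1}((rank - 0.5) / n_group) with average
    ranks for ties.  A constant group maps to all zeros with a warning.
    """
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    if groups is None:
        groups = np.zeros(len(v), dtype=int)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        mask = groups == g
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        vals = v[mask]
        if np.ptp(vals) == 0.0:
            warnings.warn(f"constant values in group {g!r}; transformed to zeros")
            out[mask] = 0.0
            continue
        ranks = stats.rankdata(vals, method="average")
        out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def residualize(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-feature least-squares residuals of X (samples x features) on C."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != X.shape[0]:
        raise ValueError("covariate rows must align with X")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def expression_pcs(X: np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k principal component scores of a samples x features matrix."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :k] * s[:k]


def pc_sex_check(
    pcs: np.ndarray, sex: Sequence[str], alpha: float | None = None
) -> pd.DataFrame:
    """Two-sample t-test of each PC across the sexes.

    A PC whose mean differs by sex (p below ``alpha``, default Bonferroni
    0.05/k) carries sex signal and must not be regressed out of expression.
    """
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    sex = np.asarray(sex, dtype=object)
    male = sex == "male"
    female = sex == "female"
    if not male.any() or not female.any():
        raise ValueError("both sexes required")
    k = pcs.shape[1]
    if alpha is None:
        alpha = 0.05 / k
    rows = []
    for j in range(k):
        t, p = stats.ttest_ind(pcs[male, j], pcs[female, j], equal_var=True)
        rows.append(
            {"pc": j + 1, "t": float(t), "p": float(p), "sex_confounded": p < alpha}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probe filters
# ---------------------------------------------------------------------------

def classify_cross_hybridising(hit: AlignmentHit) -> bool:
    """Sex-chromosome cross-hybridisation rule for 50-mer probes.

    Flag when the alignment has >= 90% identity, at least 40 of the 50 probe
    bases matching, no gaps, and a sex-chromosome target.
    """
    return (
        str(hit.target_chromosome).upper() in SEX_CHROMOSOMES
        and hit.identity >= 0.90
        and hit.matched_bp >= 40
        and hit.gaps == 0
    )


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Tab-separated hits: probe_id identity matched_bp probe_length gaps target_chromosome."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentHit(
            probe_id=str(r.probe_id),
            identity=float(r.identity),
            matched_bp=int(r.matched_bp),
            probe_length=int(r.probe_length),
            gaps=int(r.gaps),
            target_chromosome=str(r.target_chromosome),
        )
        for r in df.itertuples()
    ]


def _exclusion_reason(p: ProbeRecord) -> str | None:
    if p.cross_hybridising:
        return "cross_hybridising"
    if p.low_heritability:
        return "low_heritability"
    if p.background_fail:
        return "background_fail"
    if p.uncharacterised:
        return "uncharacterised"
    if str(p.chromosome).upper() == "X":
        return "chr_x"
    if str(p.chromosome).upper() == "Y":
        return "chr_y"
    return None


def filter_probes(
    probes: Sequence[ProbeRecord], h2_min: float = 0.10
) -> tuple[list[ProbeRecord], dict[str, int]]:
    """Retain autosomal, unflagged probes with heritability strictly above h2_min.

    Sets the ``low_heritability`` flag from ``h2_estimate`` (a missing estimate
    counts as low).  Excluded probes are tallied once each under the first
    applicable reason in the fixed order ``EXCLUSION_ORDER``.
    """
    tally = {k: 0 for k in EXCLUSION_ORDER}
    retained: list[ProbeRecord] = []
    for p in probes:
        if not (p.h2_estimate > h2_min):  # NaN-safe: NaN comparisons are False
            p.low_heritability = True
        reason = _exclusion_reason(p)
        if reason is None:
            retained.append(p)
        else:
            tally[reason] += 1
    return retained, tally
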