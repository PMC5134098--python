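"""Mixed-linear-model test for sexually dimorphic mean expression.

The model is y = a + X b + g + e with cov(g) = A * var_g (the SNP relatedness
capturing polygenic effects and sample structure) and cov(e) = I * var_e.
Sex is coded male 0 / female 1, so the fixed effect b is the female-minus-male
difference in mean expression.  Variance components come from the same AI-REML
engine used for the bivariate analysis; b and its standard error are the
generalized-least-squares solution at the REML estimates, and significance is
the Wald statistic (b/se)^2 against chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bigreml import fit_univariate
from .geno import GRMPartition, normalize_sex

__all__ = ["DimorphismResult", "fit_dimorphism", "wald_test", "dimorphism_scan"]


@dataclass
class DimorphismResult:
    probe_id: str
    beta: float  # female - male, expression units
    se: float
    wald: float
    p: float
    converged: bool
    var_g: float = float("nan")
    var_e: float = float("nan")


def wald_test(beta: float, se: float) -> tuple[float, float]:
    """Wald statistic (beta/se)^2 and its chi-square(1) upper-tail p-value."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    wald = (beta / se) ** 2
    return float(wald), float(chi2.sf(wald, df=1))


def fit_dimorphism(
    y: np.ndarray,
    sex,
    grm: GRMPartition,
    cohort=None,
    covariates: np.ndarray | None = None,
    probe_id: str = "probe",
) -> DimorphismResult:
    """REML fit of the sex-difference model for one probe.

    Cohort labels, when supplied, enter as fixed-effect indicators.  A
    non-converged REML fit is returned flagged with NA-valued statistics
    rather than raising.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != grm.n_samples:
        raise ValueError("phenotype must align with the GRM")
    labels = normalize_sex(sex)
    if len(labels) != len(y):
        raise ValueError("sex labels must align with samples")
    female = (labels == "female").astype(float)
    if female.min() == female.max():
        raise ValueError("both sexes required")

    cols = [np.ones(len(y)), female]
    if cohort is not None:
        d = pd.get_dummies(pd.Series(cohort), drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        cols.extend(C[:, j] for j in range(C.shape[1]))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")

    res = fit_univariate(y, grm, X)
    if not res.converged:
        return DimorphismResult(
            probe_id, float("nan"), float("nan"), float("nan"), float("nan"), False
        )
    beta = float(res.beta[1])
    se = float(np.sqrt(res.beta_cov[1, 1]))
    wald, p = wald_test(beta, se)
    return DimorphismResult(
        probe_id, beta, se, wald, p, True,
        var_g=float(res.theta[0]), var_e=float(res.theta[1]),
    )


def dimorphism_scan(
    Y: np.ndarray,
    probe_ids,
    sex,
    grm: GRMPartition,
    cohort=None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dimorphism test per probe over a samples x probes panel."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    rows = []
    for k, pid in enumerate(probe_ids):
        r = fit_dimorphism(Y[:, k], sex, grm, cohort=cohort,
                           covariates=covariates, probe_id=pid)
        rows.append(
            {
                "probe_id": r.probe_id, "beta": r.beta, "se": r.se,
                "wald": r.wald, "p": r.p, "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
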