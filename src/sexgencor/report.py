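"""Panel-level summaries: Bonferroni correction, genomic-control lambda,
QQ-plot coordinates, genetic-correlation distribution summaries and the
top table of probes deviating from r_G = 1.

Two null conventions are supported throughout.  The boundary test's reference
distribution is the 50:50 mixture of a point mass at 0 and chi-square(1), so
under the null half of all p-values sit exactly at 0.5 (the QQ plateau) and
the rest are uniform below 0.5.  The unconstrained analysis uses plain
chi-square(1).  For genomic control, p-values are mapped through the declared
null's inverse survival function to chi-square-equivalent statistics; the
mixture null's median equivalent is the point mass at zero, so lambda is
taken at the 75th percentile (whose null value equals the chi-square(1)
median, 0.4549) instead of the median used for the chi-square null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bigreml import GremlFit, RgTestResult, rg_scan
from .exprep import rank_inverse_normal
from .geno import compute_grm, filter_snps
from .simdata import SimulationConfig, simulate_panel

__all__ = [
    "PanelSummary",
    "bonferroni_threshold",
    "genomic_control",
    "qq_coordinates",
    "summarize_panel",
    "run_simulated_study",
    "boundary_null_calibration",
]

_CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.45493...


@dataclass
class PanelSummary:
    n_probes_input: int
    n_probes_tested: int
    n_nonconverged: int
    median_rg: float
    lambda_gc: float
    bonferroni_threshold: float
    n_significant: int
    top_table: pd.DataFrame


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("need at least one test")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def _chisq_equivalents(pvalues: np.ndarray, null: str) -> np.ndarray:
    if null == "chisq1":
        return chi2.isf(pvalues, df=1)
    if null == "mixture":
        # inverse of p = 0.5 * S(x): the point mass absorbs p >= 0.5
        return np.where(pvalues >= 0.5, 0.0, chi2.isf(2.0 * pvalues, df=1))
    raise ValueError(f"unknown null: {null!r}")


def genomic_control(pvalues, null: str = "mixture") -> float:
    """Genomic-control lambda of a p-value vector under the declared null.

    chisq1: median chi-square equivalent over the chi-square(1) median.
    mixture: 75th-percentile equivalent over its null value (the mixture's
    median is the point mass at zero, so the median ratio is degenerate).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    x = _chisq_equivalents(p, null)
    if null == "chisq1":
        return float(np.median(x) / _CHI2_1_MEDIAN)
    return float(np.quantile(x, 0.75) / _CHI2_1_MEDIAN)


def _null_quantile_p(q: np.ndarray, null: str) -> np.ndarray:
    """Expected p-value at cumulative rank q under the declared null."""
    if null == "chisq1":
        return q
    # mixture: p uniform below 0.5, atom of mass 0.5 at p = 0.5
    return np.minimum(q, 0.5)


def qq_coordinates(pvalues, null: str = "mixture") -> pd.DataFrame:
    """Ordered (expected, observed) -log10 p pairs for a QQ plot.

    Under the mixture null the expected quantiles plateau at 0.5, matching the
    flat leading segment of the boundary test's observed p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = p.size
    q = (np.arange(1, n + 1) - 0.5) / n
    exp = _null_quantile_p(q, null)
    return pd.DataFrame(
        {
            "expected": -np.log10(exp),
            "observed": -np.log10(obs),
            "expected_p": exp,
            "observed_p": obs,
        }
    )


def summarize_panel(
    fits: list[GremlFit],
    tests: list[RgTestResult],
    alpha: float = 0.05,
    top_k: int = 10,
    null: str = "mixture",
    probe_meta: pd.DataFrame | None = None,
) -> PanelSummary:
    """Panel summary over per-probe fits and boundary tests.

    The Bonferroni threshold divides by the number of input probes; medians,
    lambda and the top table use converged fits only.  Significance is strict
    (p exactly at the threshold does not count).  Top-table ties in p are
    broken by |1 - rg| descending, then probe id.
    """
    if len(fits) != len(tests):
        raise ValueError("fits and tests must align")
    for f, t in zip(fits, tests):
        if f.probe_id != t.probe_id:
            raise ValueError("fits and tests must refer to the same probes")
    m = len(fits)
    converged = [(f, t) for f, t in zip(fits, tests) if f.converged and np.isfinite(t.p)]
    if not converged:
        raise ValueError("no converged probes to summarize")
    thr = bonferroni_threshold(alpha, m)
    rg = np.array([f.rg for f, _ in converged])
    p = np.array([t.p for _, t in converged])

    rows = []
    for f, t in converged:
        rows.append(
            {
                "probe_id": f.probe_id,
                "h2_male": f.h2_male,
                "h2_female": f.h2_female,
                "rg": f.rg,
                "rg_se": f.rg_se,
                "lrt": t.lrt,
                "p": t.p,
                "mode": f.mode,
            }
        )
        t.significant_bonferroni = bool(t.p < thr)
    table = pd.DataFrame(rows)
    if probe_meta is not None:
        table = table.merge(
            probe_meta[["probe_id", "chromosome", "position", "gene_symbol"]],
            on="probe_id",
            how="left",
        )
    table["_tie"] = -np.abs(1.0 - table["rg"].fillna(1.0))
    table = (
        table.sort_values(["p", "_tie", "probe_id"])
        .drop(columns="_tie")
        .reset_index(drop=True)
    )

    return PanelSummary(
        n_probes_input=m,
        n_probes_tested=len(converged),
        n_nonconverged=m - len(converged),
        median_rg=float(np.median(rg[np.isfinite(rg)])),
        lambda_gc=genomic_control(p, null=null),
        bonferroni_threshold=thr,
        n_significant=int((p < thr).sum()),
        top_table=table.head(top_k),
    )


def run_simulated_study(
    config: SimulationConfig,
    mode: str = "constrained",
    rint: bool = True,
    with_null: bool = True,
):
    """Full pipeline on one synthetic study: simulate, SNP QC, GRM, per-sex
    rank-normal transform, then the per-probe bivariate scan with its LRT.

    Returns (fits, tests, truth_table).
    """
    G, panel, truth = simulate_panel(config)
    G_qc, _ = filter_snps(G)
    grm = compute_grm(G_qc)
    sex = panel.sample_meta["sex"].to_numpy()
    Y = panel.intensities
    if rint:
        Y = np.column_stack(
            [rank_inverse_normal(Y[:, k], groups=sex) for k in range(Y.shape[1])]
        )
    fits, tests = rg_scan(
        Y, panel.probe_meta["probe_id"], sex, grm, mode=mode, with_null=with_null
    )
    return fits, tests, truth


def boundary_null_calibration(
    n_probes: int = 400,
    n_males: int = 200,
    n_females: int = 200,
    n_snps: int = 500,
    h2: float = 0.5,
    seed: int = 1,
    maf_range: tuple[float, float] = (0.05, 0.5),
):
    """Calibration study for the r_G = 1 boundary test on independent probes.

    Each probe is a fresh draw of genotypes *and* expression (its own GRM), so
    probes are fully independent replicates and the fraction of zero LRT
    statistics carries a plain binomial envelope.  Sharing one genotype panel
    across probes (as a real study does) correlates all estimates through the
    realized relatedness and widens the panel-to-panel spread of that
    fraction.  Returns (fits, tests).
    """
    ss = np.random.SeedSequence(seed).spawn(n_probes)
    all_fits, all_tests = [], []
    for k in range(n_probes):
        cfg = SimulationConfig(
            n_males=n_males,
            n_females=n_females,
            n_snps=n_snps,
            maf_range=maf_range,
            h2_male=h2,
            h2_female=h2,
            rg_true=1.0,
            n_probes=1,
            seed=int(ss[k].generate_state(1)[0] % (2**31)),
        )
        fits, tests, _ = run_simulated_study(cfg, mode="constrained")
        fits[0].probe_id = f"probe{k + 1:05d}"
        tests[0].probe_id = fits[0].probe_id
        all_fits.append(fits[0])
        all_tests.append(tests[0])
    return all_fits, all_tests
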