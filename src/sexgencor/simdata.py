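"""Synthetic genotype and sex-stratified expression panels with known truth.

Genotypes are drawn at Hardy-Weinberg equilibrium (dosage ~ Binomial(2, p),
p ~ Uniform over a MAF range).  Expression for each probe follows the additive
polygenic model used downstream: a shared set of causal SNPs carries per-sex
effect vectors (u_m, u_f) drawn from a bivariate normal with correlation
``rg_true``, genetic values are formed on standardized genotypes and rescaled
within sex so the realized heritability equals the target exactly, Gaussian
residuals fill the remainder, and an additive mean shift (female - male) plants
sexual dimorphism.  Because the causal set is shared, the true cross-sex
genetic correlation is exactly the correlation of the effect vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geno import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "ExpressionPanel",
    "simulate_genotypes",
    "simulate_expression_probe",
    "simulate_panel",
    "write_expression_tsv",
    "read_expression_tsv",
    "load_config",
    "save_config",
]

N_AUTOSOMES = 22
CELL_TYPES = ("neutrophils", "lymphocytes", "monocytes")
# typical whole-blood composition (rough means 0.58 / 0.31 / 0.08)
_CELL_DIRICHLET = np.array([15.0, 8.0, 2.0])
_CELL_TOTAL = 0.97


@dataclass
class SimulationConfig:
    """Generative truth for one synthetic study.

    Heritabilities are per-sex fractions of total (unit) phenotypic variance;
    ``rg_true`` is the cross-sex correlation of causal effect sizes;
    ``sex_effect`` is the additive female-minus-male mean shift in expression
    units.
    """

    n_males: int = 200
    n_females: int = 200
    n_snps: int = 500
    n_causal: int | None = None  # None -> fully polygenic (all SNPs causal)
    maf_range: tuple[float, float] = (0.01, 0.5)
    h2_male: float = 0.5
    h2_female: float = 0.5
    rg_true: float = 1.0
    sex_effect: float = 0.0
    n_probes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_males, self.n_females) < 1 or self.n_snps < 1:
            raise ValueError("dimensions must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for h2 in (self.h2_male, self.h2_female):
            if not 0.0 <= h2 < 1.0:
                raise ValueError("heritability must be in [0, 1)")
        if not -1.0 <= self.rg_true <= 1.0:
            raise ValueError("rg_true must be in [-1, 1]")
        if self.n_causal is not None and not 1 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must be in [1, n_snps]")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_males + self.n_females

    @property
    def effective_n_causal(self) -> int:
        return self.n_snps if self.n_causal is None else self.n_causal


@dataclass
class ExpressionPanel:
    """n samples x P probes of expression intensities with metadata tables."""

    intensities: np.ndarray
    probe_meta: pd.DataFrame  # probe_id, chromosome, position, gene_symbol
    sample_meta: pd.DataFrame  # sample_id, sex, cohort [, batch, cell props]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = self.intensities.shape
        if len(self.sample_meta) != n or len(self.probe_meta) != p:
            raise ValueError("metadata does not match intensity matrix")
        sex = self.sample_meta["sex"]
        if sex.isna().any() or not set(sex) <= {"male", "female"}:
            raise ValueError("sex must be binary and non-missing")
        if self.sample_meta["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.probe_meta["probe_id"].duplicated().any():
            raise ValueError("probe ids must be unique")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    M: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed=0,
    sibling_pairs: bool = False,
) -> GenotypeMatrix:
    """HWE genotypes: per SNP p ~ Uniform(maf_range), dosage ~ Binomial(2, p).

    With ``sibling_pairs`` the sample consists of n/2 full-sib pairs drawn from
    shared parental haplotypes (independent transmissions per SNP; no LD), to
    mimic a mixed pedigree/unrelated design.
    """
    if n < 2 or M < 1:
        raise ValueError("need n >= 2 samples and M >= 1 SNPs")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=M)
    if sibling_pairs:
        if n % 2:
            raise ValueError("sibling_pairs requires an even sample size")
        npairs = n // 2
        hap_f = rng.binomial(1, p, size=(npairs, 2, M))
        hap_m = rng.binomial(1, p, size=(npairs, 2, M))
        sibs = []
        for _ in range(2):
            cf = rng.integers(0, 2, size=(npairs, 1, M))
            cm = rng.integers(0, 2, size=(npairs, 1, M))
            sibs.append(
                np.take_along_axis(hap_f, cf, axis=1)[:, 0, :]
                + np.take_along_axis(hap_m, cm, axis=1)[:, 0, :]
            )
        dosages = np.empty((n, M))
        dosages[0::2] = sibs[0]
        dosages[1::2] = sibs[1]
        dosages = dosages.astype(float)
    else:
        dosages = rng.binomial(2, p, size=(n, M)).astype(float)
    obs_maf = np.array(
        [min(f, 1 - f) for f in dosages.mean(axis=0) / 2.0]
    )
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:06d}" for j in range(M)],
            "chromosome": (np.arange(M) % N_AUTOSOMES) + 1,
            "position": (np.arange(M) // N_AUTOSOMES + 1) * 1000,
            "a1": ["A"] * M,
            "a2": ["B"] * M,
            "maf": obs_maf,
            "p_drawn": p,
        }
    )
    sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages=dosages, snp_meta=snp_meta, sample_ids=sample_ids)


def _standardized(G: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    X = G.dosages[:, cols]
    p = np.nanmean(X, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic causal SNP; widen maf_range or resample")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z[np.isnan(Z)] = 0.0
    return Z


def _scale_to_variance(v: np.ndarray, target: float) -> np.ndarray:
    """Rescale so the sample variance (ddof=1) equals ``target`` exactly."""
    if target == 0.0:
        return np.zeros_like(v)
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate vector cannot be scaled to positive variance")
    return v * np.sqrt(target) / sd


def simulate_expression_probe(
    G: GenotypeMatrix,
    sex: Sequence[str],
    config: SimulationConfig,
    probe_seed=0,
) -> tuple[np.ndarray, dict]:
    """One probe's expression vector plus its generative truth record.

    Male and female causal effects share the causal set and are drawn with
    correlation ``rg_true`` (exactly equal vectors at rg_true = 1).  Genetic
    values and residuals are rescaled within sex so the realized heritability
    matches the target exactly.
    """
    sex = np.asarray(sex, dtype=object)
    if len(sex) != G.n_samples:
        raise ValueError("sex labels must align with genotypes")
    rng = _rng(probe_seed)
    # the genotype panel may have fewer SNPs than the config nominally asked
    # for (e.g. after QC); the causal set can never exceed what is there
    n_causal = min(config.effective_n_causal, G.n_snps)
    causal = np.sort(rng.choice(G.n_snps, size=n_causal, replace=False))
    Z = _standardized(G, causal)

    rg = config.rg_true
    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    u_m = z1
    u_f = rg * z1 + np.sqrt(max(0.0, 1.0 - rg * rg)) * z2

    male = sex == "male"
    female = sex == "female"
    g_m_all = Z @ u_m
    g_f_all = Z @ u_f
    g = np.zeros(G.n_samples)
    e = rng.standard_normal(G.n_samples)
    # scaling is around each group's own mean (ddof=1), so between-sex mean
    # noise survives and the null of the dimorphism test stays calibrated
    for mask, h2 in ((male, config.h2_male), (female, config.h2_female)):
        g[mask] = _scale_to_variance(g_m_all[mask] if mask is male else g_f_all[mask], h2)
        e[mask] = _scale_to_variance(e[mask], 1.0 - h2)
    y = g + e + config.sex_effect * female.astype(float)

    rg_realized = (
        float(np.corrcoef(u_m, u_f)[0, 1]) if n_causal > 1 and abs(rg) != 1.0 else rg
    )
    truth = {
        "h2_male": config.h2_male,
        "h2_female": config.h2_female,
        "rg_true": rg,
        "rg_effects_realized": rg_realized,
        "sex_effect": config.sex_effect,
        "n_causal": n_causal,
        "causal_idx": causal,
        "g_male": g[male],
        "g_female": g[female],
    }
    return y, truth


def _dirichlet_cells(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(_CELL_DIRICHLET, size=n) * _CELL_TOTAL


def simulate_panel(
    config: SimulationConfig,
    *,
    low_h2_fraction: float = 0.0,
    low_h2_value: float = 0.05,
    dimorphic_fraction: float = 1.0,
    with_cells: bool = False,
    cell_effects: Sequence[float] | None = None,
) -> tuple[GenotypeMatrix, ExpressionPanel, pd.DataFrame]:
    """A full study: genotypes, an expression panel and its truth table.

    A leading fraction of probes can be generated with heritability
    ``low_h2_value`` (both sexes) to exercise the downstream heritability
    filter, and the planted mean sex difference is applied only to the first
    ``dimorphic_fraction`` of the remaining probes.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_probes + 2)
    G = simulate_genotypes(
        config.n_samples, config.n_snps, config.maf_range,
        seed=np.random.default_rng(children[0]),
    )
    sex = np.array(
        ["male"] * config.n_males + ["female"] * config.n_females, dtype=object
    )

    n_low = int(round(low_h2_fraction * config.n_probes))
    intensities = np.empty((config.n_samples, config.n_probes))
    rows = []
    for k in range(config.n_probes):
        pc = config
        if k < n_low:
            pc = replace(pc, h2_male=low_h2_value, h2_female=low_h2_value)
        planted = k >= n_low and (k - n_low) < dimorphic_fraction * (
            config.n_probes - n_low
        )
        if not planted:
            pc = replace(pc, sex_effect=0.0)
        y, truth = simulate_expression_probe(
            G, sex, pc, probe_seed=np.random.default_rng(children[k + 1])
        )
        intensities[:, k] = y
        rows.append(
            {
                "probe_id": f"probe{k + 1:05d}",
                "h2_male": truth["h2_male"],
                "h2_female": truth["h2_female"],
                "rg_true": truth["rg_true"],
                "rg_effects_realized": truth["rg_effects_realized"],
                "sex_effect": truth["sex_effect"],
                "n_causal": truth["n_causal"],
            }
        )
    truth_df = pd.DataFrame(rows)

    rng_meta = np.random.default_rng(children[-1])
    probe_meta = pd.DataFrame(
        {
            "probe_id": truth_df["probe_id"],
            "chromosome": rng_meta.integers(1, N_AUTOSOMES + 1, config.n_probes).astype(str),
            "position": np.arange(1, config.n_probes + 1) * 5000,
            "gene_symbol": [f"GENE{k + 1:05d}" for k in range(config.n_probes)],
        }
    )
    sample_meta = pd.DataFrame(
        {"sample_id": G.sample_ids, "sex": sex, "cohort": "sim"}
    )
    if with_cells or cell_effects is not None:
        cells = _dirichlet_cells(rng_meta, config.n_samples)
        for i, ct in enumerate(CELL_TYPES):
            sample_meta[ct] = cells[:, i]
        if cell_effects is not None:
            eff = np.asarray(cell_effects, dtype=float)
            if eff.shape != (len(CELL_TYPES),):
                raise ValueError("cell_effects must give one effect per cell type")
            intensities += (cells @ eff)[:, None]

    panel = ExpressionPanel(
        intensities=intensities, probe_meta=probe_meta, sample_meta=sample_meta
    )
    return G, panel, truth_df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_expression_tsv(panel: ExpressionPanel, path: str | Path) -> None:
    """Probes x samples TSV with a header row of sample ids."""
    df = pd.DataFrame(
        panel.intensities.T,
        index=panel.probe_meta["probe_id"].to_numpy(),
        columns=panel.sample_meta["sample_id"].to_numpy(),
    )
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(
    path: str | Path, sample_meta: pd.DataFrame, probe_meta: pd.DataFrame | None = None
) -> ExpressionPanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    order = sample_meta["sample_id"].to_numpy()
    df = df[order]
    if probe_meta is None:
        probe_meta = pd.DataFrame(
            {
                "probe_id": df.index.to_numpy(),
                "chromosome": "1",
                "position": np.arange(1, len(df) + 1),
                "gene_symbol": df.index.to_numpy(),
            }
        )
    return ExpressionPanel(
        intensities=df.to_numpy(dtype=float).T,
        probe_meta=probe_meta.reset_index(drop=True),
        sample_meta=sample_meta.reset_index(drop=True),
    )


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = {
        "n_males": config.n_males,
        "n_females": config.n_females,
        "n_snps": config.n_snps,
        "n_causal": config.n_causal,
        "maf_range": list(config.maf_range),
        "h2_male": config.h2_male,
        "h2_female": config.h2_female,
        "rg_true": config.rg_true,
        "sex_effect": config.sex_effect,
        "n_probes": config.n_probes,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
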