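# sexgencor

**Sex-specific genetic architecture of gene expression from SNP data.**

Do males and females share the same common-SNP genetic control of gene
expression?  `sexgencor` answers this per expression probe by treating male
and female expression as two traits measured on disjoint samples and
estimating their genetic correlation with bivariate GREML (genomic-
relatedness-matrix restricted maximum likelihood):

    r_G = cov(g_m, g_f) / sqrt(var(g_m) · var(g_f))

with the mixed-model covariance

    V = [ A_m σ²_gm + I σ²_em      A_mf σ_gmgf        ]
        [ A_mf' σ_gmgf             A_f σ²_gf + I σ²_ef ]

where A_m, A_f, A_mf are the sex blocks of the SNP-derived genomic
relatedness matrix.  The null hypothesis of identical genetic control,
r_G = 1, sits on the edge of the parameter space, so the likelihood-ratio
statistic is referred to a 50:50 mixture of a point mass at 0 and χ²₁ —
under the null, half of all p-values are exactly 0.5.  The package also
provides a mixed-model Wald test for sexually dimorphic mean expression
(β̂ = female − male difference, (β̂/SE)² ~ χ²₁), genotype QC (MAF ≥ 0.01,
Hardy-Weinberg exact p ≥ 1e-6), GRM construction, expression normalization
(quantile + per-sex rank-inverse-normal), probe filters (sex-chromosome
cross-hybridisation, heritability > 10%), panel summaries (Bonferroni,
genomic-control λ, QQ coordinates, top tables) — and a synthetic-data
generator with known truth, so the whole pipeline is testable end to end
without any external data.

Intended users: statistical geneticists and eQTL analysts who want a tested,
reusable implementation of the sex-stratified bivariate GREML design, or a
simulation bench for boundary likelihood-ratio calibration.

## Worked example

```python
import numpy as np
from sexgencor import (SimulationConfig, simulate_panel, filter_snps,
                       compute_grm, rank_inverse_normal, rg_scan,
                       summarize_panel)

cfg = SimulationConfig(n_males=200, n_females=200, n_snps=500,
                       maf_range=(0.05, 0.5), h2_male=0.5, h2_female=0.5,
                       rg_true=1.0, n_probes=40, seed=1)
G, panel, truth = simulate_panel(cfg)
G_qc, _ = filter_snps(G)                       # MAF >= 0.01, HWE p >= 1e-6
grm = compute_grm(G_qc)
sex = panel.sample_meta["sex"].to_numpy()
Y = np.column_stack([rank_inverse_normal(panel.intensities[:, k], groups=sex)
                     for k in range(cfg.n_probes)])
fits, tests = rg_scan(Y, panel.probe_meta["probe_id"], sex, grm)
s = summarize_panel(fits, tests)
print(f"median rG = {s.median_rg:.3f}")
print(f"fraction of LRT statistics at 0 = "
      f"{np.mean([t.lrt == 0 for t in tests]):.2f}")
print(f"lambda_GC = {s.lambda_gc:.2f}")
```

Output:

```
median rG = 1.000
fraction of LRT statistics at 0 = 0.55
lambda_GC = 0.67
```

All 40 probes were simulated with fully shared genetic control (true
r_G = 1), and the scan reproduces the boundary behaviour of the test: the
constrained estimates pile up at 1 (median 1.00) and roughly half of the
likelihood-ratio statistics land exactly on the zero boundary, where their
p-values are exactly 0.5 (the QQ-plot plateau).  At this small scale the
fraction sits a few points above one half — the point-mass weight is an
asymptotic result, and with 500 SNPs on 400 people the variance components
are estimated with sizeable error (see docs/methods.md) — and λ_GC computed
from only 40 p-values is correspondingly noisy.

The same pipeline is available from the shell:

```sh
sexgencor run-all --config study.yaml --seed 1 --out results/
```

which chains simulate → SNP QC/GRM → preprocessing → dimorphism scan →
bivariate r_G scan → panel summary, writing TSV/JSON at each stage.

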