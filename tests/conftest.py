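"""Shared fixtures: small simulated studies and the brute-force REML oracle."""

from __future__ import annotations

import numpy as np
import pytest

from sexgencor.geno import compute_grm, filter_snps
from sexgencor.simdata import SimulationConfig, simulate_genotypes


def make_study(n_males, n_females, n_snps, maf_range=(0.05, 0.5), seed=11):
    """Genotypes, sex labels and GRM for a two-sex sample."""
    G = simulate_genotypes(n_males + n_females, n_snps, maf_range, seed=seed)
    G, _ = filter_snps(G, maf_min=1e-9, hwe_min=0.0)  # drop monomorphic draws
    sex = np.array(["male"] * n_males + ["female"] * n_females, dtype=object)
    grm = compute_grm(G)
    return G, sex, grm


@pytest.fixture(scope="session")
def small_study():
    """200 + 200 samples, 300 SNPs: big enough for stable bivariate fits."""
    return make_study(200, 200, 300, seed=11)


@pytest.fixture(scope="session")
def tiny_study():
    """10 + 10 samples, 40 SNPs: the brute-force oracle scale."""
    return make_study(10, 10, 40, maf_range=(0.1, 0.5), seed=5)


def grid_search_loglik(y, X, components, step=0.05, vmax=1.2, band=(0.55, 1.45),
                       batch=20000):
    """Brute-force REML oracle: max log-likelihood over a dense parameter grid.

    Evaluates the restricted likelihood at every grid point of the five
    variance components (step ``step`` on the unit-variance scale, per-sex
    total variance within ``band``, covariance within the positive-definite
    bound), entirely independently of the iterative fitter.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    vals = np.arange(step, vmax + 1e-9, step)
    # per-sex (var_g, var_e) pairs within the total-variance band
    a, b = np.meshgrid(vals, vals, indexing="ij")
    keep = (a + b >= band[0]) & (a + b <= band[1])
    pairs = np.column_stack([a[keep], b[keep]])
    cov_vals = np.arange(-vmax, vmax + 1e-9, step)

    # full cross of male pairs x female pairs x admissible covariances
    pm = np.repeat(pairs, len(pairs), axis=0)
    pf = np.tile(pairs, (len(pairs), 1))
    bound = np.sqrt(pm[:, 0] * pf[:, 0])
    thetas = []
    for c in cov_vals:
        ok = np.abs(c) <= bound
        t = np.empty((ok.sum(), 5))
        t[:, 0] = pm[ok, 0]
        t[:, 1] = pf[ok, 0]
        t[:, 2] = c
        t[:, 3] = pm[ok, 1]
        t[:, 4] = pf[ok, 1]
        thetas.append(t)
    thetas = np.concatenate(thetas)

    K = np.stack([np.asarray(c, float) for c in components])
    XY = np.column_stack([X, y])
    best = -np.inf
    for i in range(0, len(thetas), batch):
        th = thetas[i : i + batch]
        Vb = np.einsum("bk,kij->bij", th, K)
        sign, logdetV = np.linalg.slogdet(Vb)
        sol = np.linalg.solve(Vb, np.broadcast_to(XY, (len(th), n, p + 1)))
        ViX = sol[:, :, :p]
        Viy = sol[:, :, p]
        XtViX = np.einsum("ij,bjk->bik", X.T, ViX)
        s2, logdetX = np.linalg.slogdet(XtViX)
        XtViy = np.einsum("ij,bj->bi", X.T, Viy)
        beta = np.linalg.solve(XtViX, XtViy[:, :, None])[:, :, 0]
        yPy = Viy @ y - np.einsum("bi,bi->b", XtViy, beta)
        ll = -0.5 * (logdetV + logdetX + yPy)
        ll[(sign <= 0) | (s2 <= 0)] = -np.inf
        best = max(best, float(ll.max()))
    return best
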