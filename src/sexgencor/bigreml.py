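"""Bivariate GREML: sex-specific genetic variances, the cross-sex genetic
covariance, and the boundary likelihood-ratio test against r_G = 1.

Male and female expression of the same probe are treated as two traits
measured on disjoint samples.  With samples ordered arbitrarily and ``A`` the
SNP-derived relatedness matrix, the phenotypic covariance is

    V = sg_m * B_m + sg_f * B_f + c * B_mf + se_m * D_m + se_f * D_f

where B_m / B_f are A masked to the male / female blocks, B_mf is A masked to
the cross blocks, and D_m / D_f are the sex-indicator diagonals.  The genetic
correlation is r_G = c / sqrt(sg_m * sg_f) and the per-sex heritability is
h2_s = sg_s / (sg_s + se_s).

Estimation is restricted maximum likelihood by average-information updates
with EM-REML warm-up and likelihood-guarded step halving.  Three modes:

* ``constrained`` — variances floored, |c| <= sqrt(sg_m * sg_f) by boundary
  projection (so |r_G| <= 1);
* ``unconstrained`` — parameters free apart from positive-definiteness of V,
  so r_G may leave [-1, 1] (the unbiased-estimate analysis);
* ``rg_fixed_1`` — the null for the boundary test: c tied to
  sqrt(sg_m * sg_f) via the parameterization (gamma_m, gamma_f, se_m, se_f)
  with sg_s = gamma_s**2 and c = gamma_m * gamma_f.

Because r_G = 1 sits on the edge of the constrained parameter space, the LRT
statistic is distributed under the null as a 50:50 mixture of a point mass at
zero and chi-square with 1 df; ``mixture_pvalue`` implements that reference
distribution (and plain chi-square(1) for the unconstrained analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg
from scipy.linalg import lapack
from scipy.stats import chi2

from .geno import GRMPartition, normalize_sex

__all__ = [
    "VarianceComponents",
    "GremlFit",
    "RgTestResult",
    "fit_bivariate",
    "fit_univariate",
    "genetic_correlation",
    "heritability",
    "lrt_rg_equal_one",
    "mixture_pvalue",
    "adjust_cell_counts",
    "RemlResult",
    "reml_optimize",
    "LinearVarianceModel",
    "RgFixedOneModel",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
N_EM_WARMUP = 3
VAR_FLOOR_FRAC = 1e-6
LRT_ZERO_TOL = 1e-4
BOUNDARY_TOL = 1e-8


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    var_g_male: float
    var_g_female: float
    cov_g: float
    var_e_male: float
    var_e_female: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.var_g_male, self.var_g_female, self.cov_g,
             self.var_e_male, self.var_e_female]
        )


@dataclass
class GremlFit:
    probe_id: str
    vc: VarianceComponents
    rg: float
    rg_se: float
    h2_male: float
    h2_female: float
    loglik: float
    converged: bool
    n_iterations: int
    mode: str
    rg_na_reason: str | None = None
    beta: np.ndarray | None = None
    ll_history: list = field(default_factory=list)

    @property
    def at_boundary(self) -> bool:
        return (
            self.mode == "constrained"
            and np.isfinite(self.rg)
            and abs(self.rg) >= 1.0 - BOUNDARY_TOL
        )


@dataclass
class RgTestResult:
    probe_id: str
    lrt: float
    p: float
    significant_bonferroni: bool = False


@dataclass
class RemlResult:
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    beta_cov: np.ndarray
    ai: np.ndarray
    ll_history: list


# ---------------------------------------------------------------------------
# variance models
# ---------------------------------------------------------------------------

class LinearVarianceModel:
    """V(theta) = sum_k theta_k K_k with constant derivative matrices."""

    linear = True

    def __init__(self, components: Sequence[np.ndarray]):
        self.components = [np.asarray(K, dtype=float) for K in components]

    def V(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros_like(self.components[0])
        for t, K in zip(theta, self.components):
            V += t * K
        return V

    def dV(self, theta: np.ndarray) -> list[np.ndarray]:
        return self.components


class RgFixedOneModel:
    """Null model with the genetic covariance tied to sqrt(sg_m * sg_f).

    theta = (gamma_m, gamma_f, se_m, se_f); sg_s = gamma_s**2,
    c = sign * gamma_m * gamma_f, so r_G = sign identically.  The same
    parameterization with sign = -1 traverses the r_G = -1 boundary.
    """

    linear = False

    def __init__(self, B_m, B_f, B_mf, D_m, D_f, sign: float = 1.0):
        self.B_m, self.B_f, self.B_mf = B_m, B_f, B_mf
        self.D_m, self.D_f = D_m, D_f
        self.sign = sign

    def V(self, theta: np.ndarray) -> np.ndarray:
        gm, gf, em, ef = theta
        return (
            gm * gm * self.B_m + gf * gf * self.B_f
            + self.sign * gm * gf * self.B_mf
            + em * self.D_m + ef * self.D_f
        )

    def dV(self, theta: np.ndarray) -> list[np.ndarray]:
        gm, gf, _, _ = theta
        return [
            2.0 * gm * self.B_m + self.sign * gf * self.B_mf,
            2.0 * gf * self.B_f + self.sign * gm * self.B_mf,
            self.D_m,
            self.D_f,
        ]


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _chol_inv_logdet(V: np.ndarray):
    L, info = lapack.dpotrf(V, lower=1)
    if info != 0:
        return None
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    Vi, info = lapack.dpotri(L, lower=1)
    if info != 0:
        return None
    Vi = np.tril(Vi) + np.tril(Vi, -1).T
    return Vi, logdet


def _loglik_only(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> float | None:
    """REML log-likelihood (constant dropped) via one Cholesky factorization."""
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetV = 2.0 * float(np.log(np.diag(cf[0])).sum())
    ViX = linalg.cho_solve(cf, X, check_finite=False)
    Viy = linalg.cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    yPy = float(y @ Viy - XtViy @ beta)
    return -0.5 * (logdetV + logdetX + yPy)


def _quantities(V, X, y, dVs):
    """Log-likelihood, score, average-information matrix and GLS solution."""
    r = _chol_inv_logdet(V)
    if r is None:
        return None
    Vi, logdetV = r
    W = Vi @ X
    XtViX = X.T @ W
    try:
        cf = linalg.cho_factor(XtViX)
    except linalg.LinAlgError:
        return None
    logdetX = 2.0 * float(np.log(np.diag(cf[0])).sum())
    XtViy = W.T @ y
    beta = linalg.cho_solve(cf, XtViy)
    P = Vi - W @ linalg.cho_solve(cf, W.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    S = np.column_stack([dV @ Py for dV in dVs])
    ySy = S.T @ Py  # y' P dV_k P y
    trPdV = np.array([float((P * dV).sum()) for dV in dVs])
    grad = 0.5 * (ySy - trPdV)
    T = P @ S
    AI = 0.5 * (S.T @ T)
    beta_cov = linalg.cho_solve(cf, np.eye(X.shape[1]))
    return {
        "ll": ll, "grad": grad, "AI": AI, "beta": beta,
        "beta_cov": beta_cov, "ySy": ySy, "trPdV": trPdV,
    }


def _solve_direction(AI: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """AI^-1 grad with a ridge fallback for (near-)singular AI."""
    try:
        d = np.linalg.solve(AI, grad)
        if np.isfinite(d).all():
            return d
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * max(1.0, float(np.trace(AI)) / len(grad))
    return np.linalg.lstsq(AI + ridge * np.eye(len(grad)), grad, rcond=None)[0]


def reml_optimize(
    y: np.ndarray,
    X: np.ndarray,
    model,
    theta0: Sequence[float],
    *,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_em: int = N_EM_WARMUP,
) -> RemlResult:
    """AI-REML with EM warm-up and likelihood-guarded step halving.

    ``project`` applies parameter constraints (floors, covariance boundary)
    after every proposed step.  The accepted log-likelihood sequence is
    non-decreasing by construction.
    """
    if project is None:
        project = lambda t: t
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    theta = project(np.asarray(theta0, dtype=float).copy())
    q = _quantities(model.V(theta), X, y, model.dV(theta))
    if q is None:
        raise RuntimeError("singular covariance at the starting values")
    ll_history = [q["ll"]]
    converged = False
    n_iter = 0

    def _attempt(delta, ll_ref):
        step = 1.0
        for k in range(30):
            cand = project(theta + step * delta)
            ll_new = _loglik_only(model.V(cand), X, y)
            if ll_new is not None and ll_new >= ll_ref - 1e-9 * max(1.0, abs(ll_ref)):
                return cand, ll_new, step
            step *= 0.5
        return None

    def _em_delta():
        return theta**2 * (q["ySy"] - q["trPdV"]) / n

    for it in range(1, max_iter + 1):
        n_iter = it
        use_em = model.linear and it <= n_em
        if use_em:
            accepted = _attempt(_em_delta(), q["ll"])
        else:
            delta = _solve_direction(q["AI"], q["grad"])
            accepted = _attempt(delta, q["ll"])
            # a full AI step is trusted outright; when halving (or a rejected
            # step) signals that a constraint blocked the joint direction,
            # also try the Newton step with blocked components held and the
            # AI system reduced, and an EM step, keeping the best
            if accepted is None or accepted[2] < 1.0:
                alternates = []
                trial = project(theta + delta)
                blocked = ~np.isclose(trial, theta + delta, rtol=1e-12, atol=1e-15)
                if blocked.any() and not blocked.all():
                    free = ~blocked
                    delta2 = np.zeros_like(delta)
                    delta2[free] = _solve_direction(
                        q["AI"][np.ix_(free, free)], q["grad"][free]
                    )
                    alternates.append(delta2)
                if model.linear:
                    alternates.append(_em_delta())
                for d in alternates:
                    got = _attempt(d, q["ll"])
                    if got is not None and (accepted is None or got[1] > accepted[1]):
                        accepted = got
        if accepted is None:
            # no admissible ascent left along any direction we know
            converged = len(ll_history) > 1 and (
                abs(ll_history[-1] - ll_history[-2])
                < np.sqrt(tol) * max(1.0, abs(ll_history[-1]))
            )
            break
        theta, ll_new, _ = accepted
        q_new = _quantities(model.V(theta), X, y, model.dV(theta))
        if q_new is None:  # pragma: no cover - guarded by _loglik_only
            break
        ll_history.append(q_new["ll"])
        if abs(q_new["ll"] - q["ll"]) < tol * max(1.0, abs(q_new["ll"])):
            q = q_new
            converged = True
            break
        q = q_new
    return RemlResult(
        theta=theta,
        loglik=q["ll"],
        converged=converged,
        n_iter=n_iter,
        beta=q["beta"],
        beta_cov=q["beta_cov"],
        ai=q["AI"],
        ll_history=ll_history,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def genetic_correlation(vc: VarianceComponents) -> float:
    """r_G = cov(g_m, g_f) / sqrt(var(g_m) var(g_f))."""
    if vc.var_g_male <= 0.0 or vc.var_g_female <= 0.0:
        raise ValueError("genetic variances must be positive")
    return float(vc.cov_g / np.sqrt(vc.var_g_male * vc.var_g_female))


def heritability(vc: VarianceComponents, sex: str) -> float:
    """Per-sex h2 = var_g / (var_g + var_e)."""
    sex = normalize_sex([sex])[0]
    vg = vc.var_g_male if sex == "male" else vc.var_g_female
    ve = vc.var_e_male if sex == "male" else vc.var_e_female
    total = vg + ve
    if total <= 0.0:
        raise ValueError("total variance must be positive")
    return float(vg / total)


def _rg_se_delta(theta: np.ndarray, ai: np.ndarray) -> float:
    """Delta-method SE of r_G from the inverse average-information matrix."""
    vgm, vgf, c = theta[0], theta[1], theta[2]
    if vgm <= 0 or vgf <= 0:
        return float("nan")
    r = c / np.sqrt(vgm * vgf)
    J = np.zeros(len(theta))
    J[0] = -r / (2.0 * vgm)
    J[1] = -r / (2.0 * vgf)
    J[2] = 1.0 / np.sqrt(vgm * vgf)
    cov = np.linalg.pinv(ai)
    var = float(J @ cov @ J)
    return float(np.sqrt(var)) if var > 0 else float("nan")


def mixture_pvalue(lrt: float, null: str = "mixture") -> float:
    """P-value of the boundary LRT.

    ``mixture``: 50:50 mix of a point mass at 0 and chi-square(1): p = 0.5 at
    lrt = 0 and 0.5 * S_chi2_1(lrt) above it.  ``chisq1``: plain chi-square(1)
    survival (the unconstrained analysis).
    """
    if lrt < 0:
        raise ValueError("likelihood-ratio statistic must be non-negative")
    if null == "chisq1":
        return float(chi2.sf(lrt, df=1))
    if null != "mixture":
        raise ValueError(f"unknown null: {null!r}")
    if lrt == 0.0:
        return 0.5
    return float(0.5 * chi2.sf(lrt, df=1))


# ---------------------------------------------------------------------------
# model construction and fitting
# ---------------------------------------------------------------------------

def _design_matrix(
    female: np.ndarray, covariates: np.ndarray | None, sex_specific: bool
) -> np.ndarray:
    male = ~female
    base = [male.astype(float), female.astype(float)]
    extra = []
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(female):
            raise ValueError("covariate rows must align with samples")
        for j in range(C.shape[1]):
            if sex_specific:
                extra.append(C[:, j] * male)
                extra.append(C[:, j] * female)
            else:
                extra.append(C[:, j])
    X = np.column_stack(base)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    # covariate columns collinear with what is already present carry no
    # information (e.g. constant cell proportions vs the sex means) and are
    # dropped rather than breaking the fit
    for col in extra:
        cand = np.column_stack([X, col])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            X = cand
    return X


def _sex_masks(sex, n: int) -> tuple[np.ndarray, np.ndarray]:
    labels = normalize_sex(sex)
    if len(labels) != n:
        raise ValueError("sex labels must align with samples")
    female = labels == "female"
    return ~female, female


def _bivariate_components(A: np.ndarray, male: np.ndarray, female: np.ndarray):
    m = male.astype(float)
    f = female.astype(float)
    B_m = A * np.outer(m, m)
    B_f = A * np.outer(f, f)
    B_mf = A * (np.outer(m, f) + np.outer(f, m))
    D_m = np.diag(m)
    D_f = np.diag(f)
    return B_m, B_f, B_mf, D_m, D_f


def fit_bivariate(
    y: np.ndarray,
    sex,
    grm: GRMPartition,
    covariates: np.ndarray | None = None,
    mode: str = "constrained",
    probe_id: str = "probe",
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> GremlFit:
    """Bivariate REML fit of one probe; see the module docstring for modes.

    ``y`` and ``sex`` must be aligned with ``grm.ids``.  Covariates (e.g. cell
    proportions) receive sex-specific fixed effects, matching the two-trait
    formulation.
    """
    if mode not in ("constrained", "unconstrained", "rg_fixed_1"):
        raise ValueError(f"unknown mode: {mode!r}")
    y = np.asarray(y, dtype=float)
    n = grm.n_samples
    if len(y) != n:
        raise ValueError("phenotype must align with the GRM")
    male, female = _sex_masks(sex, n)
    if male.sum() < 10 or female.sum() < 10:
        raise ValueError("need at least 10 samples of each sex")
    X = _design_matrix(female, covariates, sex_specific=True)
    B_m, B_f, B_mf, D_m, D_f = _bivariate_components(grm.values, male, female)

    var_m = float(y[male].var(ddof=1))
    var_f = float(y[female].var(ddof=1))
    floor = VAR_FLOOR_FRAC * max(var_m, var_f)

    if mode == "rg_fixed_1":
        model = RgFixedOneModel(B_m, B_f, B_mf, D_m, D_f)
        theta0 = [np.sqrt(0.5 * var_m), np.sqrt(0.5 * var_f),
                  0.5 * var_m, 0.5 * var_f]

        def project(t):
            t = t.copy()
            t[:2] = np.maximum(t[:2], 0.0)
            t[2:] = np.maximum(t[2:], floor)
            return t

        res = reml_optimize(y, X, model, theta0, project=project,
                            max_iter=max_iter, tol=tol, n_em=0)
        gm, gf, em, ef = res.theta
        vc = VarianceComponents(gm * gm, gf * gf, gm * gf, em, ef)
        rg = 1.0
        rg_se = 0.0
    else:
        model = LinearVarianceModel([B_m, B_f, B_mf, D_m, D_f])
        theta0 = [0.5 * var_m, 0.5 * var_f,
                  0.25 * np.sqrt(0.25 * var_m * var_f), 0.5 * var_m, 0.5 * var_f]
        if mode == "constrained":
            def project(t):
                t = t.copy()
                t[[0, 1, 3, 4]] = np.maximum(t[[0, 1, 3, 4]], floor)
                bound = np.sqrt(t[0] * t[1])
                t[2] = np.clip(t[2], -bound, bound)
                return t
        else:
            project = None
        res = reml_optimize(y, X, model, theta0, project=project,
                            max_iter=max_iter, tol=tol)
        if mode == "constrained":
            # A projected fit can stall on (or in the corner wedge near) the
            # |r_G| = 1 boundary below the true boundary maximum.  The
            # constrained maximum on the boundary equals the tied 4-parameter
            # model's maximum, which traverses the curved surface freely, so
            # refit along the boundary and restart the 5-parameter search from
            # that point; keep the best (equal when the optimum is on the
            # boundary).
            bound = np.sqrt(res.theta[0] * res.theta[1])
            vg_floored = (res.theta[0] <= 2.0 * floor) or (res.theta[1] <= 2.0 * floor)
            near_boundary = abs(res.theta[2]) >= 0.9 * bound or vg_floored
            if near_boundary or not res.converged:
                signs = [1.0 if res.theta[2] >= 0 else -1.0]
                if vg_floored:  # covariance sign uninformative at the corner
                    signs.append(-signs[0])

                def projectB(t):
                    t = t.copy()
                    t[:2] = np.maximum(t[:2], 0.0)
                    t[2:] = np.maximum(t[2:], floor)
                    return t

                for sign in signs:
                    modelB = RgFixedOneModel(B_m, B_f, B_mf, D_m, D_f, sign=sign)
                    resB = reml_optimize(
                        y, X, modelB,
                        [np.sqrt(0.5 * var_m), np.sqrt(0.5 * var_f),
                         0.5 * var_m, 0.5 * var_f],
                        project=projectB, max_iter=max_iter, tol=tol, n_em=0,
                    )
                    gm, gf = resB.theta[0], resB.theta[1]
                    theta_b = np.array(
                        [gm * gm, gf * gf, sign * gm * gf,
                         resB.theta[2], resB.theta[3]]
                    )
                    res2 = reml_optimize(y, X, model, theta_b, project=project,
                                         max_iter=max_iter, tol=tol, n_em=0)
                    if res2.loglik > res.loglik:
                        res = res2
        vc = VarianceComponents(*res.theta)
        rg = float("nan")
        rg_se = float("nan")

    fit = GremlFit(
        probe_id=probe_id,
        vc=vc,
        rg=rg,
        rg_se=rg_se,
        h2_male=float("nan"),
        h2_female=float("nan"),
        loglik=res.loglik,
        converged=res.converged,
        n_iterations=res.n_iter,
        mode=mode,
        beta=res.beta,
        ll_history=res.ll_history,
    )
    # NA contract: a genetic correlation is numerically unidentifiable when
    # either genetic variance estimate is at the floor or a negligible share
    # (< 1%) of that sex's phenotypic variance
    at_floor = (
        vc.var_g_male <= max(floor * (1 + 1e-9), 0.01 * var_m)
        or vc.var_g_female <= max(floor * (1 + 1e-9), 0.01 * var_f)
    )
    if mode != "rg_fixed_1":
        if at_floor or vc.var_g_male <= 0 or vc.var_g_female <= 0:
            fit.rg = float("nan")
            fit.rg_na_reason = "no genetic variance"
        else:
            fit.rg = genetic_correlation(vc)
            fit.rg_se = _rg_se_delta(res.theta, res.ai)
    total_m = vc.var_g_male + vc.var_e_male
    total_f = vc.var_g_female + vc.var_e_female
    fit.h2_male = vc.var_g_male / total_m if total_m > 0 else float("nan")
    fit.h2_female = vc.var_g_female / total_f if total_f > 0 else float("nan")
    return fit


def fit_univariate(
    y: np.ndarray,
    grm: GRMPartition,
    X: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> RemlResult:
    """Univariate REML (V = A*vg + I*ve) with the shared AI-REML engine."""
    y = np.asarray(y, dtype=float)
    var_p = float(y.var(ddof=1))
    floor = VAR_FLOOR_FRAC * var_p
    A = grm.values
    has_genetic = bool(np.any(A))
    model = LinearVarianceModel([A, np.eye(len(y))])

    def project(t):
        t = t.copy()
        if not has_genetic:
            t[0] = 0.0
        else:
            t[0] = max(t[0], floor)
        t[1] = max(t[1], floor)
        return t

    theta0 = [0.5 * var_p if has_genetic else 0.0, 0.5 * var_p]
    return reml_optimize(y, X, model, theta0, project=project,
                         max_iter=max_iter, tol=tol)


def lrt_rg_equal_one(fit_free: GremlFit, fit_fixed: GremlFit) -> RgTestResult:
    """Boundary LRT of H0: r_G = 1 from a constrained and a tied-null fit.

    A constrained fit projected onto the r_G = +1 boundary shares its
    parameter space with the null, so its statistic is exactly zero; tiny
    positive values below the optimizer noise scale are clamped to zero.
    Non-converged fits yield an NA result.
    """
    if fit_free.probe_id != fit_fixed.probe_id:
        raise ValueError("fits must refer to the same probe")
    if fit_free.mode != "constrained" or fit_fixed.mode != "rg_fixed_1":
        raise ValueError("need a constrained fit and an rg_fixed_1 fit")
    if not (fit_free.converged and fit_fixed.converged):
        return RgTestResult(fit_free.probe_id, float("nan"), float("nan"))
    lrt = max(0.0, 2.0 * (fit_free.loglik - fit_fixed.loglik))
    if (np.isfinite(fit_free.rg) and fit_free.rg >= 1.0 - BOUNDARY_TOL) or (
        lrt < LRT_ZERO_TOL
    ):
        lrt = 0.0
    return RgTestResult(fit_free.probe_id, lrt, mixture_pvalue(lrt))


def h2_scan(
    Y: np.ndarray,
    probe_ids: Sequence[str],
    grm: GRMPartition,
    covariates: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Pooled-sample univariate SNP heritability per probe.

    These estimates feed the probe retention filter (heritability strictly
    above 10%).  Returns a frame with probe_id, var_g, var_e, h2, converged.
    """
    import pandas as pd

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = grm.n_samples
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        cols.extend(C[:, j] for j in range(C.shape[1]))
    X = np.column_stack(cols)
    rows = []
    for k, pid in enumerate(probe_ids):
        res = fit_univariate(Y[:, k], grm, X)
        vg, ve = float(res.theta[0]), float(res.theta[1])
        rows.append(
            {
                "probe_id": pid,
                "var_g": vg,
                "var_e": ve,
                "h2": vg / (vg + ve) if vg + ve > 0 else float("nan"),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def rg_scan(
    Y: np.ndarray,
    probe_ids: Sequence[str],
    sex,
    grm: GRMPartition,
    covariates: np.ndarray | None = None,
    mode: str = "constrained",
    with_null: bool = True,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[list[GremlFit], list[RgTestResult]]:
    """Per-probe bivariate fits (plus the tied r_G = 1 null and LRT) over a panel.

    ``Y`` is samples x probes aligned with ``grm.ids``.  In unconstrained mode
    the LRT is referred to plain chi-square(1).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    fits: list[GremlFit] = []
    tests: list[RgTestResult] = []
    for k, pid in enumerate(probe_ids):
        y = Y[:, k]
        fit = fit_bivariate(y, sex, grm, covariates=covariates, mode=mode,
                            probe_id=pid, max_iter=max_iter, tol=tol)
        fits.append(fit)
        if not with_null:
            continue
        fit0 = fit_bivariate(y, sex, grm, covariates=covariates,
                             mode="rg_fixed_1", probe_id=pid,
                             max_iter=max_iter, tol=tol)
        if mode == "constrained":
            tests.append(lrt_rg_equal_one(fit, fit0))
        else:
            if fit.converged and fit0.converged:
                lrt = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
                tests.append(
                    RgTestResult(pid, lrt, mixture_pvalue(lrt, null="chisq1"))
                )
            else:
                tests.append(RgTestResult(pid, float("nan"), float("nan")))
    return fits, tests


def adjust_cell_counts(
    y: np.ndarray,
    sex,
    grm: GRMPartition,
    cell_proportions: np.ndarray,
    mode: str = "constrained",
    **kwargs,
) -> GremlFit:
    """Bivariate fit with cell-count proportions as fixed-effect covariates.

    Proportions must lie in [0, 1] with row sums at most 1, one row per
    sample in GRM order.
    """
    C = np.atleast_2d(np.asarray(cell_proportions, dtype=float))
    if C.shape[0] != grm.n_samples:
        raise ValueError("cell proportions must align with the GRM samples")
    if np.any((C < 0.0) | (C > 1.0)):
        raise ValueError("cell proportions must lie in [0, 1]")
    if np.any(C.sum(axis=1) > 1.0 + 1e-9):
        raise ValueError("cell proportions must sum to at most 1")
    return fit_bivariate(y, sex, grm, covariates=C, mode=mode, **kwargs)
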