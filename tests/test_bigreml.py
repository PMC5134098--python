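"""Bivariate REML: derived quantities, the boundary LRT, optimizer quality
against the brute-force grid oracle, and cell-count adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexgencor.bigreml import (
    VarianceComponents,
    _bivariate_components,
    _design_matrix,
    adjust_cell_counts,
    fit_bivariate,
    genetic_correlation,
    h2_scan,
    heritability,
    lrt_rg_equal_one,
    mixture_pvalue,
    rg_scan,
)
from sexgencor.exprep import rank_inverse_normal
from sexgencor.simdata import SimulationConfig, simulate_expression_probe

from conftest import grid_search_loglik, make_study


class TestGeneticCorrelation:
    def test_simple_ratio(self):
        vc = VarianceComponents(1.0, 1.0, 0.5, 0.5, 0.5)
        assert genetic_correlation(vc) == pytest.approx(0.5)

    def test_perfect_correlation(self):
        vc = VarianceComponents(0.4, 0.9, np.sqrt(0.36), 0.5, 0.5)
        assert genetic_correlation(vc) == pytest.approx(1.0)

    def test_negative_boundary(self):
        vc = VarianceComponents(0.9, 0.1, -0.3, 0.5, 0.5)
        assert genetic_correlation(vc) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            genetic_correlation(VarianceComponents(0.0, 1.0, 0.0, 0.5, 0.5))


class TestHeritability:
    def test_half(self):
        vc = VarianceComponents(0.3, 0.2, 0.0, 0.3, 0.2)
        assert heritability(vc, "male") == pytest.approx(0.5)

    def test_zero_genetic(self):
        vc = VarianceComponents(0.0, 0.2, 0.0, 0.7, 0.2)
        assert heritability(vc, "male") == 0.0

    def test_unit_variance_scale(self):
        vc = VarianceComponents(0.68, 0.5, 0.0, 0.32, 0.5)
        assert heritability(vc, "male") == pytest.approx(0.68)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 1.0, 0.0, 0.0, 1.0), "male")


class TestMixturePvalue:
    def test_point_mass(self):
        assert mixture_pvalue(0.0) == 0.5

    def test_chi2_quantiles(self):
        assert mixture_pvalue(3.841) == pytest.approx(0.025, abs=2e-4)
        assert mixture_pvalue(6.635) == pytest.approx(0.005, abs=5e-5)

    def test_plain_chisq_option(self):
        assert mixture_pvalue(3.841, null="chisq1") == pytest.approx(0.05, abs=4e-4)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            mixture_pvalue(-0.1)

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert mixture_pvalue(hi) <= mixture_pvalue(lo)


@pytest.fixture(scope="module")
def null_fits(small_study):
    """Constrained + tied-null fits for probes simulated at rg_true = 1."""
    G, sex, grm = small_study
    cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                           h2_male=0.5, h2_female=0.5, rg_true=1.0)
    Y = []
    for k in range(12):
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=500 + k)
        Y.append(rank_inverse_normal(y, groups=sex))
    Y = np.column_stack(Y)
    fits, tests = rg_scan(Y, [f"p{k}" for k in range(12)], sex, grm)
    return fits, tests


class TestBoundaryBehaviour:
    def test_constrained_estimates_within_bounds(self, null_fits):
        fits, _ = null_fits
        for f in fits:
            if f.converged and np.isfinite(f.rg):
                assert abs(f.rg) <= 1.0 + 1e-9

    def test_boundary_likelihood_not_below_tied_null(self, small_study):
        G, sex, grm = small_study
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                               rg_true=1.0)
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=500)
        y = rank_inverse_normal(y, groups=sex)
        free = fit_bivariate(y, sex, grm, mode="constrained", probe_id="p")
        fixed = fit_bivariate(y, sex, grm, mode="rg_fixed_1", probe_id="p")
        assert free.loglik >= fixed.loglik - 1e-4

    def test_lrt_zero_iff_boundary(self, null_fits):
        fits, tests = null_fits
        for f, t in zip(fits, tests):
            if not f.converged:
                continue
            if f.at_boundary:
                assert t.lrt == 0.0
                assert t.p == 0.5
            else:
                assert t.p <= 0.5

    def test_nonconverged_gives_na(self, null_fits):
        fits, _ = null_fits
        bad = fits[0].__class__(**{**fits[0].__dict__})
        bad.converged = False
        fixed = fits[0].__class__(**{**fits[0].__dict__})
        fixed.mode = "rg_fixed_1"
        res = lrt_rg_equal_one(bad, fixed)
        assert np.isnan(res.lrt) and np.isnan(res.p)

    def test_em_then_ai_loglik_monotone(self, null_fits):
        fits, _ = null_fits
        for f in fits:
            hist = np.asarray(f.ll_history)
            # non-decreasing up to likelihood-recomputation noise
            assert np.all(np.diff(hist) >= -1e-6 * np.maximum(1.0, np.abs(hist[:-1])))


class TestModes:
    def test_no_genetic_signal_rg_na(self, small_study):
        G, sex, grm = small_study
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                               h2_male=0.0, h2_female=0.0)
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=77)
        fit = fit_bivariate(y, sex, grm, mode="constrained")
        assert np.isnan(fit.rg)
        assert fit.rg_na_reason == "no genetic variance"

    def test_rg_fixed_mode_pins_correlation(self, small_study):
        G, sex, grm = small_study
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300)
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=78)
        fit = fit_bivariate(y, sex, grm, mode="rg_fixed_1")
        assert fit.rg == 1.0
        assert fit.vc.cov_g == pytest.approx(
            np.sqrt(fit.vc.var_g_male * fit.vc.var_g_female), rel=1e-9
        )

    def test_unconstrained_can_leave_unit_interval(self, small_study):
        G, sex, grm = small_study
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                               h2_male=0.3, h2_female=0.3, rg_true=1.0)
        rgs = []
        for k in range(8):
            y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=900 + k)
            y = rank_inverse_normal(y, groups=sex)
            f = fit_bivariate(y, sex, grm, mode="unconstrained")
            if f.converged and np.isfinite(f.rg):
                rgs.append(f.rg)
        assert max(rgs) > 1.0  # sampling noise pushes past the boundary

    def test_too_few_per_sex_errors(self, small_study):
        G, sex, grm = small_study
        with pytest.raises(ValueError):
            fit_bivariate(np.zeros(grm.n_samples), ["male"] * grm.n_samples, grm)

    def test_unknown_mode_errors(self, small_study):
        _, sex, grm = small_study
        with pytest.raises(ValueError):
            fit_bivariate(np.zeros(grm.n_samples), sex, grm, mode="banana")


class TestGridOracle:
    """AI-REML must reach the dense-grid likelihood maximum on tiny data."""

    @pytest.mark.parametrize("inst", [0, 1])
    def test_fit_beats_grid(self, inst):
        G, sex, grm = make_study(10, 10, 40, maf_range=(0.1, 0.5), seed=30 + inst)
        cfg = SimulationConfig(n_males=10, n_females=10, n_snps=40,
                               h2_male=0.5, h2_female=0.5, rg_true=0.5)
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=40 + inst)
        y = rank_inverse_normal(y, groups=sex)
        fit = fit_bivariate(y, sex, grm, mode="constrained")
        female = sex == "female"
        comps = _bivariate_components(grm.values, ~female, female)
        X = _design_matrix(female, None, True)
        grid_best = grid_search_loglik(y, X, comps)
        assert fit.loglik >= grid_best - 1e-3


def test_h2_scan_recovers_pooled_heritability(small_study):
    """Univariate SNP h2 per probe tracks the simulated target."""
    G, sex, grm = small_study
    cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                           h2_male=0.6, h2_female=0.6, rg_true=1.0)
    Y = np.column_stack(
        [simulate_expression_probe(G, sex, cfg, probe_seed=700 + k)[0]
         for k in range(10)]
    )
    out = h2_scan(Y, [f"p{k}" for k in range(10)], grm)
    assert out["converged"].all()
    est = out["h2"][out["converged"]]
    assert abs(est.mean() - 0.6) < 0.15


class TestCellAdjustment:
    def test_constant_proportions_equal_unadjusted(self, small_study):
        G, sex, grm = small_study
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300)
        y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=55)
        cells = np.tile([0.6, 0.3, 0.1], (grm.n_samples, 1))
        plain = fit_bivariate(y, sex, grm, mode="constrained")
        adj = adjust_cell_counts(y, sex, grm, cells, mode="constrained")
        assert adj.loglik == pytest.approx(plain.loglik, abs=1e-6)
        assert adj.vc.var_g_male == pytest.approx(plain.vc.var_g_male, rel=1e-3)

    def test_planted_cell_effect_recovery_improves(self, small_study):
        G, sex, grm = small_study
        rng = np.random.default_rng(12)
        cells = rng.dirichlet([15, 8, 2], size=grm.n_samples)
        # interior truth: boundary sticking cannot mask a noisier fit
        cfg = SimulationConfig(n_males=200, n_females=200, n_snps=300,
                               h2_male=0.6, h2_female=0.6, rg_true=0.5)
        errs_adj, errs_plain = [], []
        for k in range(6):
            y, _ = simulate_expression_probe(G, sex, cfg, probe_seed=600 + k)
            # a monocyte effect large enough to swamp the genetic signal
            # unless it is modelled as a fixed effect
            y = y + cells @ np.array([0.0, 0.0, 30.0])
            f_adj = adjust_cell_counts(y, sex, grm, cells)
            f_plain = fit_bivariate(y, sex, grm, mode="constrained")
            if np.isfinite(f_adj.rg):
                errs_adj.append(abs(f_adj.rg - 0.5))
            if np.isfinite(f_plain.rg):
                errs_plain.append(abs(f_plain.rg - 0.5))
        assert np.mean(errs_adj) <= np.mean(errs_plain) + 1e-9

    def test_out_of_range_proportions_error(self, small_study):
        _, sex, grm = small_study
        bad = np.full((grm.n_samples, 3), 0.4)
        bad[0, 0] = 1.2
        with pytest.raises(ValueError):
            adjust_cell_counts(np.zeros(grm.n_samples), sex, grm, bad)
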