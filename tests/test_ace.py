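"""Variance-component threshold models: likelihood, fitting, AIC, bivariate rg."""

import numpy as np
import pytest
from scipy.special import ndtr

from conftest import expected_joint_tables, expected_univariate_tables, simulated_joint_tables
from twinmd._normal import joint_cell_probs, norm_ppf
from twinmd.ace import (
    JointPairTable,
    _biv_ll,
    aic_select,
    fit_bivariate,
    fit_univariate,
    joint_table_from_pairs,
    univariate_loglik,
)
from twinmd.simulate import CriterionParams, simulate_criterion_pairs
from twinmd.tetrachoric import PairTable, table_from_pairs


class TestUnivariateLoglik:
    def test_independence_factorizes_to_bernoulli(self):
        tabs = {
            "MZ": PairTable(30, 70, 70, 330, n_pairs_raw=250),
            "DZ": PairTable(20, 55, 55, 270, n_pairs_raw=200),
        }
        tau = 0.9
        ll = univariate_loglik({"VE": 1.0}, tau, tabs)
        # with a2 = c2 = 0 the pair likelihood is a product of margins
        p_pos = 1 - ndtr(tau)
        expected = 0.0
        for tab in tabs.values():
            n_pos = tab.loglik_scale * (2 * tab.n11 + tab.n10 + tab.n01)
            n_neg = tab.loglik_scale * (2 * tab.n00 + tab.n10 + tab.n01)
            expected += n_pos * np.log(p_pos) + n_neg * np.log(1 - p_pos)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_normalization_scale_invariant(self):
        tabs = expected_univariate_tables(0.4, 0.1, 0.2)
        a = univariate_loglik({"VA": 0.4, "VC": 0.1, "VE": 0.5}, 0.8, tabs)
        b = univariate_loglik({"VA": 4.0, "VC": 1.0, "VE": 5.0}, 0.8, tabs)
        assert a == pytest.approx(b, rel=1e-12)

    def test_truth_beats_perturbed_grid(self):
        # expected-count tables at (a2=0.5, c2=0, prevalence 0.5)
        tabs = expected_univariate_tables(0.5, 0.0, 0.5)
        ll_true = univariate_loglik({"VA": 0.5, "VE": 0.5}, 0.0, tabs)
        for a2 in np.arange(0.0, 1.01, 0.05):
            for c2 in np.arange(0.0, 1.01 - a2, 0.05):
                if abs(a2 - 0.5) < 1e-9 and c2 < 1e-9:
                    continue
                ll = univariate_loglik({"VA": a2, "VC": c2, "VE": 1 - a2 - c2}, 0.0, tabs)
                assert ll < ll_true

    def test_out_of_bounds_penalized_not_raised(self):
        tabs = expected_univariate_tables(0.5, 0.0, 0.5)
        assert univariate_loglik({"VA": 1.5, "VE": -0.5}, 0.0, tabs) < -1e11


class TestFitUnivariate:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [
            (0.50, 0.25, (0.50, 0.00, 0.50)),   # Falconer: a2 = 2(rMZ - rDZ)
            (0.35, 0.20, (0.30, 0.05, 0.65)),
            (0.30, 0.30, (0.00, 0.30, 0.70)),   # rMZ = rDZ: pure shared environment
            (0.00, 0.00, (0.00, 0.00, 1.00)),
        ],
    )
    def test_moment_inversion_on_expected_tables(self, r_mz, r_dz, expected):
        # generate via (a2, c2) implied by moment inversion, then refit
        a2, c2 = 2 * (r_mz - r_dz), 2 * r_dz - r_mz
        tabs = expected_univariate_tables(a2, c2, 0.15)
        fit = fit_univariate(tabs, "ACE", compute_ci=False)
        assert fit.a2 == pytest.approx(expected[0], abs=1e-4)
        assert fit.c2 == pytest.approx(expected[1], abs=1e-4)
        assert fit.e2 == pytest.approx(expected[2], abs=1e-4)
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-10)

    def test_threshold_recovered(self):
        tabs = expected_univariate_tables(0.3, 0.1, 0.10)
        fit = fit_univariate(tabs, "ACE", compute_ci=False)
        assert fit.threshold == pytest.approx(float(norm_ppf(0.9)), abs=1e-3)

    def test_submodels_and_k(self):
        tabs = expected_univariate_tables(0.4, 0.0, 0.2)
        ae = fit_univariate(tabs, "AE", compute_ci=False)
        ce = fit_univariate(tabs, "CE", compute_ci=False)
        e = fit_univariate(tabs, "E", compute_ci=False)
        assert ae.c2 == 0.0 and ae.k == 2
        assert ae.a2 == pytest.approx(0.4, abs=1e-4)
        assert ce.va == 0.0 and ce.k == 2
        assert e.k == 1 and e.e2 == 1.0
        for f in (ae, ce, e):
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.k)

    def test_profile_ci_brackets_estimate(self, rng):
        x1, x2 = simulate_criterion_pairs(0.45, 0.25, 2000, rng)
        y1, y2 = simulate_criterion_pairs(0.25, 0.25, 1500, rng)
        tabs = {"MZ": table_from_pairs(x1, x2), "DZ": table_from_pairs(y1, y2)}
        fit = fit_univariate(tabs, "ACE", compute_ci=True)
        for comp in ("a2", "c2", "e2"):
            lo, hi = fit.ci[comp]
            assert lo <= getattr(fit, comp) <= hi

    def test_unbounded_components_can_go_negative(self):
        # rDZ > rMZ/2 + a bit is fine, but rMZ < rDZ forces negative a2
        tabs = expected_univariate_tables(0.0, 0.25, 0.2)
        # overwrite MZ with a *lower* correlation table than DZ
        tabs["MZ"] = expected_univariate_tables(0.0, 0.10, 0.2)["MZ"]
        fit = fit_univariate(tabs, "ACE", compute_ci=False)
        assert fit.a2 < 0
        assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-10)

    def test_missing_zygosity_rejected(self):
        tabs = expected_univariate_tables(0.3, 0.0, 0.2)
        with pytest.raises(ValueError):
            fit_univariate({"MZ": tabs["MZ"]}, "ACE")


class TestAicSelect:
    class Dummy:
        def __init__(self, model, loglik, k):
            self.model, self.loglik, self.k = model, loglik, k
            self.aic = -2 * loglik + 2 * k

    def test_equal_loglik_prefers_fewer_params(self):
        ace = self.Dummy("ACE", -100.0, 3)
        ae = self.Dummy("AE", -100.0, 2)
        assert aic_select([ace, ae]).model == "AE"

    def test_single_fit_returned(self):
        f = self.Dummy("CE", -5.0, 2)
        assert aic_select([f]) is f

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aic_select([])

    def test_ordering_invariant_to_loglik_shift(self):
        fits = [self.Dummy(m, ll, k) for m, ll, k in
                [("ACE", -100.0, 3), ("AE", -100.9, 2), ("CE", -103.0, 2)]]
        shifted = [self.Dummy(f.model, f.loglik + 57.3, f.k) for f in fits]
        assert aic_select(fits).model == aic_select(shifted).model

    def test_pure_c_data_prefers_ce_over_ae(self, rng):
        # a2=0, c2=0.4: CE should win on AIC in the vast majority of replicates
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            x1, x2 = simulate_criterion_pairs(0.4, 0.3, 4000, rng)   # rMZ = c2
            y1, y2 = simulate_criterion_pairs(0.4, 0.3, 4000, rng)   # rDZ = c2
            tabs = {"MZ": table_from_pairs(x1, x2), "DZ": table_from_pairs(y1, y2)}
            ae = fit_univariate(tabs, "AE", compute_ci=False)
            ce = fit_univariate(tabs, "CE", compute_ci=False)
            if aic_select([ae, ce]).model == "CE":
                wins += 1
        assert wins / n_rep >= 0.9


class TestFitBivariate:
    def test_null_cross_structure_recovers_zero_rg(self):
        p = CriterionParams(0.31, 0.0, 0.10, 0.15, 0.0, 0.15, rg=0.0, rc=0.0, re=0.0)
        fit = fit_bivariate(expected_joint_tables(p), "AE", compute_ci=True)
        assert fit.rg == pytest.approx(0.0, abs=0.01)
        assert fit.rg_ci[0] < 0.0 < fit.rg_ci[1]
        assert fit.a2[0] == pytest.approx(0.31, abs=0.005)
        assert fit.a2[1] == pytest.approx(0.15, abs=0.005)

    def test_nonzero_rg_recovered_from_expected_tables(self):
        p = CriterionParams(0.31, 0.0, 0.10, 0.15, 0.0, 0.15, rg=0.31, rc=0.0, re=0.0)
        fit = fit_bivariate(expected_joint_tables(p), "AE", compute_ci=False)
        assert fit.rg == pytest.approx(0.31, abs=0.01)

    def test_duplicated_trait_rg_boundary(self, rng):
        x1, x2 = simulate_criterion_pairs(0.4, 0.3, 4000, rng)
        y1, y2 = simulate_criterion_pairs(0.2, 0.3, 4000, rng)
        tabs = {
            "MZ": joint_table_from_pairs(np.column_stack([x1, x1, x2, x2])),
            "DZ": joint_table_from_pairs(np.column_stack([y1, y1, y2, y2])),
        }
        fit = fit_bivariate(tabs, "AE", compute_ci=False)
        assert fit.rg == pytest.approx(1.0, abs=0.01)

    def test_duplicated_trait_likelihood_peaks_at_univariate_solution(self, rng):
        # near the degenerate boundary the likelihood prefers the shared
        # trait's univariate component value over perturbed values
        x1, x2 = simulate_criterion_pairs(0.4, 0.3, 4000, rng)
        y1, y2 = simulate_criterion_pairs(0.2, 0.3, 4000, rng)
        tabs = {
            "MZ": joint_table_from_pairs(np.column_stack([x1, x1, x2, x2])),
            "DZ": joint_table_from_pairs(np.column_stack([y1, y1, y2, y2])),
        }
        uni = fit_univariate(
            {"MZ": table_from_pairs(x1, x2), "DZ": table_from_pairs(y1, y2)},
            "AE", compute_ci=False,
        )
        tau = uni.threshold

        def ll_at(a2):
            return _biv_ll(
                {"A11": a2, "A22": a2, "A12": a2, "E12": 1 - 1e-6 - a2,
                 "tau_i": tau, "tau_o": tau},
                tabs, 24,
            )

        lls = {a2: ll_at(a2) for a2 in np.arange(0.25, 0.56, 0.05)}
        best_a2 = max(lls, key=lls.get)
        assert best_a2 == pytest.approx(uni.a2, abs=0.05)

    def test_zero_additive_variance_flags_rg_undefined(self):
        # a trait with no additive variance puts A11 on the zero boundary,
        # where the genetic-correlation ratio is meaningless
        W = np.eye(2)
        W[0, 1] = W[1, 0] = 0.1
        tau = np.array([0.5, 0.8])

        def tab(r_in, r_out):
            B = np.array([[r_in, 0.0], [0.0, r_out]])
            return JointPairTable(joint_cell_probs(W, B, tau) * 50_000, n_pairs_raw=50_000)

        fit = fit_bivariate(
            {"MZ": tab(0.0, 0.3), "DZ": tab(0.0, 0.15)}, "AE", compute_ci=False
        )
        assert fit.rg is None
        assert "undefined" in fit.note

    def test_ce_model_has_no_a(self):
        p = CriterionParams(0.0, 0.3, 0.2, 0.0, 0.2, 0.2, rc=0.5)
        fit = fit_bivariate(expected_joint_tables(p), "CE", compute_ci=False)
        assert fit.A is None and fit.rg is None
        assert fit.c2[0] == pytest.approx(0.3, abs=0.01)
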