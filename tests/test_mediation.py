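import numpy as np
import pandas as pd
import pytest

import medlmm
from medlmm.genotype import DegenerateInputError, standardize
from medlmm.mediation import (
    fit_mediation,
    indirect_permutation_test,
    mediator_scan,
    natural_effects,
)


def two_stage_ols(y, m, x):
    """Independent oracle: two separate ordinary regressions on the
    standardized inputs."""
    y, m, x = standardize(y), standardize(m), standardize(x)
    n = len(y)
    Xm = np.column_stack([np.ones(n), x])
    Xy = np.column_stack([np.ones(n), x, m])
    b_m = np.linalg.lstsq(Xm, m, rcond=None)[0]
    b_y = np.linalg.lstsq(Xy, y, rcond=None)[0]
    return b_m[1], b_y[1], b_y[2]  # beta1, beta2, theta1


@pytest.fixture(scope="module")
def unconfounded():
    rng = np.random.default_rng(77)
    n = 250
    x = (rng.random(n) < 0.4).astype(float)
    m = 0.4 * standardize(x) + rng.standard_normal(n)
    y = 0.25 * standardize(x) + 0.51 * m + rng.standard_normal(n)
    return y, m, x


class TestFitMediation:
    def test_matches_two_stage_ols_oracle(self, unconfounded):
        y, m, x = unconfounded
        fit = fit_mediation(y, m, x, k=None)
        b1, b2, t1 = two_stage_ols(y, m, x)
        assert fit.beta1 == pytest.approx(b1, abs=1e-8)
        assert fit.beta2 == pytest.approx(b2, abs=1e-8)
        assert fit.theta1 == pytest.approx(t1, abs=1e-8)
        assert fit.lambda1 == 0.0 and fit.lambda2 == 0.0 and not fit.adjusted

    def test_adjusted_fit_on_structured_panel(self, mediation_data):
        g, k, x, m, y, truth = mediation_data
        fit = fit_mediation(y, m, x, k)
        assert fit.adjusted
        assert fit.lambda1 >= 0 and fit.lambda2 >= 0
        # estimates land within 3 SEs of truth on a single dataset
        assert abs(fit.beta1 - truth.beta1) < 3 * fit.se_beta1
        assert abs(fit.theta1 - truth.theta1) < 3 * fit.se_theta1

    def test_null_theta_within_coverage(self):
        inside = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            x = standardize((rng.random(n) < 0.4).astype(float))
            m = 0.4 * x + rng.standard_normal(n)
            y = 0.25 * x + rng.standard_normal(n)  # theta1 = 0
            fit = fit_mediation(y, m, x, k=None)
            if abs(fit.theta1) <= 2 * fit.se_theta1:
                inside += 1
        assert inside >= 35  # ~95% nominal coverage, 40 draws

    def test_plugin_consistency_with_total_effect(self):
        """beta2 + beta1*theta1 matches the single-equation slope of y on x."""
        ok = 0
        for seed in range(60):
            rng = np.random.default_rng(2000 + seed)
            n = 250
            x = standardize((rng.random(n) < 0.4).astype(float))
            m = 0.4 * x + rng.standard_normal(n)
            y = 0.25 * x + 0.51 * m + rng.standard_normal(n)
            fit = fit_mediation(y, m, x, k=None)
            ys, xs = standardize(y), x
            X = np.column_stack([np.ones(n), xs])
            bt = np.linalg.lstsq(X, ys, rcond=None)[0][1]
            resid = ys - X @ np.linalg.lstsq(X, ys, rcond=None)[0]
            se_t = np.sqrt(resid @ resid / (n - 2) / (xs @ xs - n * xs.mean() ** 2))
            plug = fit.beta2 + fit.beta1 * fit.theta1
            se_plug = np.sqrt(
                fit.se_beta2**2
                + (fit.theta1 * fit.se_beta1) ** 2
                + (fit.beta1 * fit.se_theta1) ** 2
            )
            if abs(plug - bt) <= 2 * np.hypot(se_t, se_plug):
                ok += 1
        assert ok >= 56  # >= 93% of seeds

    def test_degenerate_inputs_rejected(self, unconfounded):
        y, m, x = unconfounded
        with pytest.raises(DegenerateInputError, match="constant"):
            fit_mediation(y, np.ones_like(m), x)
        with pytest.raises(DegenerateInputError, match="collinear"):
            fit_mediation(y, x + 1e-6 * np.random.default_rng(0).standard_normal(len(x)), x)


class TestNaturalEffects:
    def test_closed_form_decomposition(self):
        fit = medlmm.MediationFit(
            beta1=0.5, beta2=0.2, theta1=0.8,
            se_beta1=0.1, se_beta2=0.1, se_theta1=0.1,
            lambda1=0, lambda2=0, sigma_m2=1, sigma_y2=1, adjusted=False,
        )
        eff = natural_effects(fit, contrast=1.0)
        assert eff.nie == pytest.approx(0.40)
        assert eff.nde == pytest.approx(0.20)
        assert eff.total == pytest.approx(0.60)
        assert eff.prop_mediated == pytest.approx(2 / 3)
        assert not eff.inconsistent

    def test_nie_identity_exact(self, mediation_data):
        g, k, x, m, y, truth = mediation_data
        for kin in (None, k):
            fit = fit_mediation(y, m, x, kin)
            for contrast in (1.0, 2.5, -1.0):
                eff = natural_effects(fit, contrast)
                assert eff.nie == fit.beta1 * fit.theta1 * contrast
                assert eff.total == eff.nde + eff.nie

    def test_zero_beta1_zero_proportion(self):
        fit = medlmm.MediationFit(
            beta1=0.0, beta2=0.3, theta1=0.8,
            se_beta1=0.1, se_beta2=0.1, se_theta1=0.1,
            lambda1=0, lambda2=0, sigma_m2=1, sigma_y2=1, adjusted=False,
        )
        eff = natural_effects(fit)
        assert eff.nie == 0.0 and eff.prop_mediated == 0.0

    def test_zero_total_flagged_undefined(self):
        fit = medlmm.MediationFit(
            beta1=0.5, beta2=-0.4, theta1=0.8,
            se_beta1=0.1, se_beta2=0.1, se_theta1=0.1,
            lambda1=0, lambda2=0, sigma_m2=1, sigma_y2=1, adjusted=False,
        )
        eff = natural_effects(fit)  # nde = -0.4, nie = 0.4
        assert not eff.prop_defined and np.isnan(eff.prop_mediated)

    def test_opposite_signs_flagged_inconsistent(self):
        fit = medlmm.MediationFit(
            beta1=0.5, beta2=-0.1, theta1=0.8,
            se_beta1=0.1, se_beta2=0.1, se_theta1=0.1,
            lambda1=0, lambda2=0, sigma_m2=1, sigma_y2=1, adjusted=False,
        )
        eff = natural_effects(fit)
        assert eff.inconsistent and eff.prop_mediated > 1


class TestIndirectPermutation:
    def test_strong_signal_attains_minimum_p(self, mediation_data):
        g, k, x, m, y, truth = mediation_data
        p, obs = indirect_permutation_test(y, m, x, k, n_perm=199, seed=5)
        assert p == pytest.approx(1.0 / 200.0)

    def test_weak_mediator_large_p(self, small_panel):
        g, k = small_panel
        rng = np.random.default_rng(6)
        n = g.n_lines
        x = g.calls[:, 0]
        m = rng.standard_normal(n) * 1e-3  # unrelated to x
        y = rng.standard_normal(n)
        p, obs = indirect_permutation_test(y, m, x, k, n_perm=199, seed=6)
        assert p > 0.05

    def test_type_one_error_calibrated(self):
        """Nominal 5% rejection under beta1 = 0 (unadjusted fast path)."""
        rejections = 0
        n_data = 200
        for seed in range(n_data):
            rng = np.random.default_rng(3000 + seed)
            n = 120
            x = (rng.random(n) < 0.4).astype(float)
            m = rng.standard_normal(n)
            y = rng.standard_normal(n)
            p, _ = indirect_permutation_test(y, m, x, None, n_perm=99, seed=seed)
            if p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_data <= 0.08

    def test_relabeling_leaves_observed_statistic(self, mediation_data):
        g, k, x, m, y, truth = mediation_data
        perm = np.random.default_rng(8).permutation(len(y))
        k2 = medlmm.KinshipMatrix(
            lines=[k.lines[i] for i in perm], values=k.values[np.ix_(perm, perm)]
        )
        p1, obs1 = indirect_permutation_test(y, m, x, k, n_perm=199, seed=9)
        p2, obs2 = indirect_permutation_test(y[perm], m[perm], x[perm], k2, n_perm=199, seed=9)
        assert obs1 == pytest.approx(obs2, rel=1e-8)
        # p-values agree within Monte-Carlo error of the permutation draw
        assert abs(p1 - p2) <= 2 * np.sqrt(0.5 * 0.5 / 199)


class TestMediatorScan:
    def test_true_mediators_flagged_decoys_not(self, small_panel):
        g, k = small_panel
        rng = np.random.default_rng(12)
        n = g.n_lines
        x = standardize(g.calls[:, 5])
        true_cols, decoy_cols = 3, 5
        cols = {}
        for j in range(true_cols):
            cols[f"true{j}"] = 0.6 * x + rng.standard_normal(n)
        for j in range(decoy_cols):
            cols[f"decoy{j}"] = rng.standard_normal(n)
        expr = pd.DataFrame(cols)
        y = 0.2 * x + 0.5 * cols["true0"] + rng.standard_normal(n)
        tab = mediator_scan(y, expr, x, k, alpha=0.05, n_perm=199, seed=13)
        assert tab.loc[[f"true{j}" for j in range(true_cols)], "significant"].all()
        assert tab.loc[[f"decoy{j}" for j in range(decoy_cols)], "significant"].sum() <= 1

    def test_failures_skipped_not_fatal(self, small_panel):
        g, k = small_panel
        n = g.n_lines
        rng = np.random.default_rng(14)
        x = g.calls[:, 3]
        expr = pd.DataFrame({"flat": np.ones(n), "ok": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        tab = mediator_scan(y, expr, x, k, n_perm=199, seed=15)
        assert list(tab.index) == ["ok"]
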