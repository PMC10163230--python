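"""IV 2SLS, effective F, mechanism blocking, LDV and Oster bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import befcausal as bc
from befcausal.estimators import IdentificationError
from befcausal.robustness import (
    FirstStage,
    OsterInputs,
    _oster_cubic_coefficients,
    oster_adjusted_beta,
)


class TestTwoStageLeastSquares:
    def test_degenerate_iv_equals_within_estimator(self, confounded_panel):
        """Instrumenting ln richness with itself collapses 2SLS to OLS."""
        panel, _ = confounded_panel
        df = panel.data.copy()
        df["self_iv"] = np.log(df.richness.to_numpy(float))
        iv = bc.two_stage_least_squares(df, instrument_col="self_iv")
        within = bc.estimate_main_design(df)
        assert iv.beta == pytest.approx(within.params["ln_richness"], abs=1e-10)

    def test_just_identified_ratio_identity(self, confounded_panel):
        """beta = reduced-form / first-stage after identical FE absorption."""
        panel, _ = confounded_panel
        iv = bc.two_stage_least_squares(panel)
        from befcausal.panel import FixedEffectsSpec, absorb_fixed_effects

        df = panel.data.assign(
            lny=np.log(panel.data.live_mass), lnr=np.log(panel.data.richness)
        )
        dem, _ = absorb_fixed_effects(
            df[["lny", "lnr", "instrument"]],
            FixedEffectsSpec(("plot", "site_year")).codes(df),
        )
        z, y, x = (dem[c].to_numpy() for c in ("instrument", "lny", "lnr"))
        reduced = (z @ y) / (z @ z)
        first = (z @ x) / (z @ z)
        assert iv.beta == pytest.approx(reduced / first, abs=1e-10)
        assert iv.first_stage.gamma == pytest.approx(first, abs=1e-12)

    def test_missing_instrument_rows_dropped_with_log(self, confounded_panel):
        panel, _ = confounded_panel
        df = panel.data.copy()
        df.loc[df.index[:7], "instrument"] = np.nan
        iv = bc.two_stage_least_squares(df)
        assert iv.n_dropped_missing_instrument == 7
        assert iv.n_obs == len(df) - 7

    def test_constant_instrument_raises(self, confounded_panel):
        panel, _ = confounded_panel
        df = panel.data.assign(flat_iv=1.0)
        with pytest.raises(IdentificationError):
            bc.two_stage_least_squares(df, instrument_col="flat_iv")

    def test_block_mean_instrument_leave_one_out(self):
        df = pd.DataFrame({"block": ["a", "a", "a", "b", "b"],
                           "richness": [2.0, 4.0, 6.0, 1.0, 3.0]})
        out = bc.block_mean_instrument(df, ("block",), "richness")
        np.testing.assert_allclose(out, [5.0, 4.0, 3.0, 3.0, 1.0])


class TestEffectiveF:
    def test_matches_classical_f_under_homoskedasticity(self):
        """With iid homoskedastic errors and singleton clusters the robust
        Wald statistic and the classical first-stage F are asymptotically the
        same quantity (the robust meat converges to s^2 Z'Z)."""
        from befcausal.lsq import cluster_robust_vcov

        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 4000
            z = rng.standard_normal(n)
            u = rng.standard_normal(n)
            gamma_hat = (z @ (0.4 * z + u)) / (z @ z)
            resid = 0.4 * z + u - gamma_hat * z
            var_rob = cluster_robust_vcov(z[:, None], resid, np.arange(n))[0, 0]
            var_cl = (resid @ resid) / (n - 1) / (z @ z)
            ratios.append(var_cl / var_rob)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)

    def test_invariant_to_instrument_scaling(self, confounded_panel):
        panel, _ = confounded_panel
        base = bc.two_stage_least_squares(panel)
        df = panel.data.assign(instrument=lambda d: 7.5 * d.instrument + 2.0)
        scaled = bc.two_stage_least_squares(df)
        assert scaled.effective_f == pytest.approx(base.effective_f, rel=1e-9)
        assert scaled.beta == pytest.approx(base.beta, abs=1e-10)

    def test_weak_instrument_gives_small_f(self):
        panel, _ = bc.simulate_panel(
            bc.scenario("confounded", seed=1, instrument_strength=0.0)
        )
        iv = bc.two_stage_least_squares(panel)
        assert iv.effective_f < 10  # conventional weak-instrument territory

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            bc.effective_f(FirstStage(gamma=1.0, var_robust=0.0,
                                      var_classical=1.0, n=10, df_absorbed=1))


class TestMechanismBlock:
    def test_noop_when_no_reverse_causality(self, confounded_panel):
        panel, _ = confounded_panel
        base = bc.estimate_main_design(panel)
        blocked = bc.mechanism_block(panel)
        assert blocked.params["ln_richness"] == pytest.approx(
            base.params["ln_richness"], abs=2 * base.se["ln_richness"]
        )

    def test_missing_shade_column_raises(self, confounded_panel):
        panel, _ = confounded_panel
        df = panel.data.drop(columns=["shade_lag"])
        with pytest.raises(bc.PanelError, match="shad"):
            bc.mechanism_block(df)

    def test_blocking_removes_reverse_causality_bias(self):
        """Monte Carlo: with feedback through lagged shading, controlling the
        lagged shade moves the estimate toward the truth."""
        cfg = bc.scenario("reverse_causality", seed=55)
        mc = bc.monte_carlo(cfg, n_reps=60, designs=("main", "mechanism_block"))
        bias = mc.per_design["bias"].abs()
        assert bias["mechanism_block"] < bias["main"]
        assert mc.per_design.loc["main", "bias"] > 2 * mc.per_design.loc["main", "mc_se"]


class TestLDV:
    def test_sample_loses_first_usable_year_per_plot(self):
        panel, _ = bc.simulate_panel(bc.scenario("confounded", seed=2))
        res = bc.estimate_ldv(panel)
        assert res.n_obs == len(panel) - panel.n_plots
        assert res.extra["n_dropped_no_lag"] == panel.n_plots

    def test_theta_zero_no_plot_confounding_recovers_beta(self):
        cfg = bc.scenario("ideal", seed=3, n_sites=40, n_years=8)
        panel, truth = bc.simulate_panel(cfg)
        res = bc.estimate_ldv(panel)
        assert res.params["ln_richness"] == pytest.approx(
            truth.beta_true, abs=3 * res.se["ln_richness"]
        )

    def test_no_consecutive_years_raises(self):
        df = pd.DataFrame(
            dict(site_id="S", plot_id=["P1"] * 3, year=[2007, 2009, 2011],
                 live_mass=[100.0, 120.0, 90.0], richness=[4, 5, 6])
        )
        with pytest.raises(IdentificationError):
            bc.estimate_ldv(df)

    def test_bracketing_pattern(self):
        """LDV is closer to truth under lagged-productivity dynamics; the
        within estimator is closer under plot-level confounding."""
        dyn = bc.monte_carlo(bc.scenario("reverse_causality", seed=66),
                             n_reps=60, designs=("main", "ldv"))
        conf = bc.monte_carlo(bc.scenario("confounded", seed=67),
                              n_reps=60, designs=("main", "ldv"))
        dyn_bias = dyn.per_design["bias"].abs()
        conf_bias = conf.per_design["bias"].abs()
        assert dyn_bias["ldv"] < dyn_bias["main"]
        assert conf_bias["main"] < conf_bias["ldv"]

    def test_bracket_contains_truth_often_enough(self):
        """When one design's assumptions hold, the truth sits at one endpoint
        of the bracket in expectation, so containment should approach one half
        times the probability the biased design lands on its far side."""
        mc = bc.monte_carlo(bc.scenario("confounded", seed=68),
                            n_reps=60, designs=("main", "ldv"))
        pr = mc.per_rep.pivot(index="rep", columns="design", values="estimate")
        lo = pr[["main", "ldv"]].min(axis=1)
        hi = pr[["main", "ldv"]].max(axis=1)
        inside = ((lo <= mc.beta_true) & (mc.beta_true <= hi)).mean()
        assert inside >= 0.25


class TestBracket:
    def test_ordered_interval_and_sign_agreement(self):
        res = bc.bracket(-0.24, -0.20)
        assert res.interval == (-0.24, -0.20)
        assert res.sign_agreement and "negative" in res.interpretation

    def test_disagreeing_signs_give_no_interpretation(self):
        res = bc.bracket(-0.1, 0.2)
        assert not res.sign_agreement and res.interpretation is None

    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_interval_always_ordered(self, a, b):
        res = bc.bracket(a, b)
        assert res.interval[0] <= res.interval[1]
        assert res.interval == (min(a, b), max(a, b))


def _model_instance(beta=-0.4, a=0.6, delta=0.5, n=400_000, seed=7, sd_e=0.5):
    """On-model data: y = beta x + w + q + e with proportional selection
    cov(q,x)/var(q) = delta * cov(w,x)/var(w); returns exact OsterInputs."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    q = rng.standard_normal(n)
    x = a * w + delta * a * q + rng.standard_normal(n)
    y = beta * x + w + q + sd_e * rng.standard_normal(n)

    def fit(X):
        X1 = np.column_stack([X, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
        r = y - X1 @ coef
        return coef[0], 1 - (r @ r) / ((y - y.mean()) ** 2).sum()

    bdot, rdot = fit(x[:, None])
    btilde, rtilde = fit(np.column_stack([x, w]))
    _, rmax = fit(np.column_stack([x, w, q]))
    xw = np.column_stack([w, np.ones(n)])
    xr = x - xw @ np.linalg.lstsq(xw, x, rcond=None)[0]
    return beta, OsterInputs(
        beta_dot=bdot, r2_dot=rdot, beta_tilde=btilde, r2_tilde=rtilde,
        pi=delta, r_max=rmax, sigma2_y=y.var(ddof=1), sigma2_x=x.var(ddof=1),
        tau_x=xr.var(ddof=1),
    )


class TestOster:
    def test_pi_zero_returns_controlled_beta(self):
        inp = OsterInputs(0.3, 0.1, 0.1, 0.5, pi=0.0, r_max=1.0)
        for method in ("approximation",):
            assert oster_adjusted_beta(inp, method).beta_star == pytest.approx(0.1)

    def test_rmax_equals_r2_tilde_returns_controlled_beta(self):
        inp = OsterInputs(0.3, 0.1, 0.1, 0.5, pi=-0.1, r_max=0.5,
                          sigma2_y=1.0, sigma2_x=1.0, tau_x=0.6)
        for method in ("approximation", "exact_root"):
            assert oster_adjusted_beta(inp, method).beta_star == pytest.approx(0.1, abs=1e-10)

    def test_exact_root_recovers_true_beta_on_model(self):
        beta, inp = _model_instance()
        res = oster_adjusted_beta(inp, method="exact_root")
        assert res.beta_star == pytest.approx(beta, abs=0.01)

    def test_cubic_roots_match_grid_search_oracle(self):
        _, inp = _model_instance(n=50_000)
        coefs = _oster_cubic_coefficients(inp)

        def f(b):
            return ((coefs[3] * b + coefs[2]) * b + coefs[1]) * b + coefs[0]

        grid = np.linspace(-10, 10, 2_000_001)
        vals = f(grid)
        sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        brute_roots = sorted(
            float((grid[i] + grid[i + 1]) / 2) for i in sign_changes
        )
        res = oster_adjusted_beta(inp, method="exact_root")
        in_range = [r for r in res.roots if -10 < r < 10]
        assert len(brute_roots) == len(in_range)
        np.testing.assert_allclose(in_range, brute_roots, atol=1e-4)

    def test_approximation_agrees_with_exact_to_first_order(self):
        """For small pi the two methods coincide up to O(pi^2)."""
        diffs = []
        for pi in (0.02, 0.01, 0.005):
            beta, inp = _model_instance(delta=pi)
            appr = oster_adjusted_beta(inp, "approximation").beta_star
            exact = oster_adjusted_beta(inp, "exact_root").beta_star
            diffs.append(abs(appr - exact))
        assert diffs[0] < 5e-3
        # halving pi should roughly quarter the discrepancy
        assert diffs[2] < diffs[0] / 2

    def test_monotone_in_pi_and_rmax(self):
        base = dict(beta_dot=0.3, r2_dot=0.05, beta_tilde=-0.2, r2_tilde=0.6)
        stars_pi = [
            oster_adjusted_beta(OsterInputs(**base, pi=p, r_max=1.0)).beta_star
            for p in np.linspace(-0.5, 0.5, 11)
        ]
        # beta_dot > beta_tilde: beta* decreases as pi rises
        assert all(np.diff(stars_pi) < 0)
        stars_rmax = [
            oster_adjusted_beta(OsterInputs(**base, pi=-0.1, r_max=r)).beta_star
            for r in np.linspace(0.65, 1.0, 8)
        ]
        assert all(np.diff(stars_rmax) > 0)

    def test_degenerate_r2_raises(self):
        with pytest.raises(ZeroDivisionError):
            oster_adjusted_beta(OsterInputs(0.3, 0.5, 0.1, 0.5, pi=-0.1, r_max=1.0))
        with pytest.raises(ValueError):
            OsterInputs(0.3, 0.6, 0.1, 0.5, pi=-0.1, r_max=1.0).validate()

    def test_exact_root_requires_moments(self):
        inp = OsterInputs(0.3, 0.1, 0.1, 0.5, pi=-0.1, r_max=1.0)
        with pytest.raises(ValueError, match="sigma2_y"):
            oster_adjusted_beta(inp, method="exact_root")

    def test_inputs_from_designs_wire_through(self, confounded_panel):
        panel, _ = confounded_panel
        inp = bc.oster_inputs_from_designs(panel, pi=-0.10, r_max=1.0)
        assert inp.r2_dot < inp.r2_tilde < 1.0
        res = bc.oster_adjusted_beta(inp, method="exact_root")
        lo, hi = res.identified_set
        assert lo <= res.beta_star <= hi or np.isclose(res.beta_star, hi)
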