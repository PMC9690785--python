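"""Generator truth consistency, metrics, Kaplan-Meier and the study harness."""

import dataclasses

import numpy as np
import pytest

import riaft_bart as rb
from riaft_bart.sim_eval import (
    ScenarioConfig,
    _calibrate_censoring,
    ate_metrics,
    kaplan_meier,
    oracle_estimator_factory,
    pehe,
    run_study,
    simulate,
    true_survival_curve,
)


class TestSimulate:
    def test_same_seed_reproduces_everything(self):
        cfg = ScenarioConfig(n=200, n_clusters=8, seed=5)
        d1, t1 = simulate(cfg)
        d2, t2 = simulate(cfg)
        np.testing.assert_array_equal(d1.time, d2.time)
        np.testing.assert_array_equal(d1.treatment, d2.treatment)
        np.testing.assert_array_equal(t1.surv_prob, t2.surv_prob)

    def test_zero_censoring_target_gives_all_events(self):
        cfg = ScenarioConfig(n=150, censoring_target=0.0, seed=1)
        ds, _ = simulate(cfg)
        assert ds.event.all()

    def test_censoring_calibration_hits_target(self):
        cfg = ScenarioConfig(n=4000, censoring_target=0.2, seed=2)
        ds, _ = simulate(cfg)
        assert 1.0 - ds.event.mean() == pytest.approx(0.2, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(censoring_target=0.95).validate()
        with pytest.raises(ValueError):
            ScenarioConfig(family="weird").validate()
        with pytest.raises(ValueError):
            ScenarioConfig(family="nph", shapes_nph=(1.0,)).validate()

    def test_truth_probabilities_and_contrast_consistency(self):
        cfg = ScenarioConfig(n=300, seed=3)
        _, truth = simulate(cfg)
        assert ((truth.surv_prob >= 0) & (truth.surv_prob <= 1)).all()
        c12, c13, c23 = (truth.contrast(p) for p in [(1, 2), (1, 3), (2, 3)])
        np.testing.assert_allclose(c12 + c23, c13, atol=1e-12)

    def test_empirical_km_matches_analytic_truth(self):
        """With no confounding and no cluster variance, the per-arm
        Kaplan-Meier estimate at t* must agree with the mean analytic truth."""
        cfg = ScenarioConfig(
            n=5000, seed=4, tau_true=0.0, censoring_target=0.0,
            assignment={1: {"const": 0.0}, 2: {"const": 0.0}, 3: {"const": 0.0}},
        )
        ds, truth = simulate(cfg)
        for a in (1, 2, 3):
            sel = ds.treatment == a
            times, surv = kaplan_meier(ds.time[sel], ds.event[sel])
            km_at_t = surv[np.searchsorted(times, cfg.t_star, side="right") - 1]
            target = truth.surv_prob[a - 1][sel].mean()
            mc_se = np.sqrt(target * (1 - target) / sel.sum())
            assert abs(km_at_t - target) < 4 * mc_se

    def test_ph_and_nph_hazard_ratio_structure(self):
        """PH: arm-wise hazard ratio constant in t; nPH: it varies with t.

        For Weibull hazards h_a(t) = lam_a nu_a t^(nu_a - 1) e^eta the ratio
        h_1/h_2 is constant iff nu_1 = nu_2.
        """
        ph, nph = ScenarioConfig(family="ph"), ScenarioConfig(family="nph")

        def hr(cfg, t):
            h1 = cfg.base_rate(1) * cfg.shape(1) * t ** (cfg.shape(1) - 1)
            h2 = cfg.base_rate(2) * cfg.shape(2) * t ** (cfg.shape(2) - 1)
            return h1 / h2

        assert hr(ph, 10.0) == pytest.approx(hr(ph, 100.0))
        assert hr(nph, 10.0) != pytest.approx(hr(nph, 100.0), rel=1e-3)

    def test_true_curve_reproduces_t_star_value(self):
        cfg = ScenarioConfig(n=100, seed=8)
        _, truth = simulate(cfg)
        curve = true_survival_curve(cfg, truth, 2, np.array([30.0, cfg.t_star]))
        assert curve[1] == pytest.approx(truth.surv_prob[1].mean(), abs=1e-10)
        assert curve[0] > curve[1]


class TestMetrics:
    def test_pehe_identities(self):
        truth = np.array([0.1, 0.5])
        assert pehe(truth, truth) == 0.0
        assert pehe(truth + 0.07, truth) == pytest.approx(0.07)
        assert pehe(np.array([0.3, 0.5]), truth) == pytest.approx(np.sqrt(0.02))
        with pytest.raises(ValueError):
            pehe(np.ones(3), np.ones(2))

    def test_pehe_invariant_to_common_relabeling(self):
        rng = np.random.default_rng(0)
        est, tru = rng.random(50), rng.random(50)
        # flipping the contrast direction in both estimate and truth
        assert pehe(-est, -tru) == pytest.approx(pehe(est, tru))

    def test_ate_metrics_identities(self):
        bias, rmse = ate_metrics(np.array([1.1, 0.9]), np.array([1.0, 1.0]))
        assert bias == pytest.approx(0.0)
        assert rmse == pytest.approx(0.1)
        bias1, rmse1 = ate_metrics(np.array([2.0]), np.array([1.5]))
        assert rmse1 == pytest.approx(abs(bias1))
        est = np.array([0.2, 0.5, 0.1])
        tru = np.array([0.1, 0.4, 0.4])
        bias2, rmse2 = ate_metrics(est, tru)
        assert bias2 == pytest.approx(np.mean(est - tru))
        assert rmse2 == pytest.approx(np.sqrt(np.mean((est - tru) ** 2)))
        assert rmse2 >= abs(bias2)


class TestKaplanMeier:
    def test_all_censored_gives_unit_survival(self):
        times, surv = kaplan_meier(np.array([1.0, 2.0]), np.array([0, 0]))
        assert times.size == 0

    def test_product_limit_by_hand(self):
        times, surv = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(surv, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40) + 0.1
        e = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        t1, s1 = kaplan_meier(t, e)
        t2, s2 = kaplan_meier(t[perm], e[perm])
        np.testing.assert_allclose(t1, t2)
        np.testing.assert_allclose(s1, s2)

    def test_censored_only_shrink_risk_sets(self):
        # a censored subject leaves the risk set but contributes no event
        # factor: S(2) = (1 - 1/4) * (1 - 1/2) = 3/8
        _, s_cens = kaplan_meier(
            np.array([1.0, 1.5, 2.0, 3.0]), np.array([1, 0, 1, 1])
        )
        assert s_cens[1] == pytest.approx(3 / 8)


class TestRunStudy:
    def test_oracle_estimator_achieves_zero_pehe(self):
        cfg = ScenarioConfig(n=120, n_clusters=6, seed=0)
        truths = {}

        def oracle(dataset, t_star, seed):
            return truths[seed]

        # pre-simulate the truths the harness will generate
        for rep in range(3):
            seed = int((7 + 1000 * rep + 1) % (2**31 - 1))
            _, truth = simulate(dataclasses.replace(cfg, seed=seed))
            truths[seed] = truth.surv_prob
        table = run_study(cfg, 3, oracle, master_seed=7, method_name="oracle")
        assert (table["mean_pehe"] == 0.0).all()
        assert (table["bias"].abs() < 1e-12).all()

    def test_noise_estimator_pehe_converges_to_noise_sd(self):
        cfg = ScenarioConfig(n=2000, n_clusters=10, seed=0)
        sd = 0.05

        def noisy(dataset, t_star, seed):
            rng = np.random.default_rng(seed)
            _, truth = simulate(dataclasses.replace(cfg, seed=seed))
            return truth.surv_prob + sd * rng.standard_normal(truth.surv_prob.shape)

        table = run_study(cfg, 2, noisy, master_seed=3, method_name="noisy")
        # contrast of two independent noises has sd sqrt(2)*sd
        np.testing.assert_allclose(
            table["mean_pehe"], np.sqrt(2) * sd, rtol=0.1
        )

    def test_identical_seeds_reproduce_metrics(self):
        cfg = ScenarioConfig(n=100, n_clusters=5, seed=0)

        def crude(dataset, t_star, seed):
            # arm-wise empirical survival fractions, no covariates
            out = np.zeros((3, len(dataset)))
            for a in (1, 2, 3):
                out[a - 1] = (dataset.time > t_star).mean()
            return out

        t1 = run_study(cfg, 2, crude, master_seed=5)
        t2 = run_study(cfg, 2, crude, master_seed=5)
        assert t1.equals(t2)

    def test_estimator_failure_recorded_not_dropped(self):
        cfg = ScenarioConfig(n=80, n_clusters=4, seed=0)
        calls = {"k": 0}

        def flaky(dataset, t_star, seed):
            calls["k"] += 1
            if calls["k"] == 1:
                raise RuntimeError("boom")
            return np.full((3, len(dataset)), 0.5)

        table = run_study(cfg, 2, flaky, master_seed=1)
        assert table["n_replications"].iloc[0] == 1
        assert len(table.attrs["failures"]) == 1


def test_censoring_calibration_bisection():
    rng = np.random.default_rng(2)
    t = rng.weibull(1.3, 5000) * 50
    for target in (0.1, 0.3, 0.6):
        c_max = _calibrate_censoring(t, target)
        c = rng.uniform(0, c_max, t.size)
        assert np.mean(c < t) == pytest.approx(target, abs=0.03)
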