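import numpy as np
import pandas as pd
import pytest

from dynpred.simulate import (ScenarioConfig, VISIT_OFFSETS, _calibrate,
                              default_marker_designs, generate_cohort,
                              generate_covariates, generate_event_times,
                              generate_markers, generate_visits,
                              linear_predictor, true_summaries)


class TestVisits:
    def test_zero_variance_hits_theoretical_times(self):
        v = generate_visits(4, np.random.default_rng(0), t_landmark=4.0,
                            jitter_var=0.0)
        assert np.allclose(v, 4.0 + np.asarray(VISIT_OFFSETS), atol=1e-9)

    def test_jitter_sd_matches_declared_variance(self):
        rng = np.random.default_rng(1)
        v = generate_visits(20000, rng, t_landmark=4.0)
        # first visit never clips (offset -4), so its jitter is untouched
        jit = v[:, 0] - 0.0
        assert abs(np.std(jit) - np.sqrt(0.15)) < 0.01

    def test_seeded_reproducibility_and_ordering(self):
        v1 = generate_visits(50, np.random.default_rng(7))
        v2 = generate_visits(50, np.random.default_rng(7))
        assert np.array_equal(v1, v2)
        # within-row times are unique (no duplicate measurement times)
        assert all(np.unique(row).size == row.size for row in v1)
        assert np.all(v1 <= 4.0)


class TestMarkers:
    def test_design_count_and_summary_total(self):
        designs = default_marker_designs()
        assert len(designs) == 17
        qs = sorted(d.q for d in designs)
        assert qs.count(3) == 9 and qs.count(2) == 6 and qs.count(1) == 2
        assert sum(d.q + 3 for d in designs) == 92

    def test_noise_free_markers_sit_on_population_polynomial(self):
        designs = [d.__class__(d.name, d.beta, tuple(0.0 for _ in d.re_sd),
                               1e-12) for d in default_marker_designs()[:2]]
        long, _ = generate_markers(10, np.random.default_rng(2),
                                   designs=designs)
        for d in designs:
            sub = long.frame[long.frame["marker"] == d.name]
            X = d.basis().design(sub["time"].to_numpy())
            assert np.allclose(sub["value"], X @ np.asarray(d.beta), atol=1e-6)

    def test_random_effect_moments(self):
        _, true_b = generate_markers(8000, np.random.default_rng(3),
                                     designs=default_marker_designs()[:3])
        for name, b in true_b.items():
            d = [x for x in default_marker_designs() if x.name == name][0]
            emp = np.std(b, axis=0)
            assert np.allclose(emp, d.re_sd, rtol=0.05)

    def test_true_summary_matrix_is_92_wide(self):
        designs = default_marker_designs()
        _, true_b = generate_markers(30, np.random.default_rng(4),
                                     designs=designs)
        gamma0 = true_summaries(designs, true_b)
        assert gamma0.shape == (30, 92)


class TestCovariates:
    def test_moments(self):
        X = generate_covariates(30000, np.random.default_rng(5))
        norm = X[[c for c in X if c.startswith("xnorm")]]
        binv = X[[c for c in X if c.startswith("xbin")]]
        assert norm.shape[1] == 5 and binv.shape[1] == 5
        assert np.allclose(norm.mean(), 0.0, atol=0.02)
        assert np.allclose(norm.std(), 1.0, atol=0.02)
        assert np.allclose(binv.mean(), 0.5, atol=0.01)

    def test_seeded_determinism(self):
        a = generate_covariates(20, np.random.default_rng(6))
        b = generate_covariates(20, np.random.default_rng(6))
        pd.testing.assert_frame_equal(a, b)


class TestLinearPredictor:
    def _setup(self, link, n=200, n_active=4):
        sc = ScenarioConfig(n_active=n_active, link=link, n_subjects=n)
        rng = np.random.default_rng(7)
        _, true_b = generate_markers(n, rng, sc.designs)
        gamma0 = true_summaries(sc.designs, true_b)
        X = generate_covariates(n, rng)
        return sc, gamma0, X

    def test_zero_coefficients_give_constant_eta(self):
        sc, gamma0, X = self._setup("linear")
        sc0 = ScenarioConfig(n_active=4, link="linear", coef=0.0,
                             covariate_coef=0.0)
        eta = linear_predictor(gamma0, X, sc0)
        assert np.allclose(eta, 0.0)

    def test_interactions_match_hand_expansion(self):
        sc, gamma0, X = self._setup("interactions")
        eta_int = linear_predictor(gamma0, X, sc)
        sc_lin = ScenarioConfig(n_active=4, link="linear")
        eta_lin = linear_predictor(gamma0, X, sc_lin)
        from dynpred.simulate import _summary_moments

        means, scales = _summary_moments(sc)
        Z = (gamma0[sc.active_summaries].to_numpy() - means) / scales
        levels = Z[:, 0::2]
        hand = eta_lin + 0.5 * sc.coef * levels[:, 0] * levels[:, 1]
        assert np.allclose(eta_int, hand, atol=1e-12)

    def test_nonlinear_uses_squares_and_binarization(self):
        sc, gamma0, X = self._setup("nonlinear")
        eta = linear_predictor(gamma0, X, sc)
        sc_lin = ScenarioConfig(n_active=4, link="linear")
        eta_lin = linear_predictor(gamma0, X, sc_lin)
        # not an affine transform of the linear predictor
        r = np.corrcoef(eta, eta_lin)[0, 1]
        assert abs(r) < 0.9


class TestEventTimes:
    def test_exponential_special_case_median(self):
        """Shape k=1, eta=0: conditional on T > t_LM the excess time is
        exponential(lam), so median(T - t_LM) = ln 2 / lam."""
        sc = ScenarioConfig(weibull_shape=1.0, n_subjects=10)
        cal = _calibrate(sc)
        rng = np.random.default_rng(8)
        eta = np.zeros(100000)
        T_star, delta, pi0 = generate_event_times(eta, sc, rng)
        # remove censoring by regenerating true times only
        lam = cal["rate"]
        u = np.random.default_rng(9).uniform(size=200000)
        T = 4.0 - np.log(u) / lam
        assert abs(np.median(T - 4.0) - np.log(2) / lam) < 0.02 * np.log(2) / lam

    def test_extreme_negative_eta_gives_no_events(self):
        sc = ScenarioConfig(n_subjects=10)
        rng = np.random.default_rng(10)
        T_star, delta, pi0 = generate_event_times(np.full(500, -30.0), sc, rng)
        assert np.allclose(pi0, 0.0, atol=1e-9)
        assert ((T_star > 7.0) | (delta == 0)).all()

    def test_event_fraction_consistent_with_mean_pi0(self):
        sc = ScenarioConfig(n_subjects=10)
        rng = np.random.default_rng(11)
        eta = rng.normal(0, 1, 40000)
        T_star, delta, pi0 = generate_event_times(eta, sc, rng)
        # compare against uncensored event occurrence within the window
        cal = _calibrate(sc)
        u = rng.uniform(size=len(eta))
        T = (4.0 ** 1.5 - np.log(u) / (cal["rate"] * np.exp(eta))) ** (1 / 1.5)
        frac = (T <= 7.0).mean()
        assert abs(frac - pi0.mean()) < 0.01

    def test_pi0_strictly_increasing_in_eta(self):
        sc = ScenarioConfig(n_subjects=10)
        eta = np.linspace(-3, 3, 50)
        _, _, pi0 = generate_event_times(eta, sc, np.random.default_rng(12))
        assert np.all(np.diff(pi0) > 0)
        from scipy.stats import spearmanr

        assert spearmanr(eta, pi0).statistic >= 1.0 - 1e-12


class TestCohort:
    def test_calibrated_event_rate_near_target(self):
        sc = ScenarioConfig(n_subjects=4000, link="linear")
        cohort = generate_cohort(sc, seed=13)
        assert abs(cohort.pi0.mean() - 0.40) < 0.03

    def test_all_subjects_at_risk(self):
        cohort = generate_cohort(ScenarioConfig(n_subjects=100), seed=14)
        assert (cohort.surv.frame["time"] > 4.0).all()
        assert (cohort.long.frame["time"] <= 4.0).all()

    def test_deterministic_given_seed(self):
        a = generate_cohort(ScenarioConfig(n_subjects=25), seed=15)
        b = generate_cohort(ScenarioConfig(n_subjects=25), seed=15)
        pd.testing.assert_frame_equal(a.long.frame, b.long.frame)
        pd.testing.assert_frame_equal(a.surv.frame, b.surv.frame)
        assert np.array_equal(a.pi0, b.pi0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_active=7)
        with pytest.raises(ValueError):
            ScenarioConfig(link="exotic")
        with pytest.raises(ValueError):
            ScenarioConfig(weibull_shape=0.0)


def test_estimated_summaries_track_truth():
    """Full pipeline sanity: per-summary correlation between estimated and
    generating summaries is high at the default noise level."""
    from dynpred import build_summary_matrix
    from dynpred.simulate import marker_specs_for
    from dynpred.superlearner import fit_all_markers

    sc = ScenarioConfig(n_subjects=250)
    cohort = generate_cohort(sc, seed=16)
    models = fit_all_markers(cohort.long, marker_specs_for(sc))
    ld = build_summary_matrix(models, cohort.long, cohort.surv,
                              sc.landmark_config)
    ids = ld.features.index.to_numpy()
    corrs = []
    for c in ld.summary_columns:
        truth = cohort.gamma0.loc[ids, c]
        if truth.std() > 1e-12:
            corrs.append(np.corrcoef(ld.features[c], truth)[0, 1])
    assert np.median(corrs) > 0.8
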