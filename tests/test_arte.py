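"""Radiobiology math, outcome estimator and the environment step API."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qdrlart.arte import (
    Arte,
    EstimatorConfig,
    LogisticParams,
    OutcomeEstimate,
    RadiobioParams,
    TransitionModel,
    compute_eqd2,
    compute_geud,
    fit_outcome_estimator,
    geud_transition,
    outcome_probability,
    reward,
)
from qdrlart.cohort import CohortConfig, PatientState, generate_cohort


class TestEqd2:
    @pytest.mark.parametrize("d, n, ab, expected", [
        (2.0, 30, 10.0, 60.0),            # fixed point at the 2 Gy/frac reference
        (3.0, 10, 10.0, 32.5),            # 10*3*13/12
        (0.0, 30, 4.0, 0.0),
    ])
    def test_reference_values(self, d, n, ab, expected):
        assert compute_eqd2(d, n, ab) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.1, 100.0), st.integers(1, 50))
    def test_two_gray_fixed_point(self, alpha_beta, n_frac):
        assert compute_eqd2(2.0, n_frac, alpha_beta) == pytest.approx(2.0 * n_frac, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_eqd2(-1.0, 30, 10.0)
        with pytest.raises(ValueError):
            compute_eqd2(2.0, 30, 0.0)


class TestGeud:
    def test_uniform_dose_is_identity_for_any_exponent(self):
        for a in (-10.0, -1.0, 0.5, 1.0, 7.0):
            voxels = [(0.2, 60.0), (0.3, 60.0), (0.5, 60.0)]
            assert compute_geud(voxels, a) == pytest.approx(60.0, rel=1e-12)

    def test_arithmetic_mean_at_a_one(self):
        assert compute_geud([(0.5, 40.0), (0.5, 60.0)], 1.0) == pytest.approx(50.0)

    def test_cold_spot_weighting_at_tumor_exponent(self):
        # independently computed: (0.5*40^-10 + 0.5*60^-10)^(-1/10)
        assert compute_geud([(0.5, 40.0), (0.5, 60.0)], -10.0) == pytest.approx(
            42.797294330177477, rel=1e-12)

    def test_zero_dose_with_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            compute_geud([(0.5, 0.0), (0.5, 60.0)], -10.0)

    def test_unnormalized_volumes_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compute_geud([(0.5, 40.0), (0.4, 60.0)], 1.0)


class TestGeudTransition:
    def test_zero_dose_is_identity(self):
        rb = RadiobioParams()
        assert geud_transition(50.0, 0.0, 2.0, rb, "tumor") == 50.0

    def test_reference_increment(self):
        rb = RadiobioParams(kappa_tumor=1.0)
        # 50 + 1*1*2*(1 + 2/10) = 52.4
        assert geud_transition(50.0, 2.0, 1.0, rb, "tumor") == pytest.approx(52.4)

    @given(st.floats(0.0, 5.0), st.floats(0.1, 5.0))
    def test_monotone_in_dose(self, d, dt):
        rb = RadiobioParams()
        g1 = geud_transition(30.0, d, dt, rb, "lung")
        g2 = geud_transition(30.0, d + 0.5, dt, rb, "lung")
        assert g2 > g1 >= 30.0

    def test_additive_over_equal_periods(self):
        rb = RadiobioParams()
        one = geud_transition(geud_transition(30.0, 2.5, 1.0, rb, "tumor"),
                              2.5, 1.0, rb, "tumor")
        two = geud_transition(30.0, 2.5, 2.0, rb, "tumor")
        assert one == pytest.approx(two, rel=1e-12)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            geud_transition(30.0, 2.0, 0.0, RadiobioParams(), "tumor")


class TestOutcomeProbability:
    def test_midpoint(self):
        assert outcome_probability(60.0, LogisticParams(60.0, -5.0)) == 0.5

    def test_reference_value(self):
        # 1 / (1 + e^-2)
        assert outcome_probability(70.0, LogisticParams(60.0, -5.0)) == pytest.approx(
            0.8807970779778823, rel=1e-12)

    def test_saturation(self):
        assert outcome_probability(1e6, LogisticParams(60.0, -5.0)) == pytest.approx(1.0)
        assert outcome_probability(0.0, LogisticParams(60.0, -5.0)) < 0.01

    def test_nondecreasing_in_g_with_negative_t(self):
        g = np.linspace(0, 120, 200)
        p = outcome_probability(g, LogisticParams(60.0, -5.0))
        assert np.all(np.diff(p) >= 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(60.0, 0.0)


class TestReward:
    @pytest.mark.parametrize("p_lc, p_rp2, expected", [
        (0.9, 0.1, 10.81),     # clinical region: P+ + 10
        (0.6, 0.3, 5.42),      # computational region: P+ + 5
        (0.3, 0.6, -0.88),     # failure: P+ - 1
    ])
    def test_reference_values(self, p_lc, p_rp2, expected):
        assert reward(p_lc, p_rp2) == pytest.approx(expected, rel=1e-12)

    def test_clinical_region_takes_precedence(self):
        # inside both regions: the +10 box wins
        assert reward(0.8, 0.1) == pytest.approx(0.8 * 0.9 + 10.0)

    def test_printed_gap_is_covered(self):
        # (0.9, 0.3) matches no printed box; the ordered rule gives it +5
        assert reward(0.9, 0.3) == pytest.approx(0.9 * 0.7 + 5.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_total_and_bounded(self, p_lc, p_rp2):
        r = reward(p_lc, p_rp2)
        assert -1.0 <= r <= 11.0
        base = p_lc * (1.0 - p_rp2)
        assert r - base in (10.0, 5.0, -1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reward(1.2, 0.5)


class TestTransitionModel:
    def test_identity_model_returns_pre_state(self):
        model = TransitionModel.identity()
        s = PatientState(30.0, 2.0, 25.0, 10.0, 1)
        assert model.predict(s, 2.0) == (30.0, 2.0)

    def test_untrained_model_raises(self):
        with pytest.raises(RuntimeError, match="trained"):
            TransitionModel().predict(PatientState(1, 1, 1, 1, 0), 2.0)

    def test_out_of_range_dose_rejected(self):
        model = TransitionModel.identity()
        model.dose_range = (1.0, 4.1)
        with pytest.raises(ValueError, match="outside grid range"):
            model.predict(PatientState(1, 1, 1, 1, 0), 9.0)

    def test_recovers_linear_dose_response(self, small_cohort):
        """On a cohort whose true biomarker transition is linear in dose,
        the net's predicted dose slope matches the generator's."""
        cfg = CohortConfig(n_patients=500, seed=21, biomarker_noise_sd=0.01)
        records = generate_cohort(cfg)
        model = TransitionModel(seed=0, dose_range=(1.0, 4.1)).fit(records, epochs=500)
        r = records[0]
        lo = model.predict(r.state_pre, 1.5)[0]
        hi = model.predict(r.state_pre, 3.5)[0]
        slope = (hi - lo) / 2.0 / r.state_pre.ip10
        assert slope == pytest.approx(cfg.ip10_dose_slope, abs=0.03)

    def test_serialization_round_trip(self, small_cohort):
        model = TransitionModel(seed=1).fit(small_cohort, epochs=50)
        back = TransitionModel.from_dict(model.to_dict())
        s = small_cohort[0].state_pre
        assert back.predict(s, 2.0) == pytest.approx(model.predict(s, 2.0))


class TestOutcomeEstimator:
    def test_recovers_known_logistic_curve(self):
        """Labels drawn from a known logistic (mu*=60, T*=-5) are recovered
        to within 0.05 absolute probability over the g range."""
        from qdrlart.arte import _EndpointEstimator

        rng = np.random.default_rng(0)
        n = 2000
        cov = np.column_stack([rng.lognormal(3, 0.5, n), rng.lognormal(0.7, 0.6, n),
                               rng.integers(0, 3, n)])
        g = rng.normal(60.0, 10.0, n)
        truth = LogisticParams(60.0, -5.0)
        y = (rng.random(n) < outcome_probability(g, truth)).astype(float)
        est = _EndpointEstimator(EstimatorConfig()).fit(cov, g, y)
        g_grid = np.linspace(40.0, 80.0, 81)
        med = np.median(cov, axis=0)[None, :].repeat(g_grid.size, axis=0)
        p_hat = est.predict(med, g_grid)
        p_true = outcome_probability(g_grid, truth)
        assert np.max(np.abs(p_hat - p_true)) < 0.05

    def test_single_class_labels_rejected(self, small_cohort):
        records = [r for r in small_cohort]
        forced = [type(r)(r.patient_id, r.state_pre, r.state_mid, r.clinical_dose, 1, r.rp2)
                  for r in records]
        with pytest.raises(ValueError, match="single-class"):
            fit_outcome_estimator(forced)

    def test_refit_is_deterministic(self, small_cohort):
        cfg = EstimatorConfig(inner_epochs=10, max_rounds=3)
        a = fit_outcome_estimator(small_cohort, cfg)
        b = fit_outcome_estimator(small_cohort, cfg)
        s = small_cohort[0].state_mid
        assert a.predict_state(s) == b.predict_state(s)

    def test_probability_monotone_in_g(self, small_cohort):
        cfg = EstimatorConfig(inner_epochs=20, max_rounds=5)
        est = fit_outcome_estimator(small_cohort, cfg)
        s = small_cohort[0].state_mid
        cov = np.array([[s.ip10, s.glszm_zsv, float(s.cxcr1_genotype)]])
        g_grid = np.linspace(20.0, 90.0, 100)
        p_lc = est.lc.predict(cov.repeat(100, axis=0), g_grid)
        p_rp2 = est.rp2.predict(cov.repeat(100, axis=0), g_grid)
        assert np.all(np.diff(p_lc) >= 0)
        assert np.all(np.diff(p_rp2) >= 0)


@pytest.fixture(scope="module")
def env(small_cohort):
    transition = TransitionModel.identity()
    est = fit_outcome_estimator(small_cohort, EstimatorConfig(inner_epochs=20, max_rounds=5))
    return Arte(transition, est, RadiobioParams(), max_steps=10)


class TestArteStep:

    def test_step_composes_transition_outcome_reward(self, env, small_cohort):
        r = small_cohort[0]
        result = env.step_state(r.state_mid, 2.0)
        rb = env.radbio
        expected_g = geud_transition(r.state_mid.tumor_geud, 2.0, rb.dt_weeks, rb, "tumor")
        assert result.next_state.tumor_geud == pytest.approx(expected_g)
        assert result.reward == pytest.approx(
            reward(result.outcome.p_lc, result.outcome.p_rp2))

    def test_step_is_deterministic(self, env, small_cohort):
        r = small_cohort[1]
        a = env.step_state(r.state_mid, 3.0)
        b = env.step_state(r.state_mid, 3.0)
        assert a == b

    def test_done_iff_clinical_region(self, env, small_cohort):
        for r in small_cohort[:10]:
            res = env.step_state(r.state_mid, 2.0)
            in_region = res.outcome.p_lc > 0.7 and res.outcome.p_rp2 < 0.172
            assert res.done == in_region

    def test_episode_respects_step_cap(self, env, small_cohort):
        env.reset(small_cohort[0])
        n = 0
        while True:
            n += 1
            if env.step(1.0).done:
                break
        assert n <= env.max_steps
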