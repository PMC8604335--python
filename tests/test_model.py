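"""Model mathematics: single-step operations, limits, and the loop oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mabc
from mabc.model import ContingencyTable, MABCParams, get_spec

FULL = get_spec("mabc_full")


def probs():
    return st.floats(1e-4, 1 - 1e-4)


class TestContingencyAndLikelihood:
    def test_single_cell_delta_update(self):
        t0 = ContingencyTable()
        t1 = mabc.update_contingency(t0, 1, 0, 1, 0.3)
        assert t1.p_reward[1, 0] == pytest.approx(0.65)
        # every other cell untouched; input table not mutated
        assert np.all(t0.p_reward == 0.5)
        assert t1.p_reward[1, 1] == 0.5 and np.all(t1.p_reward[0] == 0.5)

    def test_zero_prediction_error_is_fixed_point(self):
        t = ContingencyTable(np.full((2, 2), 1.0))
        t2 = mabc.update_contingency(t, 0, 1, 1, 0.9)
        assert np.all(t2.p_reward == t.p_reward)

    def test_repeated_rewards_converge_monotonically(self):
        t = ContingencyTable()
        prev = 0.5
        for _ in range(50):
            t = mabc.update_contingency(t, 1, 0, 1, 0.3)
            assert prev < t.p_reward[1, 0] <= 1.0
            prev = t.p_reward[1, 0]
        assert prev == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_reads_table_and_complement(self):
        t = ContingencyTable()
        t.p_reward[1, 0] = 0.8
        ls, lo = mabc.compute_likelihoods(t, 0, 1, 1)
        assert ls == pytest.approx(0.8) and lo == pytest.approx(0.5)
        ls, lo = mabc.compute_likelihoods(t, 0, 1, 0)
        assert ls == pytest.approx(0.2) and lo == pytest.approx(0.5)


class TestPosteriorUpdate:
    def test_symmetric_evidence_stays_even(self):
        p = mabc.posterior_update(0.5, 0.5, 0.5, 1, MABCParams(), FULL)
        assert p == pytest.approx(0.5)

    def test_hand_bayes_arithmetic(self):
        p = mabc.posterior_update(0.5, 0.8, 0.2, 1, MABCParams(), FULL)
        assert p == pytest.approx(0.8)  # 0.4 / (0.4 + 0.1)

    def test_positive_bias_inflates_self(self):
        params = MABCParams(bias_pos=np.log(2.0))
        p = mabc.posterior_update(0.5, 0.5, 0.5, 1, params, FULL)
        assert p == pytest.approx(2.0 / 3.0)

    def test_extreme_bias_saturates_to_clip_bound(self):
        up = mabc.posterior_update(0.5, 0.5, 0.5, 1,
                                   MABCParams(bias_pos=1e4), FULL)
        down = mabc.posterior_update(0.5, 0.5, 0.5, 0,
                                     MABCParams(bias_neg=-1e4), FULL)
        assert up == pytest.approx(1.0, abs=1e-5)
        assert down == pytest.approx(0.0, abs=1e-5)

    def test_nonfinite_input_raises(self):
        with pytest.raises(FloatingPointError):
            mabc.posterior_update(0.5, np.nan, 0.5, 1, MABCParams(), FULL)

    def test_single_agent_replaces_other_likelihood_with_chance(self):
        spec = get_spec("single_agent")
        # other-likelihood argument must be inert
        a = mabc.posterior_update(0.6, 0.8, 0.01, 1, MABCParams(), spec)
        b = mabc.posterior_update(0.6, 0.8, 0.99, 1, MABCParams(), spec)
        assert a == b
        assert a == pytest.approx(
            mabc.posterior_update(0.6, 0.8, 0.5, 1, MABCParams(), FULL))

    @given(ls=probs(), lo=probs(), pp=probs())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_self_likelihood_and_normalized(self, ls, lo, pp):
        p = mabc.posterior_update(pp, ls, lo, 1, MABCParams(), FULL)
        assert 0.0 < p < 1.0
        p_hi = mabc.posterior_update(pp, min(ls + 0.1, 1.0), lo, 1,
                                     MABCParams(), FULL)
        assert p_hi >= p


class TestScalarRules:
    @pytest.mark.parametrize("theta,post,expected", [
        (1.0, 0.9, 0.5),   # full drift forgets the inference
        (0.0, 0.73, 0.73),  # no drift
        (0.2, 0.9, 0.82),
    ])
    def test_drifted_prediction(self, theta, post, expected):
        assert mabc.predict_next(post, theta) == pytest.approx(expected)

    @pytest.mark.parametrize("pp,tau,beta0,expected", [
        (0.8, 0.0, 1.7, 1.7),  # tau=0 leaves the baseline untouched
        (0.5, 3.0, 2.0, 2.0),  # unit odds ratio
        (0.8, 1.0, 1.0, 4.0),
    ])
    def test_controllability_modulated_temperature(self, pp, tau, beta0, expected):
        params = MABCParams(beta0=beta0, tau=tau)
        assert mabc.trial_inverse_temperature(pp, params, FULL) == \
            pytest.approx(expected)

    def test_choice_prob_limits(self):
        assert mabc.choice_prob(0.9, 0.1, 0.0) == 0.5
        assert mabc.choice_prob(0.4, 0.4, 25.0) == 0.5
        assert mabc.choice_prob(0.2, 0.8, 4.0) == \
            pytest.approx(1 / (1 + np.exp(-2.4)))

    def test_report_prob_forms(self):
        assert mabc.causality_report_prob(0.5, 5.0) == 0.5
        assert mabc.causality_report_prob(0.9, 0.0) == 0.5
        assert mabc.causality_report_prob(0.9, 2.0) == \
            pytest.approx(1 / (1 + np.exp(-1.6)))
        assert mabc.causality_report_prob(0.8, 1.0, form="lcr") == \
            pytest.approx(0.8)  # logistic inverts the log odds

    def test_lcr_values_and_antisymmetry(self):
        assert mabc.lcr(0.5) == 0.0
        assert mabc.lcr(0.8) == pytest.approx(np.log(4.0))
        for p in (0.1, 0.3, 0.77):
            assert mabc.lcr(p) == pytest.approx(-mabc.lcr(1 - p))


class TestGeneralizedPosterior:
    def test_two_agent_case_reduces_to_pairwise_update(self):
        params = MABCParams(bias_pos=0.4)
        pair = mabc.posterior_update(0.6, 0.7, 0.3, 1, params, FULL)
        vec = mabc.generalized_posterior([0.6, 0.4], [0.7, 0.3],
                                         bias_pos=0.4, outcome=1)
        assert vec[0] == pytest.approx(pair, abs=1e-9)
        assert vec.sum() == pytest.approx(1.0)

    def test_uniform_inputs_stay_uniform(self):
        vec = mabc.generalized_posterior([1 / 3] * 3, [0.5] * 3)
        assert np.allclose(vec, 1 / 3)

    def test_three_agent_hand_normalization(self):
        vec = mabc.generalized_posterior([1 / 3] * 3, [0.8, 0.1, 0.1])
        assert np.allclose(vec, [0.8, 0.1, 0.1])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mabc.generalized_posterior([0.5, 0.5], [0.5, 0.3, 0.2])


def brute_force_trace(session, params, spec):
    """Independent sequential-Bayes calculator over the raw trial records.

    Recomputes the whole recursion with scalar arithmetic straight from the
    model definition, without the package's single-step helpers.
    """
    eps = 1e-6
    out = {"prior": [], "post": [], "beta": [], "p_right": [], "p_rep": []}
    task = None
    for rec in session.records:
        if rec.task_id != task:
            task = rec.task_id
            p_self = {0: 0.5, 1: 0.5}
            p_oth = {0: 0.5, 1: 0.5}
            pp = 0.5
        pp = min(max(pp, eps), 1 - eps)
        out["prior"].append(pp)
        beta = params.beta0 * (pp / (1 - pp)) ** params.tau
        out["beta"].append(beta)
        d = p_self[1] - p_self[0]
        pr = 0.5 if d == 0 else 1 / (1 + np.exp(-beta * d))
        out["p_right"].append(pr)
        a, b, o = rec.action_self, rec.action_other, rec.outcome
        p_self[a] += params.a_self * (o - p_self[a])
        p_oth[b] += params.a_other * (o - p_oth[b])
        ls = p_self[a] if o == 1 else 1 - p_self[a]
        lo = (p_oth[b] if o == 1 else 1 - p_oth[b]) \
            if spec.use_other_likelihood else 0.5
        w = np.exp(params.bias_pos if o == 1 else params.bias_neg)
        post = w * ls * pp / (w * ls * pp + lo * (1 - pp))
        post = min(max(post, eps), 1 - eps)
        out["post"].append(post)
        out["p_rep"].append(1 / (1 + np.exp(-params.beta_con * (2 * post - 1))))
        pp = (1 - params.theta) * post + 0.5 * params.theta
    return {k: np.array(v) for k, v in out.items()}


class TestSessionLoglik:
    @pytest.mark.parametrize("label", ["mabc_full", "single_agent",
                                       "mabc_nobias"])
    def test_trace_matches_brute_force_oracle(self, canonical_session, label):
        spec = get_spec(label)
        params = spec.pin(MABCParams(a_self=0.35, a_other=0.25, bias_pos=0.3,
                                     bias_neg=-0.2, beta0=1.8, tau=0.6,
                                     theta=0.15, beta_con=2.5))
        _, trace = mabc.session_loglik(canonical_session, params, spec)
        oracle = brute_force_trace(canonical_session, params, spec)
        np.testing.assert_allclose(trace.prior_pred_self, oracle["prior"],
                                   atol=1e-10)
        np.testing.assert_allclose(trace.posterior_self, oracle["post"],
                                   atol=1e-10)
        np.testing.assert_allclose(trace.beta_trial, oracle["beta"],
                                   atol=1e-10)
        np.testing.assert_allclose(trace.p_choose_right, oracle["p_right"],
                                   atol=1e-10)
        probes = np.isfinite(trace.p_report_self)
        np.testing.assert_allclose(trace.p_report_self[probes],
                                   oracle["p_rep"][probes], atol=1e-10)

    def test_flat_model_is_pure_chance(self, canonical_session):
        params = MABCParams(beta0=0.0 + 1e-300, beta_con=1e-300)
        ll, _ = mabc.session_loglik(
            canonical_session, MABCParams(beta0=0, beta_con=0), "flat")
        n_choices = len(canonical_session)
        n_probes = sum(r.probe == "CAUSALITY" for r in canonical_session.records)
        assert ll == pytest.approx((n_choices + n_probes) * np.log(0.5))

    def test_generating_params_beat_outcome_permuted_session(
            self, default_config, canonical_session):
        import copy
        ll_true, _ = mabc.session_loglik(canonical_session,
                                         mabc.CANONICAL_PARAMS, "mabc_full")
        rng = np.random.default_rng(0)
        shuffled = copy.deepcopy(canonical_session)
        perm = rng.permutation(len(shuffled))
        outcomes = [shuffled.records[i].outcome for i in perm]
        for rec, o in zip(shuffled.records, outcomes):
            rec.outcome = o
        ll_perm, _ = mabc.session_loglik(shuffled, mabc.CANONICAL_PARAMS,
                                         "mabc_full")
        assert ll_true > ll_perm

    def test_posterior_rises_in_self_blocks(self, default_config):
        # averaged over subjects, inferred controllability should be higher
        # in truly self-controllable blocks than in other-controllable ones
        diffs = []
        for seed in range(10):
            log = mabc.simulate_subject(default_config, mabc.CANONICAL_PARAMS,
                                        "mabc_full", seed=seed)
            _, trace = mabc.session_loglik(log, mabc.CANONICAL_PARAMS,
                                           "mabc_full")
            ctrl = log.schedule.controller.astype(bool)
            diffs.append(trace.posterior_self[ctrl].mean()
                         - trace.posterior_self[~ctrl].mean())
        assert np.mean(diffs) > 0.05

    def test_bias_nesting_is_bit_exact(self, canonical_session):
        base = MABCParams(bias_pos=0.0, bias_neg=0.0, tau=0.4, theta=0.2)
        ll_full, tr_full = mabc.session_loglik(canonical_session, base,
                                               "mabc_full")
        ll_nobias, tr_nobias = mabc.session_loglik(canonical_session, base,
                                                   "mabc_nobias")
        assert ll_full == ll_nobias
        assert np.array_equal(tr_full.posterior_self, tr_nobias.posterior_self)

    def test_theta_one_pins_predictions_at_half(self, canonical_session):
        params = MABCParams(theta=1.0 - 1e-12, tau=0.5)
        _, trace = mabc.session_loglik(canonical_session, params, "mabc_full")
        assert np.allclose(trace.prior_pred_self, 0.5, atol=1e-9)
        assert np.allclose(trace.beta_trial, params.beta0, atol=1e-6)

    def test_trace_csv_export(self, tmp_path, canonical_session):
        _, trace = mabc.session_loglik(canonical_session,
                                       mabc.CANONICAL_PARAMS, "mabc_full")
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns)[:4] == ["prior_pred_self", "likelihood_self",
                                           "likelihood_other", "posterior_self"]
        assert len(frame) == len(canonical_session)


class TestGenerativeMode:
    def test_seeded_simulation_reproducible(self, default_config):
        a = mabc.simulate_subject(default_config, mabc.CANONICAL_PARAMS,
                                  "mabc_full", seed=5)
        b = mabc.simulate_subject(default_config, mabc.CANONICAL_PARAMS,
                                  "mabc_full", seed=5)
        assert a.to_frame().equals(b.to_frame())

    def test_value_utilization_raises_late_optimality(self, default_config):
        # tau >> 0 subjects should exploit learned values in the second half
        # of self-controllable blocks more than tau = 0 subjects
        hi, lo = [], []
        for seed in range(12):
            p_hi = mabc.CANONICAL_PARAMS.replace(tau=1.2)
            p_lo = mabc.CANONICAL_PARAMS.replace(tau=0.0)
            s_hi = mabc.simulate_subject(default_config, p_hi, "mabc_full",
                                         seed=seed)
            s_lo = mabc.simulate_subject(default_config, p_lo, "mabc_full",
                                         seed=seed)
            hi.append(mabc.optimal_choice_stats(s_hi)["second_half"])
            lo.append(mabc.optimal_choice_stats(s_lo)["second_half"])
        assert np.mean(hi) > np.mean(lo)
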