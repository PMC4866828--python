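"""Trial-by-trial learning model: values, updates, likelihood, model zoo."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anticipation_rl import (
    MODEL_NAMES,
    QState,
    SubjectDataset,
    TrialRecord,
    builtin_design,
    make_model,
    outcome_value,
    q_update,
    read_trials,
    session_loglik,
    simulate_subject,
    trial_choice_prob,
    write_trials,
    FITTED_GROUP_MEANS,
)


def loop_loglik(dataset, params):
    """Independent likelihood oracle built from the scalar per-trial ops."""
    state = QState()
    ll = 0.0
    for rec in dataset.records:
        p_info = trial_choice_prob(state, params.sigma)
        ll += math.log(p_info if rec.choice == "info" else 1.0 - p_info)
        v = outcome_value(params, (rec.choice, rec.cue, rec.outcome), rec.delay_s)
        state = q_update(state, rec.choice, v, params.alpha)
    return ll


class TestOutcomeValue:
    def test_fitted_mean_values_at_long_delay(self, group_mean_params):
        # A+ and B+ from the closed-form oracles at T = 20 s
        v_info = outcome_value(group_mean_params, ("info", "reward_cue", "reward"), 20.0)
        assert v_info == pytest.approx(5.109 + 0.374, abs=2e-3)
        v_noinfo = outcome_value(group_mean_params, ("noinfo", "none", "reward"), 20.0)
        assert v_noinfo == pytest.approx(0.374, abs=1e-3)  # eta0 = 0: no credit

    def test_zero_delay_gives_outcome_magnitude(self, group_mean_params):
        assert outcome_value(
            group_mean_params, ("info", "reward_cue", "reward"), 0.0
        ) == pytest.approx(group_mean_params.r_plus)

    def test_dread_path_is_negative(self, group_mean_params):
        v = outcome_value(group_mean_params, ("info", "noreward_cue", "noreward"), 7.5)
        assert v < 0

    def test_inconsistent_event_rejected(self, group_mean_params):
        with pytest.raises(ValueError):
            outcome_value(group_mean_params, ("info", "none", "reward"), 1.0)
        with pytest.raises(ValueError):
            outcome_value(group_mean_params, ("info", "reward_cue", "noreward"), 1.0)


class TestQUpdate:
    @pytest.mark.parametrize(
        "q0,v,alpha,expected",
        [(0.0, 1.0, 0.17, 0.17), (0.3, 1.0, 1.0, 1.0), (0.3, 1.0, 0.0, 0.3)],
    )
    def test_delta_rule(self, q0, v, alpha, expected):
        out = q_update(QState(q_info=q0), "info", v, alpha)
        assert out.q_info == pytest.approx(expected)
        assert out.q_noinfo == 0.0

    def test_unchosen_target_untouched(self):
        out = q_update(QState(0.5, 0.7), "noinfo", 2.0, 0.5)
        assert out.q_info == 0.5
        assert out.q_noinfo == pytest.approx(1.35)


class TestChoiceProb:
    def test_indifference_and_logistic(self):
        assert trial_choice_prob(QState(), 1.0) == 0.5
        assert trial_choice_prob(QState(q_info=1.0), 1.0) == pytest.approx(
            1 / (1 + math.exp(-1))
        )

    def test_asymptotic_difference_is_mean_boosted_anticipation(self, group_mean_params):
        """With eta0 = 0 the expected long-run value difference between the
        targets is c*(A+ + A-)/2: only the boosted anticipation of the
        informative cues separates them."""
        from anticipation_rl import integrated_anticipation

        p = group_mean_params
        T = 20.0
        a_plus = integrated_anticipation(p.r_plus, p.nu_plus, p.gamma_plus, T)
        a_minus = integrated_anticipation(p.r_minus, p.nu_minus, p.gamma_minus, T)
        expected_dq = p.c * (a_plus + a_minus) / 2
        # expected V difference: info path averages (1*A+ + B+) and (1*A- + B-),
        # noinfo path averages (B+) and (B-); the difference is (A+ + A-)/2
        v_info = 0.5 * (
            outcome_value(p, ("info", "reward_cue", "reward"), T)
            + outcome_value(p, ("info", "noreward_cue", "noreward"), T)
        )
        v_noinfo = 0.5 * (
            outcome_value(p, ("noinfo", "none", "reward"), T)
            + outcome_value(p, ("noinfo", "none", "noreward"), T)
        )
        assert v_info - v_noinfo == pytest.approx(expected_dq, rel=1e-12)


class TestSessionLoglik:
    def test_matches_loop_oracle_on_simulated_sessions(self, group_mean_params):
        design = builtin_design("exp1")
        for seed in range(3):
            ds = simulate_subject(group_mean_params, design, seed=seed)
            fast = session_loglik(ds, group_mean_params)
            slow = loop_loglik(ds, group_mean_params)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_matches_loop_oracle_at_off_generative_parameters(self, group_mean_params):
        spec = make_model("boosted_full")
        ds = simulate_subject(group_mean_params, builtin_design("exp2"), seed=5)
        rng = np.random.default_rng(0)
        x0 = spec.vector_from_natural(group_mean_params)
        for _ in range(10):
            params = spec.natural_from_vector(x0 + 0.3 * rng.standard_normal(6))
            assert session_loglik(ds, params) == pytest.approx(
                loop_loglik(ds, params), abs=1e-9
            )

    def test_zero_learning_rate_gives_chance_likelihood(self, group_mean_params):
        spec = make_model("boosted_full")
        params = spec.params_from_values({**FITTED_GROUP_MEANS, "alpha": 0.0})
        ds = simulate_subject(group_mean_params, builtin_design("exp1"), seed=1)
        assert session_loglik(ds, params) == pytest.approx(
            ds.n_trials * math.log(0.5)
        )

    def test_each_trial_decreases_loglik(self, group_mean_params):
        ds = simulate_subject(group_mean_params, builtin_design("exp2"), seed=2)
        lls = [
            session_loglik(
                SubjectDataset(ds.subject_id, ds.records[:k]), group_mean_params
            )
            for k in range(ds.n_trials + 1)
        ]
        assert all(b < a for a, b in zip(lls, lls[1:]))

    def test_gradient_agreement_between_routes(self, group_mean_params):
        """Finite-difference gradients of the filtered likelihood and the
        per-trial loop oracle coincide, so the fast route is the same smooth
        function of the parameters."""
        spec = make_model("boosted_full")
        ds = simulate_subject(group_mean_params, builtin_design("exp2"), seed=7)
        x = spec.vector_from_natural(group_mean_params)
        h = 1e-5
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            g_fast = (
                session_loglik(ds, spec.natural_from_vector(x + e))
                - session_loglik(ds, spec.natural_from_vector(x - e))
            ) / (2 * h)
            g_slow = (
                loop_loglik(ds, spec.natural_from_vector(x + e))
                - loop_loglik(ds, spec.natural_from_vector(x - e))
            ) / (2 * h)
            assert g_fast == pytest.approx(g_slow, abs=1e-5)


class TestModelZoo:
    @pytest.mark.parametrize(
        "name,n_free",
        [
            ("q_learning", 3),
            ("q_learning_discount", 5),
            ("anticipation_no_boost", 7),
            ("boosted_no_rminus", 4),
            ("boosted_no_discount", 5),
            ("boosted_full", 6),
            ("boosted_asymmetric", 6),
        ],
    )
    def test_free_parameter_counts(self, name, n_free):
        assert make_model(name).n_free == n_free

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_model("deep_q_network")

    def test_restrictions_applied(self):
        p = make_model("q_learning").params_from_values(
            {"alpha": 0.2, "r_plus": 1.0, "r_minus": -0.5}
        )
        assert p.nu_plus == p.nu_minus == p.gamma_plus == p.gamma_minus == 0.0
        p2 = make_model("anticipation_no_boost").params_from_values(
            {"alpha": 0.2, "r_plus": 1.0, "r_minus": -0.5, "gamma": 0.05,
             "nu_plus": 0.1, "nu_minus": 0.2, "eta0": 0.7}
        )
        assert p2.c == 0.0 and p2.eta0 == 0.7
        assert p2.gamma_plus == p2.gamma_minus == 0.05

    def test_q_learning_value_is_undiscounted_outcome(self):
        p = make_model("q_learning").params_from_values(
            {"alpha": 0.2, "r_plus": 1.0, "r_minus": -0.5}
        )
        for T in (0.0, 2.5, 40.0):
            assert outcome_value(p, ("info", "reward_cue", "reward"), T) == 1.0
            assert outcome_value(p, ("noinfo", "none", "noreward"), T) == -0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        name=st.sampled_from(MODEL_NAMES),
        data=st.data(),
    )
    def test_transform_roundtrip(self, name, data):
        spec = make_model(name)
        x = np.array(
            [
                data.draw(st.floats(-4, 4), label=n)
                for n in spec.free_names
            ]
        )
        params = spec.natural_from_vector(x)
        back = spec.vector_from_natural(params)
        assert np.allclose(back, x, atol=1e-12)


class TestCsvInterchange:
    def test_roundtrip_identity(self, group_mean_params, tmp_path):
        ds = [
            simulate_subject(group_mean_params, builtin_design("exp1"), seed=s, subject_id=f"s{s}")
            for s in range(2)
        ]
        path = tmp_path / "trials.csv"
        write_trials(ds, path)
        back = read_trials(path)
        assert [d.records for d in back] == [d.records for d in ds]

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,trial_index,delay_s\ns0,0,2.5\n")
        with pytest.raises(ValueError, match="block_index"):
            read_trials(path)

    def test_invalid_records_listed(self):
        bad = SubjectDataset(
            "s0",
            [TrialRecord("s0", 0, 0, 2.5, "info", "none", "reward")],
        )
        with pytest.raises(ValueError, match="predictive cue"):
            bad.validate()
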