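"""Bayesian observer: conjugate oracles, closed forms, model invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obslearn import learner as lrn
from obslearn.task import TaskConfig, generate_session


def beta_mean_after(wins: int, losses: int) -> float:
    """Conjugate Beta-Bernoulli posterior mean from a uniform prior."""
    return (1 + wins) / (2 + wins + losses)


class TestBelief:
    def test_uniform_prior(self):
        b = lrn.init_belief(lrn.GridConfig(101, 21))
        np.testing.assert_allclose(b.mass, 1 / 2121)
        assert abs(b.posterior_mean_q - 0.5) < 1e-12

    def test_transition_identity_without_opportunity(self):
        b = lrn.init_belief()
        b2 = lrn.transition(b, at_reversal_opportunity=False)
        np.testing.assert_array_equal(b.mass, b2.mass)

    def test_transition_mixes_with_mirror(self):
        # v grid {0, 0.5, 1}: columns stay / symmetrize / mirror
        q = np.linspace(0, 1, 11)
        v = np.array([0.0, 0.5, 1.0])
        mass = np.zeros((11, 3))
        mass[8, :] = 1 / 3  # point mass at q=0.8 for every v
        b = lrn.BeliefState(q, v, mass)
        out = lrn.transition(b, True)
        col0 = out.mass[:, 0] / out.mass[:, 0].sum()
        col1 = out.mass[:, 1] / out.mass[:, 1].sum()
        col2 = out.mass[:, 2] / out.mass[:, 2].sum()
        assert col0[8] == pytest.approx(1.0)                 # v=0: unchanged
        assert col1[8] == col1[2] == pytest.approx(0.5)      # v=0.5: symmetric
        assert col2[2] == pytest.approx(1.0)                 # v=1: mirrored

    def test_single_win_matches_beta(self):
        b = lrn.update(lrn.init_belief(lrn.GridConfig(1001, 5)), "left", "win")
        assert abs(b.posterior_mean_q - beta_mean_after(1, 0)) < 1e-3

    def test_win_then_loss_returns_to_half(self):
        b = lrn.init_belief()
        b = lrn.update(b, "left", "win")
        b = lrn.update(b, "left", "lose")
        assert abs(b.posterior_mean_q - 0.5) < 1e-10

    def test_many_wins_approach_boundary(self):
        b = lrn.init_belief(lrn.GridConfig(201, 5))
        for _ in range(50):
            b = lrn.update(b, "left", "win")
        assert abs(b.posterior_mean_q - 51 / 52) < 5e-3

    def test_right_deck_loss_is_left_win_evidence(self):
        a = lrn.update(lrn.init_belief(), "left", "win")
        b = lrn.update(lrn.init_belief(), "right", "lose")
        np.testing.assert_allclose(a.mass, b.mass)

    @given(st.lists(st.booleans(), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_conjugate_oracle_any_sequence(self, outcomes):
        """Without transitions, the grid matches the Beta closed form."""
        b = lrn.init_belief(lrn.GridConfig(1001, 3))
        for win in outcomes:
            b = lrn.update(b, "left", "win" if win else "lose")
            assert abs(b.mass.sum() - 1.0) < 1e-10
        wins = sum(outcomes)
        expected = beta_mean_after(wins, len(outcomes) - wins)
        assert abs(b.posterior_mean_q - expected) < 1e-3


class TestClosedForms:
    def test_expected_value(self):
        b = lrn.init_belief()
        assert lrn.expected_value(b) == (0.5, 0.5)

    def test_entropy_values(self):
        assert lrn.choice_entropy((0.5, 0.5)) == pytest.approx(1.0)
        assert lrn.choice_entropy((1.0, 0.0)) == pytest.approx(0.0)
        assert lrn.choice_entropy((0.7, 0.3)) == pytest.approx(0.88129, abs=1e-5)

    def test_entropy_rejects_invalid(self):
        with pytest.raises(ValueError):
            lrn.choice_entropy((1.2, -0.2))

    def test_entropy_concave_peak_at_half(self):
        evs = np.linspace(0.01, 0.99, 99)
        ces = np.array([lrn.choice_entropy((p, 1 - p)) for p in evs])
        assert np.argmax(ces) == 49
        d2 = np.diff(ces, 2)
        assert np.all(d2 < 0)  # strictly concave

    def test_softmax_closed_form(self):
        p = lrn.choice_probability((0.7, 0.3), lrn.SoftmaxParams(tau=0.1))
        assert p == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-9)

    def test_softmax_symmetry_and_flat_limit(self):
        assert lrn.choice_probability((0.4, 0.4), lrn.SoftmaxParams(1.0)) == 0.5
        assert lrn.choice_probability((0.9, 0.1),
                                      lrn.SoftmaxParams(1e6)) == pytest.approx(0.5, abs=1e-5)

    def test_softmax_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            lrn.SoftmaxParams(tau=0.0)

    def test_prediction_error(self):
        assert lrn.prediction_error("win", 10.0, 1.0, "binary") == 0.0
        assert lrn.prediction_error("lose", -10.0, 0.7, "binary") == pytest.approx(-0.7)
        assert lrn.prediction_error("win", 100.0, 0.5, "amount",
                                    scale=55.0) == pytest.approx(72.5)
        with pytest.raises(ValueError):
            lrn.prediction_error("win", 10.0, 0.5, "exotic")


@pytest.fixture(scope="module")
def ev_trajectory():
    sessions = [generate_session(TaskConfig(), seed=10 + k) for k in range(4)]
    evs = []
    for s in sessions:
        out = lrn.run_model_on_session(s)
        evs.append(out[["ev1", "ev2"]].to_numpy())
    return np.vstack(evs)  # 720 trials


class TestTemperatureFit:
    def simulate_choices(self, tau, ev, rng):
        p = 1 / (1 + np.exp(-(ev[:, 0] - ev[:, 1]) / tau))
        return rng.random(len(ev)) < p

    def test_recovery(self, ev_trajectory, rng):
        choices = self.simulate_choices(0.2, ev_trajectory, rng)
        fit = lrn.fit_temperature(choices, ev_trajectory)
        assert abs(fit.tau - 0.2) / 0.2 < 0.2
        assert not fit.at_lower_bound and not fit.at_upper_bound

    def test_random_choices_flag_flat_likelihood(self, ev_trajectory, rng):
        choices = rng.random(len(ev_trajectory)) < 0.5
        fit = lrn.fit_temperature(choices, ev_trajectory)
        assert fit.at_upper_bound or fit.flat_likelihood

    def test_too_few_trials_rejected(self, ev_trajectory):
        with pytest.raises(ValueError):
            lrn.fit_temperature([True] * 5, ev_trajectory[:5])


class TestSessionRun:
    def test_first_trial_uninformed(self, session):
        out = lrn.run_model_on_session(session)
        assert out.chosen_ev.iloc[0] == pytest.approx(0.5)
        assert out.ce.iloc[0] == pytest.approx(1.0)

    def test_mirror_equivariance(self, session):
        out = lrn.run_model_on_session(session)
        flipped = session.trials.copy()
        flipped["chosen_deck"] = flipped.chosen_deck.map(
            {"left": "right", "right": "left"})
        out_m = lrn.run_model_on_session(flipped)
        np.testing.assert_allclose(out.ev1, out_m.ev2, atol=1e-12)
        np.testing.assert_allclose(out.ce, out_m.ce, atol=1e-12)
        np.testing.assert_allclose(out.chosen_ev, out_m.chosen_ev, atol=1e-12)

    def test_consistent_outcomes_push_ev_up(self):
        # hand-built 15-trial game: left deck always wins
        rows = []
        for i in range(15):
            rows.append({"subject_id": "s", "session_id": "s", "game": 1,
                         "round": i // 3 + 1, "trial_in_game": i + 1,
                         "player": ["self", "obs1", "obs2"][i % 3],
                         "chosen_deck": "left", "outcome": "win",
                         "amount": 10.0, "good_deck": "left",
                         "t_present": 6.0 * i, "t_choice": 6.0 * i + 1,
                         "t_outcome": 6.0 * i + 2, "t_offset": 6.0 * i + 5})
        out = lrn.run_model_on_session(pd.DataFrame(rows))
        assert out.ev1.is_monotonic_increasing
        assert out.ev1.iloc[-1] > 0.85

    def test_out_of_order_trials_rejected(self, session):
        shuffled = session.trials.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            lrn.run_model_on_session(shuffled)

    def test_normalization_preserved_each_trial(self, session):
        model = lrn.BayesianRevLearner(hazard_mode="per_trial")
        out = model.transform(session.trials)
        assert abs(model.final_belief_.mass.sum() - 1.0) < 1e-10
        assert ((out.ev1 + out.ev2 - 1.0).abs() < 1e-10).all()
        assert out.ce.between(0.0, 1.0).all()
        assert out.pe_binary.between(-1.0, 1.0).all()
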