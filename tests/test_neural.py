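"""Spike-train analysis: PSTH arithmetic, GLM recovery, cluster statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obslearn import neural as neu
from obslearn import synth


def make_rate_matrix(rates, times=None, unit_id="u", step=0.01):
    rates = np.asarray(rates, dtype=float)
    if times is None:
        times = -1.0 + np.arange(rates.shape[1]) * step
    return neu.RateMatrix(unit_id=unit_id, align_event="outcome",
                          times=np.asarray(times), rates=rates,
                          window=0.3, step=step,
                          trial_index=np.arange(rates.shape[0]))


class TestPSTH:
    def test_single_spike_rate(self):
        rm = neu.compute_psth(np.array([100.0]), np.array([100.0]))
        hit = rm.rates[0][rm.rates[0] > 0]
        np.testing.assert_allclose(hit, 1 / 0.3)
        # a 300 ms window stepped by 10 ms covers a spike in 30 bins
        assert hit.size == 30

    def test_bin_geometry(self):
        rm = neu.compute_psth(np.array([0.0]), np.array([0.0]),
                              span=(-3.0, 2.0), window=0.3, step=0.01)
        assert rm.times.size == int(np.floor((5.0 - 0.3) / 0.01)) + 1
        np.testing.assert_allclose(np.diff(rm.times), 0.01)
        assert rm.times[0] == pytest.approx(-2.85)

    def test_edge_spike_counted_once_per_bin(self):
        # spike exactly on a window edge: half-open [left, right) puts it
        # in the window whose left edge it is, not the one ending there
        rm = neu.compute_psth(np.array([10.30]), np.array([10.0]),
                              span=(-0.3, 0.6), window=0.3, step=0.3)
        np.testing.assert_allclose(rm.times, [-0.15, 0.15, 0.45])
        # 10.30 sits on the edge between [0, 0.3) and [0.3, 0.6)
        np.testing.assert_allclose(rm.rates[0], [0.0, 0.0, 1 / 0.3])

    def test_mass_conservation(self, rng):
        # spikes kept clear of the span edges: each then falls in exactly
        # window/step bins, so total rate mass equals the spike count
        spikes = np.sort(rng.uniform(2.5, 7.5, 200))
        rm = neu.compute_psth(spikes, np.array([5.0]), span=(-3.0, 3.0))
        expected = len(spikes) * (0.3 / 0.01)
        assert rm.rates.sum() * 0.3 == pytest.approx(expected)

    def test_homogeneous_rate_recovered(self, sim):
        model = synth.SpikeModel(unit_id="u", baseline_rate=2.0,
                                 coding_profile="null")
        st = synth.simulate_unit(model, sim.session, sim.learner_output, seed=21)
        rm = neu.compute_psth(st.times, sim.session.trials.t_outcome.to_numpy())
        mean_rate = rm.rates.mean()
        assert abs(mean_rate - 2.0) < 0.2

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            neu.compute_psth(np.array([1.0]), np.array([]))


class TestOutcomeSelection:
    def _unit(self, pre_rate, post_rate, n_trials, rng, noise=1.0):
        times = np.arange(-1.0, 1.0, 0.01)
        rates = np.where(times >= 0.0, post_rate, pre_rate) + \
            rng.normal(0, noise, (n_trials, times.size))
        return make_rate_matrix(rates, times)

    def test_responsive_unit_selected_via_t_test(self, rng):
        rm = self._unit(2.0, 6.0, 60, rng)
        sel = neu.select_outcome_responsive([rm])
        row = sel.table.iloc[0]
        assert row.crit1 and row.selected

    def test_flat_unit_not_selected(self, rng):
        rm = self._unit(2.0, 2.0, 60, rng)
        sel = neu.select_outcome_responsive([rm])
        assert not sel.table.iloc[0].selected

    def test_constant_unit_excluded(self):
        rm = make_rate_matrix(np.full((20, 200), 3.0))
        sel = neu.select_outcome_responsive([rm])
        assert sel.table.empty
        assert sel.excluded[0][1].startswith("zero-variance")

    def test_criterion1_null_calibration(self, rng):
        units = [self._unit(2.0, 2.0, 40, rng) for _ in range(300)]
        sel = neu.select_outcome_responsive(units)
        rate = sel.table.crit1.mean()
        # one-tailed alpha=0.01; allow 3 sigma of binomial noise
        assert rate < 0.01 + 3 * np.sqrt(0.01 * 0.99 / 300)


class TestEnvelope:
    def _step_units(self, n_units, amp, rng, onset=0.25, noise=0.0):
        times = np.arange(-3.0, 2.0, 0.01)
        course = 2.0 + amp * (times >= onset)
        rates = np.stack([
            np.tile(course + rng.normal(0, noise, times.size), (30, 1))
            for _ in range(n_units)])
        return [make_rate_matrix(r, times, unit_id=f"u{i}")
                for i, r in enumerate(rates)]

    def test_onset_of_noiseless_step(self, rng):
        env = neu.bootstrap_envelope(self._step_units(5, 4.0, rng),
                                     n_boot=200, rng=rng)
        # half-max of a step is reached at the step, up to smoothing bias
        assert abs(env.onset - 0.25) <= 0.06
        assert env.amplitude == pytest.approx(4.0, rel=0.1)

    def test_scale_equivariance(self, rng):
        units = self._step_units(5, 4.0, rng)
        doubled = [make_rate_matrix(rm.rates * 2, rm.times, rm.unit_id)
                   for rm in units]
        e1 = neu.bootstrap_envelope(units, n_boot=100, rng=np.random.default_rng(5))
        e2 = neu.bootstrap_envelope(doubled, n_boot=100, rng=np.random.default_rng(5))
        assert e2.amplitude == pytest.approx(2 * e1.amplitude, rel=1e-6)
        assert e2.onset == pytest.approx(e1.onset)

    def test_flat_units_flagged(self, rng):
        units = self._step_units(4, 0.0, rng, noise=0.05)
        env = neu.bootstrap_envelope(units, n_boot=100, rng=rng)
        assert env.amplitude_ci[0] <= 0.1
        assert env.n_flagged >= 0

    def test_too_few_units_rejected(self, rng):
        with pytest.raises(ValueError):
            neu.bootstrap_envelope(self._step_units(1, 1.0, rng))


class TestResponseDifference:
    def test_identical_rates_give_zero(self, rng):
        rates = np.tile(rng.normal(3, 0.5, 500), (40, 1))
        rm = make_rate_matrix(rates, np.arange(-3.0, 2.0, 0.01))
        labels = np.zeros(40, bool)
        labels[::2] = True
        res = neu.mean_response_difference([rm], [labels], n_boot=100, rng=rng)
        np.testing.assert_allclose(res.per_unit, 0.0, atol=1e-12)

    def test_label_swap_invariance(self, rng):
        rates = rng.normal(3, 1, (40, 500))
        rm = make_rate_matrix(rates, np.arange(-3.0, 2.0, 0.01))
        labels = np.zeros(40, bool)
        labels[:20] = True
        a = neu.mean_response_difference([rm], [labels], n_boot=50,
                                         rng=np.random.default_rng(1))
        b = neu.mean_response_difference([rm], [~labels], n_boot=50,
                                         rng=np.random.default_rng(1))
        np.testing.assert_allclose(a.per_unit, b.per_unit)

    def test_missing_label_rejected(self, rng):
        rm = make_rate_matrix(rng.normal(3, 1, (10, 500)),
                              np.arange(-3.0, 2.0, 0.01))
        with pytest.raises(ValueError):
            neu.mean_response_difference([rm], [np.ones(10, bool)])

    def test_correlation_of_duplicated_diffs(self, rng):
        diffs = rng.normal(0, 1, (30, 500))
        times = np.arange(-3.0, 2.0, 0.01)
        table = neu.response_difference_correlation(
            {"self": diffs, "observed": diffs.copy()}, times)
        assert table.iloc[0].r == pytest.approx(1.0)

    def test_correlation_needs_three_units(self, rng):
        diffs = rng.normal(0, 1, (2, 100))
        with pytest.raises(ValueError):
            neu.response_difference_correlation(
                {"a": diffs, "b": diffs}, np.arange(100) * 0.01)


class TestDesignMatrix:
    def test_shape_and_structure(self, sim):
        d = neu.build_design_matrix(sim.session.trials, sim.learner_output)
        assert d.X.shape == (180, 9)
        players = sim.session.trials.player.to_numpy()
        for k, role in enumerate(("self", "obs1", "obs2")):
            mask = players == role
            np.testing.assert_array_equal(d.X[mask, 3 * k], 1.0)
            # modulators are structural zeros outside their trial type
            np.testing.assert_array_equal(d.X[~mask, 3 * k + 1], 0.0)
            np.testing.assert_array_equal(d.X[~mask, 3 * k + 2], 0.0)
            # mean-centered within trial type
            assert abs(d.X[mask, 3 * k + 1].mean()) < 1e-12

    def test_contrast_algebra(self, sim):
        """The PE contrast equals the amount effect on pure amount coding."""
        d = neu.build_design_matrix(sim.session.trials, sim.learner_output)
        beta = np.zeros(9)
        beta[d.columns.index("obs1_amount")] = 1.7
        beta[d.columns.index("obs2_amount")] = 1.7
        assert d.contrasts["observed_pe"] @ beta == \
            d.contrasts["observed_amount"] @ beta == pytest.approx(3.4)

    def test_missing_ev_rejected(self, sim):
        bad = sim.learner_output.copy()
        bad.loc[5, "chosen_ev"] = np.nan
        with pytest.raises(ValueError):
            neu.build_design_matrix(sim.session.trials, bad)


@pytest.fixture(scope="module")
def fitted(sim):
    model = synth.SpikeModel(
        unit_id="trip", baseline_rate=2.28, coding_profile="tripartite_PE",
        betas=synth.DEFAULT_BETAS["tripartite_PE"], response_gain=1.0)
    st = synth.simulate_unit(model, sim.session, sim.learner_output, seed=77)
    rm = neu.compute_psth(st.times, sim.session.trials.t_outcome.to_numpy(),
                          unit_id="trip")
    design = neu.build_design_matrix(sim.session.trials, sim.learner_output)
    return rm, design, neu.fit_sliding_glm(rm, design)


class TestSlidingGLM:
    def test_planted_signs_recovered(self, fitted):
        _, _, g = fitted
        post = (g.times >= 0.3) & (g.times < 0.9)
        assert g.contrast_t["observed_amount"][post].mean() > 1.0
        assert g.contrast_t["observed_ev"][post].mean() < -1.0

    def test_null_unit_t_is_student(self, sim, rng):
        model = synth.SpikeModel(unit_id="null", baseline_rate=2.0,
                                 coding_profile="null")
        st = synth.simulate_unit(model, sim.session, sim.learner_output, seed=88)
        rm = neu.compute_psth(st.times, sim.session.trials.t_outcome.to_numpy())
        design = neu.build_design_matrix(sim.session.trials, sim.learner_output)
        g = neu.fit_sliding_glm(rm, design)
        # thin to ~independent bins (300 ms window -> every 30th bin)
        t_vals = g.contrast_t["observed_amount"][::30]
        _, p = stats.kstest(t_vals, stats.t(df=g.dof).cdf)
        assert p > 0.01

    def test_duplicated_regressor_rejected(self, fitted):
        rm, design, _ = fitted
        X = design.X.copy()
        X[:, 2] = X[:, 1]
        bad = neu.DesignMatrix(X=X, columns=design.columns,
                               contrasts=design.contrasts,
                               trial_index=design.trial_index)
        with pytest.raises(ValueError, match="collinear"):
            neu.fit_sliding_glm(rm, bad)


class TestClusterStatistics:
    def brute_force_masses(self, course, thr):
        masses = []
        run = []
        for v in list(course) + [0.0]:
            if v > thr:
                if run and run[-1] < 0:
                    masses.append(sum(run)); run = []
                run.append(v)
            elif v < -thr:
                if run and run[-1] > 0:
                    masses.append(sum(run)); run = []
                run.append(v)
            else:
                if run:
                    masses.append(sum(run)); run = []
        return sorted(masses)

    def test_cluster_masses_match_brute_force(self, rng):
        for _ in range(20):
            course = rng.normal(0, 0.4, 100)
            found = sorted(c.mass for c in neu.find_clusters(course, 0.2))
            np.testing.assert_allclose(found, self.brute_force_masses(course, 0.2))

    def test_constant_course_single_cluster(self):
        course = np.ones(17)
        clusters = neu.find_clusters(course, 0.2)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(17.0)

    def test_subthreshold_course_no_clusters(self):
        assert neu.find_clusters(np.zeros(50), 0.2) == []

    def test_planted_effect_detected(self, rng):
        bins = 120
        pool = rng.normal(0, 1, (30, 50, bins))
        observed = rng.normal(0, 1, (15, bins))
        observed[:, 40:70] += 1.5  # strong shared positive effect
        res = neu.cluster_permutation_test(observed, pool,
                                           times=np.arange(bins) * 0.01,
                                           n_shuffle=500, rng=rng)
        assert res.significant_positive
        assert not res.significant_negative

    def test_small_shuffle_count_warns(self, rng):
        pool = rng.normal(0, 1, (10, 10, 50))
        with pytest.warns(UserWarning):
            neu.cluster_permutation_test(rng.normal(0, 1, (5, 50)), pool,
                                         times=np.arange(50) * 0.01,
                                         n_shuffle=50, rng=rng)


class TestPEChecks:
    def _pe_unit(self, gain, rng, n_trials=120):
        times = np.arange(-1.0, 1.5, 0.01)
        pe = rng.uniform(-1, 1, n_trials)
        rates = 3.0 + rng.normal(0, 1.0, (n_trials, times.size))
        bump = (times >= 0.3) & (times < 0.9)
        rates[:, bump] += gain * pe[:, None]
        return make_rate_matrix(rates, times), pe

    def test_quartile_check_positive_control(self, rng):
        rm, pe = self._pe_unit(4.0, rng)
        assert neu.quartile_pe_check(rm, pe)

    def test_quartile_check_constant_pe_rejected(self, rng):
        rm, _ = self._pe_unit(0.0, rng)
        with pytest.raises(ValueError):
            neu.quartile_pe_check(rm, np.zeros(rm.rates.shape[0]))

    def test_quartile_population_null_rate(self, rng):
        units = [self._pe_unit(0.0, rng, 60) for _ in range(20)]
        flags = [neu.quartile_pe_check(rm, pe) for rm, pe in units]
        res = neu.quartile_population_test(
            np.array(flags), rates=[u[0] for u in units],
            pes=[u[1] for u in units], n_null=20, rng=rng)
        assert res["p"] > 0.01  # null population is not called significant

    def test_tercile_monotone_positive_control(self, rng):
        rm, pe = self._pe_unit(6.0, rng)
        res = neu.pe_tercile_summary(rm, pe)
        assert res["monotone_increasing"]

    def test_tercile_constant_rate_equal_means(self):
        rm = make_rate_matrix(np.full((30, 250), 2.0),
                              np.arange(-1.0, 1.5, 0.01))
        res = neu.pe_tercile_summary(rm, np.linspace(-1, 1, 30))
        assert res["tercile_means"][0] == pytest.approx(res["tercile_means"][2])


class TestModelFree:
    def test_round3_never_classified(self, sim, rng):
        trials = sim.session.trials
        times = np.arange(-1.0, 1.5, 0.01)
        rates = rng.normal(3, 1, (len(trials), times.size))
        rm = make_rate_matrix(rates, times)
        # zeroing round-3 rates must not change the early/late differences
        rates3 = rates.copy()
        rates3[(trials["round"] == 3).to_numpy()] = 0.0
        rm3 = make_rate_matrix(rates3, times)
        a = neu.model_free_early_late([rm], [trials])
        b = neu.model_free_early_late([rm3], [trials])
        pd.testing.assert_frame_equal(a, b)

    def test_planted_observational_pe_direction(self, sim, rng):
        """Early (less expected) observed wins fire above late ones."""
        trials = sim.session.trials
        times = np.arange(-1.0, 1.5, 0.01)
        is_obs_win = ((trials.player != "self") &
                      (trials.outcome == "win")).to_numpy()
        early = trials["round"].isin([1, 2]).to_numpy()
        rates = 3.0 + rng.normal(0, 0.5, (len(trials), times.size))
        resp = (times >= 0.3) & (times < 0.9)
        rates[np.ix_(is_obs_win & early, np.flatnonzero(resp))] += 3.0
        rm = make_rate_matrix(rates, times)
        table = neu.model_free_early_late([rm], [trials])
        t = table.set_index("player_class")
        assert t.loc["observed", "early_minus_late"] > 1.0
        assert abs(t.loc["self", "early_minus_late"]) < 1.0
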