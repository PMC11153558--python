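"""Population pooling, ROC decoding, choice probability, geometry and
engagement modulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import whiskpop as wp
import whiskpop.population as pop
from whiskpop.exceptions import InputError


def _pool(weights):
    w = np.asarray(weights, dtype=float)
    return pop.Pool("p", np.arange(len(w)), w)


def _weights_df(bf1, bf2):
    return pd.DataFrame({"beta_f1": bf1, "beta_f2": bf2})


class TestPools:
    def test_assignment_by_strict_preference(self):
        df = _weights_df([0.4, 0.1, 0.2], [0.1, 0.3, 0.2])
        p1, p2 = pop.assign_pools(df, "beta_f1", "beta_f2")
        assert list(p1.members) == [0]
        assert list(p2.members) == [1]          # tie (index 2) excluded

    def test_partition_bound(self, rng):
        df = _weights_df(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        p1, p2 = pop.assign_pools(df, "beta_f1", "beta_f2")
        assert len(p1) + len(p2) <= 200
        assert set(p1.members).isdisjoint(p2.members)

    def test_empty_pool_warns(self):
        df = _weights_df([1.0, 2.0], [0.0, 0.0])
        with pytest.warns(UserWarning):
            pop.assign_pools(df, "beta_f2", "beta_f1")


class TestPoolSignal:
    def test_single_positive_member_identity(self, rng):
        act = rng.normal(0, 1, (1, 30))
        np.testing.assert_allclose(pop.pool_signal(act, _pool([0.7])), act[0])

    def test_single_negative_member_sign_flip(self, rng):
        act = rng.normal(0, 1, (1, 30))
        np.testing.assert_allclose(pop.pool_signal(act, _pool([-0.7])),
                                   -act[0])

    def test_matches_direct_formula(self, rng):
        act = rng.normal(0, 1, (5, 40))
        w = rng.normal(0, 1, 5)
        got = pop.pool_signal(act, _pool(w))
        expected = np.array([                 # brute-force re-computation
            sum(w[n] * act[n, t] for n in range(5)) / sum(abs(x) for x in w)
            for t in range(40)])
        np.testing.assert_allclose(got, expected)

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(0.1, 10))
    def test_linearity_in_activity(self, c):
        rng = np.random.default_rng(7)
        act = rng.normal(0, 1, (4, 20))
        w = rng.normal(0, 1, 4)
        np.testing.assert_allclose(pop.pool_signal(c * act, _pool(w)),
                                   c * pop.pool_signal(act, _pool(w)),
                                   rtol=1e-9)

    def test_member_permutation_invariance(self, rng):
        act = rng.normal(0, 1, (6, 15))
        w = rng.normal(0, 1, 6)
        perm = rng.permutation(6)
        a = pop.pool_signal(act, pop.Pool("p", np.arange(6), w))
        b = pop.pool_signal(act, pop.Pool("p", perm, w[perm]))
        np.testing.assert_allclose(a, b)


class TestRocThreshold:
    def test_perfect_separation(self):
        sig = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        lab = np.array([False, False, False, True, True, True])
        auc, thr = pop.roc_threshold(sig, lab)
        assert auc == 1.0
        assert 3.0 < thr < 10.0

    def test_identical_distributions_chance(self, rng):
        sig = rng.normal(0, 1, 2000)
        lab = rng.random(2000) < 0.5
        auc, _ = pop.roc_threshold(sig, lab)
        assert abs(auc - 0.5) < 0.05

    def test_auc_equals_pairwise_count_oracle(self, rng):
        for _ in range(20):
            sig = rng.integers(0, 5, 10).astype(float)   # ties included
            lab = rng.random(10) < 0.5
            if lab.all() or not lab.any():
                continue
            auc, _ = pop.roc_threshold(sig, lab)
            wins = ties = 0
            for a in sig[lab]:
                for b in sig[~lab]:
                    wins += a > b
                    ties += a == b
            expected = (wins + 0.5 * ties) / (lab.sum() * (~lab).sum())
            assert auc == pytest.approx(expected)

    def test_complement_symmetry(self, rng):
        sig = rng.normal(0, 1, 100)          # continuous: tie-free
        lab = rng.random(100) < 0.4
        a1, _ = pop.roc_threshold(sig, lab)
        a2, _ = pop.roc_threshold(-sig, lab)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            pop.roc_threshold(np.arange(5.0), np.ones(5, bool))


class TestDecoding:
    def test_all_above_threshold(self):
        fc, _ = pop.decode_labels(np.arange(1.0, 5.0), 0.0,
                                  np.ones(4, bool))
        assert fc == 1.0

    def test_shuffled_labels_chance(self, rng):
        sig = rng.normal(0, 1, 4000)
        lab = rng.random(4000) < 0.5
        fc, _ = pop.decode_labels(sig, 0.0, lab)
        assert abs(fc - 0.5) < 0.03

    def test_curve_by_delta_f(self, rng):
        sig = np.array([1.0, 1.0, -1.0])
        _, curve = pop.decode_labels(sig, 0.0, np.ones(3, bool),
                                     delta_f=np.array([10.0, 10.0, -10.0]))
        assert curve.set_index("delta_f_hz").loc[10.0, "p_decoded_1"] == 1.0
        assert curve.set_index("delta_f_hz").loc[-10.0, "p_decoded_1"] == 0.0


class TestNeurometric:
    def _trials(self, n, rng):
        df = rng.choice(np.linspace(-90, 90, 9), n)
        return pd.DataFrame({"delta_f_hz": df,
                             "F1_hz": 45 + df / 2, "F2_hz": 45 - df / 2})

    def test_noiseless_signal_steplike(self, rng):
        trials = self._trials(900, rng)
        sig = trials["delta_f_hz"].to_numpy()
        fit, curve, thr = pop.neurometric_curve(sig, trials)
        assert fit.lapse < 0.02 and fit.gamma < 0.02
        assert abs(thr) < 25.0

    def test_uninformative_signal_flat(self, rng):
        trials = self._trials(900, rng)
        sig = rng.normal(0, 1, 900)
        fit, curve, _ = pop.neurometric_curve(sig, trials)
        # the decoded fraction carries no stimulus dependence: flat curve
        p = curve["p_decoded_1"]
        assert p.max() - p.min() < 0.12
        assert fit.max_slope_per_hz < 0.004

    def test_neurometric_outperforms_behavior_with_full_pools(
            self, default_session):
        """Pooling every neuron yields a steeper neurometric than the
        psychometric (the generator's single-trial noise is sub-behavioural)."""
        from whiskpop.behavior import fit_psychometric_trials
        from whiskpop.pipeline import session_analysis
        b = default_session
        an = session_analysis(b)
        diff = (pop.pool_signal(b.epoch_rates["stimulus"], an["pools"]["w1"])
                - pop.pool_signal(b.epoch_rates["stimulus"], an["pools"]["w2"]))
        nfit, _, _ = pop.neurometric_curve(diff, b.trials)
        pfit = fit_psychometric_trials(b.trials)
        assert nfit.max_slope_per_hz >= pfit.max_slope_per_hz

    def test_near_zero_threshold_symmetric_session(self):
        cfg = wp.GeneratorConfig.symmetric(n_neurons=150, n_trials=2000,
                                           include_rate_bins=False,
                                           include_markers=False, seed=5)
        b = wp.generate_session(cfg)
        from whiskpop.pipeline import session_analysis
        an = session_analysis(b)
        ev = b.epoch_rates["stimulus"] - b.epoch_rates["baseline"]
        diff = (pop.pool_signal(ev, an["pools"]["w1"])
                - pop.pool_signal(ev, an["pools"]["w2"]))
        df = b.trials["delta_f_hz"].to_numpy()
        _, thr = pop.roc_threshold(diff[df != 0], df[df != 0] > 0)
        assert abs(thr) < 0.1


class TestNeuronsNeeded:
    def _trials(self, n, rng):
        df = rng.choice([-45.0, 45.0], n)
        return pd.DataFrame({"delta_f_hz": df, "F1_hz": 45 + df / 2,
                             "F2_hz": 45 - df / 2})

    def test_perfect_neuron_needs_one(self, rng):
        trials = self._trials(200, rng)
        act = np.vstack([trials["delta_f_hz"].to_numpy(),
                         -trials["delta_f_hz"].to_numpy()])
        pools = [pop.Pool("w1", np.array([0]), np.array([1.0])),
                 pop.Pool("w2", np.array([1]), np.array([1.0]))]
        k, _, reached = pop.neurons_needed(act, pools, trials, 0.9,
                                           repeats=5)
        assert k == 1 and reached

    def test_noise_population_flagged(self, rng):
        trials = self._trials(200, rng)
        act = rng.normal(0, 1, (10, 200))
        pools = [pop.Pool("w1", np.arange(5), rng.normal(0, 1, 5)),
                 pop.Pool("w2", np.arange(5, 10), rng.normal(0, 1, 5))]
        k, table, reached = pop.neurons_needed(act, pools, trials, 0.95,
                                               repeats=10)
        assert not reached and k == 5

    def test_subsample_variance_decreases(self, small_session):
        from whiskpop.pipeline import session_analysis
        b = small_session
        an = session_analysis(b)
        ev = b.epoch_rates["stimulus"] - b.epoch_rates["baseline"]
        _, table, _ = pop.neurons_needed(
            ev, [an["pools"]["w1"], an["pools"]["w2"]], b.trials,
            behavioral_fc=2.0, k_max=12, repeats=40)   # unreachable: full scan
        assert table["sd_fc"].iloc[-1] < table["sd_fc"].iloc[0]


class TestNeuronAuroc:
    def test_null_rates_not_significant(self, rng):
        rates = rng.normal(0, 1, (30, 80))
        out = pop.neuron_auroc(rates, rng.random(80) < 0.5,
                               n_permutations=200)
        assert (np.abs(out["auroc"] - 0.5) < 0.25).all()
        assert out["significant"].mean() < 0.2

    def test_sign_convention(self):
        # rate strictly higher on every class-2 trial -> AUROC 1 under the
        # preferred-side convention
        rates = np.concatenate([np.zeros(10), np.ones(10)])[None, :]
        label2 = np.arange(20) >= 10
        out = pop.neuron_auroc(rates, label2, n_permutations=50)
        assert out.loc[0, "auroc"] == 1.0

    def test_matches_exhaustive_pair_count(self, rng):
        rates = rng.integers(0, 4, (3, 8)).astype(float)
        label2 = np.array([0, 1, 0, 1, 0, 1, 0, 1], bool)
        out = pop.neuron_auroc(rates, label2, n_permutations=10, seed=0)
        for n in range(3):
            wins = ties = 0
            for a in rates[n, label2]:
                for b in rates[n, ~label2]:
                    wins += a > b
                    ties += a == b
            expected = (wins + 0.5 * ties) / 16.0
            assert out.loc[n, "auroc"] == pytest.approx(expected)

    def test_bootstrap_mode_runs(self, rng):
        rates = rng.normal(0, 1, (5, 60))
        rates[0] += np.where(rng.random(60) < 0.5, 0, 3)
        out = pop.neuron_auroc(rates, rng.random(60) < 0.5,
                               n_permutations=100, method="bootstrap")
        assert set(out.columns) >= {"auroc", "significant"}


class TestMatching:
    def test_equal_counts_per_condition(self, rng):
        trials = pd.DataFrame({
            "F1_hz": rng.choice([45.0, 90.0], 300),
            "F2_hz": rng.choice([22.5, 67.5], 300)})
        group2 = rng.random(300) < 0.3
        idx = pop.stimulus_matched_subset(trials, group2, seed=0)
        sub = trials.iloc[idx]
        g = group2[idx]
        for c, grp in sub.groupby(["F1_hz", "F2_hz"]):
            pos = sub.index.get_indexer(grp.index)
            assert g[pos].sum() * 2 == len(grp)


class TestGeometry:
    def test_vertical_arrow_is_ninety(self):
        x = np.zeros(20) + np.linspace(-0.01, 0.01, 20)
        y = np.concatenate([np.zeros(10), np.ones(10)])
        res = pop.representational_angle(x, y, np.arange(20) >= 10,
                                         match_conditions=False,
                                         standardize=False)
        assert res.theta_deg == pytest.approx(90.0, abs=1.0)

    def test_horizontal_arrow_is_zero(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.zeros(20) + np.linspace(-0.01, 0.01, 20)
        res = pop.representational_angle(x, y, np.arange(20) >= 10,
                                         match_conditions=False,
                                         standardize=False)
        assert min(res.theta_deg, 180 - res.theta_deg) < 1.0

    def test_group_swap_invariance(self, rng):
        x, y = rng.normal(0, 1, (2, 40))
        g = rng.random(40) < 0.5
        a = pop.representational_angle(x, y, g, match_conditions=False)
        b = pop.representational_angle(x, y, ~g, match_conditions=False)
        assert a.theta_deg == pytest.approx(b.theta_deg)

    def test_axis_rescaling_invariance_after_standardization(self, rng):
        x, y = rng.normal(0, 1, (2, 60))
        g = rng.random(60) < 0.5
        a = pop.representational_angle(x, y, g, match_conditions=False)
        b = pop.representational_angle(5 * x, 0.2 * y, g,
                                       match_conditions=False)
        assert a.theta_deg == pytest.approx(b.theta_deg)

    def test_degenerate_arrow_flagged(self):
        x = np.tile([0.0, 1.0], 10)
        res = pop.representational_angle(x, x, np.arange(20) < 10,
                                         match_conditions=False,
                                         standardize=False)
        assert res.degenerate and np.isnan(res.theta_deg)

    def test_too_few_trials_per_group(self):
        with pytest.raises(InputError):
            pop.representational_angle(np.arange(8.0), np.arange(8.0),
                                       np.arange(8) < 2,
                                       match_conditions=False)

    def test_condition_breakdown_inclusion_rule(self, rng):
        trials = pd.DataFrame({"F1_hz": np.repeat([45.0, 90.0], 50),
                               "F2_hz": np.repeat([22.5, 0.0], 50)})
        g = np.zeros(100, bool)
        g[:3] = True            # first condition: only 3 group-2 trials
        g[50:75] = True
        out = pop.condition_angles(rng.normal(0, 1, 100),
                                   rng.normal(0, 1, 100), g, trials)
        assert len(out) == 1    # under-populated condition omitted


class TestEngagement:
    def _trials(self, n, rng):
        f1 = rng.choice([22.5, 67.5], n)
        return pd.DataFrame({"F1_hz": f1, "F2_hz": 90 - f1,
                             "delta_f_hz": 2 * f1 - 90})

    def test_identical_states_zero(self, rng):
        trials = self._trials(200, rng)
        engaged = np.arange(200) < 100
        act = np.tile(rng.normal(2, 0.01, (4, 1)), (1, 200))
        rates = {"baseline": np.ones((4, 200)), "stimulus": act}
        mod = pop.engagement_ratio(rates, _pool(np.ones(4)), engaged, trials)
        assert abs(mod) < 2.0

    def test_constructed_gain_recovered(self, rng):
        trials = self._trials(400, rng)
        engaged = np.arange(400) < 200
        evoked = np.tile(rng.uniform(1, 2, (6, 1)), (1, 400))
        evoked[:, engaged] *= 1.25
        rates = {"baseline": np.zeros((6, 400)), "stimulus": evoked}
        mod = pop.engagement_ratio(rates, _pool(np.ones(6)), engaged, trials)
        assert mod == pytest.approx(25.0, abs=1.0)

    def test_default_generator_sign_pattern(self, default_session):
        from whiskpop.pipeline import engagement_modulation
        mods = engagement_modulation(default_session, seed=0)
        assert mods["w1"] > 0 and mods["w2"] > 0 and mods["w1xw2"] < 0

    def test_profile_binning(self, default_session):
        b = default_session
        w = b.truth.weights["beta_f1"].to_numpy()
        prof = pop.engagement_profile(b.epoch_rates, w, b.truth.engaged,
                                      b.trials)
        assert len(prof) == 10
        assert prof["weight_mean"].is_monotonic_increasing


class TestChoiceTimecourse:
    def test_choice_information_appears_after_stimulus(self, small_session):
        b = small_session
        tc = pop.choice_decode_timecourse(b.rate_bins, b.trials,
                                          b.epoch_rates, cv_folds=5, seed=0)
        t = b.bin_time_s
        fc = tc["fraction_correct"].to_numpy()
        assert abs(fc[t < 1.0].mean() - 0.5) < 0.1
        assert fc[t > 2.5].mean() > 0.75
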