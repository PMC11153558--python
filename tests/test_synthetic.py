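"""Generator unit tests: determinism, calibration, firing-rate structure,
choice behaviour, fluorescence synthesis and marker streams."""

import numpy as np
import pandas as pd
import pytest

import whiskpop as wp
from whiskpop.config import antidiagonal_pairs, grid_pairs
from whiskpop.exceptions import ConfigurationError, InputError
from whiskpop.synthetic import (GroundTruth, generate_session,
                                psychometric_curve, sample_neuron_weights,
                                simulate_choices, simulate_firing_rates,
                                simulate_trials, sparse_trace_bundle,
                                synthesize_fluorescence, weight_correlations)


def _rates_cfg(**kw):
    base = dict(n_neurons=4, n_trials=50, include_rate_bins=False,
                include_markers=False)
    base.update(kw)
    return wp.GeneratorConfig(**base)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            wp.GeneratorConfig(prestim_fraction=0.7, impulsive_fraction=0.7)
        with pytest.raises(ValueError):
            wp.GeneratorConfig(frac_activated=0.8, frac_suppressed=0.5)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            wp.GeneratorConfig(stimulus_set=[(-1.0, 10.0)])

    def test_alpha_range_must_lie_in_clamp(self):
        with pytest.raises(ValueError):
            wp.GeneratorConfig(alpha_range=(0.4, 0.8))

    def test_symmetric_constructor(self):
        cfg = wp.GeneratorConfig.symmetric()
        assert cfg.symmetric_pools
        m = cfg.engagement_modulation_pct
        assert m[0] == m[1]

    def test_stimulus_helpers(self):
        assert len(antidiagonal_pairs()) == 9
        assert all(a + b == 90 for a, b in antidiagonal_pairs())
        assert (0.0, 0.0) not in grid_pairs()


class TestDeterminismAndShape:
    def test_same_seed_bitwise_identical(self):
        cfg = wp.GeneratorConfig(n_neurons=20, n_trials=40, seed=1)
        a, b = generate_session(cfg), generate_session(cfg)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.truth.weights, b.truth.weights)
        for key in a.epoch_rates:
            np.testing.assert_array_equal(a.epoch_rates[key],
                                          b.epoch_rates[key])
        np.testing.assert_array_equal(a.rate_bins, b.rate_bins)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_zero_trials_degenerate(self):
        cfg = wp.GeneratorConfig(n_neurons=10, n_trials=0)
        b = generate_session(cfg)
        assert len(b.trials) == 0
        assert b.epoch_rates["stimulus"].shape == (10, 0)

    def test_bundle_dimensions_consistent(self, small_session):
        b = small_session
        n, t = b.config.n_neurons, b.config.n_trials
        assert b.epoch_rates["baseline"].shape == (n, t)
        assert b.rate_bins.shape == (n, t, b.config.n_bins)
        assert len(b.markers) == t * b.config.n_bins
        assert len(b.truth.alpha) == n


class TestWeightSampling:
    def test_correlation_calibration(self):
        cfg = wp.GeneratorConfig(n_neurons=5000, n_trials=0)
        w = sample_neuron_weights(cfg)
        c = weight_correlations(w)
        assert abs(c["pearson_f1_f2"] - 0.55) < 0.05
        assert abs(c["spearman_f1_f1x2"] - (-0.65)) < 0.05
        assert abs(c["spearman_f2_f1x2"] - (-0.62)) < 0.05

    def test_response_class_fractions(self):
        cfg = wp.GeneratorConfig(n_neurons=5000, n_trials=0)
        w = sample_neuron_weights(cfg)
        frac = w["response_class"].value_counts(normalize=True)
        assert abs(frac["activated"] - 0.523) < 0.03
        assert abs(frac["suppressed"] - 0.323) < 0.03

    def test_zero_targets_give_independence(self):
        from scipy import stats
        cfg = wp.GeneratorConfig(n_neurons=10000, n_trials=0, corr_f1_f2=0.0,
                                 corr_f1_f1x2=0.0, corr_f2_f1x2=0.0)
        w = sample_neuron_weights(cfg)
        bound = 3.0 / np.sqrt(len(w))
        # rank correlations have the nominal 1/sqrt(n) sampling error; the
        # heavy-tailed marginals inflate the Pearson one
        for a, b in (("beta_f1", "beta_f2"), ("beta_f1", "beta_f1xf2"),
                     ("beta_f2", "beta_f1xf2")):
            assert abs(stats.spearmanr(w[a], w[b])[0]) < bound + 0.02
        assert abs(stats.pearsonr(w["beta_f1"], w["beta_f2"])[0]) < 0.06

    def test_tiny_population_flagged_not_crashing(self):
        cfg = wp.GeneratorConfig(n_neurons=2, n_trials=0)
        c = weight_correlations(sample_neuron_weights(cfg))
        assert np.isnan(c["pearson_f1_f2"])

    def test_infeasible_correlations_raise(self):
        cfg = wp.GeneratorConfig(n_neurons=10, n_trials=0, corr_f1_f2=-0.95,
                                 corr_f1_f1x2=-0.95, corr_f2_f1x2=-0.95)
        with pytest.raises(ConfigurationError, match="pair"):
            sample_neuron_weights(cfg)

    def test_choice_weights_independent_of_sensory(self):
        cfg = wp.GeneratorConfig(n_neurons=4000, n_trials=0)
        w = sample_neuron_weights(cfg)
        for col in ("beta_c1", "beta_c2", "beta_eng"):
            r = np.corrcoef(w["beta_f1"], w[col])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(4000) + 0.03

    def test_symmetric_pools_mirror(self):
        cfg = wp.GeneratorConfig(n_neurons=50, n_trials=0,
                                 symmetric_pools=True)
        w = sample_neuron_weights(cfg)
        assert len(w) == 100
        np.testing.assert_allclose(w["beta_f1"][:50], w["beta_f2"][50:])


class TestFiringRates:
    def _truth(self, cfg, weights):
        n_tr = cfg.n_trials
        return GroundTruth(weights=weights, alpha=np.full(len(weights), 0.7),
                           positions=np.zeros((len(weights), 2)),
                           column_centers=np.array([[150., 0.], [-150., 0.]]),
                           engaged=np.ones(n_tr, dtype=bool),
                           psychometric=cfg.psychometric,
                           gain_coef=np.zeros(3))

    def test_sqrt_rule_stimulus_difference(self):
        # betaF1 = 1, all else 0: F1 = 81 vs 0 must differ by exactly sqrt(81)
        cfg = _rates_cfg(n_neurons=1, n_trials=2, noise_sd=0.0,
                         stimulus_set=[(81.0, 0.0), (0.0, 0.0)],
                         disengaged_fraction=0.0)
        w = pd.DataFrame({"beta0": [5.0], "beta_f1": [1.0], "beta_f2": [0.0],
                          "beta_f1xf2": [0.0], "beta_c1": [0.0],
                          "beta_c2": [0.0], "beta_eng": [0.0],
                          "eng_gain": [0.0]})
        trials = pd.DataFrame({
            "trial_index": [0, 1], "F1_hz": [81.0, 0.0], "F2_hz": [0.0, 0.0],
            "delta_f_hz": [81.0, 0.0], "choice": ["none", "none"],
            "correct": [np.nan, np.nan], "engaged": [1, 1],
            "trial_category": ["delayed"] * 2, "opto": ["none"] * 2,
            "reaction_time_s": [np.nan] * 2, "t_start_s": [0.0, 4.0]})
        truth = self._truth(cfg, w)
        epoch, _, _ = simulate_firing_rates(truth, trials, cfg,
                                            np.random.default_rng(0),
                                            include_bins=False)
        diff = epoch["stimulus"][0, 0] - epoch["stimulus"][0, 1]
        assert diff == pytest.approx(9.0, abs=1e-9)

    def test_engagement_weight_shifts_whole_trial(self):
        cfg = _rates_cfg(n_neurons=1, n_trials=10, noise_sd=0.0,
                         disengaged_fraction=0.5)
        w = pd.DataFrame({"beta0": [5.0], "beta_f1": [0.0], "beta_f2": [0.0],
                          "beta_f1xf2": [0.0], "beta_c1": [0.0],
                          "beta_c2": [0.0], "beta_eng": [0.8],
                          "eng_gain": [0.0]})
        trials = simulate_trials(cfg, np.random.default_rng(0))
        trials = simulate_choices(trials, cfg.psychometric, cfg,
                                  np.random.default_rng(1))
        truth = self._truth(cfg, w)
        truth.engaged = trials["engaged"].to_numpy(dtype=bool)
        epoch, _, _ = simulate_firing_rates(truth, trials, cfg,
                                            np.random.default_rng(2),
                                            include_bins=False)
        eng = trials["engaged"].to_numpy(dtype=bool)
        gap = (epoch["baseline"][0, eng].mean()
               - epoch["baseline"][0, ~eng].mean())
        assert gap == pytest.approx(0.8, abs=1e-9)

    def test_weight_recovery_against_least_squares_oracle(self):
        """Regressing generated rates on the known design recovers the
        ground-truth weights (closed-form normal equations)."""
        cfg = wp.GeneratorConfig(n_neurons=400, n_trials=600,
                                 include_rate_bins=False,
                                 include_markers=False, seed=5)
        b = wp.generate_session(cfg)
        tr = b.trials
        s1 = np.sqrt(tr["F1_hz"].to_numpy())
        s2 = np.sqrt(tr["F2_hz"].to_numpy())
        n_tr = len(tr)
        X = np.column_stack([np.ones(2 * n_tr),
                             np.concatenate([np.zeros(n_tr), s1]),
                             np.concatenate([np.zeros(n_tr), s2]),
                             np.concatenate([np.zeros(n_tr), s1 * s2])])
        Y = np.vstack([b.epoch_rates["baseline"].T,
                       b.epoch_rates["stimulus"].T])
        beta = np.linalg.solve(X.T @ X, X.T @ Y)   # oracle: normal equations
        tw = b.truth.weights
        # engaged-trial gain and choice terms perturb individual neurons;
        # across the population the fit must track the truth 1:1
        for i, col in enumerate(("beta_f1", "beta_f2", "beta_f1xf2")):
            slope, intercept = np.polyfit(tw[col], beta[i + 1], 1)
            assert 0.9 < slope < 1.1, col
            assert abs(intercept) < 0.02, col

    def test_rates_are_nonnegative(self, small_session):
        for arr in small_session.epoch_rates.values():
            assert (arr >= 0).all()
        assert (small_session.rate_bins >= 0).all()


class TestChoices:
    def test_saturated_psychometric(self):
        cfg = _rates_cfg(n_trials=200, disengaged_fraction=0.0,
                         psychometric=wp.PsychometricTruth(gamma=0, lapse=0,
                                                           beta=5.0),
                         stimulus_set=[(65.0, 25.0)])
        trials = simulate_choices(simulate_trials(cfg), cfg.psychometric, cfg)
        assert (trials["choice"] == "1").all()

    def test_midpoint_probability(self):
        truth = wp.PsychometricTruth(gamma=0, lapse=0, beta=0.06)
        assert psychometric_curve(0.0, truth) == pytest.approx(0.5)

    def test_binomial_rate_matches_curve(self):
        cfg = _rates_cfg(n_trials=10000, disengaged_fraction=0.0,
                         stimulus_set=[(55.0, 35.0)], seed=2)
        trials = simulate_choices(simulate_trials(cfg), cfg.psychometric, cfg)
        p = psychometric_curve(20.0, cfg.psychometric)
        frac = (trials["choice"] == "1").mean()
        se = np.sqrt(p * (1 - p) / len(trials))
        assert abs(frac - p) < 3 * se

    def test_disengaged_block_is_contiguous_tail(self):
        cfg = _rates_cfg(n_trials=100, disengaged_fraction=0.3)
        trials = simulate_choices(simulate_trials(cfg), cfg.psychometric, cfg)
        eng = trials["engaged"].to_numpy(dtype=bool)
        assert eng[:70].all() and not eng[70:].any()
        assert (trials.loc[~eng, "choice"] == "none").all()

    def test_outcome_consistent_with_reward_rule(self):
        cfg = _rates_cfg(n_trials=300, seed=4)
        trials = simulate_choices(simulate_trials(cfg), cfg.psychometric, cfg)
        resp = trials[trials["choice"].isin(["1", "2"])]
        win = np.where(resp["delta_f_hz"] > 0, "1",
                       np.where(resp["delta_f_hz"] < 0, "2", resp["choice"]))
        np.testing.assert_array_equal(resp["correct"].to_numpy(),
                                      (resp["choice"] == win).astype(float))


class TestFluorescence:
    def test_zero_rates_give_pure_contamination(self):
        cfg = _rates_cfg(n_neurons=2, n_trials=3, fluor_noise_sd=0.0,
                         drift_amp=0.0)
        rates = np.zeros((2, 3, cfg.n_bins))
        alpha = np.array([0.6, 0.8])
        out = synthesize_fluorescence(rates, alpha, cfg,
                                      np.random.default_rng(0))
        np.testing.assert_allclose(out["F_raw"],
                                   alpha[:, None] * out["F_neuropil"])

    def test_spike_amplitude_linearity(self):
        cfg = _rates_cfg(n_neurons=1, n_trials=3, fluor_noise_sd=0.0,
                         drift_amp=0.0)
        rng = np.random.default_rng(3)
        rates = rng.uniform(0, 5, (1, 3, cfg.n_bins))
        out1 = synthesize_fluorescence(rates, np.array([0.7]), cfg,
                                       np.random.default_rng(0))
        out2 = synthesize_fluorescence(2 * rates, np.array([0.7]), cfg,
                                       np.random.default_rng(0))
        resid1 = out1["F_raw"] - 0.7 * out1["F_neuropil"]
        resid2 = out2["F_raw"] - 0.7 * out2["F_neuropil"]
        np.testing.assert_allclose(resid2, 2 * resid1, atol=1e-9)

    def test_negative_rates_rejected(self):
        cfg = _rates_cfg()
        with pytest.raises(InputError):
            synthesize_fluorescence(-np.ones((1, 1, cfg.n_bins)),
                                    np.array([0.7]), cfg)

    def test_sparse_trace_has_low_active_fraction(self, rng):
        f, fp, t = sparse_trace_bundle(0.7, n_frames=4000, rng=rng)
        resid = f - 0.7 * fp
        active = np.mean(resid > 3 * 1.5)
        assert active < 0.10


class TestMarkers:
    def test_pupil_dilated_when_disengaged(self, small_session):
        b = small_session
        nb = b.config.n_bins
        pupil = b.markers["pupil_px"].to_numpy().reshape(-1, nb)
        base = pupil[:, :int(b.config.frame_rate)].mean(axis=1)
        eng = b.truth.engaged
        assert base[~eng].mean() > base[eng].mean() + 5.0

    def test_nose_flat_without_movement(self, small_session):
        b = small_session
        nb = b.config.n_bins
        nose = b.markers["nose_x"].to_numpy().reshape(-1, nb)
        quiet = ~np.isfinite(b.trials["reaction_time_s"].to_numpy())
        assert quiet.any()
        assert np.abs(np.diff(nose[quiet], axis=1)).max() < 1.0

    def test_theta_amplitude_larger_before_miss(self, small_session):
        b = small_session
        nb = b.config.n_bins
        theta = b.neuropil_master.reshape(-1, nb)
        amp = theta.std(axis=1)
        eng = b.truth.engaged
        assert amp[~eng].mean() > 1.5 * amp[eng].mean()
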