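"""Run configuration models.

All tunable parameters of the synthetic-session generator, the fluorescence
preprocessing pipeline and the end-to-end pipeline live here as validated
pydantic models, so that a JSON run configuration can be checked before any
computation starts.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator


def antidiagonal_pairs(n_levels: int = 9, total_hz: float = 90.0) -> list[tuple[float, float]]:
    """Stimulus pairs (F1, F2) with constant summed frequency.

    The behavioural psychometric is measured along this anti-diagonal of the
    stimulus space (F1 + F2 held constant), giving ``n_levels`` evenly spaced
    frequency differences dF = F1 - F2 from -total to +total Hz.
    """
    f1 = np.linspace(0.0, total_hz, n_levels)
    return [(float(a), float(total_hz - a)) for a in f1]


def grid_pairs(levels: Sequence[float] = (0.0, 22.5, 45.0, 67.5, 90.0)) -> list[tuple[float, float]]:
    """Full stimulus-space grid (excluding the blank (0, 0) condition)."""
    return [(float(a), float(b)) for a in levels for b in levels if not (a == 0 and b == 0)]


class PsychometricTruth(BaseModel):
    """Ground-truth parameters of the lapse-rate logistic psi(x) = gamma +
    (1 - gamma - lambda) / (1 + exp(alpha - x beta))."""

    gamma: float = 0.05
    lapse: float = 0.05
    alpha: float = 0.0
    beta: float = 0.06

    @field_validator("gamma", "lapse")
    @classmethod
    def _asymptote_range(cls, v: float) -> float:
        if not 0.0 <= v <= 0.5:
            raise ValueError("asymptotes must lie in [0, 0.5]")
        return v


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic two-whisker 2AFC session generator.

    Defaults emulate the statistical structure of a single imaging session:
    logistic choice behaviour with lapses and an end-of-session disengagement
    block, sparse correlated sensory weights with a highly responsive tail,
    adaptation dynamics within the stimulus epoch, and known neuropil
    contamination in the synthesized fluorescence.
    """

    n_neurons: int = Field(300, ge=0)
    n_trials: int = Field(500, ge=0)
    frame_rate: float = Field(29.7, gt=0)

    stimulus_set: list[Tuple[float, float]] = Field(default_factory=grid_pairs)
    baseline_s: float = Field(1.0, gt=0)
    stimulus_s: float = Field(1.0, gt=0)
    decision_s: float = Field(2.0, gt=0)

    psychometric: PsychometricTruth = Field(default_factory=PsychometricTruth)

    # behavioural state structure
    disengaged_fraction: float = Field(0.3, ge=0.0, le=1.0)
    prestim_fraction: float = Field(0.244, ge=0.0, le=1.0)
    impulsive_fraction: float = Field(0.412, ge=0.0, le=1.0)

    # weight joint distribution
    corr_f1_f2: float = 0.55          # Pearson target, betaF1 vs betaF2
    corr_f1_f1x2: float = -0.65       # Spearman target, betaF1 vs betaF1xF2
    corr_f2_f1x2: float = -0.62       # Spearman target, betaF2 vs betaF1xF2
    sensory_weight_sd: float = Field(0.06, gt=0)
    interaction_weight_sd: float = Field(0.006, gt=0)
    tail_fraction: float = Field(0.10, ge=0.0, le=1.0)
    tail_scale: float = Field(3.0, ge=1.0)
    null_weight_scale: float = Field(0.05, ge=0.0)

    frac_activated: float = Field(0.523, ge=0.0, le=1.0)
    frac_suppressed: float = Field(0.323, ge=0.0, le=1.0)
    # mirror each neuron across the two whiskers (exactly balanced pools)
    symmetric_pools: bool = False

    choice_weight_sd: float = Field(0.35, ge=0.0)
    choice_ramp_s: float = Field(1.5, gt=0)
    engagement_weight_sd: float = Field(0.15, ge=0.0)
    engagement_modulation_pct: Tuple[float, float, float] = (22.0, 16.0, -7.0)

    # firing-rate model
    baseline_rate_mean: float = Field(3.0, gt=0)
    baseline_rate_sd: float = Field(0.8, ge=0.0)
    onset_factor: float = Field(3.3, gt=0)
    sustained_factor: float = Field(1.8, gt=0)
    onset_duration_s: float = Field(0.25, gt=0)
    noise_sd: float = Field(0.25, ge=0.0)
    bin_noise_sd: float = Field(0.05, ge=0.0)
    # optional trial-to-trial variability shared across neurons (a common
    # component plus a differential component loaded by whisker selectivity,
    # i.e. column-wise co-fluctuation).  Off by default: the default
    # conditions favour exact parameter recovery; see the methods note.
    shared_noise_common_sd: float = Field(0.0, ge=0.0)
    shared_noise_diff_sd: float = Field(0.0, ge=0.0)
    poisson_events: bool = False

    # fluorescence synthesis
    alpha_range: Tuple[float, float] = (0.55, 0.80)
    alpha_clamp: Tuple[float, float] = (0.5, 0.85)
    kernel_tau_s: float = Field(0.5, gt=0)
    transient_amp: float = Field(5.0, ge=0.0)
    fluor_noise_sd: float = Field(0.3, ge=0.0)
    drift_amp: float = Field(1.0, ge=0.0)
    drift_period_s: float = Field(120.0, gt=0)
    fp_base: float = Field(100.0, gt=0)
    fp_sd: float = Field(8.0, ge=0.0)
    fp_stim_gain: float = Field(2.0, ge=0.0)

    # optogenetics
    opto_fraction: float = Field(0.0, ge=0.0, le=1.0)
    opto_condition: str = "W1"
    opto_shift_w1: float = 13.4       # rightward midpoint shift, Hz
    opto_shift_w2: float = -26.4      # leftward midpoint shift, Hz

    # behaviour markers
    nose_step_px: float = 12.0
    marker_noise_px: float = 0.05
    pupil_base_px: float = 100.0
    pupil_disengaged_shift_px: float = 15.0
    pupil_noise_px: float = 3.0
    tongue_baseline: float = 0.08
    tongue_sd: float = 0.01
    lick_likelihood: float = 0.9
    theta_freq_hz: float = 5.0
    theta_amp: float = 1.0
    theta_miss_gain: float = 2.0

    # reaction times (s, relative to stimulus onset)
    rt_lognorm_mu: float = -1.05      # exp(mu) ~ 0.35 s past stimulus offset
    rt_lognorm_sigma: float = 0.35

    # which artifacts to populate
    include_rate_bins: bool = True
    include_fluorescence: bool = False
    include_markers: bool = True

    seed: int = 0

    @field_validator("stimulus_set")
    @classmethod
    def _freqs_nonnegative(cls, v):
        for f1, f2 in v:
            if f1 < 0 or f2 < 0:
                raise ValueError("stimulus frequencies must be >= 0")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.prestim_fraction + self.impulsive_fraction > 1.0 + 1e-12:
            raise ValueError("prestim_fraction + impulsive_fraction must be <= 1")
        if self.frac_activated + self.frac_suppressed > 1.0 + 1e-12:
            raise ValueError("frac_activated + frac_suppressed must be <= 1")
        lo, hi = self.alpha_range
        clo, chi = self.alpha_clamp
        if not (clo <= lo <= hi <= chi):
            raise ValueError("alpha_range must lie inside alpha_clamp")
        if self.opto_condition not in ("W1", "W2", "broad"):
            raise ValueError("opto_condition must be one of W1, W2, broad")
        return self

    @classmethod
    def symmetric(cls, **overrides) -> "GeneratorConfig":
        """Fully whisker-symmetric variant of the default configuration.

        Mirrors every sampled neuron across the two whiskers (exactly
        balanced pools) and symmetrizes the engagement-modulation targets of
        the two single-whisker pools (their mean), keeping the interaction
        target.  This is the configuration meant by "symmetric, balanced
        whisker pools": no systematic asymmetry distinguishes W1 from W2.
        """
        defaults = cls()
        m = defaults.engagement_modulation_pct
        s = (m[0] + m[1]) / 2.0
        payload = {"symmetric_pools": True,
                   "engagement_modulation_pct": (s, s, m[2])}
        payload.update(overrides)
        return cls(**payload)

    @property
    def trial_duration_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.decision_s

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_duration_s * self.frame_rate))

    def opto_shift(self, condition: str) -> float:
        return {"W1": self.opto_shift_w1, "W2": self.opto_shift_w2,
                "broad": 0.0, "sham": 0.0, "none": 0.0}[condition]


class PreprocessParams(BaseModel):
    """Parameters of the noise-adjusted dF/F0 pipeline."""

    alpha_init: float = 0.5
    alpha_clamp: Tuple[float, float] = (0.5, 0.85)
    alpha_tol: float = 0.025
    max_iter: int = Field(10, ge=1)
    detrend_window_s: float = Field(30.0, gt=0)
    detrend_percentile: float = Field(10.0, gt=0, lt=100)
    boxcar_width: int = Field(3, ge=1)
    ar1_threshold: float = 0.5
    ena_min_frames: int = Field(5, ge=1)
    regression_window_s: float = Field(30.0, gt=0)
    regression_min_points: int = Field(5, ge=2)
    zscore_low_pct: float = 2.3
    zscore_mid_pct: float = 16.0
    kernel_tau_s: float = Field(0.5, gt=0)

    @model_validator(mode="after")
    def _checks(self):
        lo, hi = self.alpha_clamp
        if not lo <= self.alpha_init <= hi:
            raise ValueError("alpha_init must lie inside alpha_clamp")
        if not self.zscore_low_pct < self.zscore_mid_pct:
            raise ValueError("zscore_low_pct must be < zscore_mid_pct")
        return self


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (simulate -> ... -> report)."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)

    run_preprocess: bool = False      # requires include_fluorescence
    run_behavior: bool = True
    run_encoding: bool = True
    run_population: bool = True
    run_spatial: bool = True

    cv_folds: int = Field(10, ge=2)
    n_permutations: int = Field(200, ge=10)
    subsample_repeats: int = Field(50, ge=1)
    max_preprocess_neurons: int = Field(20, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _deps(self):
        if self.run_preprocess and not self.generator.include_fluorescence:
            raise ValueError(
                "run_preprocess requires generator.include_fluorescence=True")
        return self
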