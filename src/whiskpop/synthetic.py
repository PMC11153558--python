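"""Synthetic two-whisker 2AFC session generator.

Generates complete sessions — trial tables, ground-truth encoding weights,
firing rates, fluorescence traces and behaviour-marker streams — with known
parameters, so that every downstream analysis stage can be validated by
parameter recovery.

The statistical structure emulated here:

* logistic choice behaviour with guess/lapse asymptotes and a contiguous
  disengaged block at the end of the session;
* per-neuron sensory weights (betaF1, betaF2, betaF1xF2) drawn from a
  Gaussian copula with configurable Pearson/Spearman correlation targets, a
  heavy-tailed "highly responsive" subpopulation (~10%), and configurable
  fractions of activated / suppressed / unresponsive neurons;
* choice and engagement weights statistically independent of the sensory
  weights;
* within-stimulus adaptation (onset transient, then sustained elevation);
* an engagement gain that is linear in the single-whisker weights and
  anti-linear in the interaction weight, solved per session so that the
  pooled evoked modulation hits the configured targets;
* calcium fluorescence with known per-neuron neuropil contamination alpha;
* nose / whisker / tongue / pupil marker streams and a neuropil master trace
  carrying a 2-10 Hz oscillation that strengthens before misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, special, stats
from scipy.ndimage import gaussian_filter1d

from .config import GeneratorConfig, PsychometricTruth
from .exceptions import ConfigurationError, InputError

WEIGHT_COLS = ["beta0", "beta_f1", "beta_f2", "beta_f1xf2",
               "beta_c1", "beta_c2", "beta_eng"]

TRIAL_COLUMNS = ["trial_index", "F1_hz", "F2_hz", "delta_f_hz", "choice",
                 "correct", "engaged", "trial_category", "opto",
                 "reaction_time_s", "t_start_s"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    weights: pd.DataFrame            # one row per neuron, WEIGHT_COLS + extras
    alpha: np.ndarray                # neuropil contamination factor per neuron
    positions: np.ndarray            # (n, 2) um
    column_centers: np.ndarray       # (2, 2) um, row 0 = W1 column
    engaged: np.ndarray              # per-trial bool
    psychometric: PsychometricTruth
    gain_coef: np.ndarray            # (k1, k2, k3) of the engagement gain


@dataclass
class SessionBundle:
    """A complete synthetic session."""

    config: GeneratorConfig
    trials: pd.DataFrame
    epoch_rates: dict                # 'baseline'/'stimulus'/'decision'/'trial'
    truth: GroundTruth
    rate_bins: Optional[np.ndarray] = None       # (neurons, trials, bins)
    bin_time_s: Optional[np.ndarray] = None      # within-trial bin centers
    fluorescence: Optional[dict] = None          # F_raw, F_neuropil, frame_time_s
    markers: Optional[pd.DataFrame] = None
    teeth_x: Optional[float] = None
    neuropil_master: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# weight sampling


def _sqrt_regressors(f1, f2):
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(f1 < 0) or np.any(f2 < 0):
        raise InputError("stimulus frequencies must be >= 0")
    return np.sqrt(f1), np.sqrt(f2), np.sqrt(f1 * f2)


def _corr_matrix(cfg: GeneratorConfig, corr_in=None) -> np.ndarray:
    if corr_in is None:
        # starting point: Pearson target directly; Spearman targets mapped
        # through the Gaussian-copula identity rho_p = 2 sin(pi rho_s / 6)
        corr_in = np.array([
            cfg.corr_f1_f2,
            2 * np.sin(np.pi * cfg.corr_f1_f1x2 / 6),
            2 * np.sin(np.pi * cfg.corr_f2_f1x2 / 6),
        ])
    c = np.array([
        [1.0, corr_in[0], corr_in[1]],
        [corr_in[0], 1.0, corr_in[2]],
        [corr_in[1], corr_in[2], 1.0],
    ])
    eig = np.linalg.eigvalsh(c)
    if eig.min() < -1e-10:
        pairs = [("beta_f1", "beta_f2"), ("beta_f1", "beta_f1xf2"),
                 ("beta_f2", "beta_f1xf2")]
        worst = pairs[int(np.argmax(np.abs(corr_in)))]
        raise ConfigurationError(
            f"weight correlation targets are not jointly feasible "
            f"(offending pair {worst[0]}-{worst[1]})")
    return c


def _draw_sensory(corr: np.ndarray, n: int, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Copula draw of (betaF1, betaF2, betaF1xF2) with a heavy-tail scale
    mixture shared across the triple."""
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    scale = np.where(rng.random(n) < cfg.tail_fraction, cfg.tail_scale, 1.0)
    w = z * scale[:, None]
    w[:, 0] *= cfg.sensory_weight_sd
    w[:, 1] *= cfg.sensory_weight_sd
    w[:, 2] *= cfg.interaction_weight_sd
    return w


def _mean_drive(w: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Session-average evoked drive of each neuron over the stimulus set."""
    f1 = np.array([p[0] for p in cfg.stimulus_set])
    f2 = np.array([p[1] for p in cfg.stimulus_set])
    s1, s2, s12 = _sqrt_regressors(f1, f2)
    svec = np.array([s1.mean(), s2.mean(), s12.mean()])
    return w @ svec


def _impose_classes(w: np.ndarray, cfg: GeneratorConfig,
                    fixed: Optional[tuple] = None):
    """Impose response-class structure on a raw copula draw.

    A common positive shift of the single-whisker weight means is solved so
    that the drive distribution straddles zero with the configured mass on
    each side; neurons are then classed by drive quantiles — the top
    ``frac_activated`` are activated, the bottom ``frac_suppressed``
    suppressed — which makes the realized fractions exact and leaves a
    symmetric dead-band margin around zero.  Dead-band ("none") neurons have
    their sensory triple scaled to near zero so they carry no detectable
    evoked response.  Mean shifts and uniform scalings leave the Pearson /
    Spearman structure essentially intact; the residual distortion from the
    dead-band scaling is removed by the calibration loop.

    Returns ``(w, classes)`` with classes coded 0/1/2 =
    activated/suppressed/none.
    """
    w = w.copy()
    n = len(w)
    if n == 0:
        return w, np.zeros(0, dtype=int)
    fa, fs = cfg.frac_activated, cfg.frac_suppressed
    f1 = np.array([p[0] for p in cfg.stimulus_set])
    f2 = np.array([p[1] for p in cfg.stimulus_set])
    s1, s2, _ = _sqrt_regressors(f1, f2)
    c = s1.mean() + s2.mean()
    d0 = _mean_drive(w, cfg)
    if fixed is not None:
        # population-level constants from the calibration draw: keeps the
        # within-session weight distribution identical at every session size
        mu, lo, hi = fixed
    else:
        # solve the shift so the activated/suppressed cuts straddle zero
        g0 = np.quantile(d0, 1 - fa) + np.quantile(d0, fs)
        mu = -g0 / (2 * c) if c > 0 else 0.0
        d_shift = d0 + c * mu
        hi = np.quantile(d_shift, 1 - fa)
        lo = np.quantile(d_shift, fs)
    w[:, 0] += mu
    w[:, 1] += mu
    d = d0 + c * mu
    classes = np.where(d > hi, 0, np.where(d < lo, 1, 2))
    w[classes == 2] *= cfg.null_weight_scale
    return w, classes


def _measured_corrs(w: np.ndarray) -> np.ndarray:
    if len(w) < 3:
        return np.full(3, np.nan)
    return np.array([
        stats.pearsonr(w[:, 0], w[:, 1])[0],
        stats.spearmanr(w[:, 0], w[:, 2])[0],
        stats.spearmanr(w[:, 1], w[:, 2])[0],
    ])


_CALIBRATION_CACHE: dict = {}


def _calibration_key(cfg: GeneratorConfig) -> tuple:
    return (round(cfg.corr_f1_f2, 6), round(cfg.corr_f1_f1x2, 6),
            round(cfg.corr_f2_f1x2, 6), round(cfg.sensory_weight_sd, 9),
            round(cfg.interaction_weight_sd, 9), round(cfg.tail_fraction, 6),
            round(cfg.tail_scale, 6), round(cfg.null_weight_scale, 6),
            round(cfg.frac_activated, 6),
            round(cfg.frac_suppressed, 6), tuple(map(tuple, cfg.stimulus_set)))


def _calibrated_corr(cfg: GeneratorConfig, n_cal: int = 60000,
                     n_iter: int = 12) -> np.ndarray:
    """Fixed-point calibration of the copula input correlations so that the
    post-transform weight table hits the configured targets.

    Deterministic (fixed internal seed) and cached per parameter set, so every
    session generated under the same configuration uses the same inputs.
    """
    key = _calibration_key(cfg)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    target = np.array([cfg.corr_f1_f2, cfg.corr_f1_f1x2, cfg.corr_f2_f1x2])
    corr_in = np.array([
        cfg.corr_f1_f2,
        2 * np.sin(np.pi * cfg.corr_f1_f1x2 / 6),
        2 * np.sin(np.pi * cfg.corr_f2_f1x2 / 6),
    ])
    tail = []
    for it in range(n_iter):
        corr = _corr_matrix(cfg, corr_in)
        rng = np.random.default_rng(90210 + it)
        w = _draw_sensory(corr, n_cal, cfg, rng)
        w, _ = _impose_classes(w, cfg)
        measured = _measured_corrs(w)
        corr_in = np.clip(corr_in + 0.7 * (target - measured), -0.97, 0.97)
        if it >= n_iter - 4:
            tail.append(corr_in.copy())
    corr = _corr_matrix(cfg, np.mean(tail, axis=0))
    # freeze the class-imposition constants on a large reference draw
    rng = np.random.default_rng(771177)
    w_ref = _draw_sensory(corr, 100000, cfg, rng)
    f1 = np.array([p[0] for p in cfg.stimulus_set])
    f2 = np.array([p[1] for p in cfg.stimulus_set])
    s1, s2, _ = _sqrt_regressors(f1, f2)
    c = s1.mean() + s2.mean()
    fa, fs = cfg.frac_activated, cfg.frac_suppressed
    d0 = _mean_drive(w_ref, cfg)
    g0 = np.quantile(d0, 1 - fa) + np.quantile(d0, fs)
    mu = -g0 / (2 * c) if c > 0 else 0.0
    d_shift = d0 + c * mu
    result = (corr, (mu, np.quantile(d_shift, fs),
                     np.quantile(d_shift, 1 - fa)))
    _CALIBRATION_CACHE[key] = result
    return result


def sample_neuron_weights(config: GeneratorConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> pd.DataFrame:
    """Sample the per-neuron ground-truth weight table.

    Returns a DataFrame with columns ``beta0, beta_f1, beta_f2, beta_f1xf2,
    beta_c1, beta_c2, beta_eng, response_class, mean_drive``.  Sensory weights
    follow the calibrated copula; choice and engagement weights are drawn
    independently of the sensory triple.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    corr, fixed = _calibrated_corr(config)
    w = _draw_sensory(corr, n, config, rng)
    w, classes = _impose_classes(w, config, fixed=fixed)

    cv = config.baseline_rate_sd / config.baseline_rate_mean
    sig2 = np.log1p(cv ** 2)
    beta0 = rng.lognormal(np.log(config.baseline_rate_mean) - sig2 / 2,
                          np.sqrt(sig2), n)
    out = pd.DataFrame({
        "beta0": beta0,
        "beta_f1": w[:, 0] if n else np.zeros(0),
        "beta_f2": w[:, 1] if n else np.zeros(0),
        "beta_f1xf2": w[:, 2] if n else np.zeros(0),
        "beta_c1": rng.normal(0.0, config.choice_weight_sd, n),
        "beta_c2": rng.normal(0.0, config.choice_weight_sd, n),
        "beta_eng": rng.normal(0.0, config.engagement_weight_sd, n),
        "response_class": pd.Categorical.from_codes(
            classes, categories=["activated", "suppressed", "none"]),
    })
    out["mean_drive"] = _mean_drive(w, config) if n else np.zeros(0)
    if config.symmetric_pools and n:
        # append the whisker-swapped mirror of every neuron: the W1 and W2
        # pools become exact reflections of each other
        mirror = out.copy()
        mirror[["beta_f1", "beta_f2"]] = out[["beta_f2", "beta_f1"]].to_numpy()
        mirror[["beta_c1", "beta_c2"]] = out[["beta_c2", "beta_c1"]].to_numpy()
        out = pd.concat([out, mirror], ignore_index=True)
    return out


def weight_correlations(weights: pd.DataFrame) -> dict:
    """Sample correlations of the weight table (NaN-flagged when n < 3)."""
    w = weights[["beta_f1", "beta_f2", "beta_f1xf2"]].to_numpy()
    m = _measured_corrs(w)
    return {"pearson_f1_f2": m[0], "spearman_f1_f1x2": m[1],
            "spearman_f2_f1x2": m[2]}


# ---------------------------------------------------------------------------
# trials and choices


def psychometric_curve(x, truth: PsychometricTruth):
    """psi(x) = gamma + (1 - gamma - lambda) F(x; alpha, beta)."""
    x = np.asarray(x, dtype=float)
    core = special.expit(x * truth.beta - truth.alpha)
    return truth.gamma + (1.0 - truth.gamma - truth.lapse) * core


def simulate_trials(config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the trial table skeleton: stimuli, engagement block, categories,
    optogenetic labels and reaction times (choices added separately)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    if n == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    pairs = np.asarray(config.stimulus_set, dtype=float)
    idx = rng.integers(0, len(pairs), n)
    f1, f2 = pairs[idx, 0], pairs[idx, 1]

    n_dis = int(round(config.disengaged_fraction * n))
    engaged = np.arange(n) < (n - n_dis)

    opto = np.full(n, "none", dtype=object)
    if config.opto_fraction > 0:
        opto[:] = "sham"
        opto[rng.random(n) < config.opto_fraction] = config.opto_condition

    p_delayed = max(0.0, 1 - config.prestim_fraction - config.impulsive_fraction)
    cat = rng.choice(["prestim_move", "impulsive", "delayed"], size=n,
                     p=[config.prestim_fraction, config.impulsive_fraction,
                        p_delayed])
    cat = np.where(engaged, cat, "delayed")

    rt = np.full(n, np.nan)
    delayed = engaged & (cat == "delayed")
    rt[delayed] = np.minimum(
        config.stimulus_s + rng.lognormal(config.rt_lognorm_mu,
                                          config.rt_lognorm_sigma,
                                          int(delayed.sum())),
        config.stimulus_s + config.decision_s - 0.05)
    imp = engaged & (cat == "impulsive")
    rt[imp] = rng.uniform(0.15, config.stimulus_s - 0.05, int(imp.sum()))
    pre = engaged & (cat == "prestim_move")
    rt[pre] = rng.uniform(-config.baseline_s + 0.1, -0.05, int(pre.sum()))

    return pd.DataFrame({
        "trial_index": np.arange(n),
        "F1_hz": f1, "F2_hz": f2, "delta_f_hz": f1 - f2,
        "choice": "none", "correct": np.nan,
        "engaged": engaged.astype(int),
        "trial_category": cat, "opto": opto,
        "reaction_time_s": rt,
        "t_start_s": np.arange(n) * config.trial_duration_s,
    })


def simulate_choices(trials: pd.DataFrame, truth: PsychometricTruth,
                     config: GeneratorConfig,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw choices from the psychometric truth and fill outcome columns.

    Engaged trials lick side 1 with probability psi(dF - shift), where shift
    is the horizontal displacement imposed by the trial's optogenetic
    condition; disengaged trials never respond.  A response on a dF = 0 trial
    counts as correct (rewarded at chance in the task).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = trials.copy()
    if len(trials) == 0:
        return trials
    shift = trials["opto"].map(config.opto_shift).to_numpy(dtype=float)
    p1 = psychometric_curve(trials["delta_f_hz"].to_numpy() - shift, truth)
    engaged = trials["engaged"].to_numpy(dtype=bool)
    draw = rng.random(len(trials))
    choice = np.where(draw < p1, "1", "2")
    choice = np.where(engaged, choice, "none")
    trials["choice"] = choice
    df = trials["delta_f_hz"].to_numpy()
    correct = np.where(df > 0, choice == "1",
                       np.where(df < 0, choice == "2", choice != "none"))
    trials["correct"] = np.where(choice == "none", np.nan,
                                 correct.astype(float))
    return trials


# ---------------------------------------------------------------------------
# firing rates


def _drive_matrix(weights: pd.DataFrame, f1, f2) -> np.ndarray:
    s1, s2, s12 = _sqrt_regressors(f1, f2)
    return (np.outer(weights["beta_f1"], s1)
            + np.outer(weights["beta_f2"], s2)
            + np.outer(weights["beta_f1xf2"], s12))


def solve_engagement_gain(weights: pd.DataFrame, drive: np.ndarray,
                          config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Solve the engagement-gain coefficients (k1, k2, k3).

    The per-neuron engagement modulation *ratio* r scales the neuron's own
    sensory drive on engaged trials (engaged drive = (1 + r) d(F1, F2)), so
    the gain never leaks across regressors in the encoding fit.  The vector
    r is the minimal-norm pattern that satisfies the three pooled
    constraints exactly,

        sum(w_p d r) / sum(w_p d) = target_p / 100     for Rw1, Rw2, Rw1xw2,

    where w_p are the pool weights (betaF1 over the W1 pool, betaF2 over the
    W2 pool, betaF1xF2 over all neurons).  The solution lies in the span of
    the drive-weighted pool weights, so the realized gain grows with a
    neuron's single-whisker weights and is anti-related to its interaction
    weight — the qualitative single-neuron pattern this rule emulates.  r is
    clipped to +-0.8 with a few re-solve passes on the unclipped part.
    Returns ``(coef, r)``; falls back to zeros when a pool is empty or the
    constraints are degenerate (tiny sessions).
    """
    bf1 = weights["beta_f1"].to_numpy()
    bf2 = weights["beta_f2"].to_numpy()
    bx = weights["beta_f1xf2"].to_numpy()
    n = len(weights)
    if n == 0 or drive.shape[1] == 0:
        return np.zeros(3), np.zeros(n)
    dbar = drive.mean(axis=1)
    U = np.vstack([
        np.where(bf1 > bf2, bf1 * dbar, 0.0),
        np.where(bf2 > bf1, bf2 * dbar, 0.0),
        bx * dbar,
    ])
    pct = np.asarray(config.engagement_modulation_pct, dtype=float)
    denom = U.sum(axis=1)
    if np.any(denom == 0):
        return np.zeros(3), np.zeros(n)
    b = (pct / 100.0) * denom
    gram = U @ U.T
    try:
        coef = np.linalg.solve(gram, b)
    except np.linalg.LinAlgError:
        return np.zeros(3), np.zeros(n)
    r = U.T @ coef
    for _ in range(3):
        r = np.clip(r, -0.8, 0.8)
        resid = b - U @ r
        free = np.abs(r) < 0.8
        Uf = U[:, free]
        try:
            upd = np.linalg.solve(Uf @ Uf.T, resid)
        except np.linalg.LinAlgError:
            break
        r[free] += Uf.T @ upd
    return coef, np.clip(r, -0.8, 0.8)


def simulate_firing_rates(truth: GroundTruth, trials: pd.DataFrame,
                          config: GeneratorConfig,
                          rng: Optional[np.random.Generator] = None,
                          include_bins: Optional[bool] = None):
    """Simulate per-trial firing rates.

    Returns ``(epoch_rates, rate_bins, bin_time_s)``.  ``epoch_rates`` maps
    'baseline' / 'stimulus' / 'decision' / 'trial' to (neurons, trials)
    arrays of mean rate; the stimulus-epoch mean equals the linear predictor
    beta0 + betaF1 sqrt(F1) + betaF2 sqrt(F2) + betaF1xF2 sqrt(F1 F2) plus
    the choice and engagement terms, with per-trial Gaussian noise, clipped
    at zero.  Within-trial bins additionally carry the onset/sustained
    adaptation profile and the choice ramp.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if include_bins is None:
        include_bins = config.include_rate_bins
    w = truth.weights
    n_neurons, n_trials = len(w), len(trials)
    t_bin = (np.arange(config.n_bins) + 0.5) / config.frame_rate
    if n_trials == 0 or n_neurons == 0:
        empty = np.zeros((n_neurons, n_trials))
        epoch = {k: empty.copy() for k in
                 ("baseline", "stimulus", "decision", "trial")}
        bins = (np.zeros((n_neurons, n_trials, config.n_bins))
                if include_bins else None)
        return epoch, bins, t_bin

    f1 = trials["F1_hz"].to_numpy()
    f2 = trials["F2_hz"].to_numpy()
    drive = _drive_matrix(w, f1, f2)

    engaged = trials["engaged"].to_numpy(dtype=bool)[None, :]
    # engagement scales each neuron's own sensory drive by (1 + r): the gain
    # stays inside the neuron's regression span and cannot leak into the
    # fitted weights of other regressors
    r_n = truth.weights["eng_gain"].to_numpy()
    gain = r_n[:, None] * drive * engaged

    cho = trials["choice"].to_numpy()
    # only the side-differential component is injected: common (side-
    # independent) response activity is movement-related and excluded from
    # the emulated choice signal
    contrast = 0.5 * (w["beta_c1"].to_numpy() - w["beta_c2"].to_numpy())
    amp_choice = (np.outer(contrast, cho == "1")
                  - np.outer(contrast, cho == "2"))

    base0 = (w["beta0"].to_numpy()[:, None]
             + w["beta_eng"].to_numpy()[:, None] * engaged)

    t0, t1 = config.baseline_s, config.baseline_s + config.stimulus_s
    t_end = config.trial_duration_s
    b_mask = t_bin < t0
    s_mask = (t_bin >= t0) & (t_bin < t1)
    d_mask = t_bin >= t1
    ramp = np.clip((t_bin - t0) / config.choice_ramp_s, 0.0, 1.0)
    r_stim = ramp[s_mask].mean()
    r_dec = ramp[d_mask].mean()

    noise = rng.normal(0.0, config.noise_sd, (3, n_neurons, n_trials))
    # shared variability: common + selectivity-loaded differential component
    xi_c = rng.normal(0.0, config.shared_noise_common_sd, n_trials)
    xi_d = rng.normal(0.0, config.shared_noise_diff_sd, n_trials)
    sel = np.tanh((w["beta_f1"].to_numpy() - w["beta_f2"].to_numpy())
                  / (np.sqrt(2) * config.sensory_weight_sd))
    shared = xi_c[None, :] + sel[:, None] * xi_d[None, :]
    base = base0 + noise[0]
    stim = base0 + drive + gain + amp_choice * r_stim + shared + noise[1]
    dec = base0 + amp_choice * r_dec + noise[2]
    epoch = {
        "baseline": np.clip(base, 0.0, None),
        "stimulus": np.clip(stim, 0.0, None),
        "decision": np.clip(dec, 0.0, None),
    }
    epoch["trial"] = (epoch["stimulus"] * config.stimulus_s
                      + epoch["decision"] * config.decision_s) / (
                          config.stimulus_s + config.decision_s)

    bins = None
    if include_bins:
        onset_ratio = ((config.onset_factor - 1.0)
                       / max(config.sustained_factor - 1.0, 1e-9))
        prof = np.ones(int(s_mask.sum()))
        prof[t_bin[s_mask] < t0 + config.onset_duration_s] = onset_ratio
        prof /= prof.mean()
        bins = np.empty((n_neurons, n_trials, config.n_bins))
        bins[:, :, b_mask] = (base0 + noise[0])[:, :, None]
        bins[:, :, s_mask] = ((base0 + shared + noise[1])[:, :, None]
                              + (drive + gain)[:, :, None] * prof[None, None, :]
                              + amp_choice[:, :, None] * ramp[s_mask])
        bins[:, :, d_mask] = ((base0 + noise[2])[:, :, None]
                              + amp_choice[:, :, None] * ramp[d_mask])
        if config.bin_noise_sd > 0:
            bins += rng.normal(0.0, config.bin_noise_sd, bins.shape)
        np.clip(bins, 0.0, None, out=bins)
        if config.poisson_events:
            dt = 1.0 / config.frame_rate
            bins = rng.poisson(bins * dt) / dt
    return epoch, bins, t_bin


# ---------------------------------------------------------------------------
# fluorescence


def synthesize_fluorescence(rate_bins: np.ndarray, alpha: np.ndarray,
                            config: GeneratorConfig,
                            rng: Optional[np.random.Generator] = None) -> dict:
    """Synthesize ROI + neuropil fluorescence from a bin-level rate matrix.

    ROI trace = (calcium kernel * events) + alpha * Fp + slow drift + noise,
    where Fp is a smooth positive background sharing stimulus-locked
    structure with the population rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if np.any(np.asarray(rate_bins) < 0):
        raise InputError("rates must be nonnegative")
    if config.kernel_tau_s <= 0:
        raise ConfigurationError("kernel decay constant must be positive")
    n_neurons, n_trials, n_bins = rate_bins.shape
    n_frames = n_trials * n_bins
    dt = 1.0 / config.frame_rate
    frame_time = np.arange(n_frames) * dt

    rates = rate_bins.reshape(n_neurons, n_frames)
    g = float(np.exp(-dt / config.kernel_tau_s))
    events = rates * dt
    calcium = signal.lfilter([config.transient_amp], [1.0, -g], events, axis=1)

    pop = rates.mean(axis=0) if n_neurons else np.zeros(n_frames)
    evoked = np.clip(pop - np.median(pop), 0.0, None)
    wander = gaussian_filter1d(rng.standard_normal(n_frames),
                               3.0 * config.frame_rate, mode="nearest")
    if wander.std() > 0:
        wander = wander / wander.std() * config.fp_sd
    fp = np.clip(config.fp_base + wander + config.fp_stim_gain * evoked,
                 1.0, None)
    fp_all = np.broadcast_to(fp, (n_neurons, n_frames)).copy()

    phase = rng.uniform(0, 2 * np.pi, n_neurons)
    drift = config.drift_amp * np.sin(
        2 * np.pi * frame_time[None, :] / config.drift_period_s
        + phase[:, None])
    noise = (rng.normal(0.0, config.fluor_noise_sd, (n_neurons, n_frames))
             if config.fluor_noise_sd > 0 else 0.0)
    f_raw = calcium + alpha[:, None] * fp_all + drift + noise
    return {"F_raw": f_raw, "F_neuropil": fp_all, "frame_time_s": frame_time}


def sparse_trace_bundle(alpha: float, n_frames: int = 6000,
                        frame_rate: float = 29.7, event_rate_hz: float = 0.2,
                        amp: float = 8.0, tau_s: float = 0.5,
                        noise_sd: float = 1.5, fp_base: float = 100.0,
                        fp_sd: float = 8.0, drift_amp: float = 1.0,
                        drift_period_s: float = 120.0,
                        rng: Optional[np.random.Generator] = None):
    """A single sparse-transient trace with known neuropil contamination.

    Emulates a low-event-rate cortical neuron (active-frame fraction well
    below 10%, transient SNR amp/noise_sd); used to validate the neuropil
    factor estimator by recovery.  Returns ``(F, Fp, frame_time_s)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    dt = 1.0 / frame_rate
    t = np.arange(n_frames) * dt
    events = rng.poisson(event_rate_hz * dt, n_frames).astype(float)
    g = float(np.exp(-dt / tau_s))
    calcium = signal.lfilter([amp], [1.0, -g], events)
    wander = gaussian_filter1d(rng.standard_normal(n_frames),
                               3.0 * frame_rate, mode="nearest")
    if wander.std() > 0:
        wander = wander / wander.std() * fp_sd
    fp = np.clip(fp_base + wander, 1.0, None)
    drift = drift_amp * np.sin(2 * np.pi * t / drift_period_s
                               + rng.uniform(0, 2 * np.pi))
    f = calcium + alpha * fp + drift + rng.normal(0.0, noise_sd, n_frames)
    return f, fp, t


# ---------------------------------------------------------------------------
# behaviour markers


def simulate_behavior_markers(trials: pd.DataFrame, config: GeneratorConfig,
                              rng: Optional[np.random.Generator] = None):
    """Per-frame marker streams for a session.

    Returns ``(markers, teeth_x, neuropil_master)``; ``markers`` has one row
    per video frame with nose x/y, whisker y, tongue likelihood/x and pupil
    diameter.  The nose stream steps at each configured reaction time, the
    pupil baseline is larger on disengaged trials, tongue likelihood exceeds
    its detection threshold only during lick events, and the neuropil master
    trace carries a theta-band oscillation that is stronger before misses.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_trials = len(trials)
    nb = config.n_bins
    n_frames = n_trials * nb
    dt = 1.0 / config.frame_rate
    t = np.arange(n_frames) * dt
    teeth_x = 50.0

    motion_scale = rng.lognormal(0.0, 0.5, max(n_trials, 1))
    per_frame_scale = np.repeat(motion_scale[:n_trials], nb) if n_trials else np.ones(0)

    nose_x = rng.normal(0.0, config.marker_noise_px, n_frames) * per_frame_scale
    nose_y = rng.normal(0.0, config.marker_noise_px, n_frames) * per_frame_scale
    whisker_y = rng.normal(0.0, config.marker_noise_px, n_frames) * per_frame_scale
    tongue_like = rng.normal(config.tongue_baseline, config.tongue_sd, n_frames)
    tongue_x = np.full(n_frames, teeth_x) + rng.normal(0, 0.5, n_frames)
    pupil = (config.pupil_base_px
             + gaussian_filter1d(rng.standard_normal(n_frames),
                                 2.0 * config.frame_rate, mode="nearest")
             * config.pupil_noise_px * 3.0
             + rng.normal(0.0, config.pupil_noise_px, n_frames))

    theta = np.zeros(n_frames)
    for i in range(n_trials):
        sl = slice(i * nb, (i + 1) * nb)
        row = trials.iloc[i]
        miss = row["choice"] == "none"
        amp = config.theta_amp * (config.theta_miss_gain if miss else 1.0)
        theta[sl] = amp * np.sin(2 * np.pi * config.theta_freq_hz * t[sl]
                                 + rng.uniform(0, 2 * np.pi))
        if miss:
            pupil[sl] += config.pupil_disengaged_shift_px
        rt = row["reaction_time_s"]
        if np.isfinite(rt):
            k = i * nb + int(round((config.baseline_s + rt)
                                   * config.frame_rate))
            if 0 <= k < (i + 1) * nb:
                dur = min(int(0.6 * config.frame_rate), (i + 1) * nb - k)
                step = config.nose_step_px * np.exp(
                    -np.arange(dur) / (0.4 * config.frame_rate))
                nose_x[k:k + dur] += step
                whisker_y[k:k + dur] += 0.5 * step
        if row["choice"] in ("1", "2") and np.isfinite(rt):
            side = -8.0 if row["choice"] == "1" else 8.0
            lick_t0 = max(config.baseline_s + config.stimulus_s,
                          config.baseline_s + rt)
            for j in range(3):
                k = i * nb + int(round((lick_t0 + 0.25 * j)
                                       * config.frame_rate))
                if k + 3 <= (i + 1) * nb:
                    tongue_like[k:k + 3] = config.lick_likelihood
                    tongue_x[k:k + 3] = teeth_x + side
    theta += rng.normal(0.0, 0.3, n_frames)
    markers = pd.DataFrame({
        "frame_time_s": t, "nose_x": nose_x, "nose_y": nose_y,
        "whisker_y": whisker_y, "tongue_likelihood": np.clip(tongue_like, 0, 1),
        "tongue_x": tongue_x,
        "nose_likelihood": np.full(n_frames, 0.99),
        "pupil_px": pupil,
        "pupil_likelihood": np.full(n_frames, 0.99),
    })
    return markers, teeth_x, theta


# ---------------------------------------------------------------------------
# session assembly


def generate_session(config: GeneratorConfig) -> SessionBundle:
    """Generate a complete synthetic session (deterministic given the seed)."""
    ss = np.random.SeedSequence(config.seed)
    r_weights, r_trials, r_choice, r_rates, r_fluo, r_mark = [
        np.random.default_rng(s) for s in ss.spawn(6)]

    weights = sample_neuron_weights(config, r_weights)
    alpha = r_weights.uniform(config.alpha_range[0], config.alpha_range[1],
                              len(weights))
    trials = simulate_trials(config, r_trials)
    trials = simulate_choices(trials, config.psychometric, config, r_choice)

    if len(trials):
        drive = _drive_matrix(weights, trials["F1_hz"].to_numpy(),
                              trials["F2_hz"].to_numpy())
    else:
        drive = np.zeros((len(weights), 0))
    gain_coef, gains = solve_engagement_gain(weights, drive, config)
    weights = weights.assign(eng_gain=gains)

    sel = weights["beta_f1"].to_numpy() - weights["beta_f2"].to_numpy()
    scale = max(np.sqrt(2) * 1.2 * config.sensory_weight_sd, 1e-9)
    positions = np.column_stack([
        150.0 * np.tanh(sel / scale) + r_weights.normal(0, 60, len(weights)),
        r_weights.normal(0, 80, len(weights)),
    ])
    truth = GroundTruth(
        weights=weights, alpha=alpha, positions=positions,
        column_centers=np.array([[150.0, 0.0], [-150.0, 0.0]]),
        engaged=trials["engaged"].to_numpy(dtype=bool) if len(trials)
        else np.zeros(0, dtype=bool),
        psychometric=config.psychometric, gain_coef=gain_coef)

    need_bins = config.include_rate_bins or config.include_fluorescence
    epoch, bins, t_bin = simulate_firing_rates(
        truth, trials, config, r_rates, include_bins=need_bins)

    bundle = SessionBundle(config=config, trials=trials, epoch_rates=epoch,
                           truth=truth, bin_time_s=t_bin)
    if config.include_rate_bins:
        bundle.rate_bins = bins
    if config.include_fluorescence and bins is not None and bins.size:
        bundle.fluorescence = synthesize_fluorescence(bins, alpha, config,
                                                      r_fluo)
    if config.include_markers and len(trials):
        markers, teeth_x, theta = simulate_behavior_markers(trials, config,
                                                            r_mark)
        bundle.markers = markers
        bundle.teeth_x = teeth_x
        bundle.neuropil_master = theta
    return bundle
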