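"""Behavioural analyses: psychometrics, outcome classification, video-marker
normalization, reaction-time and lick detection, state covariates, and
optogenetic trial pairing.

The psychometric model is a logistic with guess and lapse asymptotes,

    psi(x) = gamma + (1 - gamma - lambda) / (1 + exp(alpha - x beta)),

fitted by binomial maximum likelihood with bounded asymptotes and random
multi-starts.  The derived midpoint is alpha/beta (Hz) and the maximal slope
beta (1 - gamma - lambda) / 4 (per Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.special import expit

from .exceptions import DegenerateDataError, InputError, SchemaError

__all__ = [
    "PsychometricFit", "MarkerSeries", "psychometric", "fit_psychometric",
    "psychometric_counts", "classify_outcomes", "normalize_pupil",
    "zscore_marker", "detect_reaction_time", "detect_tongue", "theta_power",
    "decile_analysis", "match_trials",
]


@dataclass
class PsychometricFit:
    gamma: float
    lapse: float
    alpha: float
    beta: float
    n_trials: int
    loglik: float
    identifiable: bool = True

    @property
    def midpoint_hz(self) -> float:
        return self.alpha / self.beta if self.beta != 0 else np.nan

    @property
    def max_slope_per_hz(self) -> float:
        return self.beta * (1.0 - self.gamma - self.lapse) / 4.0

    def predict(self, x):
        return psychometric(x, self.gamma, self.lapse, self.alpha, self.beta)


@dataclass
class MarkerSeries:
    """A tracked facial marker: per-frame position + detection likelihood."""

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    frame_time_s: np.ndarray
    name: str = ""

    def __post_init__(self):
        n = len(self.x)
        if not (len(self.y) == len(self.likelihood)
                == len(self.frame_time_s) == n):
            raise InputError("marker series fields must have equal length")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise InputError("likelihood must lie in [0, 1]")


def psychometric(x, gamma, lapse, alpha, beta):
    x = np.asarray(x, dtype=float)
    return gamma + (1.0 - gamma - lapse) * expit(x * beta - alpha)


def _nll(params, x, k, n):
    gamma, lapse, alpha, beta = params
    p = np.clip(psychometric(x, gamma, lapse, alpha, beta), 1e-9, 1 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))


def fit_psychometric(x: Sequence[float], k: Sequence[int], n: Sequence[int],
                     n_starts: int = 10, seed: int = 0) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the lapse-rate logistic.

    ``x`` are stimulus levels (frequency difference, Hz), ``k`` the counts of
    side-1 choices out of ``n`` trials per level.  Asymptotes are bounded in
    [0, 0.5]; ``n_starts`` random initializations guard against local optima.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(np.unique(x)) < 4:
        raise InputError("need at least 4 distinct stimulus levels")
    if np.any(n <= 0):
        raise InputError("each level needs at least one trial")
    if np.any((k < 0) | (k > n)):
        raise InputError("counts must satisfy 0 <= k <= n")

    identifiable = not (k.sum() == 0 or k.sum() == n.sum())
    rng = np.random.default_rng(seed)
    span = max(np.ptp(x), 1.0)
    bounds = [(0.0, 0.5), (0.0, 0.5), (-50.0, 50.0), (1e-4, 10.0)]
    best = None
    starts = [(0.02, 0.02, 0.0, 4.0 / span)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append((rng.uniform(0, 0.2), rng.uniform(0, 0.2),
                       rng.uniform(-span / 4, span / 4) * rng.uniform(0.01, 0.2),
                       10 ** rng.uniform(-2.5, 0.5)))
    for p0 in starts:
        res = optimize.minimize(_nll, p0, args=(x, k, n), method="L-BFGS-B",
                                bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    g, l, a, b = best.x
    return PsychometricFit(gamma=float(g), lapse=float(l), alpha=float(a),
                           beta=float(b), n_trials=int(n.sum()),
                           loglik=-float(best.fun), identifiable=identifiable)


def psychometric_counts(trials: pd.DataFrame,
                        choice_col: str = "choice") -> pd.DataFrame:
    """Aggregate a trial table into per-level (x, k, n) choice-1 counts."""
    resp = trials[trials[choice_col].isin(["1", "2"])]
    grp = resp.groupby("delta_f_hz")[choice_col]
    out = pd.DataFrame({"x": grp.size().index.to_numpy(),
                        "k": grp.apply(lambda s: int((s == "1").sum())).to_numpy(),
                        "n": grp.size().to_numpy()})
    return out


def fit_psychometric_trials(trials: pd.DataFrame, **kw) -> PsychometricFit:
    c = psychometric_counts(trials)
    return fit_psychometric(c["x"], c["k"], c["n"], **kw)


# ---------------------------------------------------------------------------
# outcomes


def classify_outcomes(trials: pd.DataFrame,
                      stimulus_s: float = 1.0) -> pd.DataFrame:
    """Derive outcome and movement-category columns from the trial table.

    Outcome: miss when no lick; otherwise correct iff the first lick matched
    the higher-frequency side (a response on a dF = 0 trial counts correct).
    Category from the reaction time relative to stimulus onset: movement
    before onset -> ``prestim_move`` (flagged for exclusion), before stimulus
    offset -> ``impulsive``, later (or no movement) -> ``delayed``.
    """
    required = {"choice", "delta_f_hz", "reaction_time_s"}
    missing = required - set(trials.columns)
    if missing:
        raise SchemaError(f"trial table missing columns: {sorted(missing)}")
    out = trials.copy()
    choice = out["choice"].astype(str)
    df = out["delta_f_hz"].to_numpy(dtype=float)
    correct = np.where(df > 0, choice == "1",
                       np.where(df < 0, choice == "2", choice != "none"))
    outcome = np.where(choice == "none", "miss",
                       np.where(correct, "correct", "error"))
    rt = out["reaction_time_s"].to_numpy(dtype=float)
    category = np.where(np.isnan(rt) | (rt >= stimulus_s), "delayed",
                        np.where(rt < 0, "prestim_move", "impulsive"))
    out["outcome"] = outcome
    out["trial_category"] = category
    out["exclude_movement"] = category == "prestim_move"
    return out


# ---------------------------------------------------------------------------
# marker normalization


def normalize_pupil(diameter: np.ndarray, likelihood: Optional[np.ndarray] = None,
                    likelihood_threshold: float = 0.5) -> np.ndarray:
    """Scale pupil diameter to its per-session 5th-95th percentile range.

    Frames with detection likelihood below threshold become NaN; by
    construction ~90% of the remaining values fall in [0, 1].
    """
    d = np.asarray(diameter, dtype=float).copy()
    if likelihood is not None:
        d[np.asarray(likelihood) < likelihood_threshold] = np.nan
    valid = np.isfinite(d)
    if valid.sum() == 0:
        warnings.warn("no valid pupil frames after likelihood filtering")
        return d
    if valid.sum() < 100:
        raise InputError("need at least 100 valid pupil frames")
    p5, p95 = np.nanpercentile(d, [5, 95])
    if p95 == p5:
        raise DegenerateDataError("pupil percentile range is zero")
    return (d - p5) / (p95 - p5)


def _per_trial_movement(x: np.ndarray, y: Optional[np.ndarray],
                        n_trials: int) -> np.ndarray:
    """Per-trial movement = Euclidean norm of the (x, y) positional SDs."""
    xs = x.reshape(n_trials, -1).std(axis=1)
    if y is None:
        return xs
    ys = y.reshape(n_trials, -1).std(axis=1)
    return np.hypot(xs, ys)


def zscore_marker(x: np.ndarray, n_trials: int,
                  y: Optional[np.ndarray] = None,
                  baseline_frames: Optional[int] = None,
                  top_fraction: float = 0.05):
    """Session-relative Z-score of a marker position.

    Trials are ranked by movement (SD of position); the top 5% define the
    scale sigma_5high and the bottom 5% the quiet reference.  Ranking ties
    break by trial order (stable sort).  Returns ``(Z, info)`` with the high /
    low trial indices in ``info``.
    """
    x = np.asarray(x, dtype=float)
    if n_trials < 20:
        raise InputError("need >= 20 trials so that 5% is at least one trial")
    per_trial = x.reshape(n_trials, -1)
    frames_per_trial = per_trial.shape[1]
    if baseline_frames is None:
        baseline_frames = max(frames_per_trial // 4, 1)
    movement = _per_trial_movement(x, y, n_trials)
    order = np.argsort(movement, kind="stable")
    n_top = max(int(round(top_fraction * n_trials)), 1)
    low = order[:n_top]
    high = order[-n_top:]
    sigma = per_trial[high].std()
    if sigma == 0:
        raise DegenerateDataError("no movement in the top-5% trials")
    w_hat = per_trial[:, :baseline_frames].mean()
    z = (x - w_hat) / sigma
    return z, {"high_trials": high, "low_trials": low,
               "sigma_5high": sigma, "w_hat": w_hat, "movement": movement}


def detect_reaction_time(z: np.ndarray, frame_time_s: np.ndarray,
                         threshold: float = 0.1) -> Optional[float]:
    """Earliest frame pair whose Z changes by more than the threshold; the
    time of the first frame of the pair is the reaction time (None if the
    trace never moves)."""
    z = np.asarray(z, dtype=float)
    jumps = np.abs(np.diff(z)) > threshold
    if not jumps.any():
        return None
    k = int(np.argmax(jumps))
    return float(frame_time_s[k])


def detect_tongue(likelihood: np.ndarray, tongue_x: np.ndarray,
                  teeth_x: float, n_trials: int,
                  low_trials: np.ndarray,
                  baseline_frames: Optional[int] = None):
    """Detect lick events and their side from the tongue marker.

    The detection threshold is the mean + 3 SD of the likelihood during the
    baseline epoch of the quietest (5_low) trials; lick events are maximal
    runs of frames above threshold, sided by the tongue's x position relative
    to the (session-average) teeth position.  Returns ``(events, threshold)``
    where events are ``(start, end, side)`` with half-open frame intervals.
    """
    likelihood = np.asarray(likelihood, dtype=float)
    per_trial = likelihood.reshape(n_trials, -1)
    if baseline_frames is None:
        baseline_frames = max(per_trial.shape[1] // 4, 1)
    base = per_trial[low_trials, :baseline_frames]
    threshold = base.mean() + 3.0 * base.std()
    if threshold >= 1:
        warnings.warn("tongue threshold >= 1: no detectable licks")
    above = likelihood > threshold
    events = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            side = "right" if np.mean(tongue_x[i:j]) > teeth_x else "left"
            events.append((i, j, side))
            i = j
        else:
            i += 1
    return events, float(threshold)


def theta_power(trace: np.ndarray, n_trials: int, frame_rate: float,
                band: tuple = (2.0, 10.0),
                window_frames: Optional[int] = None) -> np.ndarray:
    """Per-trial spectral power in the slow-oscillation band.

    ``trace`` is reshaped to (n_trials, frames); power spectral density is
    estimated per trial (Welch) over the leading ``window_frames`` frames
    (default: the whole per-trial segment, i.e. the supplied pre-stimulus
    window) and integrated over ``band`` Hz.
    """
    trace = np.asarray(trace, dtype=float).reshape(n_trials, -1)
    if window_frames is not None:
        trace = trace[:, :window_frames]
    nf = trace.shape[1]
    if band[0] > 0 and nf / frame_rate < 1.0 / band[0]:
        warnings.warn("window shorter than one slow-oscillation period; "
                      "band power truncated")
    freqs, psd = signal.welch(trace, fs=frame_rate, nperseg=min(nf, 256),
                              axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return np.trapezoid(psd[:, sel], freqs[sel], axis=1)


def decile_analysis(covariate: np.ndarray, miss: np.ndarray,
                    session: Optional[np.ndarray] = None,
                    n_bins: int = 10):
    """Miss probability across deciles of a per-trial covariate.

    The covariate is rank-normalized per session, pooled, and split into
    ``n_bins`` near-equal groups; returns ``(table, spearman_r, p)`` where
    the Spearman statistic tests the monotone trend over trials.
    """
    covariate = np.asarray(covariate, dtype=float)
    miss = np.asarray(miss, dtype=bool)
    valid = np.isfinite(covariate)
    if valid.sum() < n_bins:
        raise InputError(f"need at least {n_bins} trials with a valid covariate")
    cov, ms = covariate[valid], miss[valid]
    ses = (np.zeros(valid.sum()) if session is None
           else np.asarray(session)[valid])
    ranked = np.empty_like(cov)
    for s in np.unique(ses):
        m = ses == s
        ranked[m] = stats.rankdata(cov[m]) / m.sum()
    order = np.argsort(ranked, kind="stable")
    groups = np.array_split(order, n_bins)
    table = pd.DataFrame({
        "decile": np.arange(1, n_bins + 1),
        "n": [len(g) for g in groups],
        "covariate_mean": [cov[g].mean() for g in groups],
        "p_miss": [ms[g].mean() for g in groups],
    })
    if np.ptp(ranked) == 0 or ms.all() or not ms.any():
        r, p = np.nan, np.nan
    else:
        r, p = stats.spearmanr(ranked, ms.astype(float))
    return table, r, p


# ---------------------------------------------------------------------------
# optogenetic pairing


def match_trials(trials: pd.DataFrame, opto_label: Optional[str] = None):
    """Pair each optogenetic trial with the closest unused sham trial having
    identical stimulus frequencies (ties -> the earlier sham).

    Returns ``(pairs, n_unmatched)`` where pairs is a list of
    ``(opto_index, sham_index)`` trial-table indices.
    """
    is_opto = ~trials["opto"].isin(["sham", "none"])
    if opto_label is not None:
        is_opto &= trials["opto"] == opto_label
    opto = trials[is_opto]
    sham = trials[trials["opto"] == "sham"]
    if len(opto) == 0 or len(sham) == 0:
        raise InputError("need non-empty optogenetic and sham trial sets")
    used = set()
    pairs = []
    n_unmatched = 0
    for idx, row in opto.iterrows():
        cand = sham[(sham["F1_hz"] == row["F1_hz"])
                    & (sham["F2_hz"] == row["F2_hz"])]
        cand = cand[~cand.index.isin(used)]
        if len(cand) == 0:
            n_unmatched += 1
            continue
        dist = (cand["trial_index"] - row["trial_index"]).abs()
        best = cand.index[np.lexsort((cand["trial_index"].to_numpy(),
                                      dist.to_numpy()))[0]]
        used.add(best)
        pairs.append((idx, best))
    return pairs, n_unmatched
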