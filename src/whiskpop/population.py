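"""Population pooling, neurometric decoding and representational geometry.

Single-neuron activities are summarized into weighted population averages
(latent signals) using the encoding weights,

    Rw1 = sum_n(betaF1,n Rn) / sum_n(|betaF1,n|),

restricted to the pool of neurons preferring the defining regressor over its
rival.  Latent signals support threshold decoding (ROC-optimal), neurometric
curves, choice-probability (AUROC) analyses, representational angles between
coding dimensions, and engagement modulation ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import PsychometricFit, fit_psychometric
from .exceptions import DegenerateDataError, InputError

__all__ = [
    "Pool", "GeometryResult", "assign_pools", "pool_signal", "roc_threshold",
    "decode_labels", "neurometric_curve", "neurons_needed", "neuron_auroc",
    "choice_decode_timecourse", "representational_angle",
    "condition_angles", "engagement_ratio", "engagement_profile",
    "stimulus_matched_subset",
]


@dataclass
class Pool:
    name: str
    members: np.ndarray          # neuron indices
    weights: np.ndarray          # defining beta per member

    def __len__(self):
        return len(self.members)


@dataclass
class GeometryResult:
    theta_deg: float
    arrow: np.ndarray
    mean_group1: np.ndarray
    mean_group2: np.ndarray
    n_group1: int
    n_group2: int
    degenerate: bool = False


def assign_pools(weights: pd.DataFrame, col1: str, col2: str,
                 names: tuple = ("pool1", "pool2")):
    """Split neurons into two pools by strict preference between two
    regressor weights (ties excluded).  Pool weights are the defining betas."""
    b1 = weights[col1].to_numpy(dtype=float)
    b2 = weights[col2].to_numpy(dtype=float)
    m1 = np.where(b1 > b2)[0]
    m2 = np.where(b2 > b1)[0]
    pools = (Pool(names[0], m1, b1[m1]), Pool(names[1], m2, b2[m2]))
    for p in pools:
        if len(p) == 0:
            warnings.warn(f"pool {p.name} is empty")
    return pools


def interaction_pool(weights: pd.DataFrame, name: str = "w1xw2",
                     suffix: str = "",
                     dominant_only: bool = False,
                     regressor_scale=(1.0, 1.0, 1.0)) -> Pool:
    """Multi-whisker pool: all neurons weighted by the interaction weight.

    Unlike the two single-whisker pools, the interaction signal has no rival
    alternative, so by default every neuron contributes with weight
    betaF1xF2 (the Eq.-2 analogue).  With ``dominant_only`` the pool is
    restricted to neurons whose interaction term dominates both
    single-whisker terms on the drive scale (|beta| times the session-mean
    regressor value, ``regressor_scale``).  ``suffix`` selects the weight
    columns (e.g. ``"_raw"`` for native-scale fitted weights).
    """
    bx = weights["beta_f1xf2" + suffix].to_numpy(dtype=float)
    if dominant_only:
        s1, s2, s12 = regressor_scale
        b1 = np.abs(weights["beta_f1" + suffix].to_numpy(dtype=float)) * s1
        b2 = np.abs(weights["beta_f2" + suffix].to_numpy(dtype=float)) * s2
        m = np.where((np.abs(bx) * s12 > b1) & (np.abs(bx) * s12 > b2))[0]
    else:
        m = np.where(bx != 0)[0]
    return Pool(name, m, bx[m])


def regressor_scale_from_trials(trials: pd.DataFrame) -> tuple:
    """Session-mean magnitudes of the three sensory regressors."""
    s1 = np.sqrt(trials["F1_hz"].to_numpy(dtype=float))
    s2 = np.sqrt(trials["F2_hz"].to_numpy(dtype=float))
    return (float(s1.mean()), float(s2.mean()), float((s1 * s2).mean()))


def pool_signal(activity: np.ndarray, pool: Pool) -> np.ndarray:
    """Weighted population average sum(beta_n R_n) / sum(|beta_n|).

    ``activity`` is (neurons, trials) or (neurons, trials, bins); the neuron
    axis is contracted.
    """
    if len(pool) == 0:
        raise InputError(f"pool {pool.name} is empty")
    w = pool.weights
    sub = activity[pool.members]
    return np.tensordot(w, sub, axes=(0, 0)) / np.abs(w).sum()


# ---------------------------------------------------------------------------
# ROC decoding


def _auc_mannwhitney(values: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(values)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def roc_threshold(signal: np.ndarray, labels: np.ndarray):
    """AUC and Youden-optimal threshold of a scalar signal.

    The threshold maximizes TPR - FPR (Youden's J) over midpoints between
    consecutive observed values.  The empirical maximum is typically flat up
    to sampling noise, so all candidates whose J lies within one
    reclassified trial per class of the maximum (J >= Jmax - tie_tol, with
    tie_tol = 2 / min(n1, n0)) are treated as ties and the centre of the
    tying range is returned — this keeps the estimate symmetric instead of
    landing on an arbitrary spike of the flat region.
    """
    signal = np.asarray(signal, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("both label classes must be present")
    auc = _auc_mannwhitney(signal, labels)
    uniq = np.unique(signal)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    tpr = (signal[labels][None, :] > cands[:, None]).mean(axis=1)
    fpr = (signal[~labels][None, :] > cands[:, None]).mean(axis=1)
    j = tpr - fpr
    tie_tol = 2.0 / min(n1, n0)
    best = np.flatnonzero(j >= j.max() - tie_tol)
    thr = (cands[best[0]] + cands[best[-1]]) / 2.0
    return float(auc), float(thr)


def decode_labels(signal: np.ndarray, threshold: float, labels: np.ndarray,
                  delta_f: Optional[np.ndarray] = None):
    """Threshold decoding with a fixed threshold.

    Returns ``(fraction_correct, curve)``; the curve gives the fraction of
    trials decoded as the positive class per frequency difference (None when
    ``delta_f`` is not supplied).
    """
    signal = np.asarray(signal, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(signal) == 0:
        raise InputError("empty trial subset")
    pred = signal > threshold
    fc = float((pred == labels).mean())
    curve = None
    if delta_f is not None:
        df = pd.DataFrame({"delta_f_hz": delta_f, "pred": pred})
        curve = (df.groupby("delta_f_hz")["pred"].agg(["mean", "size"])
                 .rename(columns={"mean": "p_decoded_1", "size": "n"})
                 .reset_index())
    return fc, curve


def neurometric_curve(signal: np.ndarray, trials: pd.DataFrame,
                      threshold: Optional[float] = None,
                      seed: int = 0) -> tuple:
    """Neurometric function: decode the target side per trial by thresholding
    the latent signal, then fit the decoded fractions with the same
    lapse-rate logistic used for behaviour.

    Returns ``(fit, curve, threshold)``.
    """
    df = trials["delta_f_hz"].to_numpy(dtype=float)
    labels = df > 0
    if threshold is None:
        informative = df != 0
        _, threshold = roc_threshold(signal[informative], labels[informative])
    pred = signal > threshold
    tab = pd.DataFrame({"x": df, "pred": pred}).groupby("x")["pred"]
    x = tab.mean().index.to_numpy()
    k = tab.sum().to_numpy()
    n = tab.size().to_numpy()
    fit = fit_psychometric(x, k, n, seed=seed)
    curve = pd.DataFrame({"delta_f_hz": x, "p_decoded_1": k / n, "n": n})
    return fit, curve, float(threshold)


def neurons_needed(activity: np.ndarray, pools: Sequence[Pool],
                   trials: pd.DataFrame, behavioral_fc: float,
                   k_max: Optional[int] = None, repeats: int = 100,
                   seed: int = 0):
    """Smallest per-pool sample size whose decoded accuracy matches behaviour.

    For each k, ``repeats`` random subsamples of k neurons per pool are drawn;
    the differential signal is re-pooled, an ROC threshold fitted, and the
    decoded fraction correct averaged.  Returns ``(k_needed, table, reached)``
    — when even the largest k fails, k_max is returned with
    ``reached=False``.
    """
    rng = np.random.default_rng(seed)
    df = trials["delta_f_hz"].to_numpy(dtype=float)
    keep = df != 0
    labels = df[keep] > 0
    if k_max is None:
        k_max = min(len(p) for p in pools)
    if k_max < 1:
        raise InputError("a pool is empty")
    rows = []
    k_needed, reached = None, False
    for k in range(1, k_max + 1):
        fcs = np.empty(repeats)
        for r in range(repeats):
            sig = np.zeros(int(keep.sum()))
            for p in pools:
                sel = rng.choice(len(p), size=min(k, len(p)), replace=False)
                sub = Pool(p.name, p.members[sel], p.weights[sel])
                s = pool_signal(activity, sub)[keep]
                sig = sig + (s if p.name.endswith("1") else -s)
            _, thr = roc_threshold(sig, labels)
            fcs[r], _ = decode_labels(sig, thr, labels)
        rows.append({"k": k, "mean_fc": fcs.mean(), "sd_fc": fcs.std()})
        if k_needed is None and fcs.mean() >= behavioral_fc:
            k_needed, reached = k, True
            break
    if k_needed is None:
        k_needed = k_max
    return k_needed, pd.DataFrame(rows), reached


# ---------------------------------------------------------------------------
# choice probability


def _auc_matrix(rates: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC of (neurons, trials) rates vs bool labels."""
    ranks = stats.rankdata(rates, axis=1)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return (ranks[:, labels].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)


def neuron_auroc(rates: np.ndarray, label2: np.ndarray,
                 n_permutations: int = 1000, seed: int = 0,
                 method: str = "permutation") -> pd.DataFrame:
    """Per-neuron AUROC with the preferred-side sign convention.

    ``label2`` flags the second alternative (F1 < F2 target, or choice 2):
    the returned AUROC is < 0.5 when a neuron fires more on F1 > F2 /
    choice-1 trials and > 0.5 for the opposite preference.  Classes are
    balanced by subsampling the larger one; significance is assessed against
    a label-permutation null (default) or a bootstrap CI95.
    """
    rates = np.asarray(rates, dtype=float)
    label2 = np.asarray(label2, dtype=bool)
    rng = np.random.default_rng(seed)
    i2 = np.flatnonzero(label2)
    i1 = np.flatnonzero(~label2)
    if len(i1) == 0 or len(i2) == 0:
        raise InputError("both classes must be present")
    m = min(len(i1), len(i2))
    sel = np.concatenate([rng.choice(i1, m, replace=False),
                          rng.choice(i2, m, replace=False)])
    sub = rates[:, sel]
    lab = label2[sel]
    auc = _auc_matrix(sub, lab)
    obs = np.abs(auc - 0.5)
    if method == "permutation":
        exceed = np.zeros(rates.shape[0])
        for _ in range(n_permutations):
            perm = rng.permutation(lab)
            exceed += np.abs(_auc_matrix(sub, perm) - 0.5) >= obs - 1e-12
        p = (exceed + 1) / (n_permutations + 1)
        sig = p < 0.05
    elif method == "bootstrap":
        boots = np.empty((n_permutations, rates.shape[0]))
        for b in range(n_permutations):
            idx = rng.integers(0, sub.shape[1], sub.shape[1])
            boots[b] = _auc_matrix(sub[:, idx], lab[idx])
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        sig = (lo > 0.5) | (hi < 0.5)
        p = np.full(rates.shape[0], np.nan)
    else:
        raise InputError(f"unknown method {method!r}")
    return pd.DataFrame({"auroc": auc, "p": p, "significant": sig})


# ---------------------------------------------------------------------------
# stimulus matching and time courses


def stimulus_matched_subset(trials: pd.DataFrame, group2: np.ndarray,
                            seed: int = 0) -> np.ndarray:
    """Positional indices of a subset with equal group counts per stimulus
    condition (the larger group is subsampled; unmatched conditions drop)."""
    rng = np.random.default_rng(seed)
    group2 = np.asarray(group2, dtype=bool)
    cond = list(zip(trials["F1_hz"], trials["F2_hz"]))
    keep = []
    for c in sorted(set(cond)):
        pos = np.flatnonzero([cc == c for cc in cond])
        g1 = pos[~group2[pos]]
        g2 = pos[group2[pos]]
        m = min(len(g1), len(g2))
        if m == 0:
            continue
        keep.extend(rng.choice(g1, m, replace=False))
        keep.extend(rng.choice(g2, m, replace=False))
    return np.sort(np.array(keep, dtype=int))


def choice_decode_timecourse(rate_bins: np.ndarray, trials: pd.DataFrame,
                             epoch_rates: dict, cv_folds: int = 10,
                             seed: int = 0) -> pd.DataFrame:
    """Decoded choice-side accuracy as a function of time in the trial.

    Uses response trials matched for stimulus condition; within each
    cross-validation fold the choice-variant weights, pools and per-bin
    thresholds come from the training trials only, and accuracy is scored on
    the held-out trials, per time bin.
    """
    from .encoding import build_design, fit_population
    rng = np.random.default_rng(seed)
    is_resp = trials["choice"].isin(["1", "2"]).to_numpy()
    resp = trials[is_resp].reset_index(drop=True)
    pos_all = np.flatnonzero(is_resp)
    miss_pos = np.flatnonzero(~is_resp)     # C1 = C2 = 0 rows: they keep the
    choice2 = (resp["choice"] == "2").to_numpy()  # choice columns identifiable
    sel = stimulus_matched_subset(resp, choice2, seed=seed)
    if len(sel) < 2 * cv_folds:
        raise InputError("too few matched trials for the requested folds")
    resp = resp.iloc[sel].reset_index(drop=True)
    pos = pos_all[sel]
    choice2 = choice2[sel]
    n_bins = rate_bins.shape[2]
    folds = rng.permutation(len(resp)) % cv_folds
    correct = np.zeros(n_bins)
    total = 0
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        if choice2[tr].all() or not choice2[tr].any():
            continue
        fit_pos = np.concatenate([pos[tr], miss_pos])
        sub_trials = trials.iloc[fit_pos].copy().reset_index(drop=True)
        sub_trials["trial_category"] = "delayed"
        design = build_design(sub_trials,
                              {k: v[:, fit_pos] for k, v in
                               epoch_rates.items()}, variant="choice")
        fits = fit_population(design)
        p1, p2 = assign_pools(fits, "beta_c1", "beta_c2", ("c1", "c2"))
        if len(p1) == 0 or len(p2) == 0:
            continue
        for b in range(n_bins):
            s_tr = (pool_signal(rate_bins[:, pos[tr], b], p1)
                    - pool_signal(rate_bins[:, pos[tr], b], p2))
            s_te = (pool_signal(rate_bins[:, pos[te], b], p1)
                    - pool_signal(rate_bins[:, pos[te], b], p2))
            auc, thr = roc_threshold(s_tr, choice2[tr])
            pred = (s_te > thr) if auc >= 0.5 else (s_te <= thr)
            correct[b] += (pred == choice2[te]).sum()
        total += int(te.sum())
    if total == 0:
        raise InputError("no usable folds")
    return pd.DataFrame({"bin": np.arange(n_bins),
                         "fraction_correct": correct / total})


# ---------------------------------------------------------------------------
# representational geometry


def representational_angle(dim_x: np.ndarray, dim_y: np.ndarray,
                           group2: np.ndarray,
                           trials: Optional[pd.DataFrame] = None,
                           match_conditions: bool = True,
                           standardize: bool = True,
                           min_per_group: int = 5,
                           seed: int = 0) -> GeometryResult:
    """Angle between a coding axis and the group-transition arrow.

    The arrow runs from the group-1 mean to the group-2 mean of per-trial
    population coordinates (dim_x, dim_y); theta is its angle to the +x axis
    folded to [0, 180) degrees, so 90 means the transition is orthogonal to
    the x dimension.  Axes are z-scored over the included trials; by default
    group counts are first equalized within each stimulus condition.
    """
    dim_x = np.asarray(dim_x, dtype=float)
    dim_y = np.asarray(dim_y, dtype=float)
    group2 = np.asarray(group2, dtype=bool)
    idx = np.arange(len(dim_x))
    if match_conditions:
        if trials is None:
            raise InputError("match_conditions requires the trial table")
        idx = stimulus_matched_subset(trials, group2, seed=seed)
    x, y, g = dim_x[idx], dim_y[idx], group2[idx]
    n1, n2 = int((~g).sum()), int(g.sum())
    if n1 < min_per_group or n2 < min_per_group:
        raise InputError(
            f"need >= {min_per_group} trials per group (got {n1}, {n2})")
    if standardize:
        if x.std() == 0 or y.std() == 0:
            raise DegenerateDataError("a dimension has zero variance")
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
    m1 = np.array([x[~g].mean(), y[~g].mean()])
    m2 = np.array([x[g].mean(), y[g].mean()])
    arrow = m2 - m1
    if np.allclose(arrow, 0):
        return GeometryResult(np.nan, arrow, m1, m2, n1, n2, degenerate=True)
    theta = np.degrees(np.arctan2(arrow[1], arrow[0]))
    if theta < 0:
        theta += 180.0
    return GeometryResult(float(theta), arrow, m1, m2, n1, n2)


def condition_angles(dim_x, dim_y, group2, trials: pd.DataFrame,
                     min_per_group: int = 5, standardize: bool = True,
                     seed: int = 0) -> pd.DataFrame:
    """Per-stimulus-condition representational angles (conditions with fewer
    than ``min_per_group`` trials in either group are omitted)."""
    group2 = np.asarray(group2, dtype=bool)
    rows = []
    for (f1, f2), grp in trials.groupby(["F1_hz", "F2_hz"]):
        pos = trials.index.get_indexer(grp.index)
        g = group2[pos]
        if (~g).sum() < min_per_group or g.sum() < min_per_group:
            continue
        res = representational_angle(
            np.asarray(dim_x)[pos], np.asarray(dim_y)[pos], g,
            match_conditions=False, standardize=standardize,
            min_per_group=min_per_group, seed=seed)
        rows.append({"F1_hz": f1, "F2_hz": f2, "theta_deg": res.theta_deg,
                     "n1": res.n_group1, "n2": res.n_group2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# engagement modulation


def engagement_ratio(epoch_rates: dict, pool: Pool, engaged: np.ndarray,
                     trials: pd.DataFrame, baseline_normalize: bool = True,
                     seed: int = 0) -> float:
    """Percent modulation of a pooled signal by task engagement.

    Engaged and disengaged trials are matched for stimulus condition; the
    modulation is 100 (mean_engaged / mean_disengaged - 1) of the pooled
    signal — of the evoked (stimulus - baseline) signal when
    ``baseline_normalize`` is set.
    """
    engaged = np.asarray(engaged, dtype=bool)
    idx = stimulus_matched_subset(trials, ~engaged, seed=seed)
    if len(idx) == 0:
        raise InputError("no stimulus-matched engaged/disengaged trials")
    if baseline_normalize:
        sig = (pool_signal(epoch_rates["stimulus"], pool)
               - pool_signal(epoch_rates["baseline"], pool))
    else:
        sig = pool_signal(epoch_rates["stimulus"], pool)
    e = sig[idx][engaged[idx]].mean()
    d = sig[idx][~engaged[idx]].mean()
    if abs(d) < 1e-12:
        raise DegenerateDataError("disengaged reference signal is ~0")
    return float(100.0 * (e / d - 1.0))


def engagement_profile(epoch_rates: dict, weights: np.ndarray,
                       engaged: np.ndarray, trials: pd.DataFrame,
                       n_bins: int = 10, seed: int = 0) -> pd.DataFrame:
    """Single-neuron engagement modulation versus encoding weight.

    Neurons are split into ``n_bins`` equal-count bins of the supplied weight;
    each bin reports the mean engaged/disengaged evoked-rate ratio over
    stimulus-matched trials.
    """
    engaged = np.asarray(engaged, dtype=bool)
    idx = stimulus_matched_subset(trials, ~engaged, seed=seed)
    ev = epoch_rates["stimulus"][:, idx] - epoch_rates["baseline"][:, idx]
    e = ev[:, engaged[idx]].mean(axis=1)
    d = ev[:, ~engaged[idx]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(d) > 1e-12, e / d, np.nan)
    order = np.argsort(weights, kind="stable")
    groups = np.array_split(order, n_bins)
    return pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "weight_mean": [weights[g].mean() for g in groups],
        "ratio_mean": [np.nanmean(ratio[g]) for g in groups],
    })
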