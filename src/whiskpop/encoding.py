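"""Per-neuron linear encoding models.

Single-neuron activity (1-s epoch means of deconvolved rate, baseline and
stimulus epochs concatenated) is regressed on the square-rooted whisker
stimulation frequencies and their interaction,

    Rn = b0 + bF1 sqrt(F1) + bF2 sqrt(F2) + bF1xF2 sqrt(F1 F2) + eps,

with optional binary choice regressors (C1, C2) or an engagement regressor.
Regressors and responses are z-scored; sensory regressors are zero during
baseline epochs.  The choice variant is fitted on stimulus rows of delayed /
no-response trials only (choice is undefined at baseline); the engagement
variant keeps both epochs of those trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .exceptions import CollinearityError, InputError

__all__ = [
    "DesignMatrix", "NeuronFit", "build_design", "fit_neuron",
    "fit_population", "compare_models", "selectivity_index",
    "classify_response", "classify_population", "stimulus_space_auc",
]

SENSORY_COLS = ["sqrt_f1", "sqrt_f2", "sqrt_f1xf2"]


@dataclass
class DesignMatrix:
    X: np.ndarray                 # (rows, columns), z-scored
    columns: list
    responses: np.ndarray         # (rows, neurons), z-scored per neuron
    row_epoch: np.ndarray         # 'baseline' / 'stimulus'
    trial_index: np.ndarray
    variant: str
    X_raw: np.ndarray             # pre-z-scoring values
    col_mean: np.ndarray
    col_sd: np.ndarray
    resp_mean: np.ndarray
    resp_sd: np.ndarray


@dataclass
class NeuronFit:
    weights: dict                 # column -> beta (z-scored scale)
    intercept: float
    r2: float
    cv_r2: Optional[float]
    variance_shares: dict         # column -> delta r2 (leave-one-out)
    residual_var: float
    fold_assignments: Optional[np.ndarray] = None

    def __getitem__(self, key):
        return self.weights[key]


def _zscore_cols(M: np.ndarray, names: Sequence[str]):
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise CollinearityError(
            f"regressor(s) constant across rows: {[names[i] for i in bad]}")
    return (M - mean) / sd, mean, sd


def build_design(trials: pd.DataFrame, epoch_rates: dict,
                 variant: str = "sensory") -> DesignMatrix:
    """Assemble the regression design and z-scored response matrix.

    ``epoch_rates`` maps 'baseline'/'stimulus' to (neurons, trials) mean-rate
    arrays.  For the sensory variant every trial contributes a baseline row
    (sensory regressors zero) and a stimulus row.  The choice variant uses
    stimulus rows of delayed-response and no-response trials only, adding
    binary C1/C2 regressors (both zero on no-response trials); the engagement
    variant keeps both epochs of those trials and adds the engagement flag.
    """
    if variant not in ("sensory", "choice", "engagement"):
        raise InputError(f"unknown variant {variant!r}")
    if variant == "sensory":
        keep = trials
    else:
        keep = trials[(trials["choice"] == "none")
                      | (trials["trial_category"] == "delayed")]
    tidx = keep["trial_index"].to_numpy()
    pos = trials.index.get_indexer(keep.index)
    s1 = np.sqrt(keep["F1_hz"].to_numpy(dtype=float))
    s2 = np.sqrt(keep["F2_hz"].to_numpy(dtype=float))
    s12 = s1 * s2
    sens = np.column_stack([s1, s2, s12])
    n_k = len(keep)

    base = epoch_rates["baseline"][:, pos].T      # (trials, neurons)
    stim = epoch_rates["stimulus"][:, pos].T

    if variant == "choice":
        cho = keep["choice"].to_numpy()
        extra = np.column_stack([(cho == "1").astype(float),
                                 (cho == "2").astype(float)])
        X_raw = np.column_stack([sens, extra])
        columns = SENSORY_COLS + ["c1", "c2"]
        Y = stim
        epochs = np.full(n_k, "stimulus")
        trial_out = tidx
    else:
        X_raw = np.vstack([np.zeros((n_k, 3)), sens])
        columns = list(SENSORY_COLS)
        if variant == "engagement":
            eng = keep["engaged"].to_numpy(dtype=float)
            X_raw = np.column_stack([X_raw, np.concatenate([eng, eng])])
            columns.append("engaged")
        Y = np.vstack([base, stim])
        epochs = np.concatenate([np.full(n_k, "baseline"),
                                 np.full(n_k, "stimulus")])
        trial_out = np.concatenate([tidx, tidx])

    X, cmean, csd = _zscore_cols(X_raw, columns)
    rmean = Y.mean(axis=0)
    rsd = Y.std(axis=0)
    rsd_safe = np.where(rsd == 0, 1.0, rsd)
    R = (Y - rmean) / rsd_safe
    return DesignMatrix(X=X, columns=columns, responses=R, row_epoch=epochs,
                        trial_index=trial_out, variant=variant, X_raw=X_raw,
                        col_mean=cmean, col_sd=csd, resp_mean=rmean,
                        resp_sd=rsd)


def _solve(X1: np.ndarray, y: np.ndarray) -> np.ndarray:
    # QR-based least squares (gelsy)
    beta, *_ = linalg.lstsq(X1, y, lapack_driver="gelsy")
    return beta


def _r2(y, yhat):
    ss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum((y - yhat) ** 2) / ss if ss > 0 else np.nan


def fit_neuron(response: np.ndarray, design: DesignMatrix,
               cv_folds: Optional[int] = None, seed: int = 0) -> NeuronFit:
    """Least-squares fit of one neuron's response to the design.

    Solved by orthogonal (QR) decomposition; when ``cv_folds`` is given the
    reported ``cv_r2`` is measured on held-out folds.  Per-regressor variance
    shares are leave-one-regressor-out drops in training r2.
    """
    y = np.asarray(response, dtype=float)
    X = design.X
    n, k = X.shape
    if n <= k + 1:
        raise InputError("need more observations than regressors")
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(
            f"rank-deficient design (columns {design.columns})")
    X1 = np.column_stack([np.ones(n), X])
    beta = _solve(X1, y)
    yhat = X1 @ beta
    r2 = _r2(y, yhat)
    resid_var = float(np.var(y - yhat))

    shares = {}
    for j, col in enumerate(design.columns):
        Xr = np.delete(X1, j + 1, axis=1)
        shares[col] = r2 - _r2(y, Xr @ _solve(Xr, y))

    cv_r2 = None
    folds = None
    if cv_folds:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(n) % cv_folds
        yhat_cv = np.empty(n)
        for f in range(cv_folds):
            tr, te = folds != f, folds == f
            yhat_cv[te] = X1[te] @ _solve(X1[tr], y[tr])
        cv_r2 = _r2(y, yhat_cv)
    return NeuronFit(weights=dict(zip(design.columns, beta[1:])),
                     intercept=float(beta[0]), r2=float(r2), cv_r2=cv_r2,
                     variance_shares=shares, residual_var=resid_var,
                     fold_assignments=folds)


def fit_population(design: DesignMatrix) -> pd.DataFrame:
    """Fit every neuron against the shared design in one multi-RHS solve.

    Returns a DataFrame with one row per neuron: fitted weights (columns
    ``beta_<regressor>``), intercept and training r2.
    """
    X1 = np.column_stack([np.ones(len(design.X)), design.X])
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise CollinearityError("rank-deficient design")
    B = _solve(X1, design.responses)          # (k+1, neurons)
    Yhat = X1 @ B
    ss_res = ((design.responses - Yhat) ** 2).sum(axis=0)
    ss_tot = ((design.responses - design.responses.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), np.nan)
    name_map = {"sqrt_f1": "beta_f1", "sqrt_f2": "beta_f2",
                "sqrt_f1xf2": "beta_f1xf2", "c1": "beta_c1", "c2": "beta_c2",
                "engaged": "beta_eng"}
    out = {"intercept": B[0], "r2": r2}
    for j, col in enumerate(design.columns):
        name = name_map.get(col, f"beta_{col}")
        out[name] = B[j + 1]
        # weights back on the native regressor/response scale (rate per unit
        # regressor), for pooling and recovery against generator truth
        out[name + "_raw"] = B[j + 1] * design.resp_sd / design.col_sd[j]
    return pd.DataFrame(out)


def compare_models(response: np.ndarray, design_full: DesignMatrix,
                   design_reduced: DesignMatrix,
                   cv_folds: Optional[int] = None, seed: int = 0) -> dict:
    """AIC and explained-variance comparison of nested encoding models.

    AIC uses the Gaussian likelihood with the residual-variance MLE:
    AIC = n log(RSS/n) + 2 k.  Positive ``delta_aic`` (= AIC_full -
    AIC_reduced) favours the reduced model.
    """
    if len(design_full.X) != len(design_reduced.X):
        raise InputError("designs must describe the same observations")
    y = np.asarray(response, dtype=float)
    n = len(y)
    out = {}
    for tag, design in (("full", design_full), ("reduced", design_reduced)):
        fit = fit_neuron(y, design, cv_folds=cv_folds, seed=seed)
        X1 = np.column_stack([np.ones(n), design.X])
        rss = np.sum((y - X1 @ np.concatenate(
            [[fit.intercept], [fit.weights[c] for c in design.columns]])) ** 2)
        k = design.X.shape[1] + 2      # + intercept + noise variance
        out[tag] = {"fit": fit,
                    "aic": n * np.log(max(rss, 1e-300) / n) + 2 * k}
    out["delta_aic"] = out["full"]["aic"] - out["reduced"]["aic"]
    out["delta_r2"] = out["full"]["fit"].r2 - out["reduced"]["fit"].r2
    return out


def selectivity_index(fr1, fr2):
    """Bounded whisker-selectivity index (FR1 - FR2) / (FR1 + FR2).

    +1 = responds only to whisker 1, -1 = only to whisker 2.  Undefined
    (NaN) when both rates are zero.
    """
    fr1 = np.asarray(fr1, dtype=float)
    fr2 = np.asarray(fr2, dtype=float)
    denom = fr1 + fr2
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.where(denom != 0, (fr1 - fr2) / denom, np.nan)
    return si if si.ndim else float(si)


def classify_response(stim_rates: np.ndarray, base_rates: np.ndarray,
                      alpha: float = 0.05) -> str:
    """Label one neuron activated / suppressed / none by a two-sided paired
    t-test of per-trial stimulus vs baseline means."""
    stim = np.asarray(stim_rates, dtype=float)
    base = np.asarray(base_rates, dtype=float)
    if len(stim) < 20:
        raise InputError("need at least 20 trials")
    diff = stim - base
    if np.all(diff == diff[0]):
        return "none"
    t, p = stats.ttest_rel(stim, base)
    if p < alpha:
        return "activated" if t > 0 else "suppressed"
    return "none"


def classify_population(epoch_rates: dict, alpha: float = 0.05):
    """Vectorized response classification for all neurons.

    Returns ``(labels, fractions)`` with fractions of activated and
    suppressed neurons in percent.
    """
    stim = epoch_rates["stimulus"]
    base = epoch_rates["baseline"]
    if stim.shape[1] < 20:
        raise InputError("need at least 20 trials")
    t, p = stats.ttest_rel(stim, base, axis=1)
    sd = (stim - base).std(axis=1)
    labels = np.where((p < alpha) & (sd > 0),
                      np.where(t > 0, "activated", "suppressed"), "none")
    frac = {"activated_pct": 100.0 * np.mean(labels == "activated"),
            "suppressed_pct": 100.0 * np.mean(labels == "suppressed")}
    return labels, frac


def stimulus_space_auc(fit: NeuronFit, design: DesignMatrix,
                       trials: pd.DataFrame):
    """Discriminability of the target side from one neuron's fitted activity.

    Evaluates the fitted model on each trial's stimulus condition, then runs
    an ROC of predicted activity against the label F1 > F2 across trials
    (dF = 0 trials are excluded).  Returns ``(auc, best_threshold)`` with the
    AUC folded to >= 0.5 and the Youden-optimal iso-activity boundary.
    """
    from .population import roc_threshold
    s1 = np.sqrt(trials["F1_hz"].to_numpy(dtype=float))
    s2 = np.sqrt(trials["F2_hz"].to_numpy(dtype=float))
    raw = np.column_stack([s1, s2, s1 * s2])
    Xz = (raw - design.col_mean[:3]) / design.col_sd[:3]
    pred = fit.intercept + Xz @ np.array(
        [fit.weights[c] for c in SENSORY_COLS])
    df = trials["delta_f_hz"].to_numpy(dtype=float)
    keep = df != 0
    labels = df[keep] > 0
    if labels.all() or not labels.any():
        raise InputError("need both target sides to compute an ROC")
    auc, thr = roc_threshold(pred[keep], labels)
    if auc < 0.5:
        auc, thr = roc_threshold(-pred[keep], labels)
        thr = -thr
    return float(auc), float(thr)
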