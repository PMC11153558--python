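"""End-to-end orchestration: simulate -> preprocess -> behaviour -> encoding
-> population -> spatial, with a machine-readable metrics report.

A single global seed fans out deterministically into per-stage child seeds,
so re-running with the same configuration reproduces every number in the
report bit for bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, encoding, population, spatial
from .config import RunConfig
from .exceptions import ConfigurationError
from .synthetic import generate_session
from .traces import TraceBundle, preprocess_trace

log = logging.getLogger("whiskpop")

__all__ = ["run_pipeline", "session_analysis"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def session_analysis(bundle, cv_folds: int = 10, seed: int = 0) -> dict:
    """Standard per-session analysis battery on a generated session.

    Returns fitted weight tables, pools, latent signals and summary metrics
    used by both :func:`run_pipeline` and the acceptance script.
    """
    out: dict = {}
    trials = bundle.trials
    rates = bundle.epoch_rates

    design = encoding.build_design(trials, rates, variant="sensory")
    fits = encoding.fit_population(design)
    out["fits"] = fits
    out["weight_correlations"] = {
        k: float(v) for k, v in zip(
            ("pearson_f1_f2", "spearman_f1_f1x2", "spearman_f2_f1x2"),
            _fitted_corrs(fits))}

    labels, frac = encoding.classify_population(rates)
    out["response_labels"] = labels
    out["response_fractions"] = frac

    w1, w2 = population.assign_pools(fits, "beta_f1_raw", "beta_f2_raw",
                                     ("w1", "w2"))
    wx = population.interaction_pool(fits, suffix="_raw")
    out["pools"] = {"w1": w1, "w2": w2, "w1xw2": wx}
    if len(w1) and len(w2):
        diff = (population.pool_signal(rates["stimulus"], w1)
                - population.pool_signal(rates["stimulus"], w2))
        df = trials["delta_f_hz"].to_numpy(dtype=float)
        keep = df != 0
        auc, thr = population.roc_threshold(diff[keep], df[keep] > 0)
        out["sensory_decoder"] = {"auc": float(auc), "threshold": float(thr)}
        fc, _ = population.decode_labels(diff[keep], thr, df[keep] > 0)
        out["sensory_decoder"]["fraction_correct"] = fc
    return out


def engagement_modulation(bundle, seed: int = 0) -> dict:
    """Percent engagement modulation of the pooled evoked signals.

    Pooling weights come from a sensory-model fit on the disengaged
    (reference-state) trials, where the engagement gain is absent by
    definition; the modulation is then measured on stimulus-matched
    engaged/disengaged trials.  Fitting on gain-bearing trials would fold the
    per-neuron gain into the weights and inflate the pooled ratios.
    """
    engaged = bundle.truth.engaged
    dis = np.flatnonzero(~engaged)
    if len(dis) == 0 or engaged.sum() == 0:
        raise ConfigurationError("need both engaged and disengaged trials")
    sub_t = bundle.trials.iloc[dis].reset_index(drop=True)
    sub_r = {k: v[:, dis] for k, v in bundle.epoch_rates.items()}
    fits = encoding.fit_population(
        encoding.build_design(sub_t, sub_r, variant="sensory"))
    w1, w2 = population.assign_pools(fits, "beta_f1_raw", "beta_f2_raw",
                                     ("w1", "w2"))
    wx = population.interaction_pool(fits, suffix="_raw")
    out = {}
    for name, pool in (("w1", w1), ("w2", w2), ("w1xw2", wx)):
        out[name] = (population.engagement_ratio(
            bundle.epoch_rates, pool, engaged, bundle.trials, seed=seed)
            if len(pool) else np.nan)
    return out


def choice_geometry(bundle, target_side: str = "f2", seed: int = 0,
                    epoch_x: str = "stimulus", epoch_y: str = "decision"):
    """Representational angle between the sensory axis (Rw1 - Rw2) and the
    choice-1 -> choice-2 transition, on one target side.

    The choice-variant encoding model supplies both the sensory and the
    choice weights (its C1/C2 regressors absorb choice-locked activity that
    would otherwise leak into the sensory weights).  Weights are cross-fitted
    split-half — each half's trial coordinates use the other half's weights —
    so weight-estimation noise is independent of the coordinate noise.  Each
    dimension is evaluated in the epoch where its signal is expressed: the
    sensory axis on stimulus-epoch activity, the choice axis on
    decision-epoch activity.  ``target_side`` restricts the arrow to F2 > F1
    ("f2") or F1 > F2 ("f1") trials.  Returns a
    :class:`population.GeometryResult`.
    """
    rng = np.random.default_rng(seed)
    trials = bundle.trials
    n = len(trials)
    half = rng.permutation(n) % 2
    X = np.full(n, np.nan)
    Y = np.full(n, np.nan)
    for h in (0, 1):
        fit_idx = np.flatnonzero(half != h)
        coord_idx = np.flatnonzero(half == h)
        sub_t = trials.iloc[fit_idx].reset_index(drop=True)
        sub_r = {k: v[:, fit_idx] for k, v in bundle.epoch_rates.items()}
        fits = encoding.fit_population(
            encoding.build_design(sub_t, sub_r, variant="choice"))
        w1, w2 = population.assign_pools(fits, "beta_f1_raw", "beta_f2_raw",
                                         ("w1", "w2"))
        c1, c2 = population.assign_pools(fits, "beta_c1_raw", "beta_c2_raw",
                                         ("c1", "c2"))
        if min(len(w1), len(w2), len(c1), len(c2)) == 0:
            raise ConfigurationError("a pool is empty in one half")
        ax = bundle.epoch_rates[epoch_x][:, coord_idx]
        ay = bundle.epoch_rates[epoch_y][:, coord_idx]
        X[coord_idx] = (population.pool_signal(ax, w1)
                        - population.pool_signal(ax, w2))
        Y[coord_idx] = (population.pool_signal(ay, c1)
                        - population.pool_signal(ay, c2))
    df = trials["delta_f_hz"].to_numpy(dtype=float)
    resp = trials["choice"].isin(["1", "2"]).to_numpy()
    mask = resp & ((df < 0) if target_side == "f2" else (df > 0))
    sub = trials[mask].reset_index(drop=True)
    group2 = trials["choice"].to_numpy()[mask] == "2"
    return population.representational_angle(X[mask], Y[mask], group2,
                                             trials=sub, seed=seed)


def _fitted_corrs(fits: pd.DataFrame):
    from scipy import stats
    if len(fits) < 3:
        return (np.nan, np.nan, np.nan)
    return (stats.pearsonr(fits["beta_f1"], fits["beta_f2"])[0],
            stats.spearmanr(fits["beta_f1"], fits["beta_f1xf2"])[0],
            stats.spearmanr(fits["beta_f2"], fits["beta_f1xf2"])[0])


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the enabled stages in dependency order and return the report."""
    seeds = _child_seeds(config.seed, 6)
    gen_cfg = config.generator.model_copy(update={"seed": seeds[0]})
    log.info("simulating session (seed %d)", gen_cfg.seed)
    bundle = generate_session(gen_cfg)
    trials = bundle.trials
    report: dict = {"config_seed": config.seed,
                    "n_neurons": gen_cfg.n_neurons,
                    "n_trials": gen_cfg.n_trials}

    if config.run_preprocess:
        if bundle.fluorescence is None:
            raise ConfigurationError(
                "preprocessing enabled but no fluorescence was generated")
        n_pp = min(config.max_preprocess_neurons, gen_cfg.n_neurons)
        errs, iters = [], []
        for i in range(n_pp):
            tb = TraceBundle(bundle.fluorescence["F_raw"][i],
                             bundle.fluorescence["F_neuropil"][i],
                             bundle.fluorescence["frame_time_s"])
            res = preprocess_trace(tb, config.preprocess)
            errs.append(abs(res.alpha_hat - bundle.truth.alpha[i]))
            iters.append(res.n_iter)
            log.info("neuron %d: alpha=%.3f (true %.3f) iters=%d", i,
                     res.alpha_hat, bundle.truth.alpha[i], res.n_iter)
        report["preprocess"] = {"n_neurons": n_pp,
                                "mean_abs_alpha_error": float(np.mean(errs)),
                                "mean_iterations": float(np.mean(iters))}

    if config.run_behavior and len(trials):
        fit = behavior.fit_psychometric_trials(trials, seed=seeds[1])
        report["psychometric"] = {
            "gamma": fit.gamma, "lapse": fit.lapse,
            "midpoint_hz": fit.midpoint_hz,
            "max_slope_per_hz": fit.max_slope_per_hz}
        outcomes = behavior.classify_outcomes(trials, gen_cfg.stimulus_s)
        report["outcomes"] = outcomes["outcome"].value_counts().to_dict()

    analysis = None
    if config.run_encoding and len(trials):
        analysis = session_analysis(bundle, cv_folds=config.cv_folds,
                                    seed=seeds[2])
        report["encoding"] = {
            "weight_correlations": analysis["weight_correlations"],
            "response_fractions": analysis["response_fractions"],
            "mean_r2": float(analysis["fits"]["r2"].mean())}

    if config.run_population and analysis is not None:
        pools = analysis["pools"]
        pop: dict = dict(analysis.get("sensory_decoder", {}))
        if len(pools["w1"]) and len(pools["w2"]):
            diff = (population.pool_signal(bundle.epoch_rates["stimulus"],
                                           pools["w1"])
                    - population.pool_signal(bundle.epoch_rates["stimulus"],
                                             pools["w2"]))
            nfit, _, thr = population.neurometric_curve(diff, trials,
                                                        seed=seeds[3])
            pop["neurometric"] = {"lapse": nfit.lapse,
                                  "midpoint_hz": nfit.midpoint_hz,
                                  "max_slope_per_hz": nfit.max_slope_per_hz,
                                  "threshold": thr}
            engaged = bundle.truth.engaged
            if engaged.any() and (~engaged).any():
                pop["engagement_modulation_pct"] = engagement_modulation(
                    bundle, seed=seeds[4])
        report["population"] = pop

    if config.run_spatial and analysis is not None:
        coords = spatial.project_to_axis(bundle.truth.positions,
                                         bundle.truth.column_centers[0],
                                         bundle.truth.column_centers[1])
        si = encoding.selectivity_index(
            np.clip(analysis["fits"]["beta_f1"], 0, None),
            np.clip(analysis["fits"]["beta_f2"], 0, None))
        prof = spatial.si_profile(si, coords)
        report["spatial"] = {"n_bins": int(len(prof)),
                             "si_range": [float(prof["si_mean"].min()),
                                          float(prof["si_mean"].max())]
                             if len(prof) else None}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_session
        write_session(bundle, out)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
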