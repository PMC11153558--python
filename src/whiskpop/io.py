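"""Reading and writing session artifacts (trial CSV, trace HDF5, markers)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import SessionBundle, TRIAL_COLUMNS

__all__ = ["write_trials_csv", "read_trials_csv", "write_traces_h5",
           "read_traces_h5", "write_markers_csv", "read_markers_csv",
           "write_session"]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"choice": str, "opto": str,
                                  "trial_category": str})
    return df


def write_traces_h5(path, f_raw: np.ndarray, f_neuropil: np.ndarray,
                    frame_time_s: np.ndarray, ground_truth: dict | None = None
                    ) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("F_raw", data=f_raw)
        h5.create_dataset("F_neuropil", data=f_neuropil)
        h5.create_dataset("frame_time_s", data=frame_time_s)
        if ground_truth:
            grp = h5.create_group("ground_truth")
            for key, val in ground_truth.items():
                grp.create_dataset(key, data=np.asarray(val))


def read_traces_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as h5:
        out["F_raw"] = h5["F_raw"][()]
        out["F_neuropil"] = h5["F_neuropil"][()]
        out["frame_time_s"] = h5["frame_time_s"][()]
        if "ground_truth" in h5:
            out["ground_truth"] = {k: h5["ground_truth"][k][()]
                                   for k in h5["ground_truth"]}
    return out


def write_markers_csv(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, index=False)


def read_markers_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_session(bundle: SessionBundle, out_dir) -> dict:
    """Write a generated session to disk; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"trials": out / "trials.csv"}
    write_trials_csv(bundle.trials, paths["trials"])
    w = bundle.truth.weights
    paths["weights"] = out / "ground_truth_weights.csv"
    w.to_csv(paths["weights"], index_label="neuron_id")
    if bundle.fluorescence is not None:
        paths["traces"] = out / "traces.h5"
        truth = {"alpha": bundle.truth.alpha,
                 "positions": bundle.truth.positions,
                 "column_centers": bundle.truth.column_centers}
        for col in w.columns:
            if col == "response_class":
                continue
            truth[f"weights/{col}"] = w[col].to_numpy()
        write_traces_h5(paths["traces"], bundle.fluorescence["F_raw"],
                        bundle.fluorescence["F_neuropil"],
                        bundle.fluorescence["frame_time_s"], truth)
    if bundle.markers is not None:
        paths["markers"] = out / "markers.csv"
        write_markers_csv(bundle.markers, paths["markers"])
    return paths
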