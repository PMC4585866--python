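"""Persistence: HDF5 for arrays/models, delimited text for trial logs."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .cochleogram import Cochleogram
from .estimation import ACIModel, TrialTable
from .observer import ObserverSpec

_H5 = dict(track_times=False)  # reproducible file content


def save_cochleogram(path, coch: Cochleogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=coch.values, **_H5)
        f.create_dataset("center_freqs", data=coch.center_freqs, **_H5)
        f.attrs["time_bin"] = coch.time_bin
        f.attrs["source_ref"] = coch.source_ref


def load_cochleogram(path) -> Cochleogram:
    with h5py.File(path, "r") as f:
        return Cochleogram(values=f["values"][()],
                           center_freqs=f["center_freqs"][()],
                           time_bin=float(f.attrs["time_bin"]),
                           source_ref=str(f.attrs["source_ref"]))


def save_aci_model(path, model: ACIModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("template", data=model.template, **_H5)
        f.attrs.update({
            "bias": model.bias, "penalty_weight": model.penalty_weight,
            "penalty_matrix_spec": model.penalty_matrix_spec,
            "converged": model.converged,
            "final_objective": model.final_objective,
            "n_trials_used": model.n_trials_used,
            "n_iterations": model.n_iterations,
            "listener_id": model.listener_id,
        })


def load_aci_model(path) -> ACIModel:
    with h5py.File(path, "r") as f:
        a = f.attrs
        return ACIModel(template=f["template"][()], bias=float(a["bias"]),
                        penalty_weight=float(a["penalty_weight"]),
                        penalty_matrix_spec=str(a["penalty_matrix_spec"]),
                        converged=bool(a["converged"]),
                        final_objective=float(a["final_objective"]),
                        n_trials_used=int(a["n_trials_used"]),
                        n_iterations=int(a["n_iterations"]),
                        listener_id=str(a["listener_id"]))


def save_observer(h5_path, json_path, obs: ObserverSpec) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("template", data=obs.template, **_H5)
    with open(json_path, "w") as f:
        json.dump({"bias": obs.bias, "gain": obs.gain, "seed": obs.seed}, f)


def load_observer(h5_path, json_path) -> ObserverSpec:
    with h5py.File(h5_path, "r") as f:
        template = f["template"][()]
    with open(json_path) as f:
        scalars = json.load(f)
    return ObserverSpec(template=template, **scalars)


def save_trial_table(path, table: TrialTable) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=table.X, **_H5)
        f.create_dataset("response", data=table.response, **_H5)
        f.create_dataset("correct", data=table.correct, **_H5)
        for name in ("target_class", "snr_db", "session"):
            v = getattr(table, name)
            if v is not None:
                f.create_dataset(name, data=np.asarray(v), **_H5)
        if table.target_id is not None:
            f.create_dataset("target_id",
                             data=np.asarray(table.target_id, dtype="S"),
                             **_H5)
        f.attrs["grid_shape"] = table.grid_shape
        f.attrs["balanced"] = table.balanced
        f.attrs["listener_id"] = table.listener_id


def load_trial_table(path) -> TrialTable:
    with h5py.File(path, "r") as f:
        def get(name):
            return f[name][()] if name in f else None
        tid = get("target_id")
        if tid is not None:
            tid = tid.astype(str)
        return TrialTable(X=f["X"][()], response=f["response"][()],
                          correct=f["correct"][()],
                          grid_shape=tuple(int(v)
                                           for v in f.attrs["grid_shape"]),
                          target_id=tid, target_class=get("target_class"),
                          snr_db=get("snr_db"), session=get("session"),
                          balanced=bool(f.attrs["balanced"]),
                          listener_id=str(f.attrs["listener_id"]))


def export_trial_log(path, log) -> None:
    """Write the per-trial log as delimited text (one row per trial)."""
    log.trials.to_csv(path, sep="\t", index=False)


def export_run_config(path, config: dict) -> None:
    with open(path, "w") as f:
        json.dump(config, f, indent=2, sort_keys=True, default=float)
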