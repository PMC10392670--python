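"""HDF5/CSV persistence for ensembles, umbrella windows and PMFs."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .ensembles import EnsembleSample, UmbrellaWindow
from .restraint import TorsionalRestraint
from .wham import PMFProfile

__all__ = [
    "save_windows",
    "load_windows",
    "ensemble_to_dataframe",
    "write_pmf",
    "read_pmf",
]

PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


def _write_ensemble(group: h5py.Group, ens: EnsembleSample) -> None:
    group.create_dataset("labels", data=ens.labels, compression="gzip")
    group.create_dataset("step_twist_mean", data=ens.step_twist_mean)
    group.create_dataset("step_param_mean", data=ens.step_param_mean)
    if ens.params is not None:
        group.create_dataset("params", data=ens.params, compression="gzip")
    group.attrs["n_frames"] = ens.n_frames
    group.attrs["acceptance"] = json.dumps(ens.acceptance)
    if ens.seed is not None:
        group.attrs["seed"] = int(ens.seed)


def _read_ensemble(group: h5py.Group) -> EnsembleSample:
    return EnsembleSample(
        params=group["params"][()] if "params" in group else None,
        labels=group["labels"][()],
        seed=int(group.attrs["seed"]) if "seed" in group.attrs else None,
        acceptance=json.loads(group.attrs["acceptance"]),
        step_twist_mean=group["step_twist_mean"][()],
        step_param_mean=group["step_param_mean"][()],
        n_frames=int(group.attrs["n_frames"]),
    )


def save_windows(path, windows: list[UmbrellaWindow], model_hash: str | None = None) -> None:
    """Persist umbrella windows (restraints, CV series, ensembles) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["n_windows"] = len(windows)
        if model_hash is not None:
            f.attrs["model_hash"] = model_hash
        for i, w in enumerate(windows):
            g = f.create_group(f"window_{i:03d}")
            g.attrs["restraint"] = json.dumps(w.restraint.to_dict())
            g.create_dataset("cv_series", data=w.cv_series, compression="gzip")
            _write_ensemble(g.create_group("ensemble"), w.ensemble)


def load_windows(path) -> list[UmbrellaWindow]:
    """Load umbrella windows written by :func:`save_windows`."""
    windows = []
    with h5py.File(path, "r") as f:
        for i in range(int(f.attrs["n_windows"])):
            g = f[f"window_{i:03d}"]
            windows.append(
                UmbrellaWindow(
                    restraint=TorsionalRestraint.from_dict(
                        json.loads(g.attrs["restraint"])
                    ),
                    cv_series=g["cv_series"][()],
                    ensemble=_read_ensemble(g["ensemble"]),
                )
            )
    return windows


def ensemble_to_dataframe(ens: EnsembleSample, stride: int = 1) -> pd.DataFrame:
    """Long-format (frame, step, parameter, value) export of an ensemble."""
    if ens.params is None:
        raise ValueError("ensemble does not retain its parameter trajectory")
    frames, steps, _ = ens.params.shape
    idx = np.arange(0, frames, stride)
    rows = []
    for f in idx:
        for s in range(steps):
            for k, name in enumerate(PARAM_NAMES):
                rows.append((int(f) + 1, s + 1, name, float(ens.params[f, s, k])))
    return pd.DataFrame(rows, columns=["frame", "step", "parameter", "value"])


def write_pmf(pmf: PMFProfile, csv_path, json_path=None) -> None:
    """Write a PMF as CSV plus optional JSON convergence metadata."""
    pmf.to_dataframe().to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(pmf.metadata(), fh, indent=2)


def read_pmf(csv_path, json_path=None) -> PMFProfile:
    """Rehydrate a PMF written by :func:`write_pmf` (fit-ready subset)."""
    df = pd.read_csv(csv_path)
    meta = {}
    if json_path is not None:
        with open(json_path) as fh:
            meta = json.load(fh)
    free = df["free_energy_kcal_mol"].to_numpy()
    counts = df["n_samples"].to_numpy()[None, :].astype(float)
    return PMFProfile(
        grid=df["delta_twist_per_bp"].to_numpy(),
        free_energy=free,
        bin_counts=counts,
        mask=np.isfinite(free) & (counts[0] > 0),
        relaxed_cv=float(meta.get("relaxed_cv", np.nan)),
        n_region_steps=int(meta.get("n_region_steps", 0)),
        bin_width_total=float(meta.get("bin_width_total_deg", np.nan)),
        iterations=int(meta.get("iterations", 0)),
        final_delta=float(meta.get("final_delta", np.nan)),
        temperature=float(meta.get("temperature_K", 300.0)),
    )
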