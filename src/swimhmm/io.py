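"""Readers, writers and model serialization.

Bout tables are CSV (UTF-8, '.' decimal) with columns trajectory_id,
t, dtheta_deg and optional dt_s, d_mm.  Rasters are either a 0/1 CSV
matrix plus JSON metadata, or an HDF5 file with datasets ``activity``
and ``side`` and attribute ``frame_rate_hz``.  Models and reports are
JSON with a ``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import BehaviorHMM, BoutSequence, NeuralHMM, NeuralRaster

SCHEMA_VERSION = 1

REQUIRED_BOUT_COLUMNS = ("trajectory_id", "t", "dtheta_deg")


def read_bout_table(path: str | Path) -> list[BoutSequence]:
    """Read a bout table CSV into per-trajectory sequences.

    Rows are grouped by trajectory_id and ordered by t; inter-bout
    intervals are recovered from dt_s if present, else from t.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_BOUT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    out = []
    for tid, g in df.groupby("trajectory_id", sort=True):
        t = g["t"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(g.index[np.argmin(np.diff(t) > 0) + 1])
            raise ValueError(f"non-monotone times in trajectory {tid!r} at row {bad}")
        if "dt_s" in g.columns:
            dt = g["dt_s"].to_numpy(dtype=float)
        elif len(t) > 1:
            dt = np.append(np.diff(t), np.diff(t)[-1])
        else:
            dt = None
        d = g["d_mm"].to_numpy(dtype=float) if "d_mm" in g.columns else None
        out.append(
            BoutSequence(g["dtheta_deg"].to_numpy(dtype=float), dt=dt, d=d, trajectory_id=tid)
        )
    return out


def write_bout_table(
    path: str | Path,
    sequences: list[BoutSequence],
    labels: list[np.ndarray] | None = None,
) -> None:
    """Write sequences as a bout-table CSV; optional label column appended."""
    rows = []
    for k, b in enumerate(sequences):
        t = b.times if b.dt is not None else np.arange(len(b), dtype=float)
        for n in range(len(b)):
            row = {
                "trajectory_id": b.trajectory_id,
                "t": t[n],
                "dtheta_deg": b.dtheta[n],
            }
            if b.dt is not None:
                row["dt_s"] = b.dt[n]
            if b.d is not None:
                row["d_mm"] = b.d[n]
            if labels is not None:
                row["state"] = ("F", "L", "R")[int(labels[k][n])]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_raster(path: str | Path) -> NeuralRaster:
    """Read a raster from HDF5 (.h5/.hdf5) or CSV + sidecar JSON."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            act = fh["activity"][...]
            side = np.array([s.decode() if isinstance(s, bytes) else s for s in fh["side"][...]])
            nu = float(fh.attrs["frame_rate_hz"])
        return NeuralRaster(act, side, nu)
    act = np.loadtxt(path, delimiter=",", dtype=int)
    meta = json.loads(path.with_suffix(".json").read_text())
    return NeuralRaster(act, np.array(meta["side"]), float(meta["frame_rate_hz"]))


def write_raster(path: str | Path, raster: NeuralRaster) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("activity", data=raster.activity)
            fh.create_dataset("side", data=np.array(raster.side, dtype="S"))
            fh.attrs["frame_rate_hz"] = raster.frame_rate_hz
        return
    np.savetxt(path, raster.activity, fmt="%d", delimiter=",")
    meta = {"side": list(raster.side), "frame_rate_hz": raster.frame_rate_hz}
    path.with_suffix(".json").write_text(json.dumps(meta))


def behavior_model_to_json(model: BehaviorHMM) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "behavior_hmm",
        "states": ["F", "L", "R"],
        "transition": model.transition.ravel().tolist(),
        "initial": model.initial.tolist(),
        "sigma_f": model.sigma_f,
        "alpha": model.alpha,
        "theta": model.theta,
        "symmetric": model.symmetric,
        "training": {
            k: v for k, v in model.meta.items() if np.isscalar(v) or isinstance(v, bool)
        },
    }


def behavior_model_from_json(doc: dict) -> BehaviorHMM:
    model = BehaviorHMM(
        np.array(doc["transition"]).reshape(3, 3),
        np.array(doc["initial"]),
        doc["sigma_f"],
        doc["alpha"],
        doc["theta"],
        symmetric=doc["symmetric"],
    )
    model.meta.update(doc.get("training", {}))
    return model


def neural_model_to_json(model: NeuralHMM) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "neural_hmm",
        "n_states": model.n_states,
        "transition": model.transition.ravel().tolist(),
        "initial": model.initial.tolist(),
        "fields": model.fields.tolist(),
        "state_labels": None if model.state_labels is None else model.state_labels.tolist(),
        "training": {
            k: v for k, v in model.meta.items() if np.isscalar(v) or isinstance(v, bool)
        },
    }


def neural_model_from_json(doc: dict) -> NeuralHMM:
    K = doc["n_states"]
    labels = doc.get("state_labels")
    model = NeuralHMM(
        np.array(doc["transition"]).reshape(K, K),
        np.array(doc["initial"]),
        np.array(doc["fields"]),
        state_labels=None if labels is None else np.array(labels),
    )
    model.meta.update(doc.get("training", {}))
    return model


def save_model(path: str | Path, model: BehaviorHMM | NeuralHMM, extra: dict | None = None) -> None:
    doc = (
        behavior_model_to_json(model)
        if isinstance(model, BehaviorHMM)
        else neural_model_to_json(model)
    )
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> BehaviorHMM | NeuralHMM:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") == "behavior_hmm":
        return behavior_model_from_json(doc)
    if doc.get("kind") == "neural_hmm":
        return neural_model_from_json(doc)
    raise ValueError("unrecognized model JSON")
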