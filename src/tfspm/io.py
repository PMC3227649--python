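"""HDF5 persistence for intermediate pipeline artifacts."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from tfspm.preprocess import EpochSet
from tfspm.tfdecomp import TFMap

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_tfmaps",
    "load_tfmaps",
]


def _write_labels(g: h5py.Group, labels: pd.DataFrame) -> None:
    lg = g.create_group("labels")
    for col in labels.columns:
        vals = labels[col].to_numpy()
        if vals.dtype == object:
            vals = vals.astype("S")
        lg.create_dataset(col, data=vals)
    lg.attrs["columns"] = list(labels.columns)


def _read_labels(g: h5py.Group) -> pd.DataFrame:
    lg = g["labels"]
    out = {}
    for col in lg.attrs["columns"]:
        vals = lg[col][()]
        if vals.dtype.kind == "S":
            vals = np.char.decode(vals.astype("S"), "utf-8")
        out[col] = vals
    return pd.DataFrame(out)


def save_epochs(path: str, es: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data)
        f.create_dataset("times_ms", data=es.times_ms)
        f.create_dataset("rejected", data=es.rejected)
        f.attrs["sample_rate_hz"] = es.sample_rate_hz
        _write_labels(f, es.labels)


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times_ms=f["times_ms"][()],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            labels=_read_labels(f),
            rejected=f["rejected"][()].astype(bool),
        )


def save_tfmaps(path: str, tf: TFMap, labels: pd.DataFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tf.values.astype(np.float32))
        f.create_dataset("times_ms", data=tf.times_ms)
        f.create_dataset("freqs_hz", data=tf.freqs_hz)
        f.attrs["stage"] = tf.stage
        _write_labels(f, labels)


def load_tfmaps(path: str) -> tuple[TFMap, pd.DataFrame]:
    with h5py.File(path, "r") as f:
        tf = TFMap(
            values=f["values"][()].astype(float),
            times_ms=f["times_ms"][()],
            freqs_hz=f["freqs_hz"][()],
            stage=str(f.attrs["stage"]),
        )
        return tf, _read_labels(f)


def write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
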