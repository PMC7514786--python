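"""Segment-file readers/writers and model serialization.

The segment table has one row per 5-s segment: ``patient_id``, ``label``,
``fs``, then the 1250 sample values in mV.  It is serialized either as
CSV (portable, text) or as an HDF5 container with one group per patient
(compact, binary).  Models are stored as an HDF5 file holding the
architecture kind, its configuration and every named parameter array.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from pulsegate.dnn_models import (
    PulseNet,
    S1Config,
    S2Config,
    build_s1,
    build_s2,
)
from pulsegate.synthetic import Dataset, EcgSegment


def write_csv(dataset: Dataset, path) -> None:
    rows = []
    for seg in dataset.segments:
        rows.append({"patient_id": seg.patient_id, "label": seg.label,
                     "fs": seg.fs,
                     **{f"s{i}": v for i, v in enumerate(seg.samples)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_csv(path) -> Dataset:
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    segments = [
        EcgSegment(samples=row[sample_cols].to_numpy(dtype=float),
                   fs=float(row["fs"]), patient_id=str(row["patient_id"]),
                   label=str(row["label"]))
        for _, row in df.iterrows()
    ]
    return Dataset(segments)


def write_hdf5(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        for pid, idx in dataset.patient_index.items():
            grp = f.create_group(pid)
            segs = [dataset.segments[i] for i in idx]
            grp.create_dataset("samples", data=np.stack([s.samples for s in segs]))
            grp.attrs["label"] = segs[0].label
            grp.attrs["fs"] = segs[0].fs


def read_hdf5(path) -> Dataset:
    segments = []
    with h5py.File(path, "r") as f:
        for pid in f:
            grp = f[pid]
            label = grp.attrs["label"]
            fs = float(grp.attrs["fs"])
            for row in grp["samples"][...]:
                segments.append(EcgSegment(samples=np.asarray(row, dtype=float),
                                           fs=fs, patient_id=str(pid),
                                           label=str(label)))
    return Dataset(segments)


def save_dataset(dataset: Dataset, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        write_hdf5(dataset, path)
    else:
        write_csv(dataset, path)


def load_dataset(path) -> Dataset:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_hdf5(path)
    return read_csv(path)


def save_model(model: PulseNet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = model.kind
        f.attrs["input_len"] = model.input_len
        f.attrs["config"] = json.dumps(vars(model.config))
        grp = f.create_group("params")
        for name, value in model.state_dict().items():
            grp.create_dataset(name, data=value)


def load_model(path) -> PulseNet:
    with h5py.File(path, "r") as f:
        kind = str(f.attrs["kind"])
        input_len = int(f.attrs["input_len"])
        cfg = json.loads(f.attrs["config"])
        if kind == "s1":
            model = build_s1(S1Config(**cfg), input_len=input_len)
        else:
            model = build_s2(S2Config(**cfg), input_len=input_len)
        model.load_state_dict({k: v[...] for k, v in f["params"].items()})
    return model
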