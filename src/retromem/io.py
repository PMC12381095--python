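"""HDF5 container for epoched EEG and CSV round trips for tables.

Layout of the epoch container::

    /data      float64 (trial, channel, time), μV
    /times     float64 (time,), ms
    /channels  variable-length str (channel,)
    /metadata/<column>  one dataset per metadata column
    attrs: srate (Hz), container_version

The layout is deliberately minimal so externally supplied epochs can be
written with any HDF5 tool.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .synth import EEGEpochs

CONTAINER_VERSION = 1


def write_epochs(path, epochs: EEGEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        g = f.create_group("metadata")
        for col in epochs.metadata.columns:
            values = epochs.metadata[col].to_numpy()
            if values.dtype == object:
                values = values.astype(str).astype(h5py.string_dtype())
            g.create_dataset(col, data=values)
        g.attrs["columns"] = list(epochs.metadata.columns)
        f.attrs["srate"] = epochs.srate
        f.attrs["container_version"] = CONTAINER_VERSION


def read_epochs(path) -> EEGEpochs:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        cols = list(f["metadata"].attrs["columns"])
        meta = {}
        for col in cols:
            v = f["metadata"][col][()]
            if v.dtype.kind in ("S", "O"):
                v = np.array([x.decode() if isinstance(x, bytes) else str(x) for x in v])
            meta[col] = v
        srate = float(f.attrs["srate"])
    return EEGEpochs(
        data=data,
        times=times,
        srate=srate,
        channel_labels=channels,
        metadata=pd.DataFrame(meta, columns=cols),
    )
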