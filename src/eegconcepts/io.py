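"""Readers and writers for the package's canonical containers.

Epoched EEG lives in a simple HDF5 layout::

    /data      float64 [n_epochs, n_channels, n_times]  (µV)
    /labels    int     [n_epochs]
    /subjects  int     [n_epochs]
    /channels  str     [n_channels]
    /sfreq     scalar attribute on the root group

Model checkpoints store each layer's weight arrays under ``/layers/<index>_<name>``
with the layer kind and hyperparameters as attributes.  Continuous EEG is read
from EDF/BDF files through MNE.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .synthetic import EpochSet

__all__ = ["save_epochs", "load_epochs", "read_raw", "save_model", "load_model"]


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("subjects", data=epochs.subjects)
        f.create_dataset("channels", data=np.array(epochs.channels, dtype="S"))
        f.attrs["sfreq"] = float(epochs.sfreq)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            subjects=f["subjects"][()],
            channels=tuple(c.decode() for c in f["channels"][()]),
            sfreq=float(f.attrs["sfreq"]),
        )


def read_raw(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read continuous EEG from an EDF or BDF file.

    Returns ``(data_uv [n_channels, n_times], sfreq, channel_names)``.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix!r}")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return data, float(raw.info["sfreq"]), tuple(raw.ch_names)


def save_model(path: str | Path, model) -> None:
    """Persist a :class:`~eegconcepts.nn.model.LayerGraph` to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["n_channels"] = model.n_channels
        f.attrs["n_times"] = model.n_times
        grp = f.create_group("layers")
        for i, layer in enumerate(model.layers):
            g = grp.create_group(f"{i:02d}_{layer.name}")
            g.attrs["kind"] = layer.kind
            for key, val in layer.state().items():
                g.create_dataset(key, data=val)


def load_model(path: str | Path):
    from .nn.model import LayerGraph, build_eegnet

    with h5py.File(path, "r") as f:
        model = build_eegnet(int(f.attrs["n_channels"]), int(f.attrs["n_times"]))
        grp = f["layers"]
        names = sorted(grp.keys())
        if len(names) != len(model.layers):
            raise ValueError("checkpoint layer count does not match architecture")
        for name, layer in zip(names, model.layers):
            g = grp[name]
            if g.attrs["kind"] != layer.kind:
                raise ValueError(f"layer kind mismatch at {name}")
            layer.load_state({k: g[k][()] for k in g.keys()})
    return model
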