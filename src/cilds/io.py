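"""Dataset container, HDF5 and CSV round-trips, and run configuration.

The on-disk layout is a plain HDF5 file with groups
``/fluorescence`` (trials x neurons x time), optional ``/latents``,
``/spikes``, ``/calcium``, ``/labels`` and root attributes
``sampling_rate_hz``, ``seed`` and a JSON config blob.  A flat CSV export
(one file per trial, header row of neuron IDs, one row per time point) is
provided for interoperability with segmentation pipelines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FluorescenceDataset", "read_dataset", "write_dataset",
           "export_csv", "read_csv_trials", "config_hash"]


@dataclass
class FluorescenceDataset:
    """Multi-trial fluorescence recording: the universal model input.

    fluorescence : (n_trials, q, T) array, one row block per trial.
    """

    fluorescence: np.ndarray
    sampling_rate_hz: float
    neuron_ids: list[str] | None = None
    trial_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 3:
            raise ValueError("fluorescence must be (n_trials, q, T)")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{j:03d}" for j in range(self.n_neurons)]
        if len(self.neuron_ids) != self.n_neurons:
            raise ValueError("neuron_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.fluorescence.shape[2]

    def subset_trials(self, idx) -> "FluorescenceDataset":
        lab = None if self.trial_labels is None else np.asarray(self.trial_labels)[idx]
        return FluorescenceDataset(self.fluorescence[idx], self.sampling_rate_hz,
                                   list(self.neuron_ids), lab, dict(self.meta))

    def drop_neuron(self, j: int) -> "FluorescenceDataset":
        keep = [k for k in range(self.n_neurons) if k != j]
        return FluorescenceDataset(self.fluorescence[:, keep, :], self.sampling_rate_hz,
                                   [self.neuron_ids[k] for k in keep],
                                   self.trial_labels, dict(self.meta))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dataset(path, ds: FluorescenceDataset, latents: np.ndarray | None = None,
                  spikes: np.ndarray | None = None, calcium: np.ndarray | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("fluorescence", data=ds.fluorescence)
        if latents is not None:
            f.create_dataset("latents", data=latents)
        if spikes is not None:
            f.create_dataset("spikes", data=spikes)
        if calcium is not None:
            f.create_dataset("calcium", data=calcium)
        if ds.trial_labels is not None:
            f.create_dataset("labels", data=np.asarray(ds.trial_labels))
        f.attrs["sampling_rate_hz"] = ds.sampling_rate_hz
        f.attrs["neuron_ids"] = json.dumps(list(ds.neuron_ids))
        f.attrs["meta"] = json.dumps(ds.meta, default=str)


def read_dataset(path) -> FluorescenceDataset:
    import h5py

    with h5py.File(path, "r") as f:
        if "sampling_rate_hz" not in f.attrs:
            raise ValueError(f"{path}: missing sampling_rate_hz attribute; refusing to guess")
        Y = np.asarray(f["fluorescence"])
        labels = np.asarray(f["labels"]) if "labels" in f else None
        ids = json.loads(f.attrs.get("neuron_ids", "null"))
        meta = json.loads(f.attrs.get("meta", "{}"))
        return FluorescenceDataset(Y, float(f.attrs["sampling_rate_hz"]), ids, labels, meta)


def export_csv(directory, ds: FluorescenceDataset) -> list[Path]:
    """One CSV per trial: header row of neuron IDs, one row per time point."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in range(ds.n_trials):
        p = directory / f"trial{tr:04d}.csv"
        pd.DataFrame(ds.fluorescence[tr].T, columns=ds.neuron_ids).to_csv(p, index=False)
        paths.append(p)
    (directory / "metadata.json").write_text(json.dumps(
        {"sampling_rate_hz": ds.sampling_rate_hz, "meta": ds.meta}, default=str))
    return paths


def read_csv_trials(directory, sampling_rate_hz: float | None = None) -> FluorescenceDataset:
    import pandas as pd

    directory = Path(directory)
    meta_path = directory / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = sampling_rate_hz if sampling_rate_hz is not None else meta.get("sampling_rate_hz")
    if rate is None:
        raise ValueError("sampling rate not given and no metadata.json found")
    files = sorted(directory.glob("trial*.csv"))
    if not files:
        raise ValueError(f"no trial CSV files in {directory}")
    trials, ids = [], None
    for fpath in files:
        df = pd.read_csv(fpath)
        if ids is None:
            ids = list(df.columns)
        elif list(df.columns) != ids:
            raise ValueError(f"{fpath.name}: neuron columns differ from first trial")
        trials.append(df.to_numpy().T)
    shapes = {t.shape for t in trials}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent trial shapes across CSV files: {shapes}")
    return FluorescenceDataset(np.stack(trials), float(rate), ids,
                               meta=meta.get("meta", {}))
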