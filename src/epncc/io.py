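"""Delimited-text readers and writers for records, windows and features.

All on-disk formats are plain text: a signal/window file is one sample
value per row; a dataset directory holds one CSV per window plus a
``manifest.csv`` with columns window_id, group_id, class.  Trained models
are stored as a numpy ``.npz`` of weights plus a JSON sidecar of the
architecture.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .network import ClassifierModel
from .synthetic import SyntheticDataset


def read_signal(path: str | Path, column: int | str | None = None) -> np.ndarray:
    """Read a 1-D signal from delimited text (one value per row, or a
    named/indexed column of a delimited table)."""
    path = Path(path)
    df = pd.read_csv(path, header=None if column is None else "infer")
    if column is None:
        if df.shape[1] != 1:
            raise ParameterError(
                f"{path} has {df.shape[1]} columns; pass column= to select one")
        return df.iloc[:, 0].to_numpy(dtype=float)
    col = df.iloc[:, column] if isinstance(column, int) else df[column]
    return col.to_numpy(dtype=float)


def write_signal(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float).reshape(-1), fmt="%.10g")


def write_dataset(directory: str | Path, dataset: SyntheticDataset) -> None:
    """One CSV per window (window_000.csv ...) plus manifest.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(dataset.n_windows):
        name = f"window_{i:04d}.csv"
        write_signal(directory / name, dataset.signals[i])
        rows.append({"window_id": name, "group_id": int(dataset.group_ids[i]),
                     "class": int(dataset.class_ids[i])})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_dataset(directory: str | Path, fs: float = 125.0) -> SyntheticDataset:
    """Load a window directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    signals = np.stack([read_signal(directory / name)
                        for name in manifest["window_id"]])
    class_ids = manifest["class"].to_numpy(dtype=int)
    labels = np.zeros((len(class_ids), 3))
    labels[np.arange(len(class_ids)), class_ids] = 1.0
    return SyntheticDataset(signals=signals, labels=labels,
                            group_ids=manifest["group_id"].to_numpy(dtype=int),
                            class_ids=class_ids, fs=fs)


def save_model(path: str | Path, model: ClassifierModel) -> None:
    """Weights to ``<path>`` (.npz) and architecture to ``<path>.json``."""
    path = Path(path)
    np.savez(path, **model.get_weights())
    arch = {"input_lens": model.input_lens, "n_classes": model.n_classes,
            "modules": [vars(m) for m in model.modules]}
    Path(str(path) + ".json").write_text(json.dumps(arch, indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    arch = json.loads(Path(str(path) + ".json").read_text())
    from .network import ConvModuleConfig
    modules = tuple(ConvModuleConfig(**m) for m in arch["modules"])
    model = ClassifierModel(arch["input_lens"], n_classes=arch["n_classes"],
                            modules=modules)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    if not npz_path.exists():
        npz_path = path
    with np.load(npz_path) as data:
        model.set_weights({k: data[k] for k in data.files})
    return model
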