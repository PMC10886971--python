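"""Readers and writers for every pipeline artifact.

Formats: manifests and tables as CSV, waveforms as one-column text files or
a single HDF5 container (one dataset per event id, metadata in attributes),
model checkpoints as HDF5, reports as JSON.  Every writer has a matching
reader with round-trip fidelity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .cnn import CnnArchitecture, CNNResults, RippleEpisodeCNN, TrainingConfig
from .preprocess import SimilarityMatrix
from .waveforms import CATEGORIES, RippleError, RippleWaveform

PathLike = Union[str, Path]

MANIFEST_COLUMNS = ["id", "rat_id", "category", "fs_hz", "n_samples", "motif_start", "path"]


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path: PathLike) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise RippleError(f"manifest {path}: missing columns {missing}")
    for row_no, cat in enumerate(df["category"], start=2):  # header is line 1
        if cat not in CATEGORIES:
            raise RippleError(
                f"manifest {path}, line {row_no}: unknown category {cat!r}"
            )
    return df


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def write_waveform_txt(event: RippleWaveform, path: PathLike) -> None:
    """One sample per line, full double precision."""
    np.savetxt(path, event.samples, fmt="%.17g")


def read_waveform_txt(path: PathLike) -> np.ndarray:
    try:
        return np.atleast_1d(np.loadtxt(path, dtype=float))
    except ValueError as e:
        raise RippleError(f"waveform file {path}: {e}") from None


def write_waveforms_h5(events: Sequence[RippleWaveform], path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        for ev in events:
            d = f.create_dataset(ev.id, data=ev.samples)
            d.attrs["rat_id"] = ev.rat_id
            d.attrs["category"] = ev.category
            d.attrs["fs"] = ev.fs
            d.attrs["stage"] = ev.stage
            if ev.motif_start is not None:
                d.attrs["motif_start"] = ev.motif_start
            if ev.n_orig is not None:
                d.attrs["n_orig"] = ev.n_orig


def read_waveforms_h5(path: PathLike) -> List[RippleWaveform]:
    events = []
    with h5py.File(path, "r") as f:
        for eid in f:
            d = f[eid]
            events.append(
                RippleWaveform(
                    id=eid,
                    rat_id=int(d.attrs["rat_id"]),
                    category=str(d.attrs["category"]),
                    fs=float(d.attrs["fs"]),
                    samples=d[()],
                    stage=str(d.attrs["stage"]),
                    motif_start=(int(d.attrs["motif_start"])
                                 if "motif_start" in d.attrs else None),
                    n_orig=int(d.attrs["n_orig"]) if "n_orig" in d.attrs else None,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Similarity matrix
# ---------------------------------------------------------------------------

def write_similarity_csv(matrix: SimilarityMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path)


def read_similarity_csv(path: PathLike, threshold: float = 0.6) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise RippleError(f"similarity CSV {path}: index and columns differ")
    return SimilarityMatrix(values=df.to_numpy(), ids=list(df.index),
                            threshold=threshold)


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------

def save_model(results: CNNResults, path: PathLike) -> None:
    """HDF5 checkpoint: parameters, architecture, training config, seeds."""
    with h5py.File(path, "w") as f:
        pg = f.create_group("params")
        for k, v in results.params.items():
            pg.create_dataset(k, data=v)
        ag = f.create_group("architecture")
        for k, v in vars(results.arch).items():
            ag.attrs[k] = v
        cg = f.create_group("config")
        for k, v in vars(results.config).items():
            cg.attrs[k] = v
        f.attrs["init_seed"] = results.model.init_seed
        f.attrs["dtype"] = np.dtype(results.model.dtype).name
        hg = f.create_group("history")
        for col in results.history.columns:
            hg.create_dataset(col, data=results.history[col].to_numpy())


def load_model(path: PathLike) -> CNNResults:
    """Rebuild a results object from a checkpoint (no training data attached)."""
    with h5py.File(path, "r") as f:
        arch = CnnArchitecture(**{k: int(v) for k, v in f["architecture"].attrs.items()})
        cfg_raw = dict(f["config"].attrs.items())
        config = TrainingConfig(
            batch_size=int(cfg_raw["batch_size"]),
            epochs=int(cfg_raw["epochs"]),
            learning_rate=float(cfg_raw["learning_rate"]),
            momentum=float(cfg_raw["momentum"]),
            weight_decay=float(cfg_raw["weight_decay"]),
            shuffle_each_epoch=bool(cfg_raw["shuffle_each_epoch"]),
            seed=int(cfg_raw["seed"]),
        )
        dtype = np.dtype(str(f.attrs["dtype"]))
        params = {k: f["params"][k][()].astype(dtype) for k in f["params"]}
        history = pd.DataFrame({c: f["history"][c][()] for c in f["history"]})
        init_seed = int(f.attrs["init_seed"])
    placeholder = RippleEpisodeCNN(
        np.zeros((1, arch.input_len)), np.zeros(1, dtype=int),
        architecture=arch, init_seed=init_seed, dtype=dtype,
    )
    history = history[["epoch", "accuracy", "loss"]] if set(
        ("epoch", "accuracy", "loss")).issubset(history.columns) else history
    return CNNResults(placeholder, params, history, config)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
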