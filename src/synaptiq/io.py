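"""File formats: multichannel TIFF volumes, delimited-text sweep sets with
JSON sidecar metadata, and CSV tables.

Round-trip contract: intensities are bit-exact, floats survive to 1e-9,
metadata exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .synth_ephys import AcquisitionSpec, SweepSet
from .synth_imaging import ChannelStack


def save_channel_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a multichannel volume as one TIFF, channel axis first, with
    channel names and voxel size stored in the image description."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    meta = {"axes": "CZYX", "channels": names,
            "voxel_size_um_xyz": list(stack.voxel_size)}
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def load_channel_stack(path: str | Path) -> ChannelStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        names = meta["channels"]
        voxel = tuple(meta["voxel_size_um_xyz"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParameterError(f"malformed TIFF metadata in {path}: {exc}") from exc
    if data.ndim != 4 or data.shape[0] != len(names):
        raise ParameterError(f"{path}: expected CZYX data with {len(names)} channels")
    return ChannelStack({n: data[i] for i, n in enumerate(names)}, voxel_size=voxel)


def save_sweepset(sweeps: SweepSet, path: str | Path) -> Path:
    """Write sweeps as delimited text (time column + one column per trial)
    plus a ``.meta.json`` sidecar; truth tables go to ``_truth.csv`` files."""
    path = Path(path)
    cols = ["time_s"] + [f"trial_{i:03d}" for i in range(sweeps.n_trials)]
    arr = np.column_stack([sweeps.time, sweeps.trials.T])
    header = ",".join(cols)
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.12e")
    meta = asdict(sweeps.acquisition)
    meta["stimulus_times"] = list(meta["stimulus_times"])
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
    if sweeps.truth is not None:
        sweeps.truth.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)
    if sweeps.burst_truth is not None:
        sweeps.burst_truth.to_csv(
            path.with_name(path.stem + "_bursts.csv"), index=False
        )
    return path


def load_sweepset(path: str | Path) -> SweepSet:
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    try:
        meta = json.loads(meta_path.read_text())
        meta["stimulus_times"] = tuple(meta["stimulus_times"])
        acq = AcquisitionSpec(**meta)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParameterError(f"malformed sidecar {meta_path}: {exc}") from exc
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    trials = arr[:, 1:].T
    truth_path = path.with_name(path.stem + "_truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return SweepSet(trials, acq, truth=truth)


def save_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParameterError(f"malformed table {path}: {exc}") from exc
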