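"""File I/O: TIFF movies/stacks, delimited sweeps, ROI tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import Sweep

__all__ = [
    "save_tiff",
    "load_tiff",
    "save_sweep_text",
    "load_sweep_text",
    "load_rois_csv",
]


def save_tiff(path, array: np.ndarray, pixel_size_nm: float | None = None) -> None:
    """Write a (multi-page) TIFF; pixel size recorded as resolution metadata."""
    kwargs = {"photometric": "minisblack"}
    if pixel_size_nm is not None:
        per_um = 1000.0 / pixel_size_nm
        kwargs.update(resolution=(per_um, per_um),
                      metadata={"unit": "um", "pixel_size_nm": pixel_size_nm})
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32), **kwargs)


def load_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def save_sweep_text(path, sweep: Sweep) -> None:
    """Two-column delimited text (time s, current nA) with a JSON header line."""
    header = json.dumps(
        {"sampling_rate": sweep.sampling_rate,
         "stimulus_times": list(sweep.stimulus_times),
         "metadata": sweep.metadata},
        sort_keys=True,
    )
    t = sweep.times
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for ti, ci in zip(t, sweep.current):
            fh.write(f"{ti:.6f}\t{ci:.6f}\n")


def load_sweep_text(path) -> Sweep:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
    data = np.loadtxt(path, comments="#")
    current = data[:, 1]
    if "sampling_rate" in meta:
        fs = float(meta["sampling_rate"])
    else:
        fs = 1.0 / float(np.median(np.diff(data[:, 0])))
    return Sweep(
        current=current,
        sampling_rate=fs,
        stimulus_times=tuple(meta.get("stimulus_times", ())),
        metadata=meta.get("metadata", {}),
    )


def load_rois_csv(path) -> pd.DataFrame:
    """AZ readout positions: columns az_id, row, col [, animal, genotype]."""
    df = pd.read_csv(path)
    missing = {"az_id", "row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns {sorted(missing)}")
    return df
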