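"""CSV/TIFF readers and writers for traces, truth tables, events and images.

Trace CSVs carry one row per cell with a ``cell`` id column; acquisition
metadata (sampling rate, stage, condition) travels in ``#``-prefixed
header comment lines so a file round-trips without sidecar files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import SyntheticImage
from .simulate import SyntheticView

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_truth_csv",
    "write_events_csv",
    "write_image_tiff",
    "read_image_tiff",
]


def write_traces_csv(
    path: str | Path,
    traces: np.ndarray,
    fs: float,
    stage_label: str = "",
    condition: str = "",
) -> None:
    """Write a (cells x time) trace matrix with metadata header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(traces)
    df.insert(0, "cell", np.arange(traces.shape[0]))
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n# stage={stage_label}\n# condition={condition}\n")
        df.to_csv(fh, index=False)


def read_traces_csv(path: str | Path) -> tuple[np.ndarray, float, dict[str, str]]:
    """Read a trace CSV back into ``(matrix, fs, meta)``."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    fs = float(meta.pop("fs"))
    matrix = df.drop(columns=["cell"]).to_numpy(dtype=float)
    return matrix, fs, meta


def write_truth_csv(path: str | Path, view: SyntheticView) -> None:
    """Write the ground-truth event lists of a synthetic view (one row/event)."""
    rows = []
    for cell, (times, amps) in enumerate(view.truth_events):
        for t, a in zip(times, amps):
            rows.append({"cell": cell, "t_event": t, "amplitude": a})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["cell", "t_event", "amplitude"]).to_csv(
        path, index=False
    )


def write_events_csv(path: str | Path, tables: list, cell_ids=None) -> None:
    """Write detected event tables (one row per event, with cell id)."""
    frames = []
    for i, table in enumerate(tables):
        df = table.events.copy()
        df.insert(0, "cell", table.cell_id if cell_ids is None else cell_ids[i])
        df["threshold_used"] = table.threshold_used
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "cell", "peak_index", "t_peak", "amplitude",
                "t_on50", "t_off50", "fwhm", "threshold_used",
            ]
        )
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def write_image_tiff(path: str | Path, image: SyntheticImage) -> None:
    """Write a rendered neuron as a grayscale TIFF plus one mask TIFF per label."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    for name, mask in image.masks.items():
        tifffile.imwrite(
            path.with_name(path.stem + f"_mask_{name}.tif"),
            mask.astype(np.uint8),
        )


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
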