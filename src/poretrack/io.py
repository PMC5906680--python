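"""File-format round-tripping: localization CSV, trajectory CSV, TIFF, JSON.

Fixed dialects: comma-separated, '.' decimal, header required.
Localization tables use the column order
``frame,x_um,y_um,photons,background,channel``; trajectory tables add
``traj_id``.  Movies are multi-page TIFF, ground truth and reports JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simkit import LOC_COLUMNS

__all__ = [
    "read_locs",
    "write_locs",
    "read_stack",
    "write_stack",
    "write_json",
    "read_json",
]


def write_locs(locs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LOC_COLUMNS if c in locs.columns]
    extra = [c for c in locs.columns if c not in cols]
    locs[cols + extra].to_csv(path, index=False)


def read_locs(path: str | Path) -> pd.DataFrame:
    locs = pd.read_csv(path)
    missing = [c for c in ("frame", "x_um", "y_um") if c not in locs.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns: {missing}")
    return locs


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(stack), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
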