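"""File formats: growth-curve CSV, snapshot matrices, fit and manifest JSON.

All formats are plain text.  The growth CSV schema (header order) is::

    time_h,condition,bio_rep,tech_rep,population,relative_count

which is also the expected schema for user-supplied data (e.g. exported
imaging curves); unknown extra columns are preserved on round-trip.
Snapshots are integer CSV matrices using the shared kind codes (0 empty,
1 tumor, 2 resistant tumor, 3 fibroblast, 4 M1, 5 M2).
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GROWTH_SCHEMA, VALID_CONDITIONS, GrowthDataset

__all__ = [
    "read_growth_csv",
    "write_growth_csv",
    "export_snapshot",
    "import_snapshot",
    "render_snapshot",
    "RunManifest",
    "SNAPSHOT_PALETTE",
]

#: Rendering palette per kind code, matching the conventional figure colors:
#: tumor red, resistant dark red, fibroblast green, M1 dark blue, M2 light
#: blue; empty cells white.
SNAPSHOT_PALETTE = {
    0: (1.0, 1.0, 1.0),
    1: (0.84, 0.15, 0.16),
    2: (0.55, 0.0, 0.0),
    3: (0.17, 0.63, 0.17),
    4: (0.10, 0.15, 0.55),
    5: (0.45, 0.70, 0.95),
}

_NUMERIC = {"time_h": float, "relative_count": float}


def read_growth_csv(path, allow_any_condition: bool = False) -> GrowthDataset:
    """Read a long-format growth-curve CSV, validating the schema.

    Raises a ``ValueError`` naming any missing required column, reporting
    the row number of any non-numeric time or count, and rejecting unknown
    condition labels unless ``allow_any_condition`` is set.  Extra columns
    are kept.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, no growth data") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in GROWTH_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    for col, typ in _NUMERIC.items():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rownum = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
        elif coerced.isna().any():
            rownum = int(np.flatnonzero(coerced.isna())[0]) + 2
        else:
            df[col] = coerced.astype(typ)
            continue
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} at row {rownum}")
    if not allow_any_condition:
        unknown = set(df["condition"].unique()) - set(VALID_CONDITIONS)
        if unknown:
            raise ValueError(
                f"{path}: unknown condition label(s) {sorted(unknown)}; "
                f"expected {VALID_CONDITIONS} "
                "(pass allow_any_condition=True to override)")
    return GrowthDataset(df)


def write_growth_csv(dataset: GrowthDataset, path) -> Path:
    """Write a growth dataset as CSV (canonical columns first)."""
    path = Path(path)
    cols = list(GROWTH_SCHEMA) + [c for c in dataset.df.columns
                                  if c not in GROWTH_SCHEMA]
    dataset.df[cols].to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
def export_snapshot(snapshot, path) -> Path:
    """Write an integer-coded occupancy grid as a CSV matrix.

    Accepts a 2-D array or a state object with a ``snapshot()`` method.
    """
    if hasattr(snapshot, "snapshot"):
        snapshot = snapshot.snapshot()
    snapshot = np.asarray(snapshot)
    if snapshot.ndim != 2:
        raise ValueError("snapshot must be a 2-D integer grid")
    path = Path(path)
    np.savetxt(path, snapshot, fmt="%d", delimiter=",")
    return path


def import_snapshot(path) -> np.ndarray:
    """Read a snapshot CSV matrix back as an int array."""
    arr = np.loadtxt(Path(path), delimiter=",", dtype=np.int64, ndmin=2)
    return arr


def render_snapshot(snapshot, path=None, ax=None):
    """Render a snapshot with the fixed color legend; optionally save it."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if hasattr(snapshot, "snapshot"):
        snapshot = snapshot.snapshot()
    cmap = ListedColormap([SNAPSHOT_PALETTE[k] for k in range(6)])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(snapshot, cmap=cmap, vmin=0, vmax=5, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly (except wall time)."""

    command: str
    scenario: dict
    parameters: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    software_version: str = ""
    python_version: str = field(default_factory=platform.python_version)
    wall_time_s: float = 0.0

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
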