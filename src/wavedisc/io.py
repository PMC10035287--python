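"""Dataset I/O: a manifest table plus one delimited matrix per trial.

On-disk layout (comma-delimited, UTF-8):

* ``manifest.csv`` with columns ``trial_id, path, label``; paths are
  resolved relative to the manifest's directory.
* one CSV per trial with a header row of channel names and one row per time
  sample (so columns are channels; in memory trials are channels x time).

Trials whose files list the channels in a different order are realigned by
name to the first trial's channel order; a different channel *set* is an
error naming the file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ("trial_id", "path", "label")


def write_dataset(
    trials: Sequence[np.ndarray],
    labels: Sequence[str],
    channel_names: Sequence[str],
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write trials and manifest under ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    width = max(3, len(str(len(trials) - 1)))
    for i, (trial, label) in enumerate(zip(trials, labels)):
        trial_id = f"trial_{i:0{width}d}"
        rel = Path("trials") / f"{trial_id}.csv"
        pd.DataFrame(np.asarray(trial).T, columns=list(channel_names)).to_csv(
            out_dir / rel, index=False
        )
        rows.append({"trial_id": trial_id, "path": str(rel), "label": label})
    manifest_path = out_dir / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False
    )
    return manifest_path


def read_dataset(
    manifest_path: str | Path,
) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Read a manifest and its per-trial matrices.

    Returns ``(trials, labels, channel_names)`` with every trial aligned to
    the first trial's channel order (channels x time arrays).

    Raises
    ------
    FileNotFoundError
        For a missing manifest or trial file (the path is named).
    ValueError
        For missing manifest columns, inconsistent channel sets or
        inconsistent trial lengths (the offending file is named).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns: {sorted(missing)}")

    base = manifest_path.parent
    trials: list[np.ndarray] = []
    labels: list[str] = []
    channel_names: list[str] | None = None
    n_samples: int | None = None
    for row in manifest.itertuples(index=False):
        path = base / str(row.path)
        if not path.exists():
            raise FileNotFoundError(f"trial file not found: {path}")
        df = pd.read_csv(path)
        if channel_names is None:
            channel_names = list(df.columns)
            n_samples = len(df)
        else:
            if set(df.columns) != set(channel_names):
                raise ValueError(
                    f"{path}: channel set {sorted(df.columns)} differs from "
                    f"{sorted(channel_names)}"
                )
            if len(df) != n_samples:
                raise ValueError(
                    f"{path}: {len(df)} samples, expected {n_samples}"
                )
        trials.append(df[channel_names].to_numpy(dtype=float).T)
        labels.append(str(row.label))
    if channel_names is None:
        raise ValueError(f"manifest {manifest_path} lists no trials")
    return trials, np.array(labels), channel_names
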