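"""Output writers and seeded random-stream derivation.

One master seed derives independent per-module streams by fixed labels, so
re-running a configuration reproduces every stochastic simulation exactly.
Outputs: per-frame tracks CSV (fixed column order, 6 significant digits),
events JSONL (written live by the log), a summary JSON embedding the
resolved configuration, and optional 16-bit TIFF frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["derive_rng", "write_tracks_csv", "write_summary", "write_image",
           "write_outputs"]

_STREAM_LABELS = {
    "population": 1, "microscope": 2, "ssa": 3, "recombination": 4,
    "measurement": 5, "fit": 6, "control": 7, "scenario": 8,
}

TRACK_COLUMNS = ["frame", "track_id", "centroid_row", "centroid_col", "area",
                 "fl_GFP", "fl_RFP", "fl_CFP", "group", "targeted",
                 "applied_light"]


def derive_rng(master_seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Independent generator for a named module stream."""
    if label not in _STREAM_LABELS:
        raise KeyError(f"unknown stream label {label!r}")
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF,
                                  _STREAM_LABELS[label], int(index)])


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if x is None:
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def tracks_dataframe(rows: list[dict]) -> pd.DataFrame:
    """Normalize per-frame track rows to the fixed CSV column order."""
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.sort_values(["frame", "track_id"]).reset_index(drop=True)


def write_tracks_csv(rows: list[dict], path) -> Path:
    """Write the tracks table; 6 significant digits, diffable byte-for-byte."""
    path = Path(path)
    df = tracks_dataframe(rows)
    with path.open("w") as fh:
        fh.write(",".join(TRACK_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    return path


def write_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str)
                    + "\n")
    return path


def write_outputs(result, out_dir) -> dict:
    """Write a run's tracks CSV, events JSONL and summary JSON.

    Returns the mapping of artifact name to path. The summary embeds the
    resolved configuration, so config -> run -> summary round-trips.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": write_tracks_csv(result.track_rows, out_dir / "tracks.csv"),
        "summary": write_summary(result.summary, out_dir / "summary.json"),
    }
    events_path = out_dir / "events.jsonl"
    with events_path.open("w") as fh:
        if result.log is not None:
            for rec in result.log.records:
                fh.write(rec.to_json() + "\n")
    paths["events"] = events_path
    return paths


def write_image(image: np.ndarray, out_dir, frame: int, position: int,
                channel: str) -> Path:
    """Single-plane 16-bit TIFF, filename frame{k}_pos{p}_{channel}.tiff."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"frame{frame}_pos{position}_{channel}.tiff"
    data = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path
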