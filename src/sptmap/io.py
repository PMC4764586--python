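"""Trajectory-table and image I/O.

The universal trajectory container is a pandas ``DataFrame`` with the
columns ``track_id, frame, x_um, y_um, channel`` — one row per
localization, frames 0-based, positions in μm relative to the field
origin (top-left; x rightward, y downward).  Image stacks are multi-page
16-bit TIFFs; compartment masks are single-page 8-bit TIFFs (0/255).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "channel"]


def empty_tracks() -> pd.DataFrame:
    """Return an empty trajectory table with the canonical schema."""
    return pd.DataFrame(
        {
            "track_id": pd.Series(dtype=np.int64),
            "frame": pd.Series(dtype=np.int64),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "channel": pd.Series(dtype=object),
        }
    )


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check that ``tracks`` carries the canonical columns; return it."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    return tracks


def write_tracks(tracks: pd.DataFrame, path) -> None:
    validate_tracks(tracks)
    tracks.to_csv(path, index=False, columns=TRACK_COLUMNS)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_tracks(df)
    df["track_id"] = df["track_id"].astype(np.int64)
    df["frame"] = df["frame"].astype(np.int64)
    return df


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, rows, cols) array as a multi-page 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit TIFF with values 0/255."""
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0
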