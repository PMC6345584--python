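"""Single-cell migration speed from tracked coordinates.

Tracks arrive as frame-indexed (x, y) positions exported by a tracker; cells
are the experimental unit, so condition summaries are means of per-cell mean
speeds with their SEM. Default frame interval is 10 minutes (standard
overnight random-migration time lapse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Track", "SpeedSummary", "track_speed", "condition_summary"]


@dataclass
class Track:
    """One cell's positions over time.

    positions are (x, y) pairs in pixels (converted by pixel_size) or already
    in µm with pixel_size = 1. frame_interval is in minutes.
    """

    cell_id: str
    frames: np.ndarray
    positions: np.ndarray
    frame_interval: float = 10.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of (x, y)")
        if self.frames.size != self.positions.shape[0]:
            raise ValueError("frames and positions length mismatch")
        if self.frames.size < 2:
            raise ValueError("a track needs at least 2 positions")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")


@dataclass
class SpeedSummary:
    cell_id: str
    mean_speed: float  # µm/min
    path_length: float  # µm
    n_steps: int
    n_gaps_bridged: int = 0


def track_speed(track: Track) -> SpeedSummary:
    """Mean speed = total path length / total elapsed time.

    Missing frames are bridged by a single straight step spanning the gap
    (dt = gap × frame_interval) and counted in n_gaps_bridged; with gap-free
    tracks this equals the mean of instantaneous speeds.
    """
    disp = np.diff(track.positions, axis=0) * track.pixel_size
    step_len = np.hypot(disp[:, 0], disp[:, 1])
    frame_gaps = np.diff(track.frames)
    n_steps = int(frame_gaps.sum())
    path = float(step_len.sum())
    mean_speed = path / (n_steps * track.frame_interval)
    return SpeedSummary(
        cell_id=track.cell_id,
        mean_speed=mean_speed,
        path_length=path,
        n_steps=n_steps,
        n_gaps_bridged=int((frame_gaps > 1).sum()),
    )


def condition_summary(
    tracks: Sequence[Track],
    labels: Sequence[str],
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-condition cell counts, mean of per-cell speeds, and SEM.

    When an explicit condition list is given, any track labelled outside it is
    rejected (typo guard for plate maps).
    """
    tracks = list(tracks)
    labels = list(labels)
    if not tracks:
        raise ValueError("empty track list")
    if len(labels) != len(tracks):
        raise ValueError("every track must carry a condition label")
    if conditions is not None:
        unknown = sorted(set(labels) - set(conditions))
        if unknown:
            raise ValueError(f"unknown condition label(s): {unknown}")
    speeds = pd.DataFrame(
        {
            "condition": labels,
            "speed": [track_speed(t).mean_speed for t in tracks],
        }
    )
    rows = []
    for cond, grp in speeds.groupby("condition", sort=True):
        v = grp["speed"].to_numpy()
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(
            {
                "condition": cond,
                "n_cells": int(v.size),
                "mean_speed": float(v.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)
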