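"""Per-trial recording container and column-naming conventions.

A trial is one pass along the walkway by one participant under one walking
condition, stored as a frame-by-frame table: sagittal joint angles for both
limbs (hip, knee, ankle) plus anterior-posterior ("ap", the raw horizontal
world coordinate) and vertical positions of the heel, toe and pelvis
landmarks per side.  Positions are raw world coordinates; the walking
direction is always estimated from the pelvis trajectory, never assumed
from file orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

SIDES = ("left", "right")
LANDMARKS = ("heel", "toe", "pelvis")
AXES = ("ap", "vert")
CONDITIONS = ("level", "ascent", "descent")


def landmark_column(side: str, landmark: str, axis: str) -> str:
    """Column name for a landmark coordinate, e.g. ``left_heel_ap_m``."""
    return f"{side}_{landmark}_{axis}_m"


def angle_column(side: str, joint: str) -> str:
    """Column name for a sagittal joint angle, e.g. ``right_knee_sagittal_deg``."""
    return f"{side}_{joint}_sagittal_deg"


def expected_columns() -> list:
    """All frame columns a trial file must provide (plus ``time_s``)."""
    from .features import JOINTS

    cols = ["time_s"]
    cols += [landmark_column(s, l, a) for s in SIDES for l in LANDMARKS for a in AXES]
    cols += [angle_column(s, j) for s in SIDES for j in JOINTS]
    return cols


@dataclass
class TrialRecording:
    """One walking trial: metadata plus a per-frame table.

    Attributes
    ----------
    participant, group, condition, trial_index:
        Identifying metadata; ``condition`` is one of ``level``, ``ascent``,
        ``descent``.
    fs:
        Sampling rate in Hz.
    incline_deg:
        Nominal walkway incline (0 for level walking).
    frames:
        DataFrame with ``time_s`` plus the landmark/angle columns from
        :func:`expected_columns`.
    """

    participant: str
    group: str
    condition: str
    trial_index: int
    fs: float
    incline_deg: float
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        missing = set(expected_columns()) - set(self.frames.columns)
        if missing:
            raise ValueError(f"trial frames missing columns: {sorted(missing)}")

    @property
    def trial_id(self) -> str:
        return f"{self.participant}_{self.condition}_t{self.trial_index}"

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def landmark_xy(self, side: str, landmark: str) -> np.ndarray:
        """(n, 2) array of raw (ap, vertical) world coordinates in meters."""
        return np.column_stack(
            [
                self.frames[landmark_column(side, landmark, "ap")].to_numpy(float),
                self.frames[landmark_column(side, landmark, "vert")].to_numpy(float),
            ]
        )

    def angle(self, side: str, joint: str) -> np.ndarray:
        return self.frames[angle_column(side, joint)].to_numpy(float)

    def with_frames(self, frames: pd.DataFrame) -> "TrialRecording":
        """Copy of this recording with a replacement frame table."""
        return TrialRecording(
            participant=self.participant,
            group=self.group,
            condition=self.condition,
            trial_index=self.trial_index,
            fs=self.fs,
            incline_deg=self.incline_deg,
            frames=frames,
        )
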