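"""Coordinate-based gait event detection, foot-strike classification, trimming.

Initial contact (IC) and toe-off (TO) are found from relative landmark
excursions along the walking direction, the standard coordinate-based
approach for overground gait: the heel is maximally anterior to the pelvis
at initial contact, and the toe maximally posterior at toe-off.  So per
side,

* IC = local maxima of (heel_AP - pelvis_AP),
* TO = local minima of (toe_AP - pelvis_AP),

with peaks accepted only above a prominence floor (a fraction of the
signal's interquartile range) and separated by a minimum interval.  The
walking direction itself is estimated per trial as the first principal
axis of the pelvis trajectory, which makes detection invariant to rigid
rotations of the capture coordinates and handles ramps (the axis follows
the slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .trial import SIDES, TrialRecording

logger = logging.getLogger(__name__)


class EventDetectionError(RuntimeError):
    """Event detection produced an invalid (non-alternating) sequence."""


class StationaryTrialError(ValueError):
    """The pelvis does not move enough to define a walking direction."""


class TrimmingError(ValueError):
    """The trial is too short for the condition's trimming rule."""


@dataclass(frozen=True)
class GaitEvent:
    """A single gait event: side, kind (``IC``/``TO``), frame index, time (s)."""

    side: str
    kind: str
    frame: int
    time: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.kind not in ("IC", "TO"):
            raise ValueError("kind must be 'IC' or 'TO'")


@dataclass(frozen=True)
class EventSeries:
    """Typed, side-labelled event sequence for one trial.

    Per side, events must be strictly increasing in time and alternate
    IC/TO (starting with either kind); ipsilateral ICs must be at least
    ``min_cycle_s`` apart.  Use :meth:`validate` after construction by a
    detector; the constructor itself only sorts.
    """

    events: Tuple[GaitEvent, ...]
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: (e.frame, e.side, e.kind)))
        )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def per_side(self, side: str) -> List[GaitEvent]:
        return [e for e in self.events if e.side == side]

    def ics(self, side: Optional[str] = None) -> List[GaitEvent]:
        return [e for e in self.events if e.kind == "IC" and (side is None or e.side == side)]

    def tos(self, side: Optional[str] = None) -> List[GaitEvent]:
        return [e for e in self.events if e.kind == "TO" and (side is None or e.side == side)]

    def validate(self, min_cycle_s: float = 0.4) -> None:
        """Raise :class:`EventDetectionError` on alternation/spacing violations."""
        for side in SIDES:
            seq = self.per_side(side)
            for prev, cur in zip(seq[:-1], seq[1:]):
                if cur.frame <= prev.frame:
                    raise EventDetectionError(
                        f"{side}: events not strictly increasing at frames {prev.frame}, {cur.frame}"
                    )
                if cur.kind == prev.kind:
                    raise EventDetectionError(
                        f"{side}: consecutive {cur.kind} events at frames {prev.frame}, {cur.frame}"
                    )
            ic_frames = [e.frame for e in seq if e.kind == "IC"]
            for a, b in zip(ic_frames[:-1], ic_frames[1:]):
                if (b - a) / self.fs < min_cycle_s:
                    raise EventDetectionError(
                        f"{side}: ipsilateral ICs at frames {a}, {b} closer than {min_cycle_s}s"
                    )


def walking_direction(
    pelvis_xy: np.ndarray, min_displacement_m: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate the walking direction from the pelvis trajectory.

    Returns the unit direction (first principal axis of the pelvis
    positions, signed so the projection increases over the trial) and the
    projected anterior-posterior series.

    Raises
    ------
    StationaryTrialError
        If the pelvis net displacement is below ``min_displacement_m``.
    """
    p = np.asarray(pelvis_xy, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pelvis_xy must be an (n, 2) array")
    net = p[-1] - p[0]
    if np.linalg.norm(net) < min_displacement_m:
        raise StationaryTrialError(
            f"pelvis net displacement {np.linalg.norm(net):.3f} m < {min_displacement_m} m"
        )
    centered = p - p.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, net) < 0:
        direction = -direction
    return direction, p @ direction


def _peak_frames(
    signal: np.ndarray, fs: float, prominence_frac: float, min_interval_s: float
) -> np.ndarray:
    """Accepted local maxima; plateau ties resolve to the first frame."""
    iqr = np.subtract(*np.percentile(signal, [75, 25]))
    if iqr <= 0:
        return np.array([], dtype=int)
    peaks, props = find_peaks(
        signal,
        prominence=prominence_frac * iqr,
        distance=max(1, round(min_interval_s * fs)),
        plateau_size=(1, None),
    )
    return props["left_edges"].astype(int)


def detect_events_side(
    heel_ap: np.ndarray,
    toe_ap: np.ndarray,
    pelvis_ap: np.ndarray,
    fs: float,
    side: str,
    prominence_frac: float = 0.2,
    min_interval_s: float = 0.3,
) -> List[GaitEvent]:
    """Detect IC/TO events for one side from projected AP landmark series."""
    n = len(pelvis_ap)
    if not (len(heel_ap) == len(toe_ap) == n):
        raise ValueError("heel, toe and pelvis series must have equal length")
    ic_frames = _peak_frames(np.asarray(heel_ap) - pelvis_ap, fs, prominence_frac, min_interval_s)
    to_frames = _peak_frames(-(np.asarray(toe_ap) - pelvis_ap), fs, prominence_frac, min_interval_s)
    if len(ic_frames) == 0 and len(to_frames) == 0:
        logger.warning("%s side: no qualifying extrema; empty event series", side)
        return []
    events = [GaitEvent(side, "IC", int(f), f / fs) for f in ic_frames]
    events += [GaitEvent(side, "TO", int(f), f / fs) for f in to_frames]
    return sorted(events, key=lambda e: e.frame)


def detect_events(
    recording: TrialRecording,
    prominence_frac: float = 0.2,
    min_interval_s: float = 0.3,
    min_cycle_s: float = 0.4,
) -> EventSeries:
    """Detect IC/TO events for both sides of a (pre-filtered) trial.

    The pelvis trajectory (mean of both side columns) defines the walking
    direction; all landmarks are projected onto it before peak picking.
    The returned series satisfies the per-side alternation invariants or an
    :class:`EventDetectionError` is raised.
    """
    pelvis = 0.5 * (recording.landmark_xy("left", "pelvis") + recording.landmark_xy("right", "pelvis"))
    direction, pelvis_ap = walking_direction(pelvis)
    all_events: List[GaitEvent] = []
    for side in SIDES:
        heel_ap = recording.landmark_xy(side, "heel") @ direction
        toe_ap = recording.landmark_xy(side, "toe") @ direction
        all_events += detect_events_side(
            heel_ap, toe_ap, pelvis_ap, recording.fs, side, prominence_frac, min_interval_s
        )
    series = EventSeries(events=tuple(all_events), fs=recording.fs)
    series.validate(min_cycle_s=min_cycle_s)
    return series


def classify_foot_strike(
    recording: TrialRecording,
    ic: GaitEvent,
    direction: Optional[np.ndarray] = None,
    threshold_m: float = 0.0,
) -> str:
    """Classify an initial contact as ``heel_strike`` or ``forefoot_strike``.

    The criterion is the relative heel/toe height along the walkway normal
    at the IC frame: heel at or below the toe means heel strike.  On ramps
    the walkway normal is perpendicular to the estimated walking direction,
    so the comparison respects the slope.  Returns ``"unknown"`` when a
    landmark is missing at the IC frame.
    """
    if direction is None:
        pelvis = 0.5 * (
            recording.landmark_xy("left", "pelvis") + recording.landmark_xy("right", "pelvis")
        )
        direction, _ = walking_direction(pelvis)
    normal = np.array([-direction[1], direction[0]])  # 90 deg CCW: walkway-normal, upward
    if normal[1] < 0:
        normal = -normal
    heel = recording.landmark_xy(ic.side, "heel")[ic.frame]
    toe = recording.landmark_xy(ic.side, "toe")[ic.frame]
    if not (np.all(np.isfinite(heel)) and np.all(np.isfinite(toe))):
        return "unknown"
    return "heel_strike" if heel @ normal <= toe @ normal + threshold_m else "forefoot_strike"


@dataclass(frozen=True)
class CycleSpan:
    """One gait cycle: ipsilateral IC to the next ipsilateral IC."""

    side: str
    start: GaitEvent
    end: GaitEvent

    @property
    def start_frame(self) -> int:
        return self.start.frame

    @property
    def end_frame(self) -> int:
        return self.end.frame


@dataclass(frozen=True)
class TrimResult:
    """Steps and cycles retained by the condition's trimming rule."""

    kept_ics: Tuple[GaitEvent, ...]
    cycles: Tuple[CycleSpan, ...]
    n_steps_total: int


def trim_cycles(events: EventSeries, condition: str) -> TrimResult:
    """Apply the per-condition trial-trimming rule and list analyzable cycles.

    Steps are the initial contacts of either foot in temporal order,
    indexed 1..N.  Level walking keeps steps 3..N-3 (analysis starts with
    the third step and ends three steps before stopping); ramp walking
    keeps steps 2..N-1.  A cycle is returned only when both of its bounding
    ipsilateral ICs lie in the kept range.
    """
    ics = events.ics()
    n = len(ics)
    if condition == "level":
        first, last = 3, n - 3
    elif condition in ("ascent", "descent"):
        first, last = 2, n - 1
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if first > last:
        raise TrimmingError(
            f"trial too short for condition rule: {n} steps, kept range {first}..{last} empty"
        )
    kept = ics[first - 1 : last]  # steps are 1-indexed
    cycles: List[CycleSpan] = []
    for side in SIDES:
        side_ics = [e for e in kept if e.side == side]
        for a, b in zip(side_ics[:-1], side_ics[1:]):
            cycles.append(CycleSpan(side=side, start=a, end=b))
    cycles.sort(key=lambda c: c.start_frame)
    return TrimResult(kept_ics=tuple(kept), cycles=tuple(cycles), n_steps_total=n)


def flag_outlier_cycles(
    cycles: Sequence[CycleSpan], fs: float, n_sd: float = 3.0
) -> Dict[int, bool]:
    """QC flags: cycles whose duration deviates > ``n_sd`` scale units from
    the trial median.

    Returns ``{cycle_index: flagged}``.  Stands in for the study's manual
    event correction: flagged cycles are reported and excluded downstream.
    The scale is the MAD (scaled to be SD-consistent) so a single aberrant
    cycle cannot inflate its own acceptance threshold -- with the handful
    of cycles a trial yields, a plain SD can never exceed the 3-SD bound
    (max deviation/SD is sqrt(n-1)).  Falls back to the plain SD when the
    MAD is zero (frame-quantized identical durations).
    """
    durations = np.array([(c.end_frame - c.start_frame) / fs for c in cycles])
    if len(durations) == 0:
        return {}
    med = np.median(durations)
    scale = 1.4826 * np.median(np.abs(durations - med))
    if scale == 0:
        scale = durations.std(ddof=0)
    if scale == 0:
        return {i: False for i in range(len(cycles))}
    return {i: bool(abs(d - med) > n_sd * scale) for i, d in enumerate(durations)}
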