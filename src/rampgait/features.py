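"""Spatiotemporal parameters and representative sagittal joint-angle features.

A participant's gait in one condition is summarised by a 101-sample
representative waveform per joint (0..100 % of the gait cycle, 0 % = initial
contact) together with the toe-off location in % cycle.  From these, twelve
representative angles are extracted -- four per joint -- using fixed windows
on the cycle:

* stance phase 1 (ST1): initial contact to mid-stance,
* stance phase 2 (ST2): mid-stance to ipsilateral toe-off,
* swing: toe-off to the next initial contact,
* the stance-to-swing transition window: +/- 10 % cycle around toe-off.

Sign convention throughout: hip/knee flexion and ankle dorsiflexion are
positive; extension / plantarflexion are negative.  Peak plantarflexion is
reported as a positive magnitude (the negated window minimum), matching the
way such values are conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

JOINTS = ("hip", "knee", "ankle")

#: The twelve representative joint-angle parameters, grouped by joint.
FEATURES_BY_JOINT: Dict[str, tuple] = {
    "hip": ("RoM", "MaxFlex_Stance", "MaxFlex_Swing", "MaxExt_Stance"),
    "knee": ("RoM", "MaxFlex_ST1", "MaxFlex_Swing", "MaxExt_Stance"),
    "ankle": ("RoM", "MaxDorsiflexion_ST2", "MaxPlantarflexion_STSW", "InitialContact"),
}

#: Flat canonical feature names, e.g. ``"knee_MaxFlex_ST1"``; always 12 entries.
FEATURE_NAMES = tuple(
    f"{joint}_{name}" for joint in JOINTS for name in FEATURES_BY_JOINT[joint]
)

N_SAMPLES = 101  # 0, 1, ..., 100 % of the gait cycle


class WindowError(ValueError):
    """An extraction window is empty or invalid."""


@dataclass(frozen=True)
class PhasePartition:
    """Partition of the 0-100 % gait cycle into ST1 / ST2 / swing.

    Parameters
    ----------
    to_percent:
        Toe-off location in % of the gait cycle (0 < to_percent < 100).
    mid_stance:
        Boundary between ST1 and ST2 in % cycle.  Defaults to the temporal
        midpoint of stance, ``to_percent / 2``.
    """

    to_percent: float
    mid_stance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.to_percent < 100.0):
            raise ValueError(f"to_percent must be in (0, 100), got {self.to_percent}")
        if not (0.0 < self.mid_stance < self.to_percent):
            raise ValueError(
                f"mid_stance must be in (0, to_percent), got {self.mid_stance}"
            )

    # -- index masks on the 101-point grid ---------------------------------
    @property
    def _idx(self) -> np.ndarray:
        return np.arange(N_SAMPLES)

    @property
    def st1_mask(self) -> np.ndarray:
        return self._idx < self.mid_stance

    @property
    def st2_mask(self) -> np.ndarray:
        return (self._idx >= self.mid_stance) & (self._idx < self.to_percent)

    @property
    def stance_mask(self) -> np.ndarray:
        return self._idx < self.to_percent

    @property
    def swing_mask(self) -> np.ndarray:
        return self._idx >= self.to_percent

    def transition_mask(self, halfwidth: float = 10.0) -> np.ndarray:
        """Stance-to-swing window: ``[to_percent - halfwidth, to_percent + halfwidth]``."""
        lo = self.to_percent - halfwidth
        hi = self.to_percent + halfwidth
        return (self._idx >= lo) & (self._idx <= hi)


def partition_phases(to_percent: float, mid_stance: float | None = None) -> PhasePartition:
    """Build a :class:`PhasePartition`; mid-stance defaults to ``to_percent / 2``."""
    if mid_stance is None:
        mid_stance = to_percent / 2.0
    return PhasePartition(to_percent=float(to_percent), mid_stance=float(mid_stance))


@dataclass(frozen=True)
class FeatureSet:
    """The 12 representative joint-angle values (degrees), keyed by canonical name."""

    values: Dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"FeatureSet missing features: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _window_extremum(w: np.ndarray, mask: np.ndarray, mode: str) -> float:
    if not mask.any():
        raise WindowError("empty extraction window")
    sub = w[mask]
    val = sub.max() if mode == "max" else sub.min()
    # window-containment invariant: the arg-extremum must lie inside the mask
    arg = np.flatnonzero(mask)[int(np.argmax(sub) if mode == "max" else np.argmin(sub))]
    assert mask[arg]
    return float(val)


def extract_features(
    waveforms: Mapping[str, np.ndarray],
    partition: PhasePartition,
    transition_halfwidth: float = 10.0,
) -> FeatureSet:
    """Extract the 12 representative values from 101-sample joint waveforms.

    Parameters
    ----------
    waveforms:
        Mapping ``{"hip": w, "knee": w, "ankle": w}`` of 101-sample arrays
        (degrees, flexion/dorsiflexion positive).
    partition:
        Phase partition of the cycle (from the averaged toe-off location).
    transition_halfwidth:
        Half-width (in % cycle) of the stance-to-swing window used for peak
        plantarflexion; default 10.

    Returns
    -------
    FeatureSet
        ``RoM`` is max - min over the full cycle; ``MaxExt_Stance`` is the
        *signed* minimum flexion angle during stance (negative values mean
        hyperextension); ``MaxPlantarflexion_STSW`` is the positive magnitude
        of the most plantarflexed (most negative) angle in the transition
        window; ``InitialContact`` is the signed angle at 0 % cycle.
    """
    arrs = {}
    for joint in JOINTS:
        if joint not in waveforms:
            raise KeyError(f"missing waveform for joint {joint!r}")
        w = np.asarray(waveforms[joint], dtype=float)
        if w.shape != (N_SAMPLES,):
            raise ValueError(f"{joint} waveform must have {N_SAMPLES} samples, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"{joint} waveform contains non-finite values")
        arrs[joint] = w

    p = partition
    hip, knee, ankle = arrs["hip"], arrs["knee"], arrs["ankle"]
    full = np.ones(N_SAMPLES, dtype=bool)

    values = {
        "hip_RoM": _window_extremum(hip, full, "max") - _window_extremum(hip, full, "min"),
        "hip_MaxFlex_Stance": _window_extremum(hip, p.stance_mask, "max"),
        "hip_MaxFlex_Swing": _window_extremum(hip, p.swing_mask, "max"),
        "hip_MaxExt_Stance": _window_extremum(hip, p.stance_mask, "min"),
        "knee_RoM": _window_extremum(knee, full, "max") - _window_extremum(knee, full, "min"),
        "knee_MaxFlex_ST1": _window_extremum(knee, p.st1_mask, "max"),
        "knee_MaxFlex_Swing": _window_extremum(knee, p.swing_mask, "max"),
        "knee_MaxExt_Stance": _window_extremum(knee, p.stance_mask, "min"),
        "ankle_RoM": _window_extremum(ankle, full, "max") - _window_extremum(ankle, full, "min"),
        "ankle_MaxDorsiflexion_ST2": _window_extremum(ankle, p.st2_mask, "max"),
        "ankle_MaxPlantarflexion_STSW": -_window_extremum(
            ankle, p.transition_mask(transition_halfwidth), "min"
        ),
        "ankle_InitialContact": float(ankle[0]),
    }
    return FeatureSet(values=values)


# ---------------------------------------------------------------------------
# Spatiotemporal parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatioTemporal:
    """Cadence (steps/min), walking velocity (m/s), step length (m)."""

    cadence: float
    velocity: float
    step_length: float

    def __post_init__(self) -> None:
        for name in ("cadence", "velocity", "step_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def as_dict(self) -> Dict[str, float]:
        return {
            "cadence": self.cadence,
            "velocity": self.velocity,
            "step_length": self.step_length,
        }


def spatiotemporal(
    kept_ics: Sequence,
    heel_ap: Mapping[str, np.ndarray],
    pelvis_ap: np.ndarray,
    fs: float,
) -> SpatioTemporal:
    """Spatiotemporal parameters over the kept (post-trimming) window.

    Parameters
    ----------
    kept_ics:
        Initial-contact events (both feet, temporal order) retained by the
        trial-trimming rule; each has ``.frame``, ``.time`` and ``.side``.
    heel_ap:
        Per-side heel positions projected on the walking direction (m).
    pelvis_ap:
        Pelvis position projected on the walking direction (m).
    fs:
        Sampling rate (Hz).

    Notes
    -----
    * cadence = 60 * (n_steps - 1) / (time between first and last kept IC),
    * step length = mean leading-heel minus trailing-heel separation along
      the walking direction at each bilateral IC (along-slope on ramps),
    * velocity = pelvis displacement along the walking direction over the
      kept window divided by its duration.
    """
    ics = sorted(kept_ics, key=lambda e: e.frame)
    if len(ics) < 2:
        raise ValueError("need at least 2 kept initial contacts for spatiotemporal parameters")
    t0, t1 = ics[0].time, ics[-1].time
    cadence = 60.0 * (len(ics) - 1) / (t1 - t0)

    steps = []
    for prev, cur in zip(ics[:-1], ics[1:]):
        if prev.side == cur.side:
            continue  # step length is defined between bilateral contacts
        lead = heel_ap[cur.side][cur.frame]
        trail = heel_ap[prev.side][cur.frame]
        steps.append(lead - trail)
    if not steps:
        raise ValueError("no bilateral IC pairs in the kept window")
    step_length = float(np.mean(steps))

    velocity = float(pelvis_ap[ics[-1].frame] - pelvis_ap[ics[0].frame]) / (t1 - t0)
    return SpatioTemporal(cadence=cadence, velocity=velocity, step_length=step_length)
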