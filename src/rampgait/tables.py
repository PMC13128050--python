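"""Published group-level calibration targets for the synthetic cohort.

Spatiotemporal targets are group means (SD) of cadence (steps/min),
velocity (m/s) and step length (m) per walking condition; joint-angle
targets are the published velocity-adjusted group means (degrees) of the
12 representative sagittal parameters.  Values follow this package's sign
convention (flexion/dorsiflexion positive): hip ``MaxExt_Stance`` is
stored as the *signed* minimum flexion angle, i.e. the negated extension
magnitude that tables conventionally print; knee extension values are
already signed; ankle plantarflexion is a positive magnitude.

The joint-angle targets are model-adjusted means, so within a condition
they need not be mutually consistent as a single waveform (in particular
the knee RoM can differ from max - min of the printed extrema); the
template builder therefore treats RoM as derived when calibrating to these
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

GROUPS = ("young", "old")
CONDITIONS = ("level", "ascent", "descent")

#: (mean, SD) per parameter -> condition -> group
SPATIOTEMPORAL_TARGETS: Dict[str, Dict[str, Dict[str, Tuple[float, float]]]] = {
    "cadence": {
        "level": {"young": (114.14, 5.43), "old": (114.13, 8.30)},
        "ascent": {"young": (104.16, 5.70), "old": (102.04, 7.74)},
        "descent": {"young": (112.60, 5.35), "old": (112.04, 10.60)},
    },
    "velocity": {
        "level": {"young": (1.39, 0.13), "old": (1.28, 0.18)},
        "ascent": {"young": (1.24, 0.10), "old": (1.08, 0.10)},
        "descent": {"young": (1.27, 0.15), "old": (1.11, 0.16)},
    },
    "step_length": {
        "level": {"young": (0.73, 0.06), "old": (0.67, 0.07)},
        "ascent": {"young": (0.72, 0.05), "old": (0.64, 0.05)},
        "descent": {"young": (0.67, 0.07), "old": (0.59, 0.07)},
    },
}

#: Joint-angle group targets (deg), flat feature names -> condition -> group.
JOINT_ANGLE_TARGETS: Dict[str, Dict[str, Dict[str, float]]] = {
    "hip_RoM": {
        "level": {"young": 44.5, "old": 47.2},
        "ascent": {"young": 60.1, "old": 63.4},
        "descent": {"young": 39.6, "old": 41.2},
    },
    "hip_MaxFlex_Stance": {
        "level": {"young": 24.1, "old": 26.7},
        "ascent": {"young": 42.6, "old": 43.7},
        "descent": {"young": 21.9, "old": 25.7},
    },
    "hip_MaxFlex_Swing": {
        "level": {"young": 27.9, "old": 30.2},
        "ascent": {"young": 38.9, "old": 39.3},
        "descent": {"young": 24.8, "old": 28.2},
    },
    # signed minimum flexion angle (= -extension magnitude as printed)
    "hip_MaxExt_Stance": {
        "level": {"young": -16.2, "old": -16.2},
        "ascent": {"young": -17.3, "old": -20.4},
        "descent": {"young": -14.8, "old": -12.5},
    },
    "knee_RoM": {
        "level": {"young": 68.1, "old": 65.6},
        "ascent": {"young": 58.0, "old": 60.5},
        "descent": {"young": 71.0, "old": 69.4},
    },
    "knee_MaxFlex_ST1": {
        "level": {"young": 13.7, "old": 17.3},
        "ascent": {"young": 25.0, "old": 33.4},
        "descent": {"young": 23.5, "old": 28.7},
    },
    "knee_MaxFlex_Swing": {
        "level": {"young": 66.2, "old": 66.6},
        "ascent": {"young": 61.0, "old": 64.3},
        "descent": {"young": 69.9, "old": 72.6},
    },
    "knee_MaxExt_Stance": {
        "level": {"young": 1.4, "old": -1.5},
        "ascent": {"young": -4.0, "old": -5.2},
        "descent": {"young": 0.5, "old": -4.1},
    },
    "ankle_RoM": {
        "level": {"young": 32.6, "old": 30.7},
        "ascent": {"young": 39.9, "old": 35.8},
        "descent": {"young": 29.2, "old": 27.3},
    },
    "ankle_MaxDorsiflexion_ST2": {
        "level": {"young": 14.1, "old": 14.1},
        "ascent": {"young": 19.3, "old": 20.0},
        "descent": {"young": 15.3, "old": 17.4},
    },
    # positive plantarflexion magnitude
    "ankle_MaxPlantarflexion_STSW": {
        "level": {"young": 18.5, "old": 16.7},
        "ascent": {"young": 20.5, "old": 15.4},
        "descent": {"young": 13.8, "old": 9.9},
    },
    "ankle_InitialContact": {
        "level": {"young": -2.0, "old": -0.6},
        "ascent": {"young": 1.3, "old": 3.8},
        "descent": {"young": -0.3, "old": 2.2},
    },
}


@dataclass(frozen=True)
class GroupTargets:
    """Calibration targets for one (group, condition) cell.

    ``features`` holds the 12 joint-angle targets (deg, signed convention);
    ``cadence`` and ``velocity`` are (mean, SD) tuples.  Step length is
    implied: L = 60 * velocity / cadence, which the published spatiotemporal
    values satisfy to ~1 %.
    """

    features: Mapping[str, float]
    cadence: Tuple[float, float]
    velocity: Tuple[float, float]


def default_group_targets() -> Dict[Tuple[str, str], GroupTargets]:
    """Targets for every (group, condition) cell, from the published tables."""
    out: Dict[Tuple[str, str], GroupTargets] = {}
    for group in GROUPS:
        for cond in CONDITIONS:
            feats = {
                name: by_cond[cond][group] for name, by_cond in JOINT_ANGLE_TARGETS.items()
            }
            out[(group, cond)] = GroupTargets(
                features=feats,
                cadence=SPATIOTEMPORAL_TARGETS["cadence"][cond][group],
                velocity=SPATIOTEMPORAL_TARGETS["velocity"][cond][group],
            )
    return out
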