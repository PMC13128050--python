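"""Synthetic gait trials and cohorts with known ground truth.

The generator emulates the structure of an overground level/ramp walking
study: per-trial landmark trajectories (heel, toe, pelvis; anterior-
posterior and vertical) and sagittal joint-angle series at a fixed
sampling rate, for two age groups walking three conditions (level, 7-degree
ramp ascent, ramp descent) with several trials per condition.

Trajectory synthesis uses a single-support/double-support timing model:
each foot alternates stance (stationary on the walkway) and swing (linear
advance to the next step position with a sinusoidal clearance bump), with
stance occupying a configurable fraction of the stride (default 0.60, a
typical human value).  The construction guarantees that, noise-free, the
coordinate-based event detector recovers every ground-truth event exactly:
the heel is maximally anterior to the pelvis precisely at initial contact
and the toe maximally posterior precisely at toe-off.  Joint angles are
sampled from :class:`~rampgait.templates.WaveformTemplate` curves, so the
ground-truth representative values are known by construction.

Stride timing is quantized to whole frames (the requested cadence is
realized as the nearest even frame count per stride), which keeps
ground-truth events on exact frame indices; the realized cadence, velocity
and step length are reported in the ground truth.

Cohort structure mirrors a repeated-measures design: per-participant
feature offsets (the random intercept, ``participant_sd``), a
participant-by-condition residual (``feature_noise_sd``), and frame-level
measurement noise (``noise_sd`` on angles, with a proportional positional
jitter on landmarks).  All draws come from one seeded generator in a
documented order, so identical specs give bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .events import EventSeries, GaitEvent
from .features import FEATURE_NAMES, JOINTS
from .tables import GroupTargets, default_group_targets
from .templates import WaveformTemplate, template_set
from .trial import TrialRecording, angle_column, landmark_column

#: meters of landmark jitter per degree of angle noise (about 0.9 m of limb
#: length subtending the angular error)
NOISE_M_PER_DEG = 0.016


@dataclass(frozen=True)
class RampGeometry:
    """Walkway geometry: 7-degree ramp, 3.25 m long; 7 m level path."""

    incline_deg: float = 7.0
    ramp_length_m: float = 3.25
    level_length_m: float = 7.0
    #: extra usable distance beyond the nominal path (start/stop points and
    #: ramp landing lie outside the measured walkway)
    landing_margin_m: float = 1.0

    def __post_init__(self) -> None:
        if self.incline_deg < 0:
            raise ValueError("incline_deg must be >= 0")
        if self.ramp_length_m <= 0 or self.level_length_m <= 0:
            raise ValueError("walkway lengths must be positive")

    def usable_length(self, condition: str) -> float:
        base = self.level_length_m if condition == "level" else self.ramp_length_m
        return base + self.landing_margin_m


@dataclass(frozen=True)
class TrialGroundTruth:
    """Exact per-trial truth: events, realized spatiotemporal values."""

    events: EventSeries
    cadence: float
    velocity: float
    step_length: float
    stride_frames: int
    n_steps: int
    foot_strike: str = "heel_strike"


def simulate_trial(
    templates: Mapping[str, WaveformTemplate],
    cadence: float,
    step_length: float,
    *,
    condition: str = "level",
    n_steps: Optional[int] = None,
    geometry: Optional[RampGeometry] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    fs: float = 60.0,
    participant: str = "SYN",
    group: str = "young",
    trial_index: int = 1,
    foot_length_m: float = 0.25,
    swing_clearance_m: float = 0.05,
    toe_ic_clearance_m: float = 0.02,
    pelvis_height_m: float = 0.92,
) -> Tuple[TrialRecording, TrialGroundTruth]:
    """Synthesize one walking trial plus its exact ground truth.

    Parameters
    ----------
    templates:
        Hip/knee/ankle waveform templates (shared by both limbs); their
        ``stance_fraction`` sets the stance/swing split.
    cadence:
        Requested steps per minute (> 0); realized as the nearest
        whole-frame step duration.
    step_length:
        Distance between successive contralateral foot placements, along
        the walkway surface (m).
    condition:
        ``level``, ``ascent`` or ``descent``; ramps advance the pelvis
        along the incline, with the vertical coordinate following the
        slope.
    n_steps:
        Total steps over both feet; defaults to what the walkway holds.
        Level trials need >= 8 steps and ramp trials >= 4 so the trimming
        rule leaves something.
    noise_sd:
        Frame-level angle noise SD in degrees; landmark coordinates jitter
        proportionally (:data:`NOISE_M_PER_DEG`).
    rng:
        Seeded generator; required when ``noise_sd > 0``.
    """
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    if step_length <= 0:
        raise ValueError("step_length must be positive")
    if set(templates) != set(JOINTS):
        raise ValueError(f"templates must cover joints {JOINTS}")
    geometry = geometry or RampGeometry()
    if noise_sd > 0 and rng is None:
        raise ValueError("rng is required when noise_sd > 0")

    sf = templates["knee"].stance_fraction
    step_frames = max(2, round(fs * 60.0 / cadence))
    stride = 2 * step_frames
    stance = round(sf * stride)
    swing = stride - stance
    cadence_real = 60.0 * fs / step_frames
    v_frame = step_length / step_frames  # pelvis advance per frame (m)

    length = geometry.usable_length(condition)
    max_steps = int(np.floor(length / step_length))
    if n_steps is None:
        n_steps = max_steps
    elif n_steps > max_steps:
        warnings.warn(
            f"{n_steps} steps of {step_length:.2f} m exceed the {length:.2f} m walkway; "
            f"truncating to {max_steps}",
            stacklevel=2,
        )
        n_steps = max_steps
    min_steps = 8 if condition == "level" else 4
    if n_steps < min_steps:
        raise ValueError(
            f"{condition} trial needs >= {min_steps} steps for the trimming rule, got {n_steps}"
        )

    pad = round(0.5 * fs)  # standing still at the start
    roll = round(0.5 * fs)  # pelvis pre-roll before the first toe-off
    off = max(pad + roll + swing - step_frames, 0)
    ic_frames = {k: off + k * step_frames for k in range(1, n_steps + 1)}
    first_to = ic_frames[1] - swing
    walk0 = first_to - roll  # pelvis starts accelerating
    last_ic = ic_frames[n_steps]
    decel = 2 * roll  # pelvis decelerates to a stop over ~1 s
    n_frames = last_ic + decel + round(0.2 * fs) + 1
    t = np.arange(n_frames) / fs

    # --- pelvis along-path position -------------------------------------
    # velocity profile: linear ramp-up from standing to steady speed at the
    # first IC, constant through the last IC, linear ramp-down to a stop
    frames = np.arange(n_frames)
    w = np.zeros(n_frames)
    accel_span = ic_frames[1] - walk0
    w[walk0 : ic_frames[1] + 1] = (np.arange(accel_span + 1)) / accel_span
    w[ic_frames[1] : last_ic + 1] = 1.0
    w[last_ic : last_ic + decel + 1] = 1.0 - np.arange(decel + 1) / decel
    pelvis_s = v_frame * np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    # anchor: pelvis passes midway between the feet at the first IC
    pelvis_s += step_length / 2 - pelvis_s[ic_frames[1]]

    # --- per-side foot trajectories ------------------------------------
    side_steps = {"right": list(range(1, n_steps + 1, 2)), "left": list(range(2, n_steps + 1, 2))}
    events: List[GaitEvent] = []
    heel_s: Dict[str, np.ndarray] = {}
    heel_h: Dict[str, np.ndarray] = {}
    toe_h: Dict[str, np.ndarray] = {}
    for side, ks in side_steps.items():
        knots_f = [0.0]
        knots_s = [0.0]
        prev_pos = 0.0
        h = np.zeros(n_frames)
        th = np.zeros(n_frames)
        for k in ks:
            ic_f, to_f = ic_frames[k], ic_frames[k] - swing
            pos = k * step_length
            knots_f += [float(to_f), float(ic_f)]
            knots_s += [prev_pos, pos]
            tau = (np.arange(to_f, ic_f + 1) - to_f) / swing
            h[to_f : ic_f + 1] = swing_clearance_m * np.sin(np.pi * tau)
            th[to_f : ic_f + 1] = 0.6 * swing_clearance_m * np.sin(np.pi * tau) + toe_ic_clearance_m * tau
            settle = min(stance, round(0.15 * stride))
            tau_d = np.clip((np.arange(ic_f, min(ic_f + settle, n_frames)) - ic_f) / settle, 0, 1)
            th[ic_f : min(ic_f + settle, n_frames)] = toe_ic_clearance_m * (1.0 - tau_d)
            prev_pos = pos
            events.append(GaitEvent(side, "TO", int(to_f), to_f / fs))
            events.append(GaitEvent(side, "IC", int(ic_f), ic_f / fs))
        knots_f.append(float(n_frames - 1))
        knots_s.append(prev_pos)
        heel_s[side] = np.interp(frames, knots_f, knots_s)
        heel_h[side] = h
        toe_h[side] = th

    # --- world coordinates ----------------------------------------------
    alpha = np.deg2rad(geometry.incline_deg) if condition != "level" else 0.0
    uz = np.sin(alpha) if condition == "ascent" else (-np.sin(alpha) if condition == "descent" else 0.0)
    u = np.array([np.cos(alpha) if alpha else 1.0, uz])  # along-path unit vector
    nrm = np.array([-u[1], u[0]])  # walkway normal, upward
    z0 = -uz * (n_steps + 1) * step_length if condition == "descent" else 0.0

    def world(s: np.ndarray, h: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return s * u[0] + h * nrm[0], s * u[1] + h * nrm[1] + z0

    data: Dict[str, np.ndarray] = {"time_s": t}
    jitter = noise_sd * NOISE_M_PER_DEG

    # --- joint angles (documented draw order: angles by side then joint,
    # then landmark jitter by side then landmark) ------------------------
    for side, ks in side_steps.items():
        first_ic_side, last_ic_side = ic_frames[ks[0]], ic_frames[ks[-1]]
        first_to_side = first_ic_side - swing
        phase = ((frames - first_ic_side) / stride) % 1.0
        phase[(frames < first_to_side) | (frames > last_ic_side)] = 0.0
        for joint in JOINTS:
            ang = templates[joint](phase)
            if noise_sd > 0:
                ang = ang + rng.normal(0.0, noise_sd, n_frames)
            data[angle_column(side, joint)] = ang
    for side in side_steps:
        for name, (s_arr, h_arr) in {
            "heel": (heel_s[side], heel_h[side]),
            "toe": (heel_s[side] + foot_length_m, toe_h[side]),
            "pelvis": (pelvis_s, np.full(n_frames, pelvis_height_m)),
        }.items():
            x, z = world(s_arr, h_arr)
            if noise_sd > 0:
                x = x + rng.normal(0.0, jitter, n_frames)
                z = z + rng.normal(0.0, jitter, n_frames)
            data[landmark_column(side, name, "ap")] = x
            data[landmark_column(side, name, "vert")] = z

    recording = TrialRecording(
        participant=participant,
        group=group,
        condition=condition,
        trial_index=trial_index,
        fs=fs,
        incline_deg=geometry.incline_deg if condition != "level" else 0.0,
        frames=pd.DataFrame(data),
    )
    truth = TrialGroundTruth(
        events=EventSeries(events=tuple(events), fs=fs),
        cadence=cadence_real,
        velocity=step_length * fs / step_frames,
        step_length=step_length,
        stride_frames=stride,
        n_steps=n_steps,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: features that receive per-participant / per-condition perturbations
#: (RoM is derived from the extrema, so it is never perturbed directly)
PERTURBED_FEATURES = tuple(n for n in FEATURE_NAMES if not n.endswith("_RoM"))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group cohort.

    Defaults reproduce the study conditions: 20 young and 20 older
    participants, three walking conditions, five trials each, group targets
    from the published tables, a 3-degree participant random intercept, a
    2-degree participant-by-condition residual, and 1 degree of frame-level
    measurement noise.
    """

    n_young: int = 20
    n_old: int = 20
    conditions: Tuple[str, ...] = ("level", "ascent", "descent")
    trials_per_condition: int = 5
    group_targets: Optional[Mapping[Tuple[str, str], GroupTargets]] = None
    participant_sd: float = 3.0
    feature_noise_sd: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    geometry: RampGeometry = field(default_factory=RampGeometry)
    stance_fraction: float = 0.6
    fs: float = 60.0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("need at least one participant per group")
        if min(self.participant_sd, self.feature_noise_sd, self.noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        unknown = set(self.conditions) - {"level", "ascent", "descent"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    def resolved_targets(self) -> Mapping[Tuple[str, str], GroupTargets]:
        return self.group_targets if self.group_targets is not None else default_group_targets()


@dataclass(frozen=True)
class CohortGroundTruth:
    """Cohort-level truth: per-trial events plus per-cell parameter targets."""

    trials: Mapping[str, TrialGroundTruth]
    targets: pd.DataFrame  # participant, group, condition, parameter, value
    effect_config: pd.DataFrame  # condition, parameter, young_target, old_target


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    trials: Tuple[TrialRecording, ...]
    ground_truth: CohortGroundTruth


def _sanitize_targets(feats: Dict[str, float]) -> Dict[str, float]:
    """Clamp a perturbed target draw to the nearest feasible waveform.

    Rarely needed (a fraction of a percent of draws at the default noise
    levels); keeps extreme tails from requesting geometrically impossible
    waveforms (e.g. plantarflexion peak above the initial-contact angle).
    """
    f = dict(feats)
    # hip: stance minimum must sit clearly below both flexion peaks
    lo = min(f["hip_MaxFlex_Stance"], f["hip_MaxFlex_Swing"]) - 3.0
    f["hip_MaxExt_Stance"] = min(f["hip_MaxExt_Stance"], lo)
    # knee: early-stance peak above stance minimum; swing peak above IC angle
    f["knee_MaxFlex_ST1"] = max(f["knee_MaxFlex_ST1"], f["knee_MaxExt_Stance"] + 1.0)
    ic = f["knee_MaxExt_Stance"] + 0.35 * (f["knee_MaxFlex_ST1"] - f["knee_MaxExt_Stance"])
    f["knee_MaxFlex_Swing"] = max(f["knee_MaxFlex_Swing"], ic + 1.0)
    # ankle: push-off minimum must undercut IC and dorsiflexion peak
    f["ankle_MaxPlantarflexion_STSW"] = max(
        f["ankle_MaxPlantarflexion_STSW"],
        1.0,
        -min(f["ankle_InitialContact"], f["ankle_MaxDorsiflexion_ST2"]) + 1.0,
    )
    dip = max(min(f["ankle_InitialContact"], 0.0) - 4.0, -f["ankle_MaxPlantarflexion_STSW"] + 1.0)
    f["ankle_MaxDorsiflexion_ST2"] = max(f["ankle_MaxDorsiflexion_ST2"], dip + 1.0)
    return f


def _standardize(z: np.ndarray) -> np.ndarray:
    """Rescale draws to exact sample moments (mean 0, SD 1 per column).

    Published group means and SDs are the *sample* statistics of the
    studied participants, so a cohort calibrated to them should realize
    those moments exactly rather than only in expectation.  Degenerate
    sizes (n < 2) and zero-variance columns return zeros.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape[0] < 2:
        return np.zeros_like(z)
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    out = (z - mean) / sd
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full two-group cohort with ground truth.

    Draw order (one seeded generator, deterministic): per group (young
    first) -- the velocity and cadence propensity vectors, then the
    participant feature-offset matrix; per condition in spec order -- the
    velocity/cadence condition jitter and the condition feature residuals;
    then frame noise trial by trial in participant order.

    Per-participant feature targets are group target + participant offset +
    condition residual; per-participant velocity/cadence combine a
    participant propensity with condition jitter (weights 0.8/0.6) for
    within-participant correlation across conditions.  Every group cell's
    draws are standardized to exact sample moments -- the published group
    values are the sample statistics of the studied cohort, so the
    generated cohort reproduces them by construction.  Step length is
    implied (60 v / cadence).
    """
    rng = np.random.default_rng(spec.seed)
    targets = spec.resolved_targets()
    trials: List[TrialRecording] = []
    truth_trials: Dict[str, TrialGroundTruth] = {}
    target_rows: List[dict] = []

    groups = [("young", spec.n_young), ("old", spec.n_old)]
    nf = len(PERTURBED_FEATURES)
    for group, n in groups:
        pids = [f"{'Y' if group == 'young' else 'O'}{i:02d}" for i in range(1, n + 1)]
        # participant-level propensities and feature offsets, then
        # per-condition draws; each group cell is standardized to its exact
        # sample moments because the published group values are the sample
        # statistics of the studied cohort (see module docstring)
        u_vel = rng.normal(size=n)
        u_cad = rng.normal(size=n)
        b = spec.participant_sd * _standardize(rng.normal(size=(n, nf)))
        for cond in spec.conditions:
            cell = targets[(group, cond)]
            w_vel = rng.normal(size=n)
            w_cad = rng.normal(size=n)
            eps = spec.feature_noise_sd * _standardize(rng.normal(size=(n, nf)))
            z_vel = _standardize(0.8 * u_vel + 0.6 * w_vel)
            z_cad = _standardize(0.8 * u_cad + 0.6 * w_cad)
            vels = np.maximum(cell.velocity[0] + cell.velocity[1] * z_vel, 0.3)
            cads = np.maximum(cell.cadence[0] + cell.cadence[1] * z_cad, 40.0)
            for i, pid in enumerate(pids):
                vel, cad = float(vels[i]), float(cads[i])
                # quantize cadence to the whole-frame step duration the
                # simulator will realize, then derive step length from it so
                # the drawn velocity is reproduced exactly
                cad = 60.0 * spec.fs / round(spec.fs * 60.0 / cad)
                # cap extreme-tail step lengths so every trial holds enough
                # steps for the condition's trimming rule (>= 1 cycle)
                floor_steps = 8 if cond == "level" else 5
                step_len = min(
                    60.0 * vel / cad, 0.95, spec.geometry.usable_length(cond) / floor_steps
                )
                feats = {
                    name: cell.features[name] + b[i, k] + eps[i, k]
                    for k, name in enumerate(PERTURBED_FEATURES)
                }
                feats = _sanitize_targets(feats)
                tpls = template_set(feats, spec.stance_fraction, strict=False)
                for name, value in feats.items():
                    target_rows.append(
                        dict(participant=pid, group=group, condition=cond,
                             parameter=name, value=value)
                    )
                for par, value in (("cadence", cad), ("velocity", vel), ("step_length", step_len)):
                    target_rows.append(
                        dict(participant=pid, group=group, condition=cond,
                             parameter=par, value=value)
                    )
                for j in range(1, spec.trials_per_condition + 1):
                    rec, tr_truth = simulate_trial(
                        tpls,
                        cadence=cad,
                        step_length=step_len,
                        condition=cond,
                        geometry=spec.geometry,
                        noise_sd=spec.noise_sd,
                        rng=rng,
                        participant=pid,
                        group=group,
                        trial_index=j,
                        fs=spec.fs,
                    )
                    trials.append(rec)
                    truth_trials[rec.trial_id] = tr_truth

    effect_rows = []
    for cond in spec.conditions:
        young, old = targets[("young", cond)], targets[("old", cond)]
        for name in PERTURBED_FEATURES:
            effect_rows.append(
                dict(condition=cond, parameter=name,
                     young_target=young.features[name], old_target=old.features[name])
            )
        for par in ("cadence", "velocity"):
            effect_rows.append(
                dict(condition=cond, parameter=par,
                     young_target=getattr(young, par)[0], old_target=getattr(old, par)[0])
            )
    ground_truth = CohortGroundTruth(
        trials=truth_trials,
        targets=pd.DataFrame(target_rows),
        effect_config=pd.DataFrame(effect_rows),
    )
    return Cohort(spec=spec, trials=tuple(trials), ground_truth=ground_truth)
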