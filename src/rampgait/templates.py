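"""Periodic joint-angle waveform templates with exactly placeable extrema.

A template is a periodic monotone-cubic (PCHIP) curve through keypoints
``(cycle_phase, angle_deg)``.  Monotone interpolation never overshoots
between keypoints, so every local extremum of the curve *is* a keypoint --
which makes it possible to build a waveform whose extracted representative
values (peak flexion in early stance, peak plantarflexion at push-off, ...)
equal requested targets exactly.  The synthetic cohort generator uses these
templates as the ground-truth joint-angle trajectories.

Sign convention matches :mod:`rampgait.features`: flexion / dorsiflexion
positive.  Targets are given in the reported convention, i.e.
``MaxExt_Stance`` is the signed minimum flexion angle and
``MaxPlantarflexion_STSW`` is a positive magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Dict, Mapping, Tuple, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .features import FEATURES_BY_JOINT, JOINTS, N_SAMPLES, extract_features, partition_phases

TargetValue = Union[float, Tuple[float, float]]  # angle or (angle, phase)


class InfeasibleTemplateError(ValueError):
    """The requested target set cannot be realized by a single waveform."""


@dataclass(frozen=True)
class WaveformTemplate:
    """Periodic PCHIP waveform through ``keypoints`` for one joint.

    Attributes
    ----------
    joint:
        ``"hip"``, ``"knee"`` or ``"ankle"``.
    keypoints:
        Tuple of ``(phase, angle_deg)`` with phases strictly increasing in
        ``[0, 1)``.  The curve is 1-periodic; evaluating at a keypoint phase
        returns the keypoint angle exactly.
    stance_fraction:
        Fraction of the cycle spent in stance (toe-off phase).
    relaxed:
        Names of requested targets that could not be honoured and were
        dropped by :func:`build_template` in lenient mode (``RoM`` only).
    """

    joint: str
    keypoints: Tuple[Tuple[float, float], ...]
    stance_fraction: float = 0.6
    relaxed: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        phases = np.array([p for p, _ in self.keypoints], dtype=float)
        if len(phases) < 2:
            raise ValueError("need at least 2 keypoints")
        if not (np.all(phases >= 0.0) and np.all(phases < 1.0)):
            raise ValueError("keypoint phases must lie in [0, 1)")
        if not np.all(np.diff(phases) > 0):
            raise ValueError("keypoint phases must be strictly increasing")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")

    @cached_property
    def _spline(self) -> PchipInterpolator:
        p = np.array([k[0] for k in self.keypoints], dtype=float)
        v = np.array([k[1] for k in self.keypoints], dtype=float)
        # periodic extension: one full copy on each side keeps the wrap C1
        xs = np.concatenate([p - 1.0, p, p + 1.0])
        ys = np.concatenate([v, v, v])
        return PchipInterpolator(xs, ys, extrapolate=False)

    def __call__(self, phase) -> np.ndarray:
        """Evaluate the template at ``phase`` (any real; 1-periodic)."""
        return np.asarray(self._spline(np.mod(np.asarray(phase, dtype=float), 1.0)))

    def sample(self, n: int = N_SAMPLES) -> np.ndarray:
        """Sample ``n`` points on the uniform phase grid 0 .. (n-1)/(n-1)·1.

        With the default ``n=101`` this is the canonical 0..100 % cycle grid
        (sample ``n-1`` wraps to phase 0).
        """
        return self(np.linspace(0.0, 1.0, n))


def _snap(phase: float) -> float:
    """Snap a phase to the 101-point grid so sampled extrema are exact."""
    return round(phase * 100.0) / 100.0


def _resolve(
    targets: Mapping[str, TargetValue], name: str, default_value: float, default_phase: float
) -> Tuple[float, float, bool]:
    """Return (value, phase, was_requested) for one named feature target."""
    if name in targets:
        t = targets[name]
        if isinstance(t, tuple):
            value, phase = float(t[0]), float(t[1])
        else:
            value, phase = float(t), default_phase
        return value, _snap(phase), True
    return float(default_value), _snap(default_phase), False


# Generic fallback values for unrequested features (typical adult gait).
_DEFAULTS = {
    "hip": {"MaxFlex_Stance": 25.0, "MaxFlex_Swing": 28.0, "MaxExt_Stance": -12.0},
    "knee": {"MaxFlex_ST1": 15.0, "MaxFlex_Swing": 65.0, "MaxExt_Stance": 2.0},
    "ankle": {"MaxDorsiflexion_ST2": 14.0, "MaxPlantarflexion_STSW": 17.0, "InitialContact": -2.0},
}


def build_template(
    joint: str,
    targets: Mapping[str, TargetValue],
    stance_fraction: float = 0.6,
    *,
    strict: bool = True,
    verify_tol: float = 0.1,
) -> WaveformTemplate:
    """Build a waveform template realizing named representative-value targets.

    Parameters
    ----------
    joint:
        ``"hip"``, ``"knee"`` or ``"ankle"``.
    targets:
        Mapping from feature short names (as in
        :data:`rampgait.features.FEATURES_BY_JOINT`, e.g. ``"MaxFlex_ST1"``)
        to either an angle in degrees or an ``(angle, phase)`` tuple placing
        the extremum at an explicit cycle phase.  Values use the reported
        convention (``MaxExt_Stance`` signed, plantarflexion a positive
        magnitude).  Unrequested features fall back to typical values.
    stance_fraction:
        Toe-off location as a fraction of the cycle (default 0.6).
    strict:
        If True, any target that cannot be met within ``verify_tol`` raises
        :class:`InfeasibleTemplateError`.  If False, an inconsistent ``RoM``
        request (one that contradicts the named extrema) is dropped and
        recorded in ``template.relaxed``; all other targets stay strict.
    verify_tol:
        Round-trip tolerance in degrees for the built-in self-check, which
        samples a noiseless 101-point cycle and re-extracts every requested
        feature.

    Raises
    ------
    InfeasibleTemplateError
        For mutually inconsistent targets (e.g. a stance maximum below the
        stance minimum, or an extremum phase outside its defining window).
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    valid = set(FEATURES_BY_JOINT[joint])
    unknown = set(targets) - valid
    if unknown:
        raise ValueError(f"unknown targets for {joint}: {sorted(unknown)}; valid: {sorted(valid)}")
    sf = float(stance_fraction)
    if not (0.05 < sf < 0.95):
        raise InfeasibleTemplateError(f"stance_fraction {sf} out of plausible range")
    d = _DEFAULTS[joint]

    if joint == "hip":
        kps, requested = _hip_keypoints(targets, d, sf)
    elif joint == "knee":
        kps, requested = _knee_keypoints(targets, d, sf)
    else:
        kps, requested = _ankle_keypoints(targets, d, sf)

    relaxed: Tuple[str, ...] = ()
    if "RoM" in targets:
        rom_req = float(targets["RoM"]) if not isinstance(targets["RoM"], tuple) else float(targets["RoM"][0])
        vals = [v for _, v in kps]
        rom_implied = max(vals) - min(vals)
        if abs(rom_implied - rom_req) > verify_tol:
            msg = (
                f"{joint}: requested RoM {rom_req:.2f} contradicts the named extrema "
                f"(implied RoM {rom_implied:.2f})"
            )
            if strict:
                raise InfeasibleTemplateError(msg)
            relaxed = ("RoM",)
        else:
            requested["RoM"] = rom_req

    tpl = WaveformTemplate(joint=joint, keypoints=tuple(kps), stance_fraction=sf, relaxed=relaxed)

    # self-check: a noiseless cycle must reproduce every honoured target
    cycle = tpl.sample(N_SAMPLES)
    waveforms = {j: cycle if j == joint else np.zeros(N_SAMPLES) for j in JOINTS}
    feats = extract_features(waveforms, partition_phases(100.0 * sf))
    errs = {}
    for name, value in requested.items():
        got = feats[f"{joint}_{name}"]
        if abs(got - value) > verify_tol:
            errs[name] = (value, got)
    if errs:
        detail = ", ".join(f"{k}: requested {v[0]:.2f} got {v[1]:.2f}" for k, v in errs.items())
        raise InfeasibleTemplateError(f"{joint} template self-check failed ({detail})")
    return tpl


def _hip_keypoints(targets, d, sf):
    """Hip: flexed at contact, extends through stance, re-flexes in swing."""
    flex_st, p_fst, r1 = _resolve(targets, "MaxFlex_Stance", d["MaxFlex_Stance"], 0.067 * sf)
    ext_st, p_ext, r2 = _resolve(targets, "MaxExt_Stance", d["MaxExt_Stance"], 0.867 * sf)
    flex_sw, p_fsw, r3 = _resolve(targets, "MaxFlex_Swing", d["MaxFlex_Swing"], sf + 0.625 * (1 - sf))
    if not (0.0 < p_fst < sf) or not (0.0 < p_ext < sf):
        raise InfeasibleTemplateError("hip stance extrema must lie at phases in (0, stance_fraction)")
    if not (sf <= p_fsw < 1.0):
        raise InfeasibleTemplateError("hip swing maximum must lie at a phase in [stance_fraction, 1)")
    if not p_fst < p_ext < p_fsw:
        raise InfeasibleTemplateError("hip extrema phases must be ordered flex_stance < ext < flex_swing")
    base0 = min(flex_st, flex_sw) - 1.5
    if base0 <= ext_st:
        raise InfeasibleTemplateError(
            f"hip flexion targets ({flex_st:.1f}, {flex_sw:.1f}) too close to stance minimum {ext_st:.1f}"
        )
    kps = [(0.0, base0), (p_fst, flex_st), (p_ext, ext_st), (p_fsw, flex_sw)]
    req = {}
    if r1:
        req["MaxFlex_Stance"] = flex_st
    if r2:
        req["MaxExt_Stance"] = ext_st
    if r3:
        req["MaxFlex_Swing"] = flex_sw
    return kps, req


def _knee_keypoints(targets, d, sf):
    """Knee: loading-response flexion bump, stance extension, large swing peak."""
    st1, p_st1, r1 = _resolve(targets, "MaxFlex_ST1", d["MaxFlex_ST1"], 0.25 * sf)
    ext, p_ext, r2 = _resolve(targets, "MaxExt_Stance", d["MaxExt_Stance"], 0.667 * sf)
    sw, p_sw, r3 = _resolve(targets, "MaxFlex_Swing", d["MaxFlex_Swing"], sf + 0.325 * (1 - sf))
    mid = sf / 2.0
    if not (0.0 < p_st1 < mid):
        raise InfeasibleTemplateError(
            f"knee MaxFlex_ST1 phase {p_st1} must lie in (0, mid-stance={mid})"
        )
    if not (p_st1 < p_ext < sf):
        raise InfeasibleTemplateError("knee stance minimum must lie between the ST1 peak and toe-off")
    if not (sf <= p_sw < 1.0):
        raise InfeasibleTemplateError("knee swing maximum must lie at a phase in [stance_fraction, 1)")
    if st1 <= ext:
        raise InfeasibleTemplateError(f"knee MaxFlex_ST1 {st1:.1f} must exceed MaxExt_Stance {ext:.1f}")
    ic = ext + 0.35 * (st1 - ext)
    if sw <= ic:
        raise InfeasibleTemplateError(f"knee MaxFlex_Swing {sw:.1f} too small (initial-contact angle {ic:.1f})")
    kps = [(0.0, ic), (p_st1, st1), (p_ext, ext), (p_sw, sw)]
    req = {}
    if r1:
        req["MaxFlex_ST1"] = st1
    if r2:
        req["MaxExt_Stance"] = ext
    if r3:
        req["MaxFlex_Swing"] = sw
    return kps, req


def _ankle_keypoints(targets, d, sf):
    """Ankle: early plantar dip, dorsiflexion through ST2, push-off plantarflexion."""
    ic, _, r1 = _resolve(targets, "InitialContact", d["InitialContact"], 0.0)
    dorsi, p_do, r2 = _resolve(
        targets, "MaxDorsiflexion_ST2", d["MaxDorsiflexion_ST2"], 0.75 * sf
    )
    pf_mag, p_pf, r3 = _resolve(
        targets, "MaxPlantarflexion_STSW", d["MaxPlantarflexion_STSW"], sf + 0.125 * (1 - sf)
    )
    pf = -pf_mag  # signed angle of the push-off minimum
    mid = sf / 2.0
    if not (mid <= p_do < sf):
        raise InfeasibleTemplateError(
            f"ankle dorsiflexion peak phase {p_do} must lie in ST2 [{mid}, {sf})"
        )
    if abs(p_pf - sf) > 0.10:
        raise InfeasibleTemplateError(
            f"ankle plantarflexion peak phase {p_pf} must lie within 10% cycle of toe-off {sf}"
        )
    if pf >= min(ic, dorsi):
        raise InfeasibleTemplateError(
            f"ankle plantarflexion minimum {pf:.1f} must undercut IC ({ic:.1f}) and dorsiflexion ({dorsi:.1f})"
        )
    p_dip = _snap(0.117 * sf)
    dip = max(min(ic, 0.0) - 4.0, pf + 1.0)
    if dip >= dorsi:
        raise InfeasibleTemplateError("ankle early-stance dip would exceed the dorsiflexion peak")
    p_swd = _snap(sf + 0.7 * (1 - sf))
    swing_dorsi = max(min(ic + 2.0, dorsi - 2.0), pf + 1.0)
    kps = [(0.0, ic), (p_dip, dip), (p_do, dorsi), (p_pf, pf), (p_swd, swing_dorsi)]
    req = {}
    if r1:
        req["InitialContact"] = ic
    if r2:
        req["MaxDorsiflexion_ST2"] = dorsi
    if r3:
        req["MaxPlantarflexion_STSW"] = pf_mag
    return kps, req


def template_set(
    angle_targets: Mapping[str, TargetValue],
    stance_fraction: float = 0.6,
    *,
    strict: bool = False,
) -> Dict[str, WaveformTemplate]:
    """Build hip/knee/ankle templates from flat ``joint_Feature`` keyed targets.

    ``angle_targets`` uses the canonical flat names
    (``"knee_MaxFlex_ST1"``, ...); features absent for a joint fall back to
    defaults.  Lenient by default because published per-condition values are
    velocity-adjusted model means whose RoM need not equal max - min.
    """
    out = {}
    for joint in JOINTS:
        prefix = joint + "_"
        per_joint = {k[len(prefix):]: v for k, v in angle_targets.items() if k.startswith(prefix)}
        out[joint] = build_template(joint, per_joint, stance_fraction, strict=strict)
    return out
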