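"""Independent brute-force oracles used by the equivalence tests.

Everything here is written as plainly as possible (explicit loops, no
shared code with the package) so it can serve as an independent check of
the vectorized implementations.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# peak picking (same acceptance rules as the event detector)
# ---------------------------------------------------------------------------

def brute_force_peaks(
    x: Sequence[float], min_prominence: float, min_distance: int
) -> List[int]:
    """Local maxima filtered by distance (greedy by height) then prominence.

    Assumes no exact ties between neighbouring samples (continuous data).
    """
    x = list(map(float, x))
    n = len(x)
    candidates = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]

    # distance rule: keep highest peaks first, drop any within min_distance
    kept: List[int] = []
    for i in sorted(candidates, key=lambda i: x[i], reverse=True):
        if all(abs(i - j) >= min_distance for j in kept):
            kept.append(i)

    out = []
    for i in kept:
        # walk left until a strictly higher sample; the left base is the
        # minimum en route (same for the right); prominence is the height
        # above the higher of the two bases
        lo = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            lo = min(lo, x[j])
            j -= 1
        left_base = lo
        hi = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            hi = min(hi, x[j])
            j += 1
        right_base = hi
        prominence = x[i] - max(left_base, right_base)
        if prominence >= min_prominence:
            out.append(i)
    return sorted(out)


# ---------------------------------------------------------------------------
# representative-value extraction
# ---------------------------------------------------------------------------

def brute_force_features(
    hip: Sequence[float],
    knee: Sequence[float],
    ankle: Sequence[float],
    to_percent: float,
    mid_stance: float | None = None,
    pf_halfwidth: float = 10.0,
) -> Dict[str, float]:
    """Index-by-index scan of the 12 representative values."""
    if mid_stance is None:
        mid_stance = to_percent / 2.0

    def _inside(i, lo, hi, lo_incl, hi_incl):
        above = i > lo or (lo_incl and i >= lo)
        below = i < hi or (hi_incl and i <= hi)
        return above and below

    def scan(w, lo, hi, lo_incl, hi_incl, mode):
        best = None
        for i in range(101):
            if not _inside(i, lo, hi, lo_incl, hi_incl):
                continue
            v = float(w[i])
            if best is None or (v > best if mode == "max" else v < best):
                best = v
        return best

    out = {}
    for joint, w in (("hip", hip), ("knee", knee), ("ankle", ankle)):
        out[f"{joint}_RoM"] = scan(w, 0, 100, True, True, "max") - scan(w, 0, 100, True, True, "min")
    out["hip_MaxFlex_Stance"] = scan(hip, 0, to_percent, True, False, "max")
    out["hip_MaxFlex_Swing"] = scan(hip, to_percent, 100, True, True, "max")
    out["hip_MaxExt_Stance"] = scan(hip, 0, to_percent, True, False, "min")
    out["knee_MaxFlex_ST1"] = scan(knee, 0, mid_stance, True, False, "max")
    out["knee_MaxFlex_Swing"] = scan(knee, to_percent, 100, True, True, "max")
    out["knee_MaxExt_Stance"] = scan(knee, 0, to_percent, True, False, "min")
    out["ankle_MaxDorsiflexion_ST2"] = scan(ankle, mid_stance, to_percent, True, False, "max")
    out["ankle_MaxPlantarflexion_STSW"] = -scan(
        ankle, to_percent - pf_halfwidth, to_percent + pf_halfwidth, True, True, "min"
    )
    out["ankle_InitialContact"] = float(ankle[0])
    return out


# ---------------------------------------------------------------------------
# hierarchical averaging
# ---------------------------------------------------------------------------

def brute_force_hierarchical_mean(
    cycles: Dict[str, Dict[str, List[np.ndarray]]]
) -> np.ndarray:
    """Recompute trial->side->cycles averaging with explicit loops.

    ``cycles[trial][side]`` is a list of 101-sample arrays; sides without
    cycles are skipped (single-side fallback).
    """
    trial_waves = []
    for trial in cycles.values():
        side_waves = []
        for side_cycles in trial.values():
            if not side_cycles:
                continue
            acc = np.zeros(101)
            for c in side_cycles:
                acc = acc + np.asarray(c, float)
            side_waves.append(acc / len(side_cycles))
        if not side_waves:
            continue
        acc = np.zeros(101)
        for w in side_waves:
            acc = acc + w
        trial_waves.append(acc / len(side_waves))
    acc = np.zeros(101)
    for w in trial_waves:
        acc = acc + w
    return acc / len(trial_waves)


# ---------------------------------------------------------------------------
# effect size and multiplicity
# ---------------------------------------------------------------------------

def brute_force_cohens_d(m1, s1, n1, m2, s2, n2) -> float:
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
    return (m1 - m2) / (sp2 ** 0.5)


def brute_force_bh(p: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
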