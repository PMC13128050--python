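"""Detect gait events coordinate-wise and compare them with ground truth.

The detector projects heel, toe and pelvis onto the walking direction
(estimated from the pelvis trajectory) and picks the heel-anterior /
toe-posterior extrema.  On a noise-free trial it recovers every embedded
event exactly; here we add 1 degree of frame noise and show the residual
timing error.
"""

import numpy as np

from rampgait import (detect_events, simulate_trial, smooth_recording,
                      template_set, trim_cycles)
from rampgait.tables import default_group_targets

rng = np.random.default_rng(42)
targets = default_group_targets()[("old", "ascent")]
templates = template_set(dict(targets.features))

recording, truth = simulate_trial(
    templates, cadence=targets.cadence[0], step_length=0.64,
    condition="ascent", noise_sd=1.0, rng=rng,
)

smoothed = smooth_recording(recording)  # adaptive GCV smoothing
detected = detect_events(smoothed)

true_frames = {}
for e in truth.events:
    true_frames.setdefault((e.side, e.kind), []).append(e.frame)
errors = [
    min(abs(e.frame - f) for f in true_frames[(e.side, e.kind)])
    for e in detected
    if (e.side, e.kind) in true_frames
]
print(f"ground truth: {len(truth.events)} events; detected: {len(detected)}")
print(f"median |timing error| = {np.median(errors):.1f} frames "
      f"(1 frame = {1000 / recording.fs:.1f} ms)")

kept = trim_cycles(detected, "ascent")
print(f"steps {kept.n_steps_total}, kept after ramp trimming rule: "
      f"{len(kept.kept_ics)} (steps 2..N-1), cycles: {len(kept.cycles)}")
# A median error of 0-1 frames means initial contacts are localized to
# within ~17 ms despite centimeter-scale landmark jitter.
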