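"""Simulate one walking trial and inspect its ground truth.

Builds joint-angle templates calibrated to the young-adult level-walking
values, synthesizes a single 60 Hz trial, and prints the exact events the
generator embedded.  Every downstream stage can be checked against this
ground truth.
"""

from rampgait import simulate_trial, template_set
from rampgait.tables import default_group_targets

targets = default_group_targets()[("young", "level")]
templates = template_set(dict(targets.features))

recording, truth = simulate_trial(
    templates,
    cadence=targets.cadence[0],
    step_length=60.0 * targets.velocity[0] / targets.cadence[0],
    condition="level",
)

print(f"trial: {recording.trial_id}, {recording.n_frames} frames at {recording.fs:g} Hz")
print(f"realized cadence {truth.cadence:.2f} steps/min, velocity {truth.velocity:.3f} m/s, "
      f"step length {truth.step_length:.3f} m")
print(f"{truth.n_steps} steps; first events per side:")
for side in ("right", "left"):
    events = truth.events.per_side(side)[:4]
    print(f"  {side:5s}: " + ", ".join(f"{e.kind}@{e.frame}" for e in events))
# The printed cadence/velocity are the values the trial actually encodes
# (cadence is quantized to a whole-frame step duration); IC/TO frames are
# the exact indices where the heel lands and the toe leaves the ground.
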