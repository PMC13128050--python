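"""From raw trials to a representative waveform and its 12 parameters.

Processes a few trials of one synthetic participant, averages the
normalized cycles hierarchically (cycles -> limbs -> trials), extracts the
representative sagittal values, and saves a mean +/- SD waveform figure.
"""

import warnings

import matplotlib

matplotlib.use("Agg")

from rampgait import (
    CohortSpec,
    extract_features,
    generate_cohort,
    partition_phases,
    process_trial,
    RunConfig,
)
from rampgait.plotting import plot_waveforms
from rampgait.signal_prep import average_waveforms

cohort = generate_cohort(CohortSpec(n_young=1, n_old=1, trials_per_condition=5,
                                    conditions=("ascent",), seed=3))
config = RunConfig()
participant_trials = [t for t in cohort.trials if t.participant == "Y01"]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results = [process_trial(t, config) for t in participant_trials]
    rep = average_waveforms({r.trial_id: r.cycles for r in results})

print(f"averaged {rep.n_cycles} cycles from {rep.n_trials} trials; "
      f"toe-off at {rep.to_percent:.1f}% of the cycle")
features = extract_features(rep.mean, partition_phases(rep.to_percent))
for name, value in features.as_dict().items():
    print(f"  {name:32s} {value:7.2f} deg")

fig = plot_waveforms([("Y01 ascent", rep)])
fig.savefig("scratch_waveforms.png", dpi=100)
print("wrote scratch_waveforms.png")
# Positive values are flexion/dorsiflexion. MaxExt_Stance is the signed
# stance minimum (negative = hyperextension); plantarflexion is reported
# as a positive magnitude. RoM is max - min over the full cycle.
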