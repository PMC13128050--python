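"""Waveform plotting: mean +/- SD bands over the normalized gait cycle."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .features import JOINTS
from .signal_prep import RepresentativeWaveform

_JOINT_LABEL = {"hip": "Hip flexion (+) / extension (-)",
                "knee": "Knee flexion (+)",
                "ankle": "Ankle dorsiflexion (+) / plantarflexion (-)"}


def plot_waveforms(
    waveforms: Mapping[str, Sequence[Tuple[str, RepresentativeWaveform]]] | Sequence[Tuple[str, RepresentativeWaveform]],
    axes=None,
    colors: Optional[Mapping[str, str]] = None,
):
    """Plot labelled representative waveforms (mean with SD band) per joint.

    ``waveforms`` is a sequence of ``(label, RepresentativeWaveform)``
    pairs, plotted into one axis per joint with a vertical line at the
    averaged toe-off.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    if isinstance(waveforms, Mapping):
        waveforms = list(waveforms.items())
    if axes is None:
        fig, axes = plt.subplots(1, len(JOINTS), figsize=(4 * len(JOINTS), 3), sharex=True)
    else:
        fig = axes[0].figure
    x = np.arange(101)
    for ax, joint in zip(axes, JOINTS):
        for label, rep in waveforms:
            color = (colors or {}).get(label)
            mean, sd = np.asarray(rep.mean[joint]), np.asarray(rep.sd[joint])
            (line,) = ax.plot(x, mean, label=label, color=color)
            ax.fill_between(x, mean - sd, mean + sd, alpha=0.2, color=line.get_color())
            ax.axvline(rep.to_percent, ls=":", lw=0.8, color=line.get_color())
        ax.set_title(joint)
        ax.set_xlabel("% gait cycle")
        ax.set_ylabel(_JOINT_LABEL[joint] + " [deg]")
    axes[0].legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
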