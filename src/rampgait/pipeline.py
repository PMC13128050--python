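"""End-to-end analysis pipeline: filter -> events -> trim -> cycles ->
representative waveforms -> features -> group statistics.

`run_pipeline` consumes trial recordings (in memory or from a directory of
TSV files) and produces a results bundle mirroring the study's reporting:
a tidy per-participant feature table, spatiotemporal t-test comparisons,
and velocity-adjusted mixed-model contrasts for the joint-angle
parameters, with QC flags and full configuration provenance embedded in
every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .events import (
    EventSeries,
    TrimResult,
    classify_foot_strike,
    detect_events,
    flag_outlier_cycles,
    trim_cycles,
    walking_direction,
)
from .features import (
    JOINTS,
    SpatioTemporal,
    extract_features,
    partition_phases,
    spatiotemporal,
)
from .lmm import KinematicStats, kinematic_battery
from .signal_prep import (
    NormalizedCycle,
    RepresentativeWaveform,
    average_waveforms,
    gcv_smooth,
    lowpass,
    segment_cycles,
    time_normalize,
)
from .stats import ttest_battery
from .trial import SIDES, TrialRecording

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and trial."""


@dataclass
class TrialResult:
    """Per-trial products of the event/cycle stages."""

    trial_id: str
    participant: str
    group: str
    condition: str
    events: EventSeries
    trim: TrimResult
    cycles: List[NormalizedCycle]
    spt: SpatioTemporal
    foot_strikes: List[str]
    qc_excluded: int


@dataclass
class GaitResults:
    """Results bundle for a cohort run."""

    feature_table: pd.DataFrame
    waveforms: Mapping[Tuple[str, str], RepresentativeWaveform]
    spatiotemporal_stats: Optional[pd.DataFrame]
    kinematic_stats: Optional[KinematicStats]
    trial_results: Mapping[str, TrialResult]
    qc: Dict[str, dict]
    provenance: Dict[str, object]

    def to_dir(self, out_dir) -> Path:
        """Persist every stage output (CSV/JSON) with embedded provenance."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = json.dumps(self.provenance, indent=1)
        (out / "provenance.json").write_text(prov)

        def _write(df: pd.DataFrame, name: str) -> None:
            path = out / name
            with path.open("w") as fh:
                for line in prov.splitlines():
                    fh.write(f"# {line}\n")
                df.to_csv(fh, index=False)

        _write(self.feature_table, "features.csv")
        if self.spatiotemporal_stats is not None:
            _write(self.spatiotemporal_stats, "spatiotemporal_stats.csv")
        if self.kinematic_stats is not None:
            _write(self.kinematic_stats.contrasts, "kinematic_contrasts.csv")
            _write(self.kinematic_stats.anova, "kinematic_anova.csv")
        (out / "qc.json").write_text(json.dumps(self.qc, indent=1))
        return out


def _smooth_frames(rec: TrialRecording, config: RunConfig) -> TrialRecording:
    """Apply the configured filter to all landmark and angle columns."""
    if config.filter_method == "none":
        return rec
    frames = rec.frames.copy()
    for col in frames.columns:
        if col == "time_s":
            continue
        x = frames[col].to_numpy(float)
        if config.filter_method == "gcv":
            frames[col] = gcv_smooth(x)
        else:
            frames[col] = lowpass(x, rec.fs, config.filter_cutoff_hz)
    return rec.with_frames(frames)


def smooth_recording(rec: TrialRecording, config: Optional[RunConfig] = None) -> TrialRecording:
    """Public entry point for the configured pre-filtering of a trial."""
    return _smooth_frames(rec, config or RunConfig())


def process_trial(rec: TrialRecording, config: RunConfig) -> TrialResult:
    """Run one trial through filtering, events, trimming and normalization."""
    tid = rec.trial_id
    try:
        smoothed = _smooth_frames(rec, config)
        events = detect_events(
            smoothed,
            prominence_frac=config.event_prominence_frac,
            min_interval_s=config.event_min_interval_s,
            min_cycle_s=config.min_cycle_s,
        )
        trim = trim_cycles(events, rec.condition)

        pelvis = 0.5 * (
            smoothed.landmark_xy("left", "pelvis") + smoothed.landmark_xy("right", "pelvis")
        )
        direction, pelvis_ap = walking_direction(pelvis)
        heel_ap = {s: smoothed.landmark_xy(s, "heel") @ direction for s in SIDES}
        spt = spatiotemporal(trim.kept_ics, heel_ap, pelvis_ap, rec.fs)
        strikes = [classify_foot_strike(smoothed, ic, direction) for ic in trim.kept_ics]

        qc = flag_outlier_cycles(trim.cycles, rec.fs, config.qc_sd_threshold)
        kept_cycles = [c for i, c in enumerate(trim.cycles) if not qc.get(i, False)]
        normalized: List[NormalizedCycle] = []
        for side in SIDES:
            angles = {j: smoothed.angle(side, j) for j in JOINTS}
            spans = [c for c in kept_cycles if c.side == side]
            for raw in segment_cycles(angles, events, side, spans):
                normalized.append(time_normalize(raw))
        return TrialResult(
            trial_id=tid,
            participant=rec.participant,
            group=rec.group,
            condition=rec.condition,
            events=events,
            trim=trim,
            cycles=normalized,
            spt=spt,
            foot_strikes=strikes,
            qc_excluded=sum(qc.values()),
        )
    except Exception as e:
        raise PipelineError(f"trial {tid}: {type(e).__name__}: {e}") from e


def run_pipeline(
    trials: Union[str, Path, Sequence[TrialRecording]],
    config: Optional[RunConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> GaitResults:
    """Run the full analysis over a set of trials.

    Parameters
    ----------
    trials:
        Trial recordings, or a directory of TSV trial files.
    config:
        Analysis settings (defaults throughout if omitted).
    out_dir:
        If given, the results bundle is also written there.

    Stages run in order per trial (filter, events, trim, segment,
    normalize), then per participant x condition (limb/trial averaging,
    feature extraction), then the two statistics tiers: spatiotemporal
    t tests (needs >= 2 participants per group) and per-parameter
    velocity-adjusted mixed models (additionally needs >= 2 conditions).
    Deterministic given the inputs and config.
    """
    config = config or RunConfig()
    if isinstance(trials, (str, Path)):
        from .io import read_trial_dir

        trials = read_trial_dir(trials)
    if not trials:
        raise ValueError("no trials to process")

    trial_results: Dict[str, TrialResult] = {}
    for rec in trials:
        tr = process_trial(rec, config)
        trial_results[tr.trial_id] = tr
        logger.info(
            "trial %s: %d steps, %d cycles (%d QC-excluded)",
            tr.trial_id, tr.trim.n_steps_total, len(tr.cycles), tr.qc_excluded,
        )

    # --- participant x condition aggregation ---------------------------
    by_cell: Dict[Tuple[str, str], List[TrialResult]] = {}
    group_of: Dict[str, str] = {}
    for tr in trial_results.values():
        by_cell.setdefault((tr.participant, tr.condition), []).append(tr)
        group_of[tr.participant] = tr.group

    waveforms: Dict[Tuple[str, str], RepresentativeWaveform] = {}
    rows: List[dict] = []
    for (pid, cond), cell_trials in sorted(by_cell.items()):
        rep = average_waveforms({t.trial_id: t.cycles for t in cell_trials})
        waveforms[(pid, cond)] = rep
        partition = partition_phases(rep.to_percent, config.mid_stance_percent)
        feats = extract_features(rep.mean, partition, config.plantarflexion_halfwidth)
        base = dict(participant=pid, group=group_of[pid], condition=cond)
        for name, value in feats.as_dict().items():
            rows.append(dict(**base, parameter=name, value=value))
        for par in ("cadence", "velocity", "step_length"):
            rows.append(
                dict(**base, parameter=par,
                     value=float(np.mean([getattr(t.spt, par) for t in cell_trials])))
            )
    feature_table = pd.DataFrame(rows)

    # --- statistics tiers ----------------------------------------------
    groups = {g: len({p for p, gg in group_of.items() if gg == g}) for g in set(group_of.values())}
    both_groups = groups.get("young", 0) >= 2 and groups.get("old", 0) >= 2
    spt_stats = None
    kin_stats = None
    if both_groups:
        spt_stats = ttest_battery(
            feature_table,
            fdr_family=config.spatiotemporal_fdr_family,
            flavor=config.ttest_flavor,
        )
        n_conditions = feature_table["condition"].nunique()
        if n_conditions >= 2:
            kin_stats = kinematic_battery(
                feature_table,
                gate_on_interaction=config.gate_on_interaction,
                alpha=config.alpha,
            )
        else:
            logger.warning("single condition: skipping the mixed-model tier")
    else:
        logger.warning("fewer than 2 participants in a group: skipping statistics tiers")

    qc = {
        tid: {
            "n_steps": tr.trim.n_steps_total,
            "n_cycles": len(tr.cycles),
            "qc_excluded": tr.qc_excluded,
            "foot_strikes": sorted(set(tr.foot_strikes)),
        }
        for tid, tr in trial_results.items()
    }
    provenance = {"rampgait_version": __version__, "config": config.to_dict()}
    results = GaitResults(
        feature_table=feature_table,
        waveforms=waveforms,
        spatiotemporal_stats=spt_stats,
        kinematic_stats=kin_stats,
        trial_results=trial_results,
        qc=qc,
        provenance=provenance,
    )
    if out_dir is not None:
        results.to_dir(out_dir)
    return results
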