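"""Trial file I/O: tab-separated trial dialect and cohort read/write.

The native trial format is human-diffable UTF-8 TSV: ``#``-prefixed
``key: value`` header lines (participant, group, condition, trial index,
sampling rate, incline), then a column header row and one row per frame.
Columns may appear in any order; all declared columns must be present.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .synthetic import Cohort
from .trial import TrialRecording, expected_columns

_HEADER_KEYS = ("participant", "group", "condition", "trial_index", "fs", "incline_deg")


class TrialParseError(ValueError):
    """A trial file violates the dialect (with file/line context)."""


def write_trial(recording: TrialRecording, path) -> Path:
    """Write a trial in the TSV dialect; returns the path written."""
    path = Path(path)
    lines = [
        f"# participant: {recording.participant}",
        f"# group: {recording.group}",
        f"# condition: {recording.condition}",
        f"# trial_index: {recording.trial_index}",
        f"# fs: {recording.fs:g}",
        f"# incline_deg: {recording.incline_deg:g}",
    ]
    cols = expected_columns()
    body = recording.frames[cols].to_csv(sep="\t", index=False, float_format="%.6f")
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")
    return path


def read_trial(path) -> TrialRecording:
    """Read a trial file, validating columns, units and time monotonicity."""
    path = Path(path)
    header: Dict[str, str] = {}
    data_start = 0
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            data_start = i
            break
        body = line[1:].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            header[key.strip()] = val.strip()
    missing_meta = set(_HEADER_KEYS) - set(header)
    if missing_meta:
        raise TrialParseError(f"{path}: missing header keys: {sorted(missing_meta)}")

    columns = lines[data_start].rstrip("\n").split("\t")
    n_cols = len(columns)
    records: List[List[float]] = []
    for lineno, line in enumerate(lines[data_start + 1 :], start=data_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != n_cols:
            raise TrialParseError(
                f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)} (truncated line?)"
            )
        try:
            records.append([float(v) for v in parts])
        except ValueError as e:
            raise TrialParseError(f"{path}:{lineno}: {e}") from None
    frames = pd.DataFrame(records, columns=columns)

    missing = set(expected_columns()) - set(frames.columns)
    if missing:
        raise TrialParseError(f"{path}: missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(frames.to_numpy())):
        raise TrialParseError(f"{path}: non-finite values in frame table")
    t = frames["time_s"].to_numpy(float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise TrialParseError(f"{path}: time_s is not strictly increasing")
    fs = float(header["fs"])
    if len(t) >= 2 and abs(np.median(np.diff(t)) - 1.0 / fs) > 1e-6:
        raise TrialParseError(f"{path}: frame spacing does not match fs={fs:g} Hz")
    return TrialRecording(
        participant=header["participant"],
        group=header["group"],
        condition=header["condition"],
        trial_index=int(header["trial_index"]),
        fs=fs,
        incline_deg=float(header["incline_deg"]),
        frames=frames[expected_columns()],
    )


# ---------------------------------------------------------------------------
# cohort directories
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as one TSV per trial plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.trials:
        write_trial(rec, out_dir / f"{rec.trial_id}.tsv")
    gt = cohort.ground_truth
    sidecar = {
        "spec": {
            "n_young": cohort.spec.n_young,
            "n_old": cohort.spec.n_old,
            "conditions": list(cohort.spec.conditions),
            "trials_per_condition": cohort.spec.trials_per_condition,
            "participant_sd": cohort.spec.participant_sd,
            "feature_noise_sd": cohort.spec.feature_noise_sd,
            "noise_sd": cohort.spec.noise_sd,
            "seed": cohort.spec.seed,
            "stance_fraction": cohort.spec.stance_fraction,
            "fs": cohort.spec.fs,
        },
        "targets": gt.targets.to_dict(orient="records"),
        "effect_config": gt.effect_config.to_dict(orient="records"),
        "trial_truth": {
            tid: {
                "cadence": t.cadence,
                "velocity": t.velocity,
                "step_length": t.step_length,
                "stride_frames": t.stride_frames,
                "n_steps": t.n_steps,
                "foot_strike": t.foot_strike,
                "events": [
                    {"side": e.side, "kind": e.kind, "frame": e.frame, "time": e.time}
                    for e in t.events
                ],
            }
            for tid, t in gt.trials.items()
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_trial_dir(in_dir) -> List[TrialRecording]:
    """Read every ``*.tsv`` trial in a directory (sorted by filename)."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv trial files in {in_dir}")
    return [read_trial(p) for p in paths]


def events_to_csv(events_by_trial: Dict[str, "EventSeries"], path) -> Path:
    """Export detected events: trial_id, side, kind, frame, time_s."""
    rows = []
    for tid, series in events_by_trial.items():
        for e in series:
            rows.append(dict(trial_id=tid, side=e.side, kind=e.kind, frame=e.frame, time_s=e.time))
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
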