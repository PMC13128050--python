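"""Run configuration: every tunable analysis choice, serialized for provenance.

A :class:`RunConfig` travels with every results bundle so any output can be
traced back to the exact settings (and seed) that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings for the full pipeline.

    Attributes
    ----------
    filter_method:
        ``"gcv"`` (adaptive GCV smoother, default), ``"butterworth"``
        (fixed zero-phase low-pass at ``filter_cutoff_hz``) or ``"none"``.
    filter_cutoff_hz:
        Cutoff of the fixed filter (used only with ``"butterworth"``).
    event_prominence_frac:
        Peak prominence floor as a fraction of the signal IQR.
    event_min_interval_s:
        Minimum interval between same-kind events (rejects jitter peaks up
        to a 200 steps/min cadence).
    min_cycle_s:
        Minimum ipsilateral IC-to-IC duration accepted as a cycle.
    mid_stance_percent:
        Fixed ST1/ST2 boundary in % cycle, or None for the temporal
        midpoint of stance (toe-off / 2).
    plantarflexion_halfwidth:
        Half-width (% cycle) of the stance-to-swing window for peak
        plantarflexion.
    qc_sd_threshold:
        Cycles whose duration deviates more than this many SDs from the
        trial median are flagged and excluded.
    ttest_flavor:
        ``"student"`` (pooled variance) or ``"welch"``.
    spatiotemporal_fdr_family:
        ``"per_parameter"`` or ``"pooled"`` BH family for the t-test tier.
    gate_on_interaction:
        Evaluate simple effects only when the group x condition interaction
        is significant at ``alpha``.
    alpha:
        Significance level for the interaction gate.
    seed:
        Seed recorded for any stochastic step run under this config.
    """

    filter_method: str = "gcv"
    filter_cutoff_hz: float = 6.0
    event_prominence_frac: float = 0.2
    event_min_interval_s: float = 0.3
    min_cycle_s: float = 0.4
    mid_stance_percent: Optional[float] = None
    plantarflexion_halfwidth: float = 10.0
    qc_sd_threshold: float = 3.0
    ttest_flavor: str = "student"
    spatiotemporal_fdr_family: str = "per_parameter"
    gate_on_interaction: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_method not in ("gcv", "butterworth", "none"):
            raise ValueError("filter_method must be 'gcv', 'butterworth' or 'none'")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be positive")
        if not (0 < self.event_prominence_frac < 1):
            raise ValueError("event_prominence_frac must be in (0, 1)")
        if self.event_min_interval_s <= 0 or self.min_cycle_s <= 0:
            raise ValueError("event/cycle durations must be positive")
        if self.mid_stance_percent is not None and not (0 < self.mid_stance_percent < 100):
            raise ValueError("mid_stance_percent must be in (0, 100)")
        if not (0 < self.plantarflexion_halfwidth <= 25):
            raise ValueError("plantarflexion_halfwidth must be in (0, 25]")
        if self.ttest_flavor not in ("student", "welch"):
            raise ValueError("ttest_flavor must be 'student' or 'welch'")
        if self.spatiotemporal_fdr_family not in ("per_parameter", "pooled"):
            raise ValueError("spatiotemporal_fdr_family must be 'per_parameter' or 'pooled'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
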