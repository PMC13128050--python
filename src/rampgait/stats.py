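"""Group-comparison statistics: t tests, Cohen's d, magnitude bands, BH-FDR.

This is the spatiotemporal tier of the analysis: per parameter and walking
condition, an independent two-sample t test between age groups, a pooled-SD
Cohen's d with the conventional magnitude bands, and Benjamini-Hochberg
false-discovery-rate adjustment (family = the conditions within each
parameter by default; a pooled family is available since the appropriate
grouping is a reporting choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MAGNITUDE_BANDS = (
    (0.2, "negligible"),
    (0.5, "small"),
    (0.8, "medium"),
)


def magnitude_label(d: float) -> str:
    """Effect-size magnitude: |d|<0.2 negligible, <0.5 small, <0.8 medium, else large.

    Bands are half-open on the right: |d| = 0.8 is large.
    """
    if not np.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    a = abs(d)
    for ub, label in MAGNITUDE_BANDS:
        if a < ub:
            return label
    return "large"


def cohens_d_pooled(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Cohen's d with the pooled standard deviation.

    d = (m1 - m2) / s_p,  s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)).

    Sign is preserved (positive when group 1 exceeds group 2).  A zero
    pooled SD with equal means gives d = 0; with unequal means it raises.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    diff = m1 - m2
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ZeroDivisionError("zero pooled SD with unequal means: infinite effect size")
    return float(diff / sp)


def cohens_d_from_samples(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Pooled-SD Cohen's d computed directly from two samples."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return cohens_d_pooled(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normality_check(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (reporting only, never gating)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TTestResult:
    """One between-group comparison of a spatiotemporal parameter."""

    parameter: str
    condition: str
    mean_young: float
    sd_young: float
    mean_old: float
    sd_old: float
    t: float
    df: float
    p: float
    p_fdr: float
    d: float
    magnitude: str

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.p_fdr <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_fdr < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")


def ttest_battery(
    feature_table: pd.DataFrame,
    parameters: Iterable[str] = ("cadence", "velocity", "step_length"),
    fdr_family: str = "per_parameter",
    flavor: str = "student",
) -> pd.DataFrame:
    """Between-group t tests for spatiotemporal parameters.

    Parameters
    ----------
    feature_table:
        Tidy per-participant values: columns ``participant``, ``group``
        (``young``/``old``), ``condition``, ``parameter``, ``value`` --
        one row per participant x condition x parameter.
    parameters:
        Parameters to test (default the three spatiotemporal ones).
    fdr_family:
        ``"per_parameter"`` adjusts the conditions within each parameter
        (default); ``"pooled"`` adjusts all tests together.
    flavor:
        ``"student"`` (pooled variance, consistent with the pooled-SD
        Cohen's d) or ``"welch"``.

    Returns a tidy DataFrame, one row per parameter x condition.
    """
    if fdr_family not in ("per_parameter", "pooled"):
        raise ValueError("fdr_family must be 'per_parameter' or 'pooled'")
    if flavor not in ("student", "welch"):
        raise ValueError("flavor must be 'student' or 'welch'")
    rows: List[dict] = []
    for par in parameters:
        sub = feature_table[feature_table["parameter"] == par]
        for cond in pd.unique(sub["condition"]):
            cell = sub[sub["condition"] == cond]
            y = cell.loc[cell["group"] == "young", "value"].to_numpy(float)
            o = cell.loc[cell["group"] == "old", "value"].to_numpy(float)
            if len(y) < 2 or len(o) < 2:
                raise ValueError(f"{par}/{cond}: need >= 2 participants per group")
            res = sps.ttest_ind(y, o, equal_var=(flavor == "student"))
            d = cohens_d_from_samples(y, o)
            rows.append(
                dict(
                    parameter=par, condition=cond,
                    mean_young=y.mean(), sd_young=y.std(ddof=1),
                    mean_old=o.mean(), sd_old=o.std(ddof=1),
                    t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
                    d=d, magnitude=magnitude_label(d),
                )
            )
    out = pd.DataFrame(rows)
    if len(out):
        if fdr_family == "per_parameter":
            out["p_fdr"] = out.groupby("parameter")["p"].transform(lambda p: fdr_adjust(p.values))
        else:
            out["p_fdr"] = fdr_adjust(out["p"].values)
        out = out[
            ["parameter", "condition", "mean_young", "sd_young", "mean_old", "sd_old",
             "t", "df", "p", "p_fdr", "d", "magnitude"]
        ]
    return out
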