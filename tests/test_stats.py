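"""Effect sizes, magnitude bands, FDR and the t-test battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rampgait import (
    cohens_d_from_samples,
    cohens_d_pooled,
    fdr_adjust,
    magnitude_label,
    normality_check,
    ttest_battery,
)

from oracles import brute_force_bh, brute_force_cohens_d


class TestCohensD:
    def test_published_cadence_statistics(self):
        assert cohens_d_pooled(104.16, 5.70, 20, 102.04, 7.74, 20) == pytest.approx(0.312, abs=5e-4)

    def test_equal_means_give_zero(self):
        assert cohens_d_pooled(5.0, 1.0, 10, 5.0, 3.0, 12) == 0.0

    def test_zero_sd_equal_means_zero_unequal_raises(self):
        assert cohens_d_pooled(5.0, 0.0, 10, 5.0, 0.0, 10) == 0.0
        with pytest.raises(ZeroDivisionError):
            cohens_d_pooled(5.0, 0.0, 10, 6.0, 0.0, 10)

    def test_thousand_random_parameter_sets_match_formula_oracle(self, rng):
        for _ in range(1000):
            m1, m2 = rng.normal(0, 10, 2)
            s1, s2 = rng.uniform(0.1, 5, 2)
            n1, n2 = rng.integers(2, 50, 2)
            assert cohens_d_pooled(m1, s1, n1, m2, s2, n2) == pytest.approx(
                brute_force_cohens_d(m1, s1, n1, m2, s2, n2), abs=1e-12
            )


class TestMagnitude:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0.312, "small"),
            (-0.8, "large"),
            (0.19999, "negligible"),
            (0.0, "negligible"),
            (0.5, "medium"),
            (-0.79999, "medium"),
            (2.37, "large"),
        ],
    )
    def test_bands(self, d, label):
        assert magnitude_label(d) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            magnitude_label(float("nan"))


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037]) == pytest.approx([0.037])

    def test_hand_computed_step_up(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=150, derandomize=True)
    def test_bh_properties(self, ps):
        adj = fdr_adjust(ps)
        # matches the textbook step-up computation
        assert adj == pytest.approx(brute_force_bh(ps), abs=1e-12)
        # adjusted >= raw; the largest adjusted p equals the largest raw p
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert max(adj) == pytest.approx(max(ps))
        # order preserving
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)
        # decision equivalence: thresholding adjusted p-values at alpha
        # reproduces the step-up procedure's rejection set
        m = len(ps)
        for alpha in (0.01, 0.05, 0.25):
            k = 0
            for rank, i in enumerate(sorted(range(m), key=lambda i: ps[i]), start=1):
                if ps[i] <= alpha * rank / m:
                    k = rank
            stepup = set(sorted(range(m), key=lambda i: ps[i])[:k])
            assert {i for i in range(m) if adj[i] <= alpha + 1e-12} == stepup


class TestNormality:
    def test_three_point_symmetric_sample_computable(self):
        w, p = normality_check([-1.0, 0.0, 1.0])
        assert np.isfinite(w) and np.isfinite(p)

    def test_normal_draws_usually_pass(self, rng):
        hits = sum(normality_check(rng.normal(size=20))[1] > 0.05 for _ in range(100))
        assert hits >= 85  # nominal 95% pass rate, binomial wiggle

    def test_exponential_draws_usually_fail(self, rng):
        hits = sum(normality_check(rng.exponential(size=50))[1] < 0.05 for _ in range(100))
        assert hits >= 90

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check([2.0] * 10)


def _table(rng, diff=0.0, n=10):
    rows = []
    for g, off in (("young", 0.0), ("old", -diff)):
        for i in range(n):
            for cond in ("level", "ascent", "descent"):
                rows.append(
                    dict(participant=f"{g}{i}", group=g, condition=cond,
                         parameter="velocity", value=1.3 + off + rng.normal(0, 0.1))
                )
    return pd.DataFrame(rows)


class TestTtestBattery:
    def test_identical_groups_t0_p1_d0(self):
        rows = []
        for g in ("young", "old"):
            for i in range(5):
                for cond in ("level", "ascent"):
                    rows.append(dict(participant=f"{g}{i}", group=g, condition=cond,
                                     parameter="velocity", value=float(i)))
        out = ttest_battery(pd.DataFrame(rows), parameters=["velocity"])
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert np.allclose(out["d"], 0.0)

    def test_constructed_exact_moments_give_d_16(self):
        """Groups with means 1.24/1.08 and common SD 0.10 (n=20) give d=1.6."""
        base = np.linspace(-1, 1, 20)
        z = (base - base.mean()) / base.std(ddof=1)
        young = 1.24 + 0.10 * z
        old = 1.08 + 0.10 * z
        assert cohens_d_from_samples(young, old) == pytest.approx(1.6, abs=1e-9)

    def test_battery_d_matches_sample_oracle(self, rng):
        tbl = _table(rng, diff=0.12)
        out = ttest_battery(tbl, parameters=["velocity"]).set_index("condition")
        for cond in ("level", "ascent", "descent"):
            cell = tbl[(tbl.condition == cond)]
            y = cell[cell.group == "young"]["value"].to_numpy()
            o = cell[cell.group == "old"]["value"].to_numpy()
            assert out.loc[cond, "d"] == pytest.approx(
                brute_force_cohens_d(y.mean(), y.std(ddof=1), len(y), o.mean(), o.std(ddof=1), len(o)),
                abs=1e-12,
            )
            assert out.loc[cond, "magnitude"] == magnitude_label(out.loc[cond, "d"])

    def test_small_group_rejected(self, rng):
        tbl = _table(rng)
        tbl = tbl[~((tbl.group == "old") & (tbl.participant != "old0"))]
        with pytest.raises(ValueError, match=">= 2 participants"):
            ttest_battery(tbl, parameters=["velocity"])

    def test_d_t_consistency_for_equal_n(self, rng):
        """For equal-n two-group data, d = t * sqrt(2/n) to 1e-9."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            y, o = rng.normal(0, 1, n), rng.normal(0.4, 1.2, n)
            from scipy.stats import ttest_ind

            t = ttest_ind(y, o, equal_var=True).statistic
            assert cohens_d_from_samples(y, o) == pytest.approx(t * np.sqrt(2 / n), abs=1e-9)
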