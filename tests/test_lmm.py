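"""Mixed-model tier: recovery, reductions, and the R cross-implementation oracle."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from rampgait import anova_type3, emmeans, fit_lmm, kinematic_battery, simple_effects
from rampgait.lmm import LmmError

DATA = Path(__file__).parent / "data"
CONDS = ("level", "ascent", "descent")


def simulate_lmm_data(
    rng,
    n_per_group=10,
    participant_sd=3.0,
    resid_sd=2.0,
    group_effect=0.0,
    interaction=None,
    velocity_slope=0.0,
):
    """Draw directly from the random-intercept model (no gait pipeline)."""
    interaction = interaction or {}
    rows = []
    for g in ("young", "old"):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            b = rng.normal(0, participant_sd)
            for c in CONDS:
                v = rng.normal(1.25 if g == "young" else 1.05, 0.1)
                y = (
                    20.0
                    + {"level": 0.0, "ascent": 5.0, "descent": 2.0}[c]
                    + (group_effect if g == "old" else 0.0)
                    + interaction.get((g, c), 0.0)
                    + velocity_slope * v
                    + b
                    + rng.normal(0, resid_sd)
                )
                rows.append(dict(participant=pid, group=g, condition=c, velocity=v, value=y))
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fitted():
    df = pd.read_csv(DATA / "lmm_fixture.csv")
    exp = json.loads((DATA / "lmm_expected.json").read_text())
    return fit_lmm(df), exp


class TestAgainstReferenceImplementation:
    """Frozen lme4/lmerTest/emmeans results on the bundled fixture dataset."""

    def test_variance_components(self, fitted):
        fit, exp = fitted
        assert fit.sigma2_participant == pytest.approx(exp["sigma2_participant"], rel=1e-3)
        assert fit.sigma2_resid == pytest.approx(exp["sigma2_resid"], rel=1e-3)

    def test_type3_anova_f_and_satterthwaite_df(self, fitted):
        fit, exp = fitted
        an = anova_type3(fit).set_index("term")
        for row in exp["anova"]:
            term = row["term"].replace("velocity_c", "velocity")
            assert an.loc[term, "F"] == pytest.approx(row["F"], rel=1e-3)
            assert an.loc[term, "df_num"] == row["df_num"]
            # Satterthwaite df within 10% of the reference implementation
            assert an.loc[term, "df_den"] == pytest.approx(row["df_den"], rel=0.10)
            assert an.loc[term, "p"] == pytest.approx(row["p"], rel=2e-2, abs=1e-12)

    def test_simple_effect_contrasts(self, fitted):
        fit, exp = fitted
        se = simple_effects(fit, interaction_p=0.0).set_index("condition")
        for c in exp["contrasts"]:
            row = se.loc[c["condition"]]
            assert row["estimate"] == pytest.approx(c["estimate"], abs=1e-3)
            assert row["se"] == pytest.approx(c["se"], rel=1e-3)
            assert row["df"] == pytest.approx(c["df"], rel=0.10)
            assert row["p"] == pytest.approx(c["p"], rel=2e-2, abs=1e-12)


class TestNoiselessIdentity:
    def test_zero_noise_recovers_cell_structure_exactly(self, rng):
        df = simulate_lmm_data(rng, participant_sd=0.0, resid_sd=0.0,
                               group_effect=3.0, interaction={("old", "ascent"): 8.4})
        fit = fit_lmm(df)
        assert fit.degenerate
        assert fit.residual_sd == 0.0
        se = simple_effects(fit, interaction_p=0.0).set_index("condition")
        assert se.loc["ascent", "estimate"] == pytest.approx(-11.4, abs=1e-8)
        assert se.loc["level", "estimate"] == pytest.approx(-3.0, abs=1e-8)

    def test_velocity_orthogonal_group_emm_equals_raw_difference(self, rng):
        """With the angle independent of velocity, the EMM difference matches
        the raw group mean difference."""
        df = simulate_lmm_data(rng, participant_sd=0.0, resid_sd=0.0, group_effect=4.0)
        fit = fit_lmm(df)
        se = simple_effects(fit, interaction_p=0.0)
        assert np.allclose(se["estimate"], -4.0, atol=1e-6)


class TestReductions:
    def test_balanced_no_covariate_emm_equals_cell_mean(self, rng):
        df = simulate_lmm_data(rng, n_per_group=8, group_effect=2.0)
        fit = fit_lmm(df, include_velocity=False)
        em = emmeans(fit).set_index(["group", "condition"])
        cells = df.groupby(["group", "condition"])["value"].mean()
        for (g, c), mean in cells.items():
            assert em.loc[(g, c), "emm"] == pytest.approx(mean, abs=1e-6)

    def test_two_group_one_reduction_f_equals_t_squared(self, rng):
        """Balanced two-group comparison: the LMM group F equals the squared
        two-sample t on participant means (velocity omitted)."""
        from scipy.stats import ttest_ind

        df = simulate_lmm_data(rng, n_per_group=12, group_effect=2.5)
        fit = fit_lmm(df, include_velocity=False)
        an = anova_type3(fit).set_index("term")
        means = df.groupby(["participant", "group"])["value"].mean().reset_index()
        t = ttest_ind(
            means[means.group == "young"]["value"],
            means[means.group == "old"]["value"],
            equal_var=True,
        )
        assert an.loc["group", "F"] == pytest.approx(t.statistic ** 2, rel=1e-6)
        assert an.loc["group", "df_den"] == pytest.approx(22.0, rel=0.02)


class TestValidityChecks:
    def test_parameter_recovery_bias_small(self, rng):
        """60 simulated cohorts: mean bias of the ascent young-old contrast
        is well under the criterion bound."""
        true = -8.4  # young - old in ascent (group 3 + interaction 5.4)
        errs = []
        for _ in range(60):
            df = simulate_lmm_data(rng, n_per_group=20, group_effect=3.0,
                                   interaction={("old", "ascent"): 5.4}, velocity_slope=1.0)
            fit = fit_lmm(df)
            se = simple_effects(fit, interaction_p=0.0).set_index("condition")
            errs.append(se.loc["ascent", "estimate"] - true)
        assert abs(float(np.mean(errs))) < 0.35  # SE of the mean ~ 0.11


class TestGating:
    def test_interaction_gate_blocks_contrasts(self, rng):
        df = simulate_lmm_data(rng, group_effect=1.0)
        fit = fit_lmm(df)
        se = simple_effects(fit, interaction_p=0.2, gate_on_interaction=True)
        assert not se["evaluated"].any()
        se2 = simple_effects(fit, interaction_p=0.2, gate_on_interaction=False)
        assert se2["evaluated"].all()

    def test_battery_pools_fdr_over_evaluated_only(self, rng):
        rows = []
        for g in ("young", "old"):
            for i in range(8):
                pid = f"{g}{i}"
                b = rng.normal(0, 1)
                for c in CONDS:
                    v = rng.normal(1.2, 0.1)
                    rows.append(dict(participant=pid, group=g, condition=c,
                                     parameter="velocity", value=v))
                    rows.append(dict(participant=pid, group=g, condition=c,
                                     parameter="knee_MaxFlex_ST1",
                                     value=20 + (8 if (g, c) == ("old", "ascent") else 0) + b + rng.normal(0, 1)))
                    rows.append(dict(participant=pid, group=g, condition=c,
                                     parameter="hip_RoM", value=40 + b + rng.normal(0, 1)))
        stats = kinematic_battery(pd.DataFrame(rows), parameters=["knee_MaxFlex_ST1", "hip_RoM"])
        kc = stats.contrasts
        evaluated = kc[kc.evaluated]
        gated = kc[~kc.evaluated]
        assert evaluated["p_fdr"].notna().all()
        assert gated["p_fdr"].isna().all()
        # knee interaction is real and should be detected
        assert (kc[kc.parameter == "knee_MaxFlex_ST1"]["interaction_p"] < 0.05).all()


class TestErrors:
    def test_single_condition_rejected(self, rng):
        df = simulate_lmm_data(rng)
        with pytest.raises(LmmError, match="2 walking conditions"):
            fit_lmm(df[df.condition == "level"])

    def test_duplicate_cell_rejected(self, rng):
        df = simulate_lmm_data(rng)
        with pytest.raises(ValueError, match="one observation"):
            fit_lmm(pd.concat([df, df.iloc[:1]], ignore_index=True))
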