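"""Cost engine: PPP conversion, profiles, stratified tables, identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from asthmacost import (
    ConfigurationError,
    build_cohort,
    build_patient_profiles,
    category_contribution,
    category_cost_table,
    category_shares,
    component_share,
    cost_distribution_shares,
    overall_mean_from_cells,
    sensitivity_exclusion,
    to_international_dollars,
    total_annual_cost,
    utilization_table,
)
from asthmacost.config import StudyWindows

WINDOWS = StudyWindows()

SIZES = (14191, 3680, 1408, 1131)
TOTAL_MEANS = (67.0, 482.0, 1061.0, 2235.0)


class TestPPP:
    def test_unit_rate(self):
        assert to_international_dollars(1203.9, 1203.9) == pytest.approx(1.0)

    def test_zero(self):
        assert to_international_dollars(0.0, 1203.9) == 0.0

    def test_linearity_example(self):
        assert to_international_dollars(2407.8, 1203.9) == pytest.approx(2.0)

    def test_invalid_rate(self):
        with pytest.raises(ConfigurationError):
            to_international_dollars(100.0, 0.0)

    @given(
        a=st.floats(0, 1e9, allow_nan=False),
        b=st.floats(0, 1e9, allow_nan=False),
    )
    def test_linearity_property(self, a, b):
        rate = 1203.9
        assert to_international_dollars(a + b, rate) == pytest.approx(
            to_international_dollars(a, rate) + to_international_dollars(b, rate)
        )


def _mini_inputs():
    events = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b"],
            "date": ["2015-03-01", "2015-08-01", "2015-05-05"],
            "event_type": ["hospitalization", "hospitalization", "ed_visit"],
            "icd10_codes": ["J45", "J45", "J46"],
            "cost_cop": [100 * 1203.9, 50 * 1203.9, 10 * 1203.9],
        }
    )
    fills = pd.DataFrame(
        {
            "patient_id": ["a", "b", "b"],
            "date": ["2015-04-01", "2015-06-01", "2014-06-01"],
            "med_class": ["SABA", "OCS", "SABA"],
            "cost_cop": [5 * 1203.9, 7 * 1203.9, 99 * 1203.9],
        }
    )
    severity = pd.Series([4, 2, 1], index=pd.Index(["a", "b", "c"], name="patient_id"))
    return events, fills, severity


class TestProfiles:
    def test_summation_and_counts(self):
        events, fills, severity = _mini_inputs()
        prof = build_patient_profiles(events, fills, severity, WINDOWS)
        assert prof.loc["a", "n_hospitalization"] == 2
        assert prof.loc["a", "cost_hospitalization"] == pytest.approx(150.0)
        assert prof.loc["a", "total_cost"] == pytest.approx(155.0)

    def test_zero_utilization_patient_gets_zero_profile(self):
        events, fills, severity = _mini_inputs()
        prof = build_patient_profiles(events, fills, severity, WINDOWS)
        assert prof.loc["c", "total_cost"] == 0.0
        assert prof.loc["c"].filter(like="n_").sum() == 0

    def test_out_of_window_records_dropped(self):
        events, fills, severity = _mini_inputs()
        prof = build_patient_profiles(events, fills, severity, WINDOWS)
        assert prof.loc["b", "saba_fills"] == 0  # 2014 fill excluded
        assert prof.loc["b", "total_cost"] == pytest.approx(17.0)

    def test_foreign_patient_records_skipped(self):
        events, fills, severity = _mini_inputs()
        events.loc[len(events)] = ["zz", "2015-01-01", "ed_visit", "J45", 999.0]
        prof = build_patient_profiles(events, fills, severity, WINDOWS)
        assert "zz" not in prof.index
        assert prof.attrs["n_foreign_records_skipped"] == 1

    def test_total_is_sum_of_components(self, small_population):
        pop = small_population
        tl = pop.true_labels.set_index("patient_id")
        prof = build_patient_profiles(pop.events, pop.fills, tl["severity"], WINDOWS)
        np.testing.assert_allclose(
            prof["total_cost"],
            prof.filter(like="cost_").drop(
                columns=[c for c in prof.columns if "any" in c or c == "total_cost"],
                errors="ignore",
            ).sum(axis=1),
        )

    def test_cost_conservation_against_generator(self, small_population):
        """Profile totals equal the generator's emitted in-window costs."""
        pop = small_population
        res = build_cohort(pop.events, pop.enrollment, pop.config.windows, pop.demographics)
        tl = pop.true_labels.set_index("patient_id")
        sev = tl.loc[sorted(res.patient_ids), "severity"]
        prof = build_patient_profiles(pop.events, pop.fills, sev, WINDOWS)
        in_win = lambda df: df[
            (pd.to_datetime(df["date"]) >= "2015-01-01")
            & (pd.to_datetime(df["date"]) <= "2015-12-31")
            & df["patient_id"].isin(res.patient_ids)
        ]["cost_cop"].sum()
        emitted = (in_win(pop.events) + in_win(pop.fills)) / pop.config.ppp_rate
        assert prof["total_cost"].sum() == pytest.approx(emitted, rel=1e-9)


@pytest.fixture(scope="module")
def profiles(small_population):
    pop = small_population
    tl = pop.true_labels.set_index("patient_id")
    return build_patient_profiles(pop.events, pop.fills, tl["severity"], WINDOWS)


class TestStratifiedTables:
    def test_weighted_mean_identity_per_component(self, profiles):
        """sum_c n_c * mean_c == N * overall mean, for every component row."""
        table = category_cost_table(profiles)
        for comp, sub in table.groupby("component"):
            strata = sub[sub["severity"] != "all"]
            overall = sub[sub["severity"] == "all"].iloc[0]
            lhs = (strata["n"] * strata["mean_all"]).sum()
            assert lhs == pytest.approx(overall["n"] * overall["mean_all"], rel=1e-9), comp

    def test_users_only_vs_all_members_identity(self, profiles):
        table = category_cost_table(profiles).set_index(["component", "severity"])
        row = table.loc[("total", "all")]
        # component used by everyone: total cost among users == all-members sum
        assert row["n_users"] * row["mean_users"] == pytest.approx(
            row["n"] * row["mean_all"]
            - (row["n"] - row["n_users"]) * 0.0
        )

    def test_structural_zero_cells_flagged(self, profiles):
        table = category_cost_table(profiles).set_index(["component", "severity"])
        assert table.loc[("ed_visit", 1), "structural_zero"]
        assert table.loc[("ed_visit", 1), "n_users"] == 0
        assert not table.loc[("ed_visit", 2), "structural_zero"]

    def test_single_patient_stratum_sd_zero(self):
        prof = pd.DataFrame(
            {
                "severity": [1],
                "n_SABA": [1],
                "cost_SABA": [100.0],
                "total_cost": [100.0],
                "any_service_cost": [0.0],
                "any_medication_cost": [100.0],
            },
            index=pd.Index(["a"], name="patient_id"),
        )
        for comp in ("ed_visit", "hospitalization", "specialized_physician_visit",
                     "general_physician_visit", "other_ambulatory", "ICS", "ICS_LABA",
                     "LABA", "LM", "theophylline", "OCS"):
            prof[f"n_{comp}"] = 0
            prof[f"cost_{comp}"] = 0.0
        table = category_cost_table(prof).set_index(["component", "severity"])
        assert table.loc[("total", 1), "mean_all"] == 100.0
        assert table.loc[("total", 1), "sd_all"] == 0.0

    def test_utilization_percentages_match_configuration(self, small_population, profiles):
        """Observed user shares track the configured Bernoulli probabilities."""
        cfg = small_population.config
        util = utilization_table(profiles).set_index(["component", "severity"])
        for comp, sev in [("ICS", 1), ("ICS", 4)]:
            p = cfg.utilization_probs[comp][sev - 1]
            row = util.loc[(comp, sev)]
            se = np.sqrt(p * (1 - p) / row["n"])
            assert abs(row["pct_users"] / 100.0 - p) < 3 * se + 1e-12

    def test_shares_sum_to_100(self, profiles):
        shares = cost_distribution_shares(category_cost_table(profiles))
        sums = shares.groupby("severity")["share_pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_single_component_cohort_share_is_100(self):
        prof = pd.DataFrame(
            {
                "severity": [1, 1],
                "total_cost": [10.0, 30.0],
                "any_service_cost": [10.0, 30.0],
                "any_medication_cost": [0.0, 0.0],
            },
            index=pd.Index(["a", "b"], name="patient_id"),
        )
        for comp in ("ed_visit", "hospitalization", "specialized_physician_visit",
                     "general_physician_visit", "other_ambulatory", "ICS", "ICS_LABA",
                     "LABA", "LM", "theophylline", "OCS", "SABA"):
            prof[f"n_{comp}"] = 0
            prof[f"cost_{comp}"] = 0.0
        prof["n_general_physician_visit"] = [1, 1]
        prof["cost_general_physician_visit"] = [10.0, 30.0]
        shares = cost_distribution_shares(category_cost_table(prof))
        row = shares[(shares["severity"] == 1) & (shares["component"] == "general_physician_visit")]
        assert row["share_pct"].iloc[0] == pytest.approx(100.0)


class TestPrintedIdentities:
    def test_overall_mean(self):
        assert overall_mean_from_cells(SIZES, TOTAL_MEANS) == pytest.approx(330.5355, abs=1e-3)

    def test_total_annual_cost(self):
        assert total_annual_cost(SIZES, TOTAL_MEANS) == pytest.approx(6_746_230.0)

    def test_component_shares(self):
        med = (16.0, 147.0, 563.0, 1370.0)
        hosp = (0.0, 239.0, 368.0, 662.0)
        assert component_share(SIZES, med, TOTAL_MEANS) == pytest.approx(46.1, abs=0.05)
        assert component_share(SIZES, hosp, TOTAL_MEANS) == pytest.approx(31.8, abs=0.05)

    def test_category_contribution_and_shares(self):
        assert category_contribution(SIZES, TOTAL_MEANS, 4) == pytest.approx(37.47, abs=0.01)
        np.testing.assert_allclose(
            category_shares(SIZES), (69.53, 18.03, 6.90, 5.54), atol=0.005
        )


class TestSensitivity:
    def _profiles_and_demo(self):
        prof = pd.DataFrame(
            {
                "severity": [1, 2, 3, 4],
                "total_cost": [100.0, 200.0, 300.0, 400.0],
                "any_service_cost": [100.0, 200.0, 300.0, 400.0],
                "any_medication_cost": [0.0] * 4,
            },
            index=pd.Index(list("abcd"), name="patient_id"),
        )
        demo = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "age": [3.0, 50.0, 70.0, 50.0],
                "copd": [0, 0, 1, 1],
                "rhinitis": [0, 0, 0, 0],
            }
        )
        return prof, demo

    def test_known_share_removed(self):
        prof, demo = self._profiles_and_demo()
        rep = sensitivity_exclusion(prof, demo, ("copd",), age_bands=((45, 59),))
        assert rep["n_excluded"] == 2
        assert rep["total_change_pct"] == pytest.approx(-70.0)
        band = rep["age_subgroups"][0]
        assert band["mean_before"] == pytest.approx(300.0)
        assert band["mean_after"] == pytest.approx(200.0)

    def test_unheld_flag_changes_nothing(self):
        prof, demo = self._profiles_and_demo()
        rep = sensitivity_exclusion(prof, demo, ("rhinitis",), age_bands=())
        assert rep["total_change_pct"] == 0.0

    def test_excluding_everyone_flags_empty_cohort(self):
        prof, demo = self._profiles_and_demo()
        demo["copd"] = 1
        rep = sensitivity_exclusion(prof, demo, ("copd",), age_bands=())
        assert rep["empty_cohort"]
        assert rep["total_change_pct"] == pytest.approx(-100.0)
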