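"""Scenario trajectories, decay schedules, orchestration and PSA."""

import numpy as np
import pandas as pd
import pytest

import saltshift as ss
from saltshift.exposure import POOLED_SLOPE
from saltshift.scenarios import DEFAULT_RR, validate_tables


class TestSaltTrajectory:
    @pytest.mark.parametrize("baseline, sid, expected_decrement", [
        (10.3, 1, 0.383),   # 8 g/day by 2025, men
        (8.2, 1, 0.033),    # 8 g/day by 2025, women
        (10.3, 2, 0.300),   # 7 g/day by 2030, men
        (8.2, 2, 0.109),    # 7 g/day by 2030, women
        (10.3, 3, 0.482),   # 5 g/day by 2030, men
        (8.2, 3, 0.291),    # 5 g/day by 2030, women
    ])
    def test_annual_decrements(self, baseline, sid, expected_decrement):
        spec = ss.DEFAULT_SCENARIOS[sid]
        traj = ss.salt_target_trajectory(baseline, spec)
        decrement = traj[0] - traj[1]
        assert round(decrement, 3) == expected_decrement
        assert traj[-1] == pytest.approx(spec.target)

    def test_cohort_below_target_is_unchanged(self):
        traj = ss.salt_target_trajectory(7.0, ss.DEFAULT_SCENARIOS[1], n_years=10)
        np.testing.assert_array_equal(traj, 7.0)

    def test_intake_holds_at_target_after_target_year(self):
        traj = ss.salt_target_trajectory(10.0, ss.DEFAULT_SCENARIOS[1], n_years=20)
        np.testing.assert_allclose(traj[6:], 8.0)

    def test_target_year_before_base_rejected(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.ScenarioSpec(1, 8.0, 2019)


class TestDecaySchedule:
    def test_scenario7_effect_zero_beyond_2045(self):
        years = np.arange(2019, 2060)
        frac = ss.decay_schedule(ss.DEFAULT_SCENARIOS[7], years)
        lookup = dict(zip(years, frac))
        assert lookup[2025] == 1.0 and lookup[2030] == 1.0
        assert lookup[2031] == 0.75 and lookup[2036] == 0.5
        assert lookup[2041] == 0.25 and lookup[2045] == 0.25
        assert lookup[2046] == 0.0 and lookup[2059] == 0.0

    def test_scenario8_effect_zero_beyond_2050(self):
        years = np.arange(2019, 2060)
        frac = ss.decay_schedule(ss.DEFAULT_SCENARIOS[8], years)
        lookup = dict(zip(years, frac))
        assert lookup[2050] == 0.25 and lookup[2051] == 0.0

    def test_fractions_non_increasing_after_target(self):
        years = np.arange(2026, 2080)
        frac = ss.decay_schedule(ss.DEFAULT_SCENARIOS[7], years)
        assert (np.diff(frac) <= 0).all()

    def test_geometric_reading_available(self):
        spec = ss.ScenarioSpec(7, 8.0, 2025, horizon="lifetime", decay=True,
                               decay_mode="geometric")
        frac = ss.decay_schedule(spec, np.arange(2019, 2050))
        lookup = dict(zip(np.arange(2019, 2050), frac))
        assert lookup[2031] == 0.25 and lookup[2036] == 0.0625

    def test_non_decay_scenario_rejected(self):
        with pytest.raises(ValueError):
            ss.decay_schedule(ss.DEFAULT_SCENARIOS[1], np.arange(2019, 2030))


class TestSchemaValidation:
    def test_missing_column_reported(self, tables):
        broken = ss.FixtureTables(
            config=tables.config,
            population=tables.population.drop(columns=["population"]),
            exposure=tables.exposure, disease_rates=tables.disease_rates,
            costs=tables.costs)
        with pytest.raises(ss.SchemaError, match="population"):
            validate_tables(broken)

    def test_negative_rate_reported_with_rows(self, tables):
        bad = tables.disease_rates.copy()
        bad.loc[3, "incidence"] = -0.1
        broken = ss.FixtureTables(config=tables.config,
                                  population=tables.population,
                                  exposure=tables.exposure,
                                  disease_rates=bad, costs=tables.costs)
        with pytest.raises(ss.SchemaError, match="incidence"):
            validate_tables(broken)


class TestDeterministicRuns:
    def test_null_scenario_produces_exact_zeros(self, model):
        spec = ss.ScenarioSpec(1, 20.0, 2025)   # target above every baseline
        res = model.run_scenario(spec)
        assert (res.incidence["averted"] == 0.0).all()
        assert (res.mortality["averted"] == 0.0).all()
        assert (res.halys["haly_gained"] == 0.0).all()
        assert (res.costs["savings_musd"] == 0.0).all()
        assert (res.hypertension["prevalence_reduction_pct"] == 0.0).all()

    def test_deeper_targets_dominate(self, results_all):
        """Scenario 3 >= 2 >= 1 in every headline output (same fixture)."""
        for metric in ("averted", ):
            for attr in ("incidence", "mortality"):
                vals = [getattr(results_all[i], attr)
                        .groupby("sex")["averted"].sum()["both"]
                        for i in (1, 2, 3)]
                assert vals[2] > vals[1] > vals[0] > 0
        halys = [results_all[i].halys.set_index("sex")
                 .haly_gained_discounted["both"] for i in (1, 2, 3)]
        assert halys[2] > halys[1] > halys[0] > 0
        costs = [results_all[i].costs.groupby("sex")["savings_musd"].sum()["both"]
                 for i in (1, 2, 3)]
        assert costs[2] > costs[1] > costs[0] > 0

    def test_lifetime_horizon_dominates_target_horizon(self, results_all):
        for short, long in ((1, 4), (2, 5), (3, 6)):
            for attr in ("incidence", "mortality"):
                s = getattr(results_all[short], attr).set_index(["disease", "sex"])
                l = getattr(results_all[long], attr).set_index(["disease", "sex"])
                assert (l["averted"] >= s["averted"] - 1e-9).all()

    def test_decay_scenarios_between_base_and_sustained(self, results_all):
        for base_id, sustained_id, decay_id in ((1, 4, 7), (2, 5, 8), (3, 6, 9)):
            get = lambda i: results_all[i].halys.set_index("sex") \
                .haly_gained_discounted["both"]
            assert get(base_id) < get(decay_id) < get(sustained_id)

    def test_haly_gains_nonnegative_in_all_scenarios(self, results_all):
        for res in results_all.values():
            assert (res.halys["haly_gained_discounted"] >= 0).all()

    def test_men_gain_more_than_women(self, results_all):
        """Higher male salt intake and SBP => larger male relative reductions."""
        for sid in (1, 2, 3):
            for attr in ("incidence", "mortality"):
                df = getattr(results_all[sid], attr).set_index(["disease", "sex"])
                for disease in ("ischaemic", "haemorrhagic"):
                    assert (df.loc[(disease, "male"), "relative_reduction_pct"]
                            > df.loc[(disease, "female"), "relative_reduction_pct"])

    def test_haemorrhagic_reductions_exceed_ischaemic(self, results_all):
        """Steeper haemorrhagic RR per mmHg => larger relative incidence drop."""
        for sid in (1, 2, 3):
            df = results_all[sid].incidence.set_index(["disease", "sex"])
            assert (df.loc[("haemorrhagic", "both"), "relative_reduction_pct"]
                    > df.loc[("ischaemic", "both"), "relative_reduction_pct"])

    def test_run_deterministic_convenience(self, tables):
        results = ss.run_deterministic(tables, [1])
        assert set(results) == {1}
        assert isinstance(results[1], ss.ScenarioResult)


def _degenerate_spec(tables, n_draws=5, seed=0):
    cfg = tables.config
    dists = {
        "salt_bp_slope": ss.ParameterDistribution(
            "normal", {"mean": POOLED_SLOPE, "sd": 0.0}),
        "rr_ischaemic": ss.ParameterDistribution(
            "lognormal", {"median": DEFAULT_RR["ischaemic"], "sigma_log": 0.0}),
        "rr_haemorrhagic": ss.ParameterDistribution(
            "lognormal", {"median": DEFAULT_RR["haemorrhagic"], "sigma_log": 0.0}),
        "cost_ischaemic": ss.ParameterDistribution(
            "gamma", {"mean": cfg.cost_per_case["ischaemic"], "cv": 0.0}),
        "cost_haemorrhagic": ss.ParameterDistribution(
            "gamma", {"mean": cfg.cost_per_case["haemorrhagic"], "cv": 0.0}),
    }
    return ss.PSASpec(n_draws=n_draws, seed=seed, distributions=dists)


class TestPSA:
    def test_same_seed_gives_identical_summary(self, tables, model):
        spec = ss.default_psa_spec(tables, n_draws=10, seed=5)
        a = ss.run_psa(tables, spec, [1], model=model)
        b = ss.run_psa(tables, spec, [1], model=model)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_degenerate_distributions_collapse_to_point(self, tables, model):
        res = ss.run_psa(tables, _degenerate_spec(tables), [1], model=model)
        np.testing.assert_allclose(res.summary["ui_low"], res.summary["point"],
                                   rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(res.summary["ui_high"], res.summary["point"],
                                   rtol=1e-9, atol=1e-9)

    def test_invalid_distribution_rejected_before_running(self):
        with pytest.raises(ss.InvalidConfigError):
            ss.ParameterDistribution("gamma", {"mean": -5.0, "cv": 0.2})
        with pytest.raises(ss.InvalidConfigError):
            ss.ParameterDistribution("normal", {"mean": 1.0, "sd": -0.1})
        with pytest.raises(ss.InvalidConfigError):
            ss.PSASpec(n_draws=1)

    def test_small_sample_falls_inside_reference_interval(self, tables, model):
        """Resampling consistency: most draws of the hypertension-prevalence
        delta from a small PSA fall inside the larger run's 95% interval."""
        metric = "hypertension_prevalence_reduction_pct_both"
        big = ss.run_psa(tables, ss.default_psa_spec(tables, n_draws=600, seed=11),
                         [1], model=model)
        small = ss.run_psa(tables, ss.default_psa_spec(tables, n_draws=150, seed=12),
                           [1], model=model)
        row = big.summary.set_index("metric").loc[metric]
        vals = small.draws[metric].to_numpy()
        inside = ((vals >= row["ui_low"]) & (vals <= row["ui_high"])).mean()
        assert inside >= 0.93
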