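import numpy as np
import pytest

from ifcea import AnaemiaCEA
from ifcea.model import ARM_IFC, ARM_NON_IFC


class TestFit:
    def test_calibration_hits_config_targets(self, fitted):
        assert fitted.end_prevalence(ARM_NON_IFC) == pytest.approx(0.36, abs=1e-4)
        assert fitted.end_prevalence(ARM_IFC) == pytest.approx(0.27, abs=1e-4)

    def test_ifc_arm_never_worse(self, fitted):
        ifc = fitted.trajectories[ARM_IFC].prevalence_series()
        non = fitted.trajectories[ARM_NON_IFC].prevalence_series()
        assert np.all(ifc <= non + 1e-12)

    def test_costs_and_icer_consistent(self, fitted):
        r = fitted.cea
        assert fitted.arm_costs[ARM_IFC] == pytest.approx(291.6)
        assert fitted.arm_costs[ARM_NON_IFC] == pytest.approx(199.8)
        assert r.incremental_cost == pytest.approx(91.8)
        assert r.icer_per_disability_day.value == pytest.approx(
            91.8 / fitted.cea.incremental_effect_days, rel=1e-12
        )
        # fortification lowers burden, so the day-denominated ICER is negative
        assert r.icer_per_disability_day.value < 0
        assert fitted.averted.disability_days > 0

    def test_summary_reports_decision_quantities(self, fitted):
        s = fitted.summary()
        for token in ("ICER", "cost-effective", "net monetary benefit", "7.79 million"):
            assert token in s

    def test_cea_frame_matches_results(self, fitted):
        frame = fitted.cea_frame().set_index("quantity")["value"]
        assert frame["icer_usd_per_disability_day"] == pytest.approx(
            fitted.cea.icer_per_disability_day.value
        )
        assert frame["disability_days_averted"] == pytest.approx(
            fitted.averted.disability_days
        )

    def test_individual_mode_close_to_deterministic(self, small_config):
        model = AnaemiaCEA.from_config(small_config)
        det = model.fit(mode="cohort_fractions")
        micro = model.fit(mode="individual_microsim", seed=11)
        # non-IFC arm has ~1900 children at n=2000: allow 3 binomial SEs
        p = det.trajectories[ARM_NON_IFC].prevalence_series()
        q = micro.trajectories[ARM_NON_IFC].prevalence_series()
        se = np.sqrt(p * (1 - p) / 1900)
        assert np.all(np.abs(p - q) <= 4 * se + 0.01)

    def test_fixed_relative_risk_respected(self, small_config):
        cfg = {**small_config, "transitions": {"ifc_relative_risk": 0.5}}
        res = AnaemiaCEA.from_config(cfg).fit()
        assert res.params["ifc_relative_risk"] == 0.5

    def test_from_dataframe_roundtrip(self, fitted, small_config):
        df = fitted.model.cohort.df
        res = AnaemiaCEA.from_dataframe(df, small_config).fit()
        assert res.end_prevalence(ARM_NON_IFC) == pytest.approx(0.36, abs=1e-4)

    def test_paper_style_start_prevalences(self):
        cfg = {
            "expansion": {"n": 2000},
            "transitions": {"start_prevalence": {"non_ifc": 0.57, "ifc": 0.59}},
        }
        res = AnaemiaCEA.from_config(cfg).fit()
        t1 = {a: res.trajectories[a].prevalence_series()[0] for a in res.trajectories}
        assert res.end_prevalence(ARM_NON_IFC) == pytest.approx(0.36, abs=1e-4)
        assert res.end_prevalence(ARM_IFC) == pytest.approx(0.27, abs=1e-4)
        assert t1[ARM_IFC] < 0.59 and t1[ARM_NON_IFC] < 0.57


class TestSensitivityIntegration:
    def test_tornado_complete_and_ifc_cost_leads_costs(self, fitted):
        ow = fitted.one_way()
        assert sorted(ow.parameters()) == sorted(fitted.params)
        t = ow.table.set_index("parameter")["swing"]
        cost_swings = {k: v for k, v in t.items() if k.endswith("per_day")}
        assert max(cost_swings, key=cost_swings.get) == "ifc_increment_per_day"
        assert cost_swings["home_food_per_day"] == pytest.approx(0.0, abs=1e-9)

    def test_psa_seed_reproducible(self, fitted):
        a = fitted.run_psa(n_runs=25, seed=9)
        b = fitted.run_psa(n_runs=25, seed=9)
        assert np.array_equal(a.samples["icer"], b.samples["icer"])
        assert a.median_icer <= a.iqr[1] and a.median_icer >= a.iqr[0]

    def test_psa_median_stable_across_seeds(self, fitted):
        """Medians from independent seeds agree within the bootstrap 95%
        interval of the median."""
        a = fitted.run_psa(n_runs=400, seed=1)
        b = fitted.run_psa(n_runs=400, seed=2)
        rng = np.random.default_rng(0)
        icers = a.samples["icer"].to_numpy()
        boots = np.median(
            rng.choice(icers, size=(500, len(icers)), replace=True), axis=1
        )
        lo, hi = np.quantile(boots, [0.025, 0.975])
        assert lo <= b.median_icer <= hi

    def test_psa_stratification(self, fitted):
        res = fitted.run_psa(n_runs=20, seed=4, stratify_by="sex")
        assert res.by_stratum is not None
        assert set(res.by_stratum["stratum"]) == {"sex=boy", "sex=girl"}

    def test_ceac_at_extremes(self, fitted):
        psa = fitted.run_psa(n_runs=50, seed=6)
        curve = fitted.ceac(psa, wtp_grid=np.array([0.0, 1e6]))
        assert curve.p_cost_effective[0] == 0.0  # fortification always costs more
        assert curve.p_cost_effective[1] == 1.0  # and always averts burden


class TestPlots:
    def test_plot_methods_return_axes(self, fitted):
        psa = fitted.run_psa(n_runs=10, seed=8)
        curve = fitted.ceac(psa)
        assert fitted.plot_prevalence() is not None
        assert fitted.plot_tornado() is not None
        assert fitted.plot_ce_plane(psa) is not None
        assert fitted.plot_ceac(curve) is not None
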