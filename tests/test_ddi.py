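import numpy as np
import pytest

from ketopbpk.absorption import DoseEvent, SOLUTION
from ketopbpk.ddi import (
    DDIScenario,
    SHIPPED_SCENARIOS,
    VICTIM_DOSES_MG,
    apply_overrides,
    default_ddi_scenario,
    perpetrator_compounds,
    run_ddi_study,
    run_dfi_study,
    scenario_sweep,
)

from conftest import FAST_SOLVER


class TestOverrides:
    def test_scalar_and_process_overrides(self):
        comps = apply_overrides(
            perpetrator_compounds(),
            {"ketoconazole.logP": 3.0, "ketoconazole.k_cat.AADAC": 0.5, "m1.fu": 0.02},
        )
        ktz = next(c for c in comps if c.name == "ketoconazole")
        m1 = next(c for c in comps if c.name == "m1")
        assert ktz.logP == 3.0 and m1.fu == 0.02
        assert [p.k_cat for p in ktz.processes if p.protein == "AADAC"] == [0.5]

    def test_ki_override_moves_surrogate_km(self):
        comps = apply_overrides(perpetrator_compounds(), {"ketoconazole.K_i.CYP3A4": 0.016})
        ktz = next(c for c in comps if c.name == "ketoconazole")
        assert ktz.ki_for("CYP3A4") == 0.016
        assert [p.K_M for p in ktz.processes if p.protein == "CYP3A4"] == [0.016]

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            apply_overrides(perpetrator_compounds(), {"ketoconazole.nonsense": 1.0})


class TestDFIStudies:
    def test_identical_states_give_unit_ratios(self):
        report = run_dfi_study(
            200.0, t_end=24.0, solver_opts=FAST_SOLVER, effect_state="fasted"
        )
        assert report.ratios["fed"]["AUC_last"].ratio == pytest.approx(1.0)
        assert report.ratios["fed"]["C_max"].ratio == pytest.approx(1.0)

    def test_food_effect_at_200mg(self):
        """Fed state delays T_max and lowers C_max at the low dose."""
        report = run_dfi_study(200.0, t_end=48.0, solver_opts=FAST_SOLVER)
        assert report.arms["fed"]["T_max"] > report.arms["fasted"]["T_max"]
        assert report.ratios["fed"]["C_max"].ratio < 1.0

    def test_food_effect_on_cmax_fades_at_800mg(self):
        report = run_dfi_study(800.0, t_end=48.0, solver_opts=FAST_SOLVER)
        assert 0.5 <= report.ratios["fed"]["C_max"].ratio <= 1.5

    def test_verdicts_against_observed_ratio(self):
        report = run_dfi_study(
            400.0, t_end=48.0, solver_opts=FAST_SOLVER,
            observed_ratios={"AUC_last": 1.59},
        )
        verdict = report.verdicts["fed"]["AUC_last"]
        assert set(verdict) == {"observed", "predicted", "within_guest", "within_twofold"}
        assert verdict["within_twofold"]


@pytest.fixture(scope="module")
def midazolam_concomitant_report():
    ddi = default_ddi_scenario("midazolam", gap_h=0.0, n_ktz_days=2)
    return run_ddi_study(ddi, scenarios=("P", "P+M1", "P+M1+M2"))


class TestDDIStudies:
    def test_no_perpetrator_gives_unit_ratios(self):
        vic = [DoseEvent("midazolam", VICTIM_DOSES_MG["midazolam"], 0.0, SOLUTION, "fasted")]
        ddi = DDIScenario("midazolam", "P+M1+M2", [], vic, 0.0)
        report = run_ddi_study(ddi)
        assert report.ratios["P+M1+M2"]["AUC_last"].ratio == pytest.approx(1.0)
        assert report.ratios["P+M1+M2"]["C_max"].ratio == pytest.approx(1.0)

    def test_strong_cyp3a4_interaction_direction(self, midazolam_concomitant_report):
        ratios = midazolam_concomitant_report.ratios
        assert ratios["P+M1+M2"]["AUC_last"].ratio > 2.0  # pronounced exposure increase

    def test_monotone_across_scenarios(self, midazolam_concomitant_report):
        ratios = [
            midazolam_concomitant_report.ratios[sc]["AUC_last"].ratio
            for sc in ("P", "P+M1", "P+M1+M2")
        ]
        assert ratios[0] <= ratios[1] <= ratios[2]

    def test_reference_and_effect_share_victim_regimen(self, midazolam_concomitant_report):
        hashes = set(midazolam_concomitant_report.config_hashes.values())
        assert len(hashes) == 1

    def test_scenario_filter_equivalent_to_infinite_ki(self):
        """Dropping M2 from the scenario equals sending its K_i to infinity."""
        from ketopbpk.ddi import build_ktz_model
        from ketopbpk.engine import simulate

        vic_t = 24.0
        regimen = [
            DoseEvent("ketoconazole", 400.0, 0.0),
            DoseEvent("midazolam", 7.5, vic_t, SOLUTION, "fasted"),
        ]
        m_filtered = build_ktz_model(regimen, scenario="P+M1", victim="midazolam")
        m_huge_ki = build_ktz_model(
            regimen, scenario="P+M1+M2", victim="midazolam",
            overrides={"m2.K_i.CYP3A4": 1e15, "m2.K_i.P-gp": 1e15},
        )
        out = []
        for model in (m_filtered, m_huge_ki):
            res = simulate(model, vic_t + 12.0, 0.25, solver_opts=FAST_SOLVER)
            mask = res.times >= vic_t
            out.append(np.trapezoid(res.plasma_conc("midazolam")[mask], res.times[mask]))
        assert out[0] == pytest.approx(out[1], rel=1e-6)


class TestScenarioSweep:
    def test_empty_gap_list(self):
        assert scenario_sweep("midazolam", []).empty

    def test_sweep_order_independent(self):
        kwargs = dict(n_ktz_days=1, scenarios=("P",))
        a = scenario_sweep("alprazolam", [0.0, 8.0], **kwargs)
        b = scenario_sweep("alprazolam", [8.0, 0.0], **kwargs)
        assert np.allclose(a.to_numpy(), b.to_numpy())
        assert list(a.index) == [0.0, 8.0]


class TestSensitivityRanking:
    def test_lipophilicity_and_fraction_unbound_dominate(self):
        """Exposure after 7 days of 200 mg once daily reacts most strongly to
        the parent's lipophilicity and plasma protein binding."""
        from ketopbpk.ddi import sensitivity_ranking

        df = sensitivity_ranking(dose=200.0, n_doses=7)
        top5 = set(df.head(5)["parameter"])
        assert "ketoconazole.logP" in top5
        assert "ketoconazole.fu" in top5
        # sensitivities are finite and the ranking is by |S| of the parent
        s = df["S_ketoconazole"].abs().to_numpy()
        assert np.all(np.isfinite(s))
        assert np.all(s[:-1] >= s[1:] - 1e-12)


class TestShippedScenarios:
    def test_registry_entries_simulatable_and_conservative(self):
        from ketopbpk.ddi import build_ktz_model
        from ketopbpk.engine import simulate

        name = "single_400_fasted_solution"
        spec = SHIPPED_SCENARIOS[name]
        model = build_ktz_model(spec["regimen"], spec["prandial_state"])
        res = simulate(model, 24.0, 0.25, solver_opts=FAST_SOLVER)
        assert res.mass_balance_error() < 0.005
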