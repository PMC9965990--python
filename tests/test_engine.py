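import copy

import numpy as np
import pytest

from ketopbpk.absorption import DoseEvent, KETOCONAZOLE_TABLET, SOLUTION
from ketopbpk.compound import CompoundParameters
from ketopbpk.engine import (
    PBPKModel,
    apparent_km,
    assemble_rhs,
    build_network,
    first_order_enzyme_rate,
    mm_rate,
    simulate,
)
from ketopbpk.physiology import build_reference_individual

from conftest import FAST_SOLVER


class TestKineticLaws:
    def test_apparent_km_without_inhibitors(self):
        assert apparent_km(0.008, []) == 0.008

    def test_inhibitor_at_ki_doubles_km(self):
        assert apparent_km(0.008, [(0.008, 0.008)]) == pytest.approx(0.016)

    def test_two_inhibitors_at_their_ki(self):
        assert apparent_km(7.00, [(0.022, 0.022), (0.119, 0.119)]) == pytest.approx(21.00)

    def test_mm_half_saturation(self):
        v = mm_rate(C_unbound=0.5, K_M_app=0.5, protein_amount=2.0, k_cat=3.0)
        assert v == pytest.approx(0.5 * 2.0 * 3.0)

    def test_mm_saturation_limit(self):
        vmax = 2.0 * 3.0
        assert mm_rate(1e9, 0.5, 2.0, 3.0) == pytest.approx(vmax, rel=1e-6)

    def test_mm_first_order_limit(self):
        km = 0.5
        c = km / 100.0
        v = mm_rate(c, km, 2.0, 3.0)
        assert v == pytest.approx((2.0 * 3.0 / km) * c, rel=0.01)

    def test_first_order_rate(self):
        assert first_order_enzyme_rate(1.0, 0.09, 1.0, 1.0) == pytest.approx(0.09)
        assert first_order_enzyme_rate(0.0, 0.09, 1.0, 1.0) == 0.0
        assert first_order_enzyme_rate(2.0, 0.09, 1.0, 1.0) == pytest.approx(
            2 * first_order_enzyme_rate(1.0, 0.09, 1.0, 1.0)
        )


def _inert_probe(fu=1.0, gfr_fraction=0.0) -> CompoundParameters:
    return CompoundParameters(
        name="probe",
        MW=400.0,
        pKa_list=[],
        solubility_points=[(7.0, 1e4)],
        logP=1.0,
        fu=fu,
        GFR_fraction=gfr_fraction,
    )


def _blood_only_individual():
    """Reference individual reduced to one finite volume (venous blood)."""
    ind = build_reference_individual()
    for name, organ in ind.organs.items():
        if name != "venous_blood":
            organ.volume = 1e-4
    return ind


class TestDistributionDynamics:
    def test_conservation_without_elimination(self, individual):
        probe = _inert_probe(gfr_fraction=0.0)
        model = assemble_rhs(individual, [probe])
        y0 = model.initial_state()
        y0[model.index["probe"]["ven"]] = 100.0
        res = simulate(model, 24.0, 1.0, solver_opts=FAST_SOLVER, y0=y0)
        totals = res.trajectory.sum(axis=1)
        assert np.allclose(totals, 100.0, rtol=1e-6)
        # and the amount really redistributes out of the blood
        assert res.trajectory[-1, model.index["probe"]["ven"]] < 90.0

    def test_one_compartment_reduction_matches_exponential(self):
        """Blood shell + renal filtration collapses to C0 * exp(-k t)."""
        ind = _blood_only_individual()
        probe = _inert_probe(fu=1.0, gfr_fraction=1.0)
        probe.membrane_permeability = 0.0  # no cellular uptake anywhere
        model = assemble_rhs(ind, [probe])
        y0 = model.initial_state()
        y0[model.index["probe"]["ven"]] = 100.0
        res = simulate(model, 8.0, 0.25, solver_opts={"rtol": 1e-10, "atol": 1e-14}, y0=y0)
        # well-mixed volume: all extracellular space (cells are inaccessible)
        v_total = sum(o.extracellular_volume for o in ind.organs.values())
        cl = ind.GFR / 1000.0  # fu = 1, GFR_fraction = 1
        q_kid = ind.organs["kidney"].blood_flow
        k = (q_kid * cl / (q_kid + cl)) / v_total * 60.0  # 1/h, flow-limited kidney
        mask = res.times >= 0.5  # past the vascular mixing transient
        conc = res.plasma_conc("probe")[mask]
        t = res.times[mask]
        predicted = conc[0] * np.exp(-k * (t - t[0]))
        assert np.max(np.abs(conc / predicted - 1.0)) < 1e-3

    def test_zero_dose_regimen_is_identically_zero(self, individual, trio):
        model = assemble_rhs(individual, trio)
        res = simulate(model, 2.0, 0.5, solver_opts=FAST_SOLVER)
        assert np.all(res.trajectory == 0.0)

    def test_solver_tolerance_convergence(self, individual, trio):
        reg = [DoseEvent("ketoconazole", 200.0, 0.0, KETOCONAZOLE_TABLET, "fasted")]
        net = build_network(trio, "P+M1+M2")
        aucs = []
        for opts in ({"rtol": 1e-6, "atol": 1e-8}, {"rtol": 1e-8, "atol": 1e-10}):
            model = assemble_rhs(individual, trio, net, reg, "fasted")
            res = simulate(model, 24.0, 0.1, solver_opts=opts)
            aucs.append(np.trapezoid(res.plasma_conc("ketoconazole"), res.times))
        assert abs(aucs[1] - aucs[0]) / aucs[1] < 1e-3

    def test_linear_regime_dose_proportionality(self, individual, trio):
        """At micro-doses every saturable process is first-order."""
        aucs = []
        for dose in (0.01, 0.02):
            reg = [DoseEvent("ketoconazole", dose, 0.0, SOLUTION, "fasted")]
            model = assemble_rhs(individual, trio, regimen=reg, prandial_state="fasted")
            res = simulate(model, 24.0, 0.25, solver_opts=FAST_SOLVER)
            aucs.append(np.trapezoid(res.plasma_conc("ketoconazole"), res.times))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=0.01)


class TestWholeBodySimulation:
    def test_mass_balance(self, single_400_fasted):
        assert single_400_fasted.mass_balance_error("ketoconazole") < 0.005

    def test_m2_never_in_plasma(self, single_400_fasted):
        assert np.all(single_400_fasted.plasma_conc("m2") == 0.0)

    def test_metabolites_appear(self, single_400_fasted):
        assert single_400_fasted.tissue_conc("m1", "liver").max() > 0
        assert single_400_fasted.tissue_conc("m2", "liver").max() > 0

    def test_liver_kinetics_ordering(self, single_400_fasted):
        """M2 peaks later and declines more slowly than the parent in liver cells."""
        res = single_400_fasted
        t = res.times
        ktz = res.tissue_conc("ketoconazole", "liver")
        m2 = res.tissue_conc("m2", "liver")
        assert t[m2.argmax()] > t[ktz.argmax()]
        late = t >= 42.0
        slope = lambda c: np.polyfit(t[late], np.log(c[late]), 1)[0]
        assert slope(m2) > slope(ktz)  # both negative; m2 shallower

    def test_scenario_with_absent_inhibitor_changes_nothing(self, individual, trio):
        reg = [DoseEvent("ketoconazole", 200.0, 0.0, SOLUTION, "fasted")]
        models = {
            sc: assemble_rhs(individual, trio, build_network(trio, sc), reg, "fasted")
            for sc in ("P", "P+M1")
        }
        y = models["P"].apply_doses(models["P"].initial_state(), 0.0)
        # no M1 present anywhere: the extra inhibition entry is inert
        np.testing.assert_allclose(models["P"].rhs(0.0, y), models["P+M1"].rhs(0.0, y))

    def test_ledger_reports_all_routes(self, single_400_fasted):
        led = single_400_fasted.ledger("ketoconazole")
        assert {"urine", "feces", "AADAC->m1", "CYP3A4->sink", "UGT1A4->sink"} <= set(led)
        assert led["feces"] > 0 and led["urine"] > 0


class TestValidation:
    def test_dangling_metabolite_product_rejected(self, individual, ktz):
        with pytest.raises(ValueError, match="m1"):
            PBPKModel(individual, [ktz])

    def test_missing_protein_pool_rejected(self, ktz, m1, m2):
        ind = build_reference_individual()
        ind.pools = [p for p in ind.pools if p.protein != "AADAC"]
        with pytest.raises(ValueError, match="AADAC"):
            PBPKModel(ind, [ktz, m1, m2])

    def test_dose_for_unknown_compound_rejected(self, individual, trio):
        reg = [DoseEvent("warfarin", 5.0, 0.0, SOLUTION, "fasted")]
        with pytest.raises(ValueError, match="warfarin"):
            PBPKModel(individual, trio, regimen=reg)

    def test_negative_horizon_rejected(self, individual, trio):
        model = assemble_rhs(individual, trio)
        with pytest.raises(ValueError):
            simulate(model, -1.0)
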