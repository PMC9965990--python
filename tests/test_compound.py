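import math

import pytest
from hypothesis import given, strategies as st

from ketopbpk.compound import (
    CompoundParameters,
    ionized_fractions,
    load_compound,
    solubility_at_ph,
)
from ketopbpk.partition import cellular_permeability, partition_coefficient
from ketopbpk.physiology import OrganCompartment, build_reference_individual


class TestShippedParameterSets:
    def test_parent_spot_checks(self, ktz):
        assert ktz.fu == pytest.approx(0.01)          # 1.00 % unbound
        assert ktz.ki_for("CYP3A4") == pytest.approx(0.008)
        assert ktz.ki_for("P-gp") == pytest.approx(0.035)
        assert ktz.logP == pytest.approx(2.52)        # optimized, not literature 2.73
        assert ktz.intestinal_permeability["fasted"] == pytest.approx(1.56e-5)
        assert ktz.intestinal_permeability["fed"] == pytest.approx(9.95e-6)

    def test_km_surrogated_from_ki(self, ktz):
        """The parent's CYP3A4 and P-gp K_M equal the matching K_i values."""
        for proc in ktz.processes:
            if proc.protein in ("CYP3A4", "P-gp"):
                assert proc.K_M == ktz.ki_for(proc.protein)

    def test_metabolite_inhibition_constants(self, m1, m2):
        assert m1.ki_for("CYP3A4") == pytest.approx(0.022)
        assert m1.ki_for("P-gp") == pytest.approx(0.119)
        # M2 constants are surrogated from M1
        assert m2.ki_for("CYP3A4") == m1.ki_for("CYP3A4")
        assert m2.ki_for("P-gp") == m1.ki_for("P-gp")

    def test_m2_is_plasma_restricted_first_order(self, m2):
        assert m2.plasma_restricted
        (proc,) = m2.processes
        assert proc.kind == "FirstOrderEnzymeNormalized"
        assert proc.CL_spec == pytest.approx(0.09)

    def test_metabolic_chain(self, ktz, m1):
        assert {p.product for p in ktz.processes if p.protein == "AADAC"} == {"m1"}
        assert {p.product for p in m1.processes} == {"m2"}

    def test_surrogacy_violation_rejected(self, ktz):
        doc = {
            "name": "broken",
            "MW": 500.0,
            "solubility_points": [[7.0, 10.0]],
            "logP": 2.0,
            "fu": 0.05,
            "processes": [
                {"protein": "CYP3A4", "kind": "MichaelisMenten", "K_M": 1.0, "k_cat": 1.0}
            ],
            "inhibitions": [{"target_protein": "CYP3A4", "K_i": 0.5}],
        }
        with pytest.raises(ValueError, match="surrogacy"):
            CompoundParameters.from_dict(doc)


def _single_base(pka: float) -> CompoundParameters:
    return CompoundParameters(
        name="probe",
        MW=300.0,
        pKa_list=[(pka, "base")],
        solubility_points=[(7.0, 100.0)],
        logP=1.0,
        fu=0.5,
    )


class TestIonization:
    def test_half_protonated_at_pka(self):
        neutral, cation, anion = ionized_fractions(_single_base(6.51), 6.51)
        assert cation == pytest.approx(0.5)
        assert neutral == pytest.approx(0.5)
        assert anion == 0.0

    def test_parent_neutral_at_high_ph(self, ktz):
        neutral, _, _ = ionized_fractions(ktz, 10.0)
        assert neutral >= 0.99

    @given(st.floats(min_value=0.0, max_value=14.0))
    def test_fractions_sum_to_one(self, ph):
        ktz = load_compound("ketoconazole")
        assert sum(ionized_fractions(ktz, ph)) == pytest.approx(1.0)

    def test_ph_out_of_range_rejected(self, ktz):
        with pytest.raises(ValueError):
            ionized_fractions(ktz, 15.0)


class TestSolubility:
    @pytest.mark.parametrize("ph,expected", [(7.0, 5.40), (1.2, 2.03e4), (7.5, 6.00)])
    def test_exact_at_tabulated_points(self, ktz, ph, expected):
        assert solubility_at_ph(ktz, ph) == pytest.approx(expected)

    def test_log_linear_interpolation(self, ktz):
        # midpoint between (7.0, 5.40) and (7.5, 6.00) in log10 space
        expected = math.sqrt(5.40 * 6.00)
        assert solubility_at_ph(ktz, 7.25) == pytest.approx(expected, rel=1e-9)

    def test_constant_extrapolation(self, ktz):
        assert solubility_at_ph(ktz, 0.5) == pytest.approx(2.03e4)
        assert solubility_at_ph(ktz, 9.0) == pytest.approx(6.00)


def _water_organ() -> OrganCompartment:
    return OrganCompartment(
        name="waterbag",
        volume=1.0,
        blood_flow=0.1,
        sub_fractions=(0.0, 0.0, 1.0),
        composition={
            "water": 1.0,
            "neutral_lipid": 0.0,
            "phospholipid": 0.0,
            "protein": 0.07,
            "acidic_phospholipid": 0.0,
        },
        intracellular_pH=7.4,
    )


def _neutral_probe(logp: float, mw: float = 400.0) -> CompoundParameters:
    return CompoundParameters(
        name="probe",
        MW=mw,
        pKa_list=[],
        solubility_points=[(7.0, 100.0)],
        logP=logp,
        fu=1.0,
    )


class TestPartitionCoefficients:
    def test_pure_water_limit(self):
        kp = partition_coefficient(_neutral_probe(0.0), _water_organ(), "Berezhkovskiy")
        assert kp == pytest.approx(1.0, rel=0.10)

    @pytest.mark.parametrize("method", ["Berezhkovskiy", "RodgersRowland", "SchmittChargeDependent"])
    def test_monotone_in_logp(self, individual, method):
        liver = individual.organs["liver"]
        kps = [partition_coefficient(_neutral_probe(lp), liver, method) for lp in (0.0, 1.0, 2.0, 3.0)]
        assert all(a <= b for a, b in zip(kps, kps[1:]))
        assert all(kp > 0 for kp in kps)

    def test_method_selection_honoured(self, individual, ktz, m1):
        liver = individual.organs["liver"]
        assert partition_coefficient(ktz, liver) != partition_coefficient(m1, liver)
        assert ktz.partition_method == "Berezhkovskiy"
        assert m1.partition_method == "RodgersRowland"

    def test_missing_composition_rejected(self, ktz):
        organ = _water_organ()
        organ.composition.pop("water")
        with pytest.raises(ValueError, match="composition"):
            partition_coefficient(ktz, organ, "Berezhkovskiy")


class TestCellularPermeability:
    def test_increases_with_logp(self):
        ps = [cellular_permeability(_neutral_probe(lp), "PKSimStandard") for lp in (0.5, 1.5, 2.5)]
        assert ps[0] < ps[1] < ps[2]

    def test_decreases_with_mw(self):
        ps = [
            cellular_permeability(_neutral_probe(2.0, mw), "PKSimStandard")
            for mw in (300.0, 450.0, 600.0)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_deterministic(self, m1):
        assert cellular_permeability(m1) == cellular_permeability(m1)

    def test_override_takes_precedence(self):
        probe = _neutral_probe(2.0)
        probe.membrane_permeability = 3.3e-6
        assert cellular_permeability(probe) == 3.3e-6
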