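"""Drug-food and drug-drug interaction study orchestration.

Builds paired simulations (fed vs fasted; victim with vs without the
perpetrator), computes Eq.-3-style interaction ratios of AUC_last and C_max,
applies the Guest and two-fold acceptance criteria, and sweeps perpetrator
scenarios (P, P+M1, P+M1+M2) across victim-perpetrator dosing time gaps.

The victim models shipped with the package are reduced synthetic fixtures:
whole-body distribution with a single CYP3A4 Michaelis-Menten elimination in
liver and gut wall (alfentanil, alprazolam, midazolam, triazolam) or P-gp
efflux plus renal filtration (digoxin). They exercise the interaction
machinery; they are not reproductions of published victim models.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .absorption import DoseEvent, Formulation, KETOCONAZOLE_TABLET, SOLUTION, build_gi_tract
from .compound import CompoundParameters, load_compound
from .engine import PBPKModel, SimulationResult, build_network, simulate
from .physiology import Individual, build_reference_individual
from .pk import InteractionRatio, auc_last, cmax_tmax, interaction_ratio, within_guest, within_twofold

__all__ = [
    "VICTIM_NAMES",
    "VICTIM_DOSES_MG",
    "DDIScenario",
    "StudyReport",
    "perpetrator_compounds",
    "apply_overrides",
    "build_ktz_model",
    "simulate_ktz_plasma",
    "run_dfi_study",
    "run_ddi_study",
    "default_ddi_scenario",
    "scenario_sweep",
    "SHIPPED_SCENARIOS",
]

VICTIM_NAMES = ("alfentanil", "alprazolam", "midazolam", "triazolam", "digoxin")

#: Typical single oral doses (mg) used by the victim fixtures.
VICTIM_DOSES_MG = {
    "midazolam": 7.5,
    "alprazolam": 1.0,
    "alfentanil": 1.0,
    "triazolam": 0.25,
    "digoxin": 0.5,
}


def perpetrator_compounds() -> list[CompoundParameters]:
    """Ketoconazole and its metabolites, freshly loaded from the shipped files."""
    return [load_compound(n) for n in ("ketoconazole", "m1", "m2")]


# --------------------------------------------------------------------------
# parameter overrides (fitting and sensitivity analysis)
# --------------------------------------------------------------------------

def apply_overrides(
    compounds: list[CompoundParameters], overrides: dict[str, float]
) -> list[CompoundParameters]:
    """Return deep copies of the compounds with named parameters replaced.

    Names: ``<compound>.logP``, ``<compound>.fu``,
    ``<compound>.k_cat.<PROTEIN>``, ``<compound>.K_M.<PROTEIN>``,
    ``<compound>.CL_spec.<PROTEIN>``, ``<compound>.K_i.<PROTEIN>`` and
    ``<compound>.intestinal_permeability.<state>``. Because the parent's K_M
    for CYP3A4 and P-gp is surrogated from the matching K_i, overriding a
    K_i also moves the tied K_M.
    """
    out = copy.deepcopy(compounds)
    by_name = {c.name: c for c in out}
    for key, value in overrides.items():
        parts = key.split(".")
        comp = by_name.get(parts[0])
        if comp is None:
            raise KeyError(f"unknown compound in override {key!r}")
        if len(parts) == 2 and parts[1] in ("logP", "fu"):
            setattr(comp, parts[1], float(value))
        elif len(parts) == 3 and parts[1] in ("k_cat", "K_M", "CL_spec"):
            hits = [p for p in comp.processes if p.protein == parts[2]]
            if not hits:
                raise KeyError(f"{parts[0]} has no process for protein {parts[2]}")
            for proc in hits:
                setattr(proc, parts[1], float(value))
        elif len(parts) == 3 and parts[1] == "K_i":
            hits = [i for i in comp.inhibitions if i.target_protein == parts[2]]
            if not hits:
                raise KeyError(f"{parts[0]} has no inhibition of {parts[2]}")
            for inh in hits:
                inh.K_i = float(value)
            for proc in comp.processes:  # surrogacy tie
                if proc.protein == parts[2] and proc.K_M is not None:
                    proc.K_M = float(value)
        elif len(parts) == 3 and parts[1] == "intestinal_permeability":
            comp.intestinal_permeability[parts[2]] = float(value)
        else:
            raise KeyError(f"unrecognized override {key!r}")
    return out


def build_ktz_model(
    regimen: list[DoseEvent],
    prandial_state: str = "fasted",
    scenario: str = "P+M1+M2",
    overrides: dict[str, float] | None = None,
    victim: str | None = None,
    individual: Individual | None = None,
    GET_min: float | None = None,
) -> PBPKModel:
    """Assemble the standard parent-metabolites model (plus optional victim)."""
    compounds = perpetrator_compounds()
    if victim is not None:
        compounds.append(load_compound(victim))
    if overrides:
        compounds = apply_overrides(compounds, overrides)
    network = build_network(compounds, scenario)
    individual = individual or build_reference_individual()
    tract = build_gi_tract(prandial_state)
    if GET_min is not None:
        tract.GET = GET_min
    return PBPKModel(individual, compounds, network, regimen, prandial_state, tract)


def simulate_ktz_plasma(
    regimen: list[DoseEvent],
    times_h: np.ndarray,
    prandial_state: str = "fasted",
    overrides: dict[str, float] | None = None,
    compound: str = "ketoconazole",
    solver_opts: dict | None = None,
    GET_min: float | None = None,
) -> np.ndarray:
    """Plasma concentrations (ng/mL) of one compound at requested times."""
    model = build_ktz_model(regimen, prandial_state, overrides=overrides, GET_min=GET_min)
    times_h = np.asarray(times_h, dtype=float)
    grid = np.unique(np.concatenate([[0.0], times_h]))
    result = simulate(model, float(grid[-1]), grid, solver_opts=solver_opts)
    conc = result.plasma_conc(compound)
    return np.interp(times_h, result.times, conc)


# --------------------------------------------------------------------------
# study reports
# --------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Per-arm PK summaries, interaction ratios and acceptance verdicts."""

    arms: dict[str, dict]                      # arm -> {"AUC_last":..., "C_max":..., "T_max":...}
    ratios: dict[str, dict[str, InteractionRatio]]  # arm -> metric -> ratio vs reference
    verdicts: dict[str, dict[str, dict]] = field(default_factory=dict)
    config_hashes: dict[str, str] = field(default_factory=dict)
    results: dict[str, SimulationResult] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for arm, metrics in self.ratios.items():
            for metric, ratio in metrics.items():
                rows.append(
                    {
                        "arm": arm,
                        "metric": metric,
                        "ratio": round(ratio.ratio, 2),
                        "effect": ratio.effect,
                        "reference": ratio.reference,
                    }
                )
        return pd.DataFrame(rows)


def _arm_summary(result: SimulationResult, compound: str, t_start: float) -> dict:
    mask = result.times >= t_start
    t = result.times[mask] - t_start
    c = result.plasma_conc(compound)[mask]
    c_max, t_max = cmax_tmax(t, c)
    return {"AUC_last": auc_last(t, c), "C_max": c_max, "T_max": t_max}


def _regimen_hash(regimen: list[DoseEvent]) -> str:
    doc = [
        (d.compound, d.dose, d.time, d.formulation.kind, tuple(map(tuple, d.formulation.particle_bins)))
        for d in sorted(regimen, key=lambda d: (d.time, d.compound))
    ]
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


# --------------------------------------------------------------------------
# DFI
# --------------------------------------------------------------------------

def run_dfi_study(
    dose: float,
    formulation: Formulation = KETOCONAZOLE_TABLET,
    n_doses: int = 1,
    dosing_interval_h: float = 24.0,
    t_end: float = 48.0,
    observed_ratios: dict[str, float] | None = None,
    solver_opts: dict | None = None,
    effect_state: str = "fed",
) -> StudyReport:
    """Paired fed (effect) vs fasted (reference) ketoconazole simulations.

    Both arms share the identical regimen; only the prandial state (gastric
    emptying time and intestinal permeability) differs. Ratios follow the
    effect/reference convention with fasted as reference. ``effect_state``
    exists for self-comparison checks (both arms fasted gives ratios of 1).
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    arms: dict[str, dict] = {}
    results: dict[str, SimulationResult] = {}
    hashes: dict[str, str] = {}
    for arm_name, state in (("fasted", "fasted"), ("fed", effect_state)):
        regimen = [
            DoseEvent("ketoconazole", dose, dosing_interval_h * i, formulation, state)
            for i in range(n_doses)
        ]
        model = build_ktz_model(regimen, state)
        res = simulate(model, t_end, 0.1, solver_opts=solver_opts)
        arms[arm_name] = _arm_summary(res, "ketoconazole", 0.0)
        results[arm_name] = res
        hashes[arm_name] = _regimen_hash(
            [DoseEvent("ketoconazole", dose, dosing_interval_h * i, formulation, "fasted") for i in range(n_doses)]
        )
    ratios = {
        "fed": {
            m: interaction_ratio(arms["fed"][m], arms["fasted"][m], m)
            for m in ("AUC_last", "C_max")
        }
    }
    verdicts: dict[str, dict[str, dict]] = {}
    if observed_ratios:
        verdicts["fed"] = {}
        for metric, obs in observed_ratios.items():
            pred = ratios["fed"][metric].ratio
            verdicts["fed"][metric] = {
                "observed": obs,
                "predicted": pred,
                "within_guest": within_guest(pred, obs),
                "within_twofold": within_twofold(pred, obs),
            }
    return StudyReport(arms=arms, ratios=ratios, verdicts=verdicts, config_hashes=hashes, results=results)


# --------------------------------------------------------------------------
# DDI
# --------------------------------------------------------------------------

@dataclass
class DDIScenario:
    """One victim-perpetrator study design."""

    victim: str
    scenario: str                       # P | P+M1 | P+M1+M2
    perpetrator_regimen: list[DoseEvent]
    victim_regimen: list[DoseEvent]
    dosing_gap: float = 0.0             # h, victim dose minus nearest preceding perpetrator dose

    def __post_init__(self) -> None:
        if self.victim not in VICTIM_NAMES:
            raise ValueError(f"unknown victim {self.victim!r}; options: {VICTIM_NAMES}")


def default_ddi_scenario(
    victim: str,
    gap_h: float = 0.0,
    scenario: str = "P+M1+M2",
    ktz_dose: float = 400.0,
    n_ktz_days: int = 4,
    victim_dose: float | None = None,
) -> DDIScenario:
    """Once-daily perpetrator for several days; victim dosed ``gap_h`` after
    the last perpetrator dose (negative: victim first)."""
    perp = [
        DoseEvent("ketoconazole", ktz_dose, 24.0 * d, KETOCONAZOLE_TABLET, "fasted")
        for d in range(n_ktz_days)
    ]
    t_victim = 24.0 * (n_ktz_days - 1) + gap_h
    if t_victim < 0:
        raise ValueError("victim dose time before simulation start")
    vic = [DoseEvent(victim, victim_dose or VICTIM_DOSES_MG[victim], t_victim, SOLUTION, "fasted")]
    return DDIScenario(victim, scenario, perp, vic, gap_h)


def run_ddi_study(
    ddi: DDIScenario,
    scenarios: tuple[str, ...] | None = None,
    observation_h: float = 24.0,
    solver_opts: dict | None = None,
    keep_results: bool = False,
) -> StudyReport:
    """Victim PK with and without the perpetrator under requested scenarios.

    The reference arm carries the identical victim regimen and no
    perpetrator; interaction ratios are effect/reference per metric.
    """
    scenarios = scenarios or (ddi.scenario,)
    t_victim = ddi.victim_regimen[0].time
    t_end = t_victim + observation_h
    opts = solver_opts or {"rtol": 1e-6, "atol": 1e-8}

    def one_arm(scenario: str) -> tuple[dict, str, SimulationResult]:
        regimen = list(ddi.victim_regimen)
        if scenario != "none":
            regimen = regimen + list(ddi.perpetrator_regimen)
        model = build_ktz_model(regimen, "fasted", scenario=scenario, victim=ddi.victim)
        res = simulate(model, t_end, 0.1, solver_opts=opts)
        return _arm_summary(res, ddi.victim, t_victim), _regimen_hash(ddi.victim_regimen), res

    arms: dict[str, dict] = {}
    hashes: dict[str, str] = {}
    results: dict[str, SimulationResult] = {}
    for sc in ("none",) + tuple(scenarios):
        arms[sc], hashes[sc], res = one_arm(sc)
        if keep_results:
            results[sc] = res
    assert len(set(hashes.values())) == 1, "victim regimens differ across arms"

    ratios = {
        sc: {
            m: interaction_ratio(arms[sc][m], arms["none"][m], m)
            for m in ("AUC_last", "C_max")
        }
        for sc in scenarios
    }
    return StudyReport(arms=arms, ratios=ratios, config_hashes=hashes, results=results)


def scenario_sweep(
    victim: str,
    gaps: list[float],
    scenarios: tuple[str, ...] = ("P", "P+M1", "P+M1+M2"),
    metric: str = "AUC_last",
    **kwargs,
) -> pd.DataFrame:
    """Ratio matrix (gap x scenario) for one victim.

    Deterministic and order-independent: each cell is an independent pair of
    simulations fully determined by its design.
    """
    rows = []
    for gap in sorted(gaps):
        ddi = default_ddi_scenario(victim, gap_h=gap, **kwargs)
        report = run_ddi_study(ddi, scenarios=scenarios)
        row = {"gap_h": gap}
        for sc in scenarios:
            row[sc] = report.ratios[sc][metric].ratio
        rows.append(row)
    return pd.DataFrame(rows).set_index("gap_h") if rows else pd.DataFrame()


# --------------------------------------------------------------------------
# local sensitivity analysis
# --------------------------------------------------------------------------

#: Parameters analyzed by default: those optimized during model building or
#: assumed to impact exposure.
SENSITIVITY_PARAMETERS = (
    "ketoconazole.logP",
    "ketoconazole.fu",
    "GET",
    "ketoconazole.intestinal_permeability.fasted",
    "ketoconazole.k_cat.AADAC",
    "ketoconazole.k_cat.CYP3A4",
    "ketoconazole.k_cat.UGT1A4",
    "ketoconazole.K_M.AADAC",
    "ketoconazole.K_i.CYP3A4",
    "m1.k_cat.FMO3",
)


def _parameter_value(name: str, prandial_state: str) -> float:
    from .absorption import GET_FASTED_MIN, GET_FED_MIN

    if name == "GET":
        return GET_FED_MIN if prandial_state == "fed" else GET_FASTED_MIN
    compounds = perpetrator_compounds()
    comp = {c.name: c for c in compounds}[name.split(".")[0]]
    parts = name.split(".")
    if parts[1] in ("logP", "fu"):
        return getattr(comp, parts[1])
    if parts[1] == "intestinal_permeability":
        return comp.intestinal_permeability[parts[2]]
    if parts[1] == "K_i":
        return comp.ki_for(parts[2])
    proc = next(p for p in comp.processes if p.protein == parts[2])
    return getattr(proc, parts[1])


def sensitivity_ranking(
    dose: float = 200.0,
    n_doses: int = 7,
    dosing_interval_h: float = 24.0,
    prandial_state: str = "fasted",
    parameters: tuple[str, ...] = SENSITIVITY_PARAMETERS,
    outputs: tuple[str, ...] = ("ketoconazole", "m1"),
    relative_perturbation: float = 0.1,
    solver_opts: dict | None = None,
) -> pd.DataFrame:
    """Normalized local sensitivities of AUC to single-parameter changes.

    Central differences at +/- ``relative_perturbation``; one row per
    parameter with the sensitivity of each output compound's plasma AUC,
    sorted by the parent's |S|.
    """
    from .pk import local_sensitivity

    opts = solver_opts or {"rtol": 1e-5, "atol": 1e-7}
    t_end = dosing_interval_h * n_doses + 24.0
    regimen = [
        DoseEvent("ketoconazole", dose, dosing_interval_h * i, KETOCONAZOLE_TABLET, prandial_state)
        for i in range(n_doses)
    ]

    cache: dict = {}

    def auc_for(name: str, compound: str):
        def run(value: float) -> float:
            key = (name, round(value, 12))
            if key not in cache:
                overrides, get_min = {}, None
                if name == "GET":
                    get_min = value
                else:
                    overrides[name] = value
                model = build_ktz_model(
                    regimen, prandial_state, overrides=overrides, GET_min=get_min
                )
                cache[key] = simulate(model, t_end, 0.25, solver_opts=opts)
            res = cache[key]
            return auc_last(res.times, res.plasma_conc(compound))
        return run

    rows = []
    for name in parameters:
        base = _parameter_value(name, prandial_state)
        row = {"parameter": name, "value": base}
        for compound in outputs:
            row[f"S_{compound}"] = local_sensitivity(
                auc_for(name, compound), base, relative_perturbation
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.reindex(
        df[f"S_{outputs[0]}"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# shipped scenario registry (used by the analysis drivers and the tests)
# --------------------------------------------------------------------------

def _single(dose, state, t_end=48.0):
    return {
        "regimen": [DoseEvent("ketoconazole", dose, 0.0, KETOCONAZOLE_TABLET, state)],
        "prandial_state": state,
        "t_end": t_end,
    }


SHIPPED_SCENARIOS = {
    "single_200_fasted_tablet": _single(200.0, "fasted"),
    "single_200_fed_tablet": _single(200.0, "fed"),
    "single_400_fasted_tablet": _single(400.0, "fasted"),
    "single_400_fed_tablet": _single(400.0, "fed"),
    "single_600_fasted_tablet": _single(600.0, "fasted"),
    "single_400_fasted_solution": {
        "regimen": [DoseEvent("ketoconazole", 400.0, 0.0, SOLUTION, "fasted")],
        "prandial_state": "fasted",
        "t_end": 48.0,
    },
    "multidose_200_bid_3d": {
        "regimen": [
            DoseEvent("ketoconazole", 200.0, 12.0 * i, KETOCONAZOLE_TABLET, "fed")
            for i in range(6)
        ],
        "prandial_state": "fed",
        "t_end": 96.0,
    },
}
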