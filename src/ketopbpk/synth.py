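"""Synthetic observed datasets with the structure of digitized clinical means.

Every downstream stage (evaluation metrics, fitting, DFI/DDI workflows) is
exercised against synthetic data: the model itself simulates a "truth"
profile, which is then sampled at study times and perturbed with
proportional log-normal noise scaled for a mean of ``n_subjects``
(sd = cv / sqrt(n)), with censoring below the limit of quantification.
Profiles exist for ketoconazole and M1 only; M2 was never measured in plasma
and is never "observed" here either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .absorption import DoseEvent, KETOCONAZOLE_TABLET, SOLUTION
from .ddi import DDIScenario, build_ktz_model
from .engine import simulate
from .pk import ObservedProfile

__all__ = [
    "ErrorModel",
    "SyntheticStudy",
    "DEFAULT_LOQ",
    "generate_observed_profiles",
    "generate_study_table",
    "generate_ddi_dataset",
    "dose_grid_studies",
    "build_predictor",
]

#: Default limits of quantification (ng/mL) per measured compound.
DEFAULT_LOQ = {"ketoconazole": 1.0, "m1": 0.25}

MEASURABLE = ("ketoconazole", "m1")


@dataclass
class ErrorModel:
    """Residual-error model applied to simulated truth profiles."""

    kind: str = "proportional-lognormal"   # or additive+proportional
    cv: float = 0.2
    additive_sd: float = 0.0               # ng/mL
    loq: float | dict = field(default_factory=lambda: dict(DEFAULT_LOQ))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional-lognormal", "additive+proportional"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if self.cv < 0 or self.additive_sd < 0:
            raise ValueError("cv and additive_sd must be non-negative")

    def loq_for(self, compound: str) -> float:
        if isinstance(self.loq, dict):
            return float(self.loq.get(compound, 0.0))
        return float(self.loq)


@dataclass
class SyntheticStudy:
    """Design of one synthetic mean-profile study."""

    study_id: str
    regimen: list[DoseEvent]
    sampling_times: np.ndarray    # h
    n_subjects: int = 12
    declared_state: str = "unknown"
    true_state: str = "fasted"
    compounds_measured: tuple[str, ...] = ("ketoconazole",)

    def __post_init__(self) -> None:
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        bad = [c for c in self.compounds_measured if c not in MEASURABLE]
        if bad:
            raise ValueError(
                f"{self.study_id}: compounds {bad} cannot be measured in plasma "
                f"(only {MEASURABLE})"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


def generate_observed_profiles(
    study: SyntheticStudy,
    error: ErrorModel,
    overrides: dict[str, float] | None = None,
    solver_opts: dict | None = None,
) -> list[ObservedProfile]:
    """Simulate the truth model and emit noisy mean profiles for one study.

    Noise is multiplicative log-normal with standard deviation
    ``cv / sqrt(n_subjects)`` on the log scale (plus an optional additive
    normal component); values below the LOQ are dropped. Deterministic for a
    fixed error-model seed.
    """
    rng = np.random.default_rng(error.seed)
    model = build_ktz_model(study.regimen, study.true_state, overrides=overrides)
    grid = np.unique(np.concatenate([[0.0], study.sampling_times]))
    result = simulate(model, float(grid[-1]), grid,
                      solver_opts=solver_opts or {"rtol": 1e-6, "atol": 1e-8})
    out = []
    for comp in study.compounds_measured:
        truth = np.interp(study.sampling_times, result.times, result.plasma_conc(comp))
        sd_log = error.cv / math.sqrt(study.n_subjects)
        noisy = truth * np.exp(rng.normal(0.0, sd_log, size=truth.shape)) if sd_log > 0 else truth.copy()
        if error.kind == "additive+proportional" and error.additive_sd > 0:
            noisy = noisy + rng.normal(0.0, error.additive_sd / math.sqrt(study.n_subjects), size=truth.shape)
        loq = error.loq_for(comp)
        keep = noisy >= loq
        out.append(
            ObservedProfile(
                study_id=study.study_id,
                compound=comp,
                times=study.sampling_times[keep],
                concentrations=np.maximum(noisy[keep], 0.0),
                dose_metadata=list(study.regimen),
                prandial_state=study.declared_state,
            )
        )
    return out


# --------------------------------------------------------------------------
# study designs
# --------------------------------------------------------------------------

_STANDARD_TIMES = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0])


def dose_grid_studies(
    doses: tuple[float, ...] = (100.0, 200.0, 400.0, 600.0, 800.0, 1200.0),
    measure_m1: bool = True,
) -> list[SyntheticStudy]:
    """Single/multiple oral doses across the studied range, as solutions and
    tablets under fasted and fed conditions."""
    studies = []
    for dose in doses:
        for form_name, form in (("tab", KETOCONAZOLE_TABLET), ("sol", SOLUTION)):
            for state in ("fasted", "fed"):
                sid = f"ktz_{int(dose)}mg_{form_name}_{state}"
                studies.append(
                    SyntheticStudy(
                        study_id=sid,
                        regimen=[DoseEvent("ketoconazole", dose, 0.0, form, state)],
                        sampling_times=_STANDARD_TIMES,
                        true_state=state,
                        declared_state=state,
                        compounds_measured=("ketoconazole", "m1") if measure_m1 else ("ketoconazole",),
                    )
                )
    # one multiple-dose arm (twice daily implies fed by the assumption rules)
    studies.append(
        SyntheticStudy(
            study_id="ktz_200mg_bid_3d",
            regimen=[
                DoseEvent("ketoconazole", 200.0, 12.0 * i, KETOCONAZOLE_TABLET, "fed")
                for i in range(6)
            ],
            sampling_times=np.concatenate([_STANDARD_TIMES, [36.0, 48.0, 60.0, 72.0]]),
            true_state="fed",
            declared_state="fed",
            compounds_measured=("ketoconazole", "m1") if measure_m1 else ("ketoconazole",),
        )
    )
    return studies


def generate_study_table(
    n_studies: int,
    missing_state_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic study metadata with some prandial states masked as unknown.

    Columns include the declared state (possibly ``unknown``), the true
    state, the observed T_max, doses per day and the single dose, so the
    prandial-state assumption rules can be checked against ground truth.
    """
    if not 0.0 <= missing_state_fraction <= 1.0:
        raise ValueError("missing_state_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    doses = rng.choice([100.0, 200.0, 400.0, 600.0, 800.0, 1200.0], size=n_studies)
    per_day = rng.choice([1, 1, 1, 2], size=n_studies)
    true_fed = (per_day > 1) | (doses >= 800.0) | (rng.random(n_studies) < 0.3)
    tmax = np.where(true_fed, rng.uniform(2.5, 4.5, n_studies), rng.uniform(1.0, 2.0, n_studies))
    masked = rng.random(n_studies) < missing_state_fraction
    rows = []
    for i in range(n_studies):
        true_state = "fed" if true_fed[i] else "fasted"
        rows.append(
            {
                "study_id": f"synth_{i:03d}",
                "single_dose_mg": doses[i],
                "doses_per_day": int(per_day[i]),
                "observed_tmax_h": round(float(tmax[i]), 2),
                "declared_state": "unknown" if masked[i] else true_state,
                "true_state": true_state,
            }
        )
    return pd.DataFrame(rows)


def build_predictor(
    studies: list[SyntheticStudy],
    solver_opts: dict | None = None,
):
    """Prediction function for ``pk.fit_parameters`` over a set of studies.

    Returns ``predict(params, profile)`` where ``params`` maps override names
    (see ``ddi.apply_overrides``) to values. Each study is simulated once per
    parameter vector and shared across its measured compounds.
    """
    by_id = {s.study_id: s for s in studies}
    opts = solver_opts or {"rtol": 1e-5, "atol": 1e-7}
    cache: dict = {}

    def predict(params: dict[str, float], profile) -> np.ndarray:
        key = (tuple(sorted(params.items())), profile.study_id)
        skey = key[0]
        study = by_id[profile.study_id]
        res = cache.get((skey, profile.study_id))
        if res is None:
            model = build_ktz_model(study.regimen, study.true_state, overrides=dict(params))
            grid = np.unique(np.concatenate([[0.0], study.sampling_times]))
            res = simulate(model, float(grid[-1]), grid, solver_opts=opts)
            if len(cache) > 64:
                cache.clear()
            cache[(skey, profile.study_id)] = res
        return np.interp(profile.times, res.times, res.plasma_conc(profile.compound))

    return predict


def generate_ddi_dataset(
    ddi: DDIScenario,
    error: ErrorModel,
    sampling_times: np.ndarray | None = None,
    report=None,
) -> tuple[list[ObservedProfile], list[ObservedProfile]]:
    """Paired noisy victim profiles: (reference, effect).

    The reference arm carries the identical victim regimen and no
    perpetrator doses. With cv = 0, interaction ratios recomputed from these
    profiles equal the truth ratios exactly. A precomputed ``report`` (from
    ``run_ddi_study`` with ``keep_results=True``) can be reused across error
    seeds to avoid re-simulating the truth.
    """
    from .ddi import run_ddi_study  # local import to avoid cycle at module load

    if report is None:
        report = run_ddi_study(ddi, scenarios=(ddi.scenario,), keep_results=True)
    t_victim = ddi.victim_regimen[0].time
    times = (
        np.asarray(sampling_times, dtype=float)
        if sampling_times is not None
        else _STANDARD_TIMES
    )
    rng = np.random.default_rng(error.seed)

    def sample(arm: str, tag: str) -> list[ObservedProfile]:
        res = report.results[arm]
        truth = np.interp(t_victim + times, res.times, res.plasma_conc(ddi.victim))
        sd_log = error.cv
        noisy = truth * np.exp(rng.normal(0.0, sd_log, size=truth.shape)) if sd_log > 0 else truth
        keep = noisy > 0
        return [
            ObservedProfile(
                study_id=f"{ddi.victim}_{tag}",
                compound=ddi.victim,
                times=times[keep],
                concentrations=noisy[keep],
            )
        ]
    reference = sample("none", "reference")
    effect = sample(ddi.scenario, "effect")
    return reference, effect
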