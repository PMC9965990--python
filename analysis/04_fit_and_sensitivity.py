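#!/usr/bin/env python
"""Parameter estimation on synthetic data and local sensitivity analysis.

First, the catalytic constants of the metabolic network are re-estimated
from synthetic noisy mean profiles (proportional log-normal error, cv 0.2,
mean of 12 subjects) generated by the model itself across eight study
designs spanning 100-1200 mg: the optimizer recovers the generating values.
Second, the local sensitivity of the parent's exposure after 7 days of
200 mg once daily is ranked across the optimized/assumed parameters.

Writes results/fit_recovery.json and results/sensitivity.tsv.
"""

import json
from pathlib import Path

import numpy as np

from ketopbpk.absorption import DoseEvent, KETOCONAZOLE_TABLET, SOLUTION
from ketopbpk.ddi import sensitivity_ranking
from ketopbpk.pk import fit_parameters
from ketopbpk.synth import ErrorModel, SyntheticStudy, build_predictor, generate_observed_profiles

OUT = Path(__file__).resolve().parents[1] / "results"
FAST = {"rtol": 1e-5, "atol": 1e-7}

TIMES = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0])
TRUTH = {
    "ketoconazole.k_cat.AADAC": 0.87,
    "ketoconazole.k_cat.CYP3A4": 0.10,
    "ketoconazole.k_cat.UGT1A4": 0.31,
    "m1.k_cat.FMO3": 378.65,
}
DESIGNS = [
    (100.0, SOLUTION, "fasted"), (200.0, KETOCONAZOLE_TABLET, "fasted"),
    (200.0, KETOCONAZOLE_TABLET, "fed"), (400.0, KETOCONAZOLE_TABLET, "fasted"),
    (400.0, SOLUTION, "fed"), (600.0, KETOCONAZOLE_TABLET, "fasted"),
    (800.0, KETOCONAZOLE_TABLET, "fed"), (1200.0, KETOCONAZOLE_TABLET, "fed"),
]


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    studies = [
        SyntheticStudy(
            study_id=f"fit_{i}",
            regimen=[DoseEvent("ketoconazole", d, 0.0, f, s)],
            sampling_times=TIMES,
            true_state=s,
            declared_state=s,
            compounds_measured=("ketoconazole", "m1"),
        )
        for i, (d, f, s) in enumerate(DESIGNS)
    ]
    profiles = []
    for i, st in enumerate(studies):
        profiles.extend(
            generate_observed_profiles(st, ErrorModel(cv=0.2, seed=seed * 100 + i), solver_opts=FAST)
        )
    predict = build_predictor(studies, FAST)
    free = {n: (v * 0.55, v * 0.05, v * 6.0) for n, v in TRUTH.items()}
    fit = fit_parameters(free, profiles, predict)
    summary = {
        name: {
            "truth": truth,
            "estimate": fit.estimates[name],
            "rel_error_pct": 100 * (fit.estimates[name] / truth - 1),
        }
        for name, truth in TRUTH.items()
    }
    (OUT / "fit_recovery.json").write_text(json.dumps(
        {"converged": fit.converged, "objective": fit.objective, "parameters": summary},
        indent=2,
    ))
    print("Recovered catalytic constants (cv 0.2, 8 synthetic studies):")
    for name, s in summary.items():
        print(f"  {name:34s} truth {s['truth']:>8.3g}  est {s['estimate']:>8.4g}  ({s['rel_error_pct']:+.1f}%)")

    df = sensitivity_ranking(dose=200.0, n_doses=7)
    df.to_csv(OUT / "sensitivity.tsv", sep="\t", index=False)
    print("\nLocal sensitivity of 7-day exposure (ranked by |S| for the parent):")
    print(df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
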