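# Ketoconazole: parent compound.
# Kinetic constants: K_M for CYP3A4 and P-gp are surrogated from the
# respective autoinhibition K_i values (no direct in vitro K_M available).
name: ketoconazole
MW: 531.43
pKa_list:
  - [2.94, base]
  - [6.51, base]
solubility_points:   # (pH, mg/L)
  - [1.2, 2.03e4]
  - [3.0, 4.30e4]
  - [6.8, 7.00]
  - [7.0, 5.40]
  - [7.5, 6.00]
logP: 2.52
fu: 0.01
partition_method: Berezhkovskiy
permeability_method: PKSimStandard
intestinal_permeability:   # cm/min
  fasted: 1.56e-5
  fed: 9.95e-6
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: false
processes:
  - {protein: AADAC,  kind: MichaelisMenten, K_M: 1.88,  k_cat: 0.87, product: m1}
  - {protein: CYP3A4, kind: MichaelisMenten, K_M: 0.008, k_cat: 0.10, product: sink}
  - {protein: UGT1A4, kind: MichaelisMenten, K_M: 7.00,  k_cat: 0.31, product: sink}
  - {protein: P-gp,   kind: ActiveEffluxMM,  K_M: 0.035, k_cat: 0.33, product: sink}
inhibitions:
  - {target_protein: CYP3A4, K_i: 0.008}
  - {target_protein: P-gp,   K_i: 0.035}
metadata:
  logP_literature: 2.73
  description: imidazole antifungal; CYP3A4/P-gp perpetrator
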