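# Synthetic victim fixture: midazolam-like CYP3A4 substrate.
# A reduced stand-in (single CYP3A4 Michaelis-Menten elimination in liver and
# gut wall) whose oral half-life and high first-pass extraction are in the
# literature range; NOT a reproduction of any published full victim model.
name: midazolam
MW: 325.8
pKa_list:
  - [6.0, base]
solubility_points:
  - [7.0, 1.0e4]
logP: 3.0
fu: 0.03
partition_method: RodgersRowland
permeability_method: PKSimStandard
intestinal_permeability:
  fasted: 3.0e-4
  fed: 3.0e-4
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: false
processes:
  - {protein: CYP3A4, kind: MichaelisMenten, K_M: 2.7, k_cat: 60.0, product: sink}
inhibitions: []
metadata:
  fixture: synthetic victim model
  fraction_metabolized_cyp3a4: ~0.9
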