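# Synthetic victim fixture: alprazolam-like low-extraction CYP3A4 substrate.
name: alprazolam
MW: 308.8
pKa_list:
  - [2.4, base]
solubility_points:
  - [7.0, 1.0e4]
logP: 2.1
fu: 0.29
partition_method: RodgersRowland
permeability_method: PKSimStandard
intestinal_permeability:
  fasted: 3.0e-4
  fed: 3.0e-4
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: false
processes:
  - {protein: CYP3A4, kind: MichaelisMenten, K_M: 300.0, k_cat: 110.0, product: sink}
inhibitions: []
metadata:
  fixture: synthetic victim model
  fraction_metabolized_cyp3a4: ~0.8
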