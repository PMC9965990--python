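# Synthetic victim fixture: digoxin-like P-gp substrate (no CYP3A4 pathway);
# eliminated by renal filtration plus P-gp-mediated biliary/intestinal efflux.
name: digoxin
MW: 780.9
pKa_list: []
solubility_points:
  - [7.0, 6.0e4]
logP: 1.26
fu: 0.71
partition_method: RodgersRowland
permeability_method: PKSimStandard
# carrier-mediated cellular access; assigned rather than correlated
membrane_permeability: 1.0e-5
intestinal_permeability:
  fasted: 4.0e-6
  fed: 4.0e-6
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: false
processes:
  - {protein: P-gp, kind: ActiveEffluxMM, K_M: 73.0, k_cat: 30.0, product: sink}
inhibitions: []
metadata:
  fixture: synthetic victim model
  fraction_metabolized_cyp3a4: 0.0
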