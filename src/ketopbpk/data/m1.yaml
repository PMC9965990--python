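# M1, N-deacetylketoconazole: formed from ketoconazole by AADAC,
# oxidized to M2 by FMO3.
name: m1
MW: 489.40
pKa_list:
  - [0.20, base]
  - [6.42, base]
  - [8.90, base]
solubility_points:
  - [6.5, 1.24e3]
logP: 3.75
fu: 0.01
partition_method: RodgersRowland
permeability_method: SchmittChargeDependent
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: false
processes:
  - {protein: FMO3, kind: MichaelisMenten, K_M: 1.77, k_cat: 378.65, product: m2}
inhibitions:
  - {target_protein: CYP3A4, K_i: 0.022}
  - {target_protein: P-gp,   K_i: 0.119}
metadata:
  logP_literature: 4.58
  fu_assumed: true
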