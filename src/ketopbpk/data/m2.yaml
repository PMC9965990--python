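# M2, N-deacetyl-N-hydroxyketoconazole: formed from M1 by FMO3 and cleared
# by an FMO3-normalized first-order process. Confined to the intracellular
# space (never observed in plasma); inhibition constants surrogated from M1.
name: m2
MW: 505.40
pKa_list:
  - [3.42, base]
  - [6.42, base]
solubility_points:
  - [6.5, 4.40e3]
logP: 4.20
fu: 0.01
partition_method: Berezhkovskiy
permeability_method: SchmittChargeDependent
GFR_fraction: 1.0
EHC_continuous_fraction: 1.0
plasma_restricted: true
processes:
  - {protein: FMO3, kind: FirstOrderEnzymeNormalized, CL_spec: 0.09, product: sink}
inhibitions:
  - {target_protein: CYP3A4, K_i: 0.022}
  - {target_protein: P-gp,   K_i: 0.119}
metadata:
  fu_assumed: true
  ki_surrogated_from: m1
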