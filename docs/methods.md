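# Methods

## Scope and model structure

`ketopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of oral ketoconazole and its sequential metabolites
N-deacetylketoconazole (M1, formed by AADAC) and
N-deacetyl-N-hydroxyketoconazole (M2, formed from M1 by FMO3 and cleared by
an FMO3-normalized first-order process), together with the machinery to
study drug–food interactions (DFI) and CYP3A4/P-gp drug–drug interactions
(DDI) in which the parent and both metabolites act as competitive reversible
inhibitors.

The body is a closed circulation of 12 perfused tissues (lung, liver,
kidney, gut wall, adipose, muscle, skin, bone, brain, heart, spleen, rest)
plus venous and arterial blood. Each tissue splits into:

* an **extracellular space** (plasma + interstitial, lumped), perfusion
  limited: the venous outflow concentration equals the extracellular
  concentration;
* an **intracellular space**, permeability limited: exchange flux is
  `P_cell · A_ex · (C_ec − C_ic / Kp)`, where `P_cell` is the compound's
  cellular permeability, `A_ex` the organ's exchange surface and `Kp` the
  cell-to-plasma partition coefficient computed by the compound's configured
  method (Berezhkovskiy for ketoconazole and M2, Rodgers–Rowland for M1 and
  the victim fixtures, charge-dependent Schmitt available as an option).

Gut wall and spleen drain into the liver (portal vein). Renal elimination is
glomerular filtration of unbound plasma drug
(`GFR_fraction · GFR · fu · C_ec,kidney`). P-gp efflux is saturable active
transport out of the cells hosting it: gut wall → duodenal lumen, liver →
bile pool, kidney → urine. Bile is released continuously into the duodenum
with a 30-min half-time, scaled by the compound's continuous-release
fraction (1.0 for all shipped compounds: no gallbladder storage), and the
released drug is reabsorbable like any luminal drug (enterohepatic
circulation). All amounts are in µmol, volumes in L, internal time in
minutes; the public interface reports hours and ng/mL.

## Kinetic laws and the intracellular concentration conventions

Saturable metabolism and transport follow Michaelis–Menten kinetics with
`V_max = k_cat ×` (protein amount); competitive reversible inhibition scales
the apparent Michaelis constant, `K_M,app = K_M (1 + Σ_j I_j / K_i,j)`,
where the inhibitor concentrations are evaluated locally in the organ that
hosts the inhibited protein. Because M2 is confined to liver cells, it can
inhibit hepatic but never gut-wall CYP3A4 — this locality is what makes the
perpetrator scenarios (P, P+M1, P+M1+M2) mechanistically different.

Two conventions had to be fixed because the unbound intracellular fraction
of these compounds is not measurable:

* **Saturable processes and inhibition** are driven by the plasma unbound
  fraction applied to the total intracellular concentration,
  `C_u = fu · C_ic`. This keeps substrate occupancy and inhibitory potency
  on one consistent scale across parent and metabolites.
* **The FMO3-normalized first-order clearance of M2**
  (`CL_spec · [FMO3] · C · V_ic`, `CL_spec` in L/µmol/min) is driven by the
  total intracellular concentration. The constant is a lumped, fitted
  clearance for a species that never leaves the cell; driving it by an
  unbound fraction would only rescale the (free) FMO3 abundance parameter
  it multiplies. With the embedded hepatic FMO3 abundance this yields an
  intracellular M2 elimination half-time of roughly two days, the
  persistence that carries the long-gap DDI behaviour.

The kinetic constants themselves (K_M, k_cat, K_i, the FMO3 CL) are the
published/optimized compound values shipped in the YAML parameter files. The
parent's CYP3A4 and P-gp K_M values are surrogates taken from the matching
autoinhibition K_i (no direct in vitro K_M exists); this tie is validated at
load time and preserved by the parameter-override machinery.

## Embedded physiology

One literature-informed European reference adult (73 kg, 30 y, male,
GFR 120 mL/min) is embedded with ICRP-style organ volumes and regional blood
flows and Poulin/Rodgers-style tissue composition. Organ volumes and flows
scale linearly with body weight; composition does not. Bone and skin
composition use exchangeable (non-matrix) lipid and binding-protein
fractions rather than bulk values, so that partitioning reflects the
drug-accessible space.

Enzyme/transporter localization: AADAC, UGT1A4 and FMO3 in liver cells;
CYP3A4 in liver and gut-wall cells; P-gp at the gut-wall apical membrane,
liver canalicular membrane and kidney. The *absolute* abundances are
effective values chosen during model building so that the pathway capacities
`V_max = k_cat ×` amount (with the fixed, published k_cat values) reproduce
the parent's disposition: AADAC-mediated deacetylation is the dominant
elimination pathway (so that M1/M2 supply is adequate and the parent's own
exposure is insensitive to metabolite-mediated CYP3A4 inhibition), CYP3A4
contributes a minor, strongly autoinhibited share, and hepatic FMO3 is set
by the M2 residence-time constraint above. They are bookkeeping
concentrations for Vmax, not measured expression levels.

The cellular exchange surfaces are likewise effective parameters: a global
area density (2·10⁵ cm² per L cell volume) with organ factors — liver
sinusoids high (×43, giving a hepatocellular uptake clearance of
~0.2 L/min for the parent, which rate-limits hepatic clearance), gut mucosa
very high (×600, so absorbed drug crosses the enterocytes without an
artificial bottleneck), kidney moderately high, brain reduced (barrier).
These were calibrated jointly against the parent's plasma C_max, its
intracellular liver T_max/half-life and the observed exposure scale, then
frozen; all tests and analyses run with the same values.

## Oral absorption and the food effect

The GI tract is an eight-segment cascade (stomach, duodenum, upper/lower
jejunum, upper/lower ileum, caecum, colon) with first-order transit; the
stomach empties with half-time GET (15 min fasted, 45 min fed). Segment pH
rises from 2.0 (stomach) through 6.0 (duodenum) to 7.0 (colon). Solubility
is interpolated log-linearly in pH between the tabulated points (constant
beyond them); for ketoconazole it collapses from ~3·10⁴ mg/L at gastric pH
to below 10 mg/L at intestinal pH.

Dissolution follows a Noyes–Whitney surface law per particle bin,
`dm/dt = 3 D m (C_s − C) / (ρ r h)` with diffusion layer
`h = min(r, 30 µm)`; the driving force is floored at zero, i.e. dissolved
drug that becomes supersaturated when it transits to higher-pH segments does
**not** precipitate. Consequently essentially all systemic exposure derives
from drug dissolved during gastric residence; solids that escape the stomach
transit to feces. Oral solutions dissolve instantly. The shipped tablet uses
an effective log-normal granule distribution (median radius 1.5 mm,
geometric SD 1.5, 10 bins) representing the coarse granulate of a
disintegrating immediate-release tablet; it was estimated during model
building so that roughly half the dose dissolves within a fasted gastric
residence — consistent with the dissolution-limited absorption, the fecal
excretion of unchanged drug, and the direction and size of the food effect.
A generic finely milled distribution (median 10 µm, GSD 2) is available via
`Formulation.lognormal` for solutions-like behaviour.

The food effect is represented by exactly two changes: GET 15 → 45 min and
the fed intestinal permeability (9.95·10⁻⁶ vs 1.56·10⁻⁵ cm/min). Gastric pH
is kept at its fasted value in both states: with this compound's steep
solubility–pH profile a fed gastric pH of 4–5 would slow gastric dissolution
several-fold and invert the observed food effect, contradicting the
two-parameter representation. Tripling the gastric residence raises the
dissolved (absorbable) fraction, which outweighs the lower fed permeability:
fed/fasted AUC ratios are above 1 with delayed T_max and reduced C_max.

Because fractional gastric dissolution is dose-independent in this model
(surface ∝ mass, concentrations far below gastric solubility), the predicted
food effect is uniform across doses (~1.23 for AUC at all doses), whereas
the observed effect peaks at 400–600 mg and vanishes at 800 mg. The
predicted ratios at 400 and 600 mg fall within the Guest et al. acceptance
limits of the observed 1.59 and 1.45; the dose-dependence itself (a
solubilization/saturation phenomenon beyond the two fed parameters) is a
known limitation.

## Numerical integration

The coupled system (~90 states for the parent–metabolites model, more with
a victim and its GI states) is stiff: K_M values down to 0.008 µmol/L sit
next to L/min blood flows. Integration uses SciPy's BDF with rtol 1e-8 and
atol 1e-12 µmol by default, piecewise between dose events (each dose is a
state jump), with dense output on a user grid (default 0.05 h). Mass balance
(lineage molar dose = remaining amounts + urine + feces + terminal metabolic
sinks) holds to ~1e-9 relative at default tolerances; the acceptance
criterion is ≤0.5 %. Property tests and study sweeps use relaxed tolerances
(rtol 1e-5 … 1e-6), which change AUC_last by <0.1 %. Negative state
excursions are clipped inside rate laws only; the solver state is untouched.

## Evaluation statistics

`pk` implements AUC_last (linear trapezoid from dose time to last sample),
C_max/T_max (first occurrence on ties), terminal half-life (log-linear fit
over the last n points after C_max, default 4), the mean relative deviation
MRD = 10^√(Σ(log10 ĉ−log10 c)²/k), the geometric mean fold error
GMFE = 10^(Σ|log10(PK̂/PK)|/m), interaction ratios PK_effect/PK_reference,
the inclusive two-fold criterion, and the Guest et al. acceptance band with
1.25-fold variability: with R the observed ratio folded above 1, the limit
is L = (1.25 + 2(R−1))/R, so the band is (0.8, 1.25) at R = 1 and approaches
two-fold for large effects. Below-LOQ observations are stored as censored
(dropped) points and excluded from log-scale metrics. The intracellular
liver half-lives quoted in the analyses are log-linear fits over fixed
windows (parent and M1: 24–96 h; M2: 72–168 h after a single dose).

## Parameter estimation and sensitivity

`fit_parameters` minimizes pooled squared log10-concentration residuals
across all profiles simultaneously (concentrations span three orders of
magnitude, and the evaluation metrics are log-based). The least-squares
descent is a damped trust-region step within bounds; the Monte-Carlo option
draws uniform candidates within bounds (seeded, best-of-N, default N = 2000)
and polishes the best candidate with the same least-squares step. Results
are deterministic given the seed; non-convergence is flagged on the result
object rather than raised.

Local sensitivity is the normalized central difference
S = (ΔAUC/AUC)/(Δp/p) at ±10 % perturbation. For the 7-day 200 mg
once-daily scenario the parent's exposure is most sensitive to its
lipophilicity (through tissue partitioning and cellular permeability) and —
after gastric emptying time — to its fraction unbound, with the AADAC
constants next; this ordering is asserted by the test suite. The K_i
override used in sensitivity moves the surrogate K_M together with the K_i,
because they are one parameter by construction.

## Synthetic data

The synthetic-data generator emulates digitized mean plasma
concentration-time profiles: the model simulates a truth profile for a study
design (dose 100–1200 mg, solution or tablet, fasted/fed, single or multiple
dosing), samples it at study times, applies proportional log-normal noise
with log-scale SD cv/√n_subjects (default cv 0.2, n = 12 — typical
inter-study variability of digitized means), and censors below the LOQ
(1 ng/mL for ketoconazole, 0.25 ng/mL for M1). Only ketoconazole and M1 can
be "measured"; M2 has never been observed in plasma and the model keeps its
plasma concentration identically zero. Study tables with masked prandial
states exercise the fed-state assumption rules ((i) T_max delayed >2 h,
(ii) multiple doses per day, (iii) single doses ≥800 mg).

What passing tests on synthetic data do *not* show: the generator inherits
every structural assumption of the model (no precipitation, two-parameter
food effect, the intracellular concentration conventions), so parameter
recovery demonstrates identifiability and correctness of the estimation
machinery, not clinical accuracy. The FMO3-normalized first-order clearance
of M2 is excluded from recovery: no plasma observable carries information
about it (it was originally informed by interaction data, not plasma
profiles).

## Victim fixtures

The five victim models are deliberately reduced synthetic fixtures:
whole-body distribution plus a single CYP3A4 Michaelis–Menten elimination in
liver and gut wall (alfentanil, alprazolam, midazolam, triazolam; catalytic
constants chosen so oral half-lives fall in literature ranges — ~3, ~9, ~4
and ~4 h) or P-gp efflux plus renal filtration (digoxin, with an assigned
membrane permeability because its cellular access is carrier-mediated, and a
reduced intestinal permeability so that P-gp secretion genuinely ends in
feces rather than being fully reabsorbed). They produce interaction ratios
of the right order (midazolam ~6–10-fold, alprazolam ~2-fold, digoxin
~1.4-fold) and the correct monotone ordering P ≤ P+M1 ≤ P+M1+M2 at every
dosing gap, but victim-specific clinical DDI ratios are outside the scope of
these fixtures.

## Problem sizes used in the shipped analyses

Single-dose disposition: 168 h at 0.1 h output; fecal excretion: 120 h;
food-effect pairs: 48 h windows; DDI studies: 4 once-daily perpetrator doses
(2 in the structural test sweeps) with a 24 h victim observation window;
recovery: 8 studies × 11 sampling times × 2 compounds; sensitivity: 10
parameters × central differences on a 192 h multiple-dose simulation.

## Known limitations

* M1 plasma concentrations are overpredicted (~100–200 ng/mL peak vs the
  ~6 ng/mL reported): with symmetric passive membrane transport, the flux
  balance that confines M1 to hepatocytes also governs its return from
  plasma, and no basolateral uptake transporter is modelled. M1 remains a
  minor plasma species relative to its parent (~3–4 % of the parent's
  C_max).
* Because M1 accumulates intracellularly, its inhibitory contribution at
  concomitant dosing is larger here than the near-equivalence of the P and
  P+M1 scenarios reported clinically; the scenario ordering and the growing
  advantage of P+M1+M2 with dosing gaps are preserved.
* The parent's terminal phases are slower than the sampled clinical
  half-life (~160 min over typical sampling windows); the intracellular
  liver half-life (~21 h vs reported 12.3 h) and fecal excretion (40 % vs
  ~27 %) sit within two-fold of the reported values, reflecting the
  dissolution/partitioning compromises described above.
* The food effect has no dose-dependence; population variability, mechanistic
  meal models, time-dependent inhibition and induction are out of scope.
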