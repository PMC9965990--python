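"""Per-compound parameters: physicochemistry, kinetics, inhibition.

Parameter sets for ketoconazole and its sequential metabolites
N-deacetylketoconazole (M1) and N-deacetyl-N-hydroxyketoconazole (M2) are
shipped as YAML files under ``ketopbpk/data``. Units follow the conventions
used throughout the package: concentrations in umol/L, solubility in mg/L,
permeabilities in cm/min, rate constants in 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "CompoundParameters",
    "KineticProcess",
    "InhibitionSpec",
    "ionized_fractions",
    "solubility_at_ph",
    "load_compound",
]

PARTITION_METHODS = ("Berezhkovskiy", "RodgersRowland", "SchmittChargeDependent")
PERMEABILITY_METHODS = ("PKSimStandard", "SchmittChargeDependent")
PROCESS_KINDS = ("MichaelisMenten", "FirstOrderEnzymeNormalized", "ActiveEffluxMM")


@dataclass
class KineticProcess:
    """One enzymatic or transport process acting on a compound."""

    protein: str
    kind: str
    product: str = "sink"            # compound name or "sink"
    K_M: float | None = None         # umol/L
    k_cat: float | None = None       # 1/min
    CL_spec: float | None = None     # L/umol/min (first-order only)

    def __post_init__(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.kind in ("MichaelisMenten", "ActiveEffluxMM"):
            if self.K_M is None or self.k_cat is None:
                raise ValueError(f"{self.kind} process requires K_M and k_cat")
            if self.K_M <= 0 or self.k_cat < 0:
                raise ValueError("K_M must be > 0 and k_cat >= 0")
            if self.CL_spec is not None:
                raise ValueError("saturable process must not carry CL_spec")
        else:
            if self.CL_spec is None or self.CL_spec < 0:
                raise ValueError("first-order process requires CL_spec >= 0")
            if self.K_M is not None or self.k_cat is not None:
                raise ValueError("first-order process must not carry K_M/k_cat")


@dataclass
class InhibitionSpec:
    """Competitive reversible inhibition of a target protein."""

    target_protein: str
    K_i: float  # umol/L
    mechanism: str = "competitive reversible"

    def __post_init__(self) -> None:
        if self.target_protein not in ("CYP3A4", "P-gp"):
            raise ValueError(f"inhibition target must be CYP3A4 or P-gp, got {self.target_protein!r}")
        if self.K_i <= 0:
            raise ValueError("K_i must be positive")


@dataclass
class CompoundParameters:
    """All drug-dependent model parameters for one compound."""

    name: str
    MW: float                                   # g/mol
    pKa_list: list[tuple[float, str]]           # (value, "acid"|"base")
    solubility_points: list[tuple[float, float]]  # (pH, mg/L)
    logP: float
    fu: float                                   # fraction unbound in plasma
    partition_method: str = "Berezhkovskiy"
    permeability_method: str = "PKSimStandard"
    membrane_permeability: float | None = None  # cm/min; overrides the correlation
    intestinal_permeability: dict[str, float] = field(default_factory=dict)  # cm/min by prandial state
    GFR_fraction: float = 1.0
    EHC_continuous_fraction: float = 1.0
    plasma_restricted: bool = False
    processes: list[KineticProcess] = field(default_factory=list)
    inhibitions: list[InhibitionSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError("MW must be positive")
        if not 0 < self.fu <= 1:
            raise ValueError(f"fu must lie in (0, 1], got {self.fu}")
        if not self.solubility_points:
            raise ValueError("at least one solubility point required")
        if any(s <= 0 for _, s in self.solubility_points):
            raise ValueError("solubilities must be strictly positive")
        if self.partition_method not in PARTITION_METHODS:
            raise ValueError(f"unknown partition method {self.partition_method!r}")
        if self.permeability_method not in PERMEABILITY_METHODS:
            raise ValueError(f"unknown permeability method {self.permeability_method!r}")
        for val, kind in self.pKa_list:
            if kind not in ("acid", "base"):
                raise ValueError(f"pKa type must be acid or base, got {kind!r}")
        self.solubility_points = sorted(self.solubility_points)
        # K_i-as-K_M surrogacy: where the same protein appears as a saturable
        # process and an inhibition target, the K_M was surrogated from K_i.
        for proc in self.processes:
            for inh in self.inhibitions:
                if proc.protein == inh.target_protein and proc.K_M is not None:
                    if not math.isclose(proc.K_M, inh.K_i, rel_tol=1e-9):
                        raise ValueError(
                            f"{self.name}: K_M for {proc.protein} must equal K_i "
                            f"(surrogacy rule): {proc.K_M} != {inh.K_i}"
                        )

    def ki_for(self, target: str) -> float | None:
        for inh in self.inhibitions:
            if inh.target_protein == target:
                return inh.K_i
        return None

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "CompoundParameters":
        return cls(
            name=doc["name"],
            MW=doc["MW"],
            pKa_list=[(float(v), k) for v, k in doc.get("pKa_list", [])],
            solubility_points=[(float(p), float(s)) for p, s in doc["solubility_points"]],
            logP=doc["logP"],
            fu=doc["fu"],
            partition_method=doc.get("partition_method", "Berezhkovskiy"),
            permeability_method=doc.get("permeability_method", "PKSimStandard"),
            membrane_permeability=doc.get("membrane_permeability"),
            intestinal_permeability=dict(doc.get("intestinal_permeability", {})),
            GFR_fraction=doc.get("GFR_fraction", 1.0),
            EHC_continuous_fraction=doc.get("EHC_continuous_fraction", 1.0),
            plasma_restricted=doc.get("plasma_restricted", False),
            processes=[KineticProcess(**p) for p in doc.get("processes", [])],
            inhibitions=[InhibitionSpec(**i) for i in doc.get("inhibitions", [])],
            metadata=doc.get("metadata", {}),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "CompoundParameters":
        return cls.from_dict(yaml.safe_load(text))


def load_compound(name: str) -> CompoundParameters:
    """Load a shipped compound parameter file (e.g. 'ketoconazole', 'm1', 'm2')."""
    pkg = resources.files("ketopbpk.data")
    path = pkg / f"{name.lower()}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        path = pkg / "victims" / f"{name.lower()}.yaml"
        try:
            text = path.read_text()
        except FileNotFoundError:
            raise ValueError(f"no shipped parameter file for compound {name!r}") from None
    return CompoundParameters.from_yaml(text)


def ionized_fractions(compound: CompoundParameters, pH: float) -> tuple[float, float, float]:
    """Henderson-Hasselbalch fractions (neutral, cationic, anionic) at a pH.

    Multiple basic/acidic centres are treated independently; the neutral
    fraction is the joint probability that every centre is uncharged, and the
    average charge per centre defines the cationic/anionic split of the rest.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    p_neutral = 1.0
    cation_load = 0.0
    anion_load = 0.0
    for pka, kind in compound.pKa_list:
        if kind == "base":
            f_ion = 1.0 / (1.0 + 10.0 ** (pH - pka))
            cation_load += f_ion
        else:
            f_ion = 1.0 / (1.0 + 10.0 ** (pka - pH))
            anion_load += f_ion
        p_neutral *= 1.0 - f_ion
    ionized = 1.0 - p_neutral
    total_load = cation_load + anion_load
    if total_load <= 0.0:
        return 1.0, 0.0, 0.0
    f_cat = ionized * cation_load / total_load
    f_an = ionized * anion_load / total_load
    return p_neutral, f_cat, f_an


def solubility_at_ph(compound: CompoundParameters, pH: float) -> float:
    """Aqueous solubility (mg/L) at a pH.

    Exact at tabulated points, log10-linear between adjacent points, constant
    beyond the tabulated range.
    """
    pts = compound.solubility_points
    phs = np.array([p for p, _ in pts])
    logs = np.log10([s for _, s in pts])
    return float(10.0 ** np.interp(pH, phs, logs))
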