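"""Reference virtual individual: organs, blood flows, tissue composition, protein pools.

The package ships a single literature-informed European reference adult
(ICRP-style organ weights and regional blood flows, Poulin/Rodgers-style
tissue composition). Organ volumes and blood flows scale linearly with body
weight; composition fractions, sub-compartment fractions and intracellular pH
are weight-invariant. Enzyme and transporter tissue distribution is embedded
as a minimal expression table restricted to the organs the model needs:
AADAC, UGT1A4 and FMO3 in liver cells, CYP3A4 in liver and gut-wall cells,
P-gp at the gut-wall apical membrane, the liver canalicular membrane and the
kidney.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = [
    "OrganCompartment",
    "ProteinPool",
    "Individual",
    "build_reference_individual",
    "protein_amount",
    "REFERENCE_DEMOGRAPHICS",
    "ORGAN_NAMES",
]

ORGAN_NAMES = (
    "venous_blood",
    "arterial_blood",
    "lung",
    "liver",
    "kidney",
    "gut_wall",
    "adipose",
    "muscle",
    "skin",
    "bone",
    "brain",
    "heart",
    "spleen",
    "rest",
)

#: Demographics of the embedded reference adult.
REFERENCE_DEMOGRAPHICS = {
    "age": 30.0,          # years
    "sex": "male",
    "body_weight": 73.0,  # kg
    "height": 176.0,      # cm
    "hematocrit": 0.45,
    "GFR": 120.0,         # mL/min
}

# Organ volumes (L, density 1 kg/L) and blood flows (L/min) for the 73 kg
# reference adult. Lung "flow" is cardiac output; gut wall and spleen drain
# into the liver (portal vein); the liver entry is the hepatic artery only.
_REFERENCE_ORGANS = {
    #  name:            (volume L, flow L/min)
    "venous_blood": (3.9, 0.0),
    "arterial_blood": (1.8, 0.0),
    "lung": (0.50, 5.60),
    "liver": (1.80, 0.30),
    "kidney": (0.31, 1.24),
    "gut_wall": (1.20, 0.75),
    "adipose": (14.0, 0.32),
    "muscle": (29.0, 0.75),
    "skin": (3.30, 0.30),
    "bone": (10.5, 0.29),
    "brain": (1.45, 0.70),
    "heart": (0.33, 0.24),
    "spleen": (0.15, 0.08),
    "rest": (3.50, 0.63),
}

# Volume sub-fractions (plasma, interstitial, intracellular). Remainder up
# to 1.0 is erythrocyte/solid matrix space. Blood compartments are all plasma
# for the purposes of this model (haematocrit handled as metadata only).
_SUB_FRACTIONS = {
    "venous_blood": (1.00, 0.00, 0.00),
    "arterial_blood": (1.00, 0.00, 0.00),
    "lung": (0.11, 0.19, 0.66),
    "liver": (0.10, 0.16, 0.70),
    "kidney": (0.11, 0.20, 0.65),
    "gut_wall": (0.07, 0.28, 0.62),
    "adipose": (0.02, 0.14, 0.80),
    "muscle": (0.03, 0.12, 0.82),
    "skin": (0.03, 0.30, 0.62),
    "bone": (0.03, 0.10, 0.82),
    "brain": (0.02, 0.16, 0.78),
    "heart": (0.06, 0.14, 0.76),
    "spleen": (0.12, 0.20, 0.64),
    "rest": (0.04, 0.15, 0.77),
}

# Tissue composition: fractional content of water, neutral lipid,
# phospholipid and protein (w/w ~ v/v at density 1). Values follow the
# composition tables commonly used with the Poulin/Rodgers partition methods.
# "ap" is the acidic-phospholipid content (mg/g ~ fraction) used by the
# charge-dependent methods. pH_ic: intracellular pH.
_COMPOSITION = {
    #  name:           water   nl      ph      protein  ap       pH_ic
    "venous_blood": (0.945, 0.0023, 0.0013, 0.070, 0.0005, 7.40),
    "arterial_blood": (0.945, 0.0023, 0.0013, 0.070, 0.0005, 7.40),
    "lung": (0.811, 0.0030, 0.0090, 0.130, 0.0005, 7.00),
    "liver": (0.751, 0.0350, 0.0250, 0.160, 0.0024, 7.00),
    "kidney": (0.783, 0.0120, 0.0240, 0.150, 0.0024, 7.00),
    "gut_wall": (0.718, 0.0480, 0.0160, 0.140, 0.0024, 7.00),
    "adipose": (0.180, 0.7900, 0.0020, 0.030, 0.0004, 7.00),
    "muscle": (0.760, 0.0220, 0.0072, 0.170, 0.0024, 7.00),
    "skin": (0.718, 0.0600, 0.0044, 0.100, 0.0013, 7.00),
    "bone": (0.439, 0.0150, 0.0011, 0.050, 0.0007, 7.00),
    "brain": (0.770, 0.0510, 0.0565, 0.080, 0.0004, 7.00),
    "heart": (0.758, 0.0115, 0.0166, 0.150, 0.0024, 7.00),
    "spleen": (0.788, 0.0077, 0.0136, 0.140, 0.0013, 7.00),
    "rest": (0.750, 0.0400, 0.0100, 0.150, 0.0013, 7.00),
}

# Minimal enzyme/transporter expression table: intracellular protein
# concentration in umol per L organ intracellular volume (membrane proteins
# referenced to the same volume for bookkeeping). Absolute levels were chosen
# during model building so that the pathway capacities (Vmax = kcat * amount)
# reproduce the disposition of ketoconazole and its metabolites; see
# docs/methods.md.
_EXPRESSION = {
    # protein: {organ: umol/L intracellular}
    "CYP3A4": {"liver": 0.30, "gut_wall": 0.30},
    "AADAC": {"liver": 9.00},
    "UGT1A4": {"liver": 24.0},
    "FMO3": {"liver": 0.0042},
    "P-gp": {"gut_wall": 0.30, "liver": 0.12, "kidney": 0.10},
}

KNOWN_PROTEINS = tuple(_EXPRESSION)


@dataclass
class OrganCompartment:
    """One organ of the whole-body circulation."""

    name: str
    volume: float       # L
    blood_flow: float   # L/min (lung: cardiac output)
    sub_fractions: tuple[float, float, float]  # plasma, interstitial, intracellular
    composition: dict[str, float]  # water / neutral_lipid / phospholipid / protein / acidic_phospholipid
    intracellular_pH: float = 7.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"organ {self.name}: volume must be positive")
        if self.blood_flow < 0:
            raise ValueError(f"organ {self.name}: blood flow must be non-negative")
        if sum(self.sub_fractions) > 1.0 + 1e-9:
            raise ValueError(f"organ {self.name}: sub-fractions sum above 1")
        for key, val in self.composition.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"organ {self.name}: composition fraction {key}={val} outside [0, 1]")

    @property
    def extracellular_volume(self) -> float:
        return self.volume * (self.sub_fractions[0] + self.sub_fractions[1])

    @property
    def intracellular_volume(self) -> float:
        return self.volume * self.sub_fractions[2]


@dataclass
class ProteinPool:
    """Enzyme or transporter expressed in one organ (umol per L intracellular volume)."""

    protein: str
    organ: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("protein concentration must be non-negative")


@dataclass
class Individual:
    """A virtual individual: demographics, organs and protein pools."""

    age: float
    sex: str
    body_weight: float
    height: float
    hematocrit: float
    GFR: float  # mL/min
    organs: dict[str, OrganCompartment] = field(default_factory=dict)
    pools: list[ProteinPool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.GFR <= 0:
            raise ValueError("GFR must be positive")
        required = {"venous_blood", "arterial_blood", "lung", "liver", "kidney", "gut_wall"}
        missing = required - set(self.organs)
        if self.organs and missing:
            raise ValueError(f"individual lacks required organs: {sorted(missing)}")

    @property
    def cardiac_output(self) -> float:
        return self.organs["lung"].blood_flow

    def pool_concentration(self, protein: str, organ: str) -> float:
        for pool in self.pools:
            if pool.protein == protein and pool.organ == organ:
                return pool.concentration
        return 0.0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "demographics": {
                "age": self.age,
                "sex": self.sex,
                "body_weight": self.body_weight,
                "height": self.height,
                "hematocrit": self.hematocrit,
                "GFR": self.GFR,
            },
            "organs": {name: asdict(o) for name, o in self.organs.items()},
            "pools": [asdict(p) for p in self.pools],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Individual":
        demo = doc["demographics"]
        organs = {
            name: OrganCompartment(
                name=o["name"],
                volume=o["volume"],
                blood_flow=o["blood_flow"],
                sub_fractions=tuple(o["sub_fractions"]),
                composition=dict(o["composition"]),
                intracellular_pH=o["intracellular_pH"],
            )
            for name, o in doc["organs"].items()
        }
        pools = [ProteinPool(**p) for p in doc["pools"]]
        return cls(
            age=demo["age"],
            sex=demo["sex"],
            body_weight=demo["body_weight"],
            height=demo["height"],
            hematocrit=demo["hematocrit"],
            GFR=demo["GFR"],
            organs=organs,
            pools=pools,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Individual":
        return cls.from_dict(yaml.safe_load(text))


def build_reference_individual(
    age: float | None = None,
    body_weight: float | None = None,
    height: float | None = None,
    sex: str | None = None,
) -> Individual:
    """Build a virtual individual from the embedded reference adult.

    Missing demographics are filled from the reference defaults. Organ
    volumes and blood flows scale linearly with body weight relative to the
    73 kg reference; composition is weight-invariant.
    """
    for name, val in (("age", age), ("body_weight", body_weight), ("height", height)):
        if val is not None and val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    age = REFERENCE_DEMOGRAPHICS["age"] if age is None else float(age)
    if not 18 <= age <= 90:
        raise ValueError(f"age {age} outside supported adult range [18, 90]")
    body_weight = (
        REFERENCE_DEMOGRAPHICS["body_weight"] if body_weight is None else float(body_weight)
    )
    height = REFERENCE_DEMOGRAPHICS["height"] if height is None else float(height)
    sex = REFERENCE_DEMOGRAPHICS["sex"] if sex is None else sex
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    scale = body_weight / REFERENCE_DEMOGRAPHICS["body_weight"]
    organs = {}
    for name in ORGAN_NAMES:
        vol, flow = _REFERENCE_ORGANS[name]
        water, nl, ph, prot, ap, ph_ic = _COMPOSITION[name]
        organs[name] = OrganCompartment(
            name=name,
            volume=vol * scale,
            blood_flow=flow * scale,
            sub_fractions=_SUB_FRACTIONS[name],
            composition={
                "water": water,
                "neutral_lipid": nl,
                "phospholipid": ph,
                "protein": prot,
                "acidic_phospholipid": ap,
            },
            intracellular_pH=ph_ic,
        )
    pools = [
        ProteinPool(protein=prot, organ=organ, concentration=conc)
        for prot, per_organ in _EXPRESSION.items()
        for organ, conc in per_organ.items()
    ]
    return Individual(
        age=age,
        sex=sex,
        body_weight=body_weight,
        height=height,
        hematocrit=REFERENCE_DEMOGRAPHICS["hematocrit"],
        GFR=REFERENCE_DEMOGRAPHICS["GFR"] * scale,
        organs=organs,
        pools=pools,
    )


def protein_amount(individual: Individual, protein: str, organ: str) -> float:
    """Amount of an enzyme/transporter (umol) in one organ.

    Concentration (umol/L intracellular) times the organ's intracellular
    volume; zero where the protein is not expressed.
    """
    if protein not in KNOWN_PROTEINS:
        raise ValueError(f"unknown protein {protein!r}; known: {KNOWN_PROTEINS}")
    if organ not in individual.organs:
        raise ValueError(f"organ {organ!r} not present in individual")
    conc = individual.pool_concentration(protein, organ)
    return conc * individual.organs[organ].intracellular_volume
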