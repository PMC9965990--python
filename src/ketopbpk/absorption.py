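"""Oral absorption: GI transit, formulation dissolution, prandial state.

The gastrointestinal tract is an eight-segment cascade (stomach, duodenum,
upper/lower jejunum, upper/lower ileum, caecum, colon) with first-order
transit of fluid, dissolved drug and suspended particles. Gastric emptying
half-time is the prandial-state-dependent GET (15 min fasted, 45 min fed).
Dissolution follows a Noyes-Whitney surface law per particle-size bin with
the local, pH-dependent solubility as driving force; supersaturated luminal
concentrations do not precipitate (the dissolution driving force is floored
at zero, never negative). Absorption from each segment is the product of the
prandial-state intestinal permeability, the segment's effective absorptive
surface and the dissolved concentration, delivered to the gut-wall cells.

The food effect is carried exclusively by the gastric emptying time and the
fed intestinal permeability; gastric pH is kept at its fasted value in both
states (see docs/methods.md for why a fed gastric pH shift is inconsistent
with the solubility profile of the parent compound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Formulation",
    "DoseEvent",
    "GISegment",
    "GITract",
    "build_gi_tract",
    "resolve_prandial_state",
    "dissolution_rate",
    "KETOCONAZOLE_TABLET",
    "SOLUTION",
    "GET_FASTED_MIN",
    "GET_FED_MIN",
]

GET_FASTED_MIN = 15.0
GET_FED_MIN = 45.0

#: Drug substance diffusion coefficient in luminal fluid, cm^2/min.
DIFFUSION_COEFF = 5.0e-4
#: Particle density, g/cm^3.
PARTICLE_DENSITY = 1.2
#: Diffusion-layer cap, um.
DIFFUSION_LAYER_CAP_UM = 30.0
#: Radius below which a formulation counts as an (instantly dissolving) solution, um.
SOLUTION_RADIUS_UM = 0.002


@dataclass
class Formulation:
    """Dosage form as a discrete particle-size distribution."""

    kind: str  # solution | tablet | capsule
    particle_bins: list[tuple[float, float]]  # (radius um, mass fraction)
    density: float = PARTICLE_DENSITY  # g/cm^3

    def __post_init__(self) -> None:
        if self.kind not in ("solution", "tablet", "capsule"):
            raise ValueError(f"unknown formulation kind {self.kind!r}")
        if not self.particle_bins:
            raise ValueError("formulation requires at least one particle bin")
        fractions = [f for _, f in self.particle_bins]
        if not math.isclose(sum(fractions), 1.0, rel_tol=1e-6):
            raise ValueError("particle mass fractions must sum to 1")
        if any(r <= 0 for r, _ in self.particle_bins):
            raise ValueError("particle radii must be positive")
        if self.kind == "solution" and any(
            r >= SOLUTION_RADIUS_UM for r, _ in self.particle_bins
        ):
            raise ValueError("solution bins must have radii below 0.002 um")

    @property
    def dissolves_instantly(self) -> bool:
        return self.kind == "solution"

    @classmethod
    def solution(cls) -> "Formulation":
        return cls(kind="solution", particle_bins=[(0.001, 1.0)])

    @classmethod
    def lognormal(
        cls,
        kind: str = "tablet",
        median_radius_um: float = 10.0,
        gsd: float = 2.0,
        n_bins: int = 10,
    ) -> "Formulation":
        """Log-normal particle-size distribution discretized into equal-probability bins."""
        from scipy import stats

        qs = (np.arange(n_bins) + 0.5) / n_bins
        radii = median_radius_um * np.exp(stats.norm.ppf(qs) * math.log(gsd))
        bins = [(float(r), 1.0 / n_bins) for r in radii]
        return cls(kind=kind, particle_bins=bins)


#: Instantly dissolving oral solution.
SOLUTION = Formulation.solution()

#: Ketoconazole immediate-release tablet. The effective granule radius was
#: estimated during model building (tablet disintegration yields coarse
#: granules; the value reproduces the gastric-residence-limited dissolution
#: that drives the observed food effect and fecal excretion).
KETOCONAZOLE_TABLET = Formulation.lognormal(
    kind="tablet", median_radius_um=1500.0, gsd=1.5, n_bins=10
)


@dataclass
class DoseEvent:
    """One administration of one compound."""

    compound: str
    dose: float  # mg
    time: float  # h
    formulation: Formulation = field(default_factory=Formulation.solution)
    prandial_state: str = "fasted"  # fasted | fed | unknown

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.prandial_state not in ("fasted", "fed", "unknown"):
            raise ValueError(f"unknown prandial state {self.prandial_state!r}")


@dataclass
class GISegment:
    name: str
    volume: float        # L
    pH: float
    surface_area: float  # effective absorptive area, cm^2
    transit_time: float  # mean residence time, min

    def __post_init__(self) -> None:
        if not 1.0 <= self.pH <= 8.5:
            raise ValueError(f"segment {self.name}: pH {self.pH} outside [1, 8.5]")
        if self.transit_time <= 0 or self.volume <= 0:
            raise ValueError(f"segment {self.name}: volume/transit must be positive")


@dataclass
class GITract:
    segments: list[GISegment]
    GET: float  # gastric emptying half-time, min

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def transit_rates(self) -> np.ndarray:
        """First-order transit rate constant per segment (1/min)."""
        rates = np.array(
            [1.0 / s.transit_time for s in self.segments]
        )
        rates[0] = math.log(2.0) / self.GET  # stomach: half-time = GET
        return rates


# (volume L, pH, effective area cm^2, transit min); stomach pH is the fasted
# value and is used in both prandial states.
_SEGMENT_TABLE = [
    ("stomach", 0.25, 2.0, 0.0, GET_FASTED_MIN),
    ("duodenum", 0.10, 6.0, 2.5e5, 15.0),
    ("upper_jejunum", 0.20, 6.2, 1.8e5, 45.0),
    ("lower_jejunum", 0.20, 6.4, 1.8e5, 45.0),
    ("upper_ileum", 0.15, 6.6, 1.5e5, 45.0),
    ("lower_ileum", 0.15, 6.8, 1.5e5, 45.0),
    ("caecum", 0.10, 6.4, 1.0e4, 180.0),
    ("colon", 0.30, 7.0, 2.5e4, 720.0),
]


def build_gi_tract(prandial_state: str = "fasted") -> GITract:
    """Default eight-segment tract for a prandial state."""
    if prandial_state not in ("fasted", "fed"):
        raise ValueError(f"prandial state must be fasted or fed, got {prandial_state!r}")
    segments = [
        GISegment(name=n, volume=v, pH=ph, surface_area=a, transit_time=t)
        for n, v, ph, a, t in _SEGMENT_TABLE
    ]
    get = GET_FED_MIN if prandial_state == "fed" else GET_FASTED_MIN
    return GITract(segments=segments, GET=get)


def resolve_prandial_state(
    observed_tmax: float | None,
    doses_per_day: int,
    single_dose: float,
    declared: str = "unknown",
) -> str:
    """Resolve the prandial state of a study from its metadata.

    A declared state wins. Otherwise the fed state is assumed if (i) the
    observed T_max is delayed beyond two hours, (ii) multiple doses were
    given within a day, or (iii) a single oral dose of 800 mg or more was
    administered; else fasted.
    """
    if declared not in ("fasted", "fed", "unknown"):
        raise ValueError(f"unknown declared state {declared!r}")
    if declared != "unknown":
        return declared
    if observed_tmax is not None and observed_tmax > 2.0:
        return "fed"
    if doses_per_day > 1:
        return "fed"
    if single_dose >= 800.0:
        return "fed"
    return "fasted"


def dissolution_rate(
    remaining_mass: float,
    radius_um: float,
    local_solubility: float,
    dissolved_conc: float,
    density: float = PARTICLE_DENSITY,
    diffusion_layer_um: float | None = None,
) -> float:
    """Noyes-Whitney dissolution rate (mg/min) for one particle bin.

    Rate = 3 D m (Cs - C) / (rho r h), i.e. flux through the diffusion layer
    of thickness h = min(r, 30 um) across the bin's surface area 3 m / (rho r).
    Negative driving forces (supersaturation) are clipped to zero.
    """
    if remaining_mass <= 0.0:
        return 0.0
    h_um = diffusion_layer_um if diffusion_layer_um is not None else min(
        radius_um, DIFFUSION_LAYER_CAP_UM
    )
    driving = max(local_solubility - dissolved_conc, 0.0)  # mg/L
    r_cm = radius_um * 1e-4
    h_cm = h_um * 1e-4
    # mg * (mg/L -> g/cm^3 is 1e-6): work in consistent units
    # 3 D m (Cs-C) / (rho r h): D cm^2/min, m mg, Cs mg/L = 1e-3 mg/cm^3,
    # rho g/cm^3 = 1e3 mg/cm^3
    return (
        3.0 * DIFFUSION_COEFF * remaining_mass * driving * 1e-3
        / (density * 1e3 * r_cm * h_cm)
    )
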