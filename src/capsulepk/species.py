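"""Cross-species parameter assembly: mouse, nonhuman primate (NHP), human.

Volumes come from anatomical literature; clearance scales linearly with
body mass; the NHP IP fluid volume is set from the human IP:blood volume
ratio for lack of a direct measurement.  All outputs are in package units
(ml, ml/day, 1/day, pg/day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import PG_PER_MG, PKParameters

__all__ = [
    "SpeciesProfile",
    "nhp_blood_volume",
    "nhp_ip_volume",
    "clearance_from_mass",
    "infusion_rate_from_bsa",
    "mouse_profile",
    "human_profile",
    "nhp_profile",
    "HUMAN_V1_ML",
    "HUMAN_V2_ML",
    "HUMAN_K_CLR_ML_PER_DAY",
    "HUMAN_PERITONEAL_AREA_M2",
    "NHP_BLOOD_ML_PER_KG",
]

HUMAN_V1_ML = 20.0
HUMAN_V2_ML = 5320.0
HUMAN_K_CLR_ML_PER_DAY = 1.68e5
#: typical human peritoneal surface area used when patient data are absent
HUMAN_PERITONEAL_AREA_M2 = 1.75
#: NHP blood volume per unit body mass: V2 = 65 * m[kg] ml
NHP_BLOOD_ML_PER_KG = 65.0

MOUSE_V1_ML = 1.0
MOUSE_V2_ML = 1.2


@dataclass(frozen=True)
class SpeciesProfile:
    """Anatomical/physiological constants for one species, with provenance."""

    species: str
    V1: float
    V2: float
    k_clr: float | None = None
    k_trans_prior: float | None = None
    mass: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def parameters(
        self, k_prod: float, lambda_decay: float, k_trans: float | None = None
    ) -> PKParameters:
        """Complete a kinetic parameter set from this profile."""
        kt = k_trans if k_trans is not None else self.k_trans_prior
        if kt is None:
            raise ValueError(f"{self.species}: no transport rate available")
        if self.k_clr is None:
            raise ValueError(f"{self.species}: no clearance available")
        return PKParameters(
            k_prod=k_prod,
            k_trans=kt,
            k_clr=self.k_clr,
            lambda_decay=lambda_decay,
            V1=self.V1,
            V2=self.V2,
        )


def nhp_blood_volume(mass: float) -> float:
    """NHP blood volume (ml) from body mass (kg): V2 = 65*m."""
    if not mass > 0:
        raise ValueError("mass must be positive")
    return NHP_BLOOD_ML_PER_KG * mass


def nhp_ip_volume(V2: float) -> float:
    """NHP IP fluid volume (ml), assuming the human V1:V2 ratio."""
    if not V2 > 0:
        raise ValueError("V2 must be positive")
    return V2 * (HUMAN_V1_ML / HUMAN_V2_ML)


def clearance_from_mass(
    mass: float, reference: tuple[float, float] = (2.0, 7200.0)
) -> float:
    """Renal clearance (ml/day) from linear scaling against a reference
    (mass0 kg, clearance0 ml/day) pair."""
    mass0, clr0 = reference
    if not (mass > 0 and mass0 > 0 and clr0 > 0):
        raise ValueError("mass, mass0 and clr0 must be positive")
    return clr0 * mass / mass0


def infusion_rate_from_bsa(
    dosage_mg_per_m2_per_day: float, area_m2: float = HUMAN_PERITONEAL_AREA_M2
) -> float:
    """IL2 infusion rate k_in (pg/day) from a body-surface-area dosage."""
    if not (dosage_mg_per_m2_per_day > 0 and area_m2 > 0):
        raise ValueError("dosage and area must be positive")
    return dosage_mg_per_m2_per_day * area_m2 * PG_PER_MG


def mouse_profile() -> SpeciesProfile:
    return SpeciesProfile(
        species="mouse",
        V1=MOUSE_V1_ML,
        V2=MOUSE_V2_ML,
        provenance={
            "V1": "typical IP fluid volume observed during sample collection",
            "V2": "calculated from typical mouse body mass",
        },
    )


def human_profile() -> SpeciesProfile:
    return SpeciesProfile(
        species="human",
        V1=HUMAN_V1_ML,
        V2=HUMAN_V2_ML,
        k_clr=HUMAN_K_CLR_ML_PER_DAY,
        k_trans_prior=0.7,
        provenance={
            "V1": "literature IP fluid volume",
            "V2": "literature blood volume",
            "k_clr": "literature renal clearance",
            "k_trans_prior": "estimated from continuous-infusion clinical data",
        },
    )


def nhp_profile(mass: float, clearance_reference: tuple[float, float] = (2.0, 7200.0)) -> SpeciesProfile:
    """NHP profile for a given body mass (kg); mass is required because the
    blood volume and clearance both scale with it."""
    v2 = nhp_blood_volume(mass)
    return SpeciesProfile(
        species="NHP",
        V1=nhp_ip_volume(v2),
        V2=v2,
        k_clr=clearance_from_mass(mass, clearance_reference),
        k_trans_prior=0.7,
        mass=mass,
        provenance={
            "V1": "human V1:V2 ratio applied to NHP blood volume",
            "V2": "V2 = 65*m anatomical relation",
            "k_clr": "linear mass scaling from reference pair",
            "k_trans_prior": "human estimate carried over",
        },
    )
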