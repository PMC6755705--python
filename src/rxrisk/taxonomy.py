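"""Medication class system and dose-equivalence constants.

Respiratory prescriptions are classified into a small closed set of drug
classes. Six classes count as *maintenance* (controller) treatment: inhaled
corticosteroids (ICS) alone or in fixed combination with a long-acting
beta-2 agonist (LABA), leukotriene receptor antagonists (LTRA), long-acting
muscarinic antagonists (LAMA) alone or in fixed combination with LABA, and
LABA alone. Short-acting beta-2 agonists (SABA) are the reliever class;
oral corticosteroids (OCS) form their own class; antibiotics and
H1-antihistamines prescribed for exacerbations never count toward
maintenance or reliever totals.

Package counts convert to standardized annual amounts through
dose-equivalence constants: one standard OCS package holds 20 doses of
20 mg prednisolone-equivalent (400 mg); one SABA canister holds 200 doses
of 100 µg salbutamol-equivalent (20,000 µg).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable


class DrugClass(str, Enum):
    """Closed enumeration of drug classes carried by prescription records."""

    ICS = "ICS"
    LABA = "LABA"
    LAMA = "LAMA"
    LTRA = "LTRA"
    ICS_LABA_FIXED = "ICS_LABA_FIXED"
    LAMA_LABA_FIXED = "LAMA_LABA_FIXED"
    SABA = "SABA"
    OCS = "OCS"
    OTHER_RELIEVER = "OTHER_RELIEVER"
    EXACERBATION_ONLY = "EXACERBATION_ONLY"


class Role(str, Enum):
    MAINTENANCE = "maintenance"
    RELIEVER = "reliever"
    OCS = "ocs"
    OTHER = "other"


#: The six controller classes defining persistent respiratory treatment.
MAINTENANCE_CLASSES: frozenset[DrugClass] = frozenset(
    {
        DrugClass.ICS,
        DrugClass.ICS_LABA_FIXED,
        DrugClass.LTRA,
        DrugClass.LAMA,
        DrugClass.LAMA_LABA_FIXED,
        DrugClass.LABA,
    }
)

RELIEVER_CLASSES: frozenset[DrugClass] = frozenset(
    {DrugClass.SABA, DrugClass.OTHER_RELIEVER}
)

_ROLE_MAP: dict[DrugClass, Role] = {
    **{c: Role.MAINTENANCE for c in MAINTENANCE_CLASSES},
    **{c: Role.RELIEVER for c in RELIEVER_CLASSES},
    DrugClass.OCS: Role.OCS,
    DrugClass.EXACERBATION_ONLY: Role.OTHER,
}

#: Fixed-dose combinations expand to their mono components for labelling.
_COMPONENTS: dict[DrugClass, frozenset[DrugClass]] = {
    DrugClass.ICS_LABA_FIXED: frozenset({DrugClass.ICS, DrugClass.LABA}),
    DrugClass.LAMA_LABA_FIXED: frozenset({DrugClass.LAMA, DrugClass.LABA}),
}


class UnknownDrugClassError(ValueError):
    """Raised when a record carries a class code outside the enumeration."""

    def __init__(self, code: object) -> None:
        super().__init__(f"unknown drug class code: {code!r}")
        self.code = code


def coerce_class(code: "DrugClass | str") -> DrugClass:
    """Validate a class code (string or enum) into a :class:`DrugClass`."""
    if isinstance(code, DrugClass):
        return code
    try:
        return DrugClass(str(code))
    except ValueError:
        raise UnknownDrugClassError(code) from None


def classify_role(code: "DrugClass | str") -> Role:
    """Return the role (maintenance / reliever / ocs / other) of a class.

    The role map is a total partition of the enumeration; an unknown code
    raises :class:`UnknownDrugClassError` naming the offending code.
    """
    return _ROLE_MAP[coerce_class(code)]


def expand_components(code: "DrugClass | str") -> frozenset[DrugClass]:
    """Expand a fixed-dose combination into its mono-class components.

    Mono classes map to themselves, so the expansion is idempotent.
    """
    cls = coerce_class(code)
    return _COMPONENTS.get(cls, frozenset({cls}))


def expand_class_set(codes: Iterable["DrugClass | str"]) -> frozenset[DrugClass]:
    """Union of component expansions over a set of classes (order-free)."""
    out: set[DrugClass] = set()
    for c in codes:
        out |= expand_components(c)
    return frozenset(out)


@dataclass(frozen=True)
class EquivalenceConstants:
    """Dose-equivalence constants for standard OCS packages and SABA canisters.

    ``ocs_mg_per_dose`` is expressed in prednisolone-equivalent mg (the
    5 mg prednisolone dose is the equivalence *unit* used to standardize
    heterogeneous OCS products; the 20-dose × 20 mg standard package is
    what all banding arithmetic uses). ``saba_ug_per_dose`` is in
    salbutamol-equivalent µg.
    """

    ocs_doses_per_package: int = 20
    ocs_mg_per_dose: float = 20.0
    saba_doses_per_canister: int = 200
    saba_ug_per_dose: float = 100.0

    @property
    def ocs_mg_per_package(self) -> float:
        return self.ocs_doses_per_package * self.ocs_mg_per_dose

    @property
    def saba_ug_per_canister(self) -> float:
        return self.saba_doses_per_canister * self.saba_ug_per_dose


DEFAULT_EQUIVALENCE = EquivalenceConstants()

#: Annual prednisolone-equivalent mass at or above which OCS exposure is
#: "high dose" (4 standard packages).
HIGH_OCS_MG: float = 4 * DEFAULT_EQUIVALENCE.ocs_mg_per_package  # 1600 mg

#: Annual salbutamol-equivalent mass strictly above which SABA use is
#: "over-use" (more than one canister per month, i.e. > 12 canisters/year).
SABA_OVERUSE_UG: float = 12 * DEFAULT_EQUIVALENCE.saba_ug_per_canister  # 240,000 µg


def packages_to_ocs_mg(
    packages: float, constants: EquivalenceConstants = DEFAULT_EQUIVALENCE
) -> float:
    """Convert a count of OCS packages to prednisolone-equivalent mg.

    ``constants`` may carry per-product (doses_per_package, mg_per_dose)
    overrides; the default is the 20 × 20 mg standard package (400 mg).
    """
    if packages < 0:
        raise ValueError(f"package count must be >= 0, got {packages}")
    return packages * constants.ocs_mg_per_package


def canisters_to_saba_ug(
    canisters: float, constants: EquivalenceConstants = DEFAULT_EQUIVALENCE
) -> float:
    """Convert a count of SABA canisters to salbutamol-equivalent µg."""
    if canisters < 0:
        raise ValueError(f"canister count must be >= 0, got {canisters}")
    return canisters * constants.saba_ug_per_canister
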