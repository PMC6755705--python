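"""Patient-level exposure definitions.

Implements every derived measure of the analysis for one calendar year of
prescription and dispensing records:

* **PRT** (persistent respiratory treatment): more than 2 packages of the
  six maintenance classes prescribed in the year. The default reading pools
  packages across maintenance classes; a stricter per-single-class reading
  is available behind ``prt_rule="per_class"``.
* **OCS / SABA users**: at least one package of the class dispensed
  (filled at a pharmacy).
* **Annual equivalent doses** and the OCS dose bands
  low (0, 400] mg < medium (400, 1600) mg < high [1600, ∞) mg of
  prednisolone-equivalent, computed from **dispensed** packages.
* **SABA over-use**: more than 240,000 µg salbutamol-equivalent dispensed
  per year (strictly more than 12 canisters).
* **SABA-to-maintenance ratio** (dispensed packages) and **excessive use**
  (over-use, or ratio above 1:1; a SABA user with no maintenance fills
  counts as exceeding 1:1).
* **Maintenance-to-total** percentage (prescribed packages; maintenance
  over maintenance + relievers + OCS), dichotomized at 70% and 50%.
* **Primary adherence**: dispensed over prescribed maintenance packages,
  capped at 100%, dichotomized at 50% and 70%.
* **Combination labels** of maintenance classes prescribed (fixed
  combinations expanded to mono components).

Dispensed quantities drive OCS/SABA exposure; prescribed quantities drive
the maintenance-to-total ratio; adherence uses both — tracking which verb
(prescribed vs filled) each definition uses. OCS measures are scoped to the
PRT cohort to limit confounding by non-respiratory OCS indications; SABA
measures apply to the full respiratory-prescription cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .taxonomy import (
    DEFAULT_EQUIVALENCE,
    HIGH_OCS_MG,
    MAINTENANCE_CLASSES,
    RELIEVER_CLASSES,
    SABA_OVERUSE_UG,
    DrugClass,
    UnknownDrugClassError,
    canisters_to_saba_ug,
    expand_class_set,
    packages_to_ocs_mg,
)

PrtRule = Literal["pooled", "per_class"]

#: Canonical rendering order for maintenance combination labels.
COMBINATION_ORDER = (DrugClass.ICS, DrugClass.LTRA, DrugClass.LABA, DrugClass.LAMA)

AGE_GROUPS = ("15-44", "45-64", ">64")

OCS_BANDS = ("none", "low", "medium", "high")


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (reporting convention)."""
    x = float(x)
    if not np.isfinite(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PatientAnnualSummary:
    """Per-patient, per-class annual package totals plus demographics."""

    patient_id: str
    age: int
    sex: str  # "F" | "M"
    prescribed: dict[DrugClass, int] = field(default_factory=dict)
    dispensed: dict[DrugClass, int] = field(default_factory=dict)

    def prescribed_total(self, classes) -> int:
        return sum(self.prescribed.get(c, 0) for c in classes)

    def dispensed_total(self, classes) -> int:
        return sum(self.dispensed.get(c, 0) for c in classes)


@dataclass
class ExposureProfile:
    """All derived measures for one patient.

    Fields that are undefined for the patient (e.g. adherence with no
    maintenance prescribed, or OCS measures outside the PRT cohort) are
    ``None``.
    """

    patient_id: str
    age: int
    sex: str
    age_group: str
    prt: bool
    respiratory_rx: bool  # any maintenance or reliever class prescribed
    saba_user: bool
    saba_annual_ug: float
    saba_overuse: bool
    ratio_saba_to_maintenance: Optional[float]
    saba_excessive: bool
    maintenance_to_total_pct: Optional[float]
    m2t_ge_70: Optional[bool]
    m2t_ge_50: Optional[bool]
    primary_adherence_pct: Optional[float]
    adherence_gt_50: Optional[bool]
    adherence_gt_70: Optional[bool]
    ocs_user: Optional[bool]
    ocs_prescribed: Optional[bool]
    ocs_annual_mg: Optional[float]
    ocs_band: Optional[str]
    combination_label: Optional[str]


def age_group(age: int) -> str:
    """Assign the analysis age group: 15-44, 45-64, >64."""
    if age < 15:
        raise ValueError(f"age must be >= 15 (excluded upstream), got {age}")
    if age <= 44:
        return "15-44"
    if age <= 64:
        return "45-64"
    return ">64"


def is_prt(summary: PatientAnnualSummary, rule: PrtRule = "pooled") -> bool:
    """More than 2 maintenance packages prescribed in the year.

    ``pooled`` (default) sums packages across the six maintenance classes;
    ``per_class`` requires > 2 packages of a single class.
    """
    if rule == "pooled":
        return summary.prescribed_total(MAINTENANCE_CLASSES) > 2
    if rule == "per_class":
        return any(summary.prescribed.get(c, 0) > 2 for c in MAINTENANCE_CLASSES)
    raise ValueError(f"unknown PRT rule: {rule!r}")


def ocs_annual_mg(summary: PatientAnnualSummary) -> float:
    return packages_to_ocs_mg(summary.dispensed.get(DrugClass.OCS, 0))


def ocs_band(summary: PatientAnnualSummary) -> str:
    """Dose band of annual dispensed prednisolone-equivalent.

    none (0 packages) | low (0, 400] | medium (400, 1600) | high [1600, ∞).
    """
    mg = ocs_annual_mg(summary)
    if mg <= 0:
        return "none"
    if mg <= DEFAULT_EQUIVALENCE.ocs_mg_per_package:
        return "low"
    if mg < HIGH_OCS_MG:
        return "medium"
    return "high"


def saba_annual_ug(summary: PatientAnnualSummary) -> float:
    return canisters_to_saba_ug(summary.dispensed.get(DrugClass.SABA, 0))


def saba_overuse(summary: PatientAnnualSummary) -> bool:
    """Strictly more than one canister per month dispensed (> 240,000 µg/yr)."""
    return saba_annual_ug(summary) > SABA_OVERUSE_UG


def ratio_saba_to_maintenance(summary: PatientAnnualSummary) -> Optional[float]:
    """Dispensed SABA packages over dispensed maintenance packages.

    Undefined (``None``) when no maintenance packages were dispensed;
    excessive-use classification then treats any SABA fill as exceeding 1:1.
    """
    denom = summary.dispensed_total(MAINTENANCE_CLASSES)
    if denom == 0:
        return None
    return summary.dispensed.get(DrugClass.SABA, 0) / denom


def saba_excessive(summary: PatientAnnualSummary) -> bool:
    """Over-use, or SABA-to-maintenance ratio above 1:1.

    A SABA user with zero maintenance fills counts as exceeding 1:1 (the
    "no controller" over-user rows of the stratum tables live inside the
    excessive-use population).
    """
    if saba_overuse(summary):
        return True
    saba = summary.dispensed.get(DrugClass.SABA, 0)
    ratio = ratio_saba_to_maintenance(summary)
    if ratio is None:
        return saba >= 1
    return ratio > 1


def maintenance_to_total(summary: PatientAnnualSummary) -> Optional[float]:
    """Percent of prescribed packages that are maintenance treatment.

    Denominator is prescribed maintenance + relievers + OCS packages;
    undefined when that total is 0 (exacerbation-only classes never count).
    """
    maint = summary.prescribed_total(MAINTENANCE_CLASSES)
    total = (
        maint
        + summary.prescribed_total(RELIEVER_CLASSES)
        + summary.prescribed.get(DrugClass.OCS, 0)
    )
    if total == 0:
        return None
    return 100.0 * maint / total


def primary_adherence(summary: PatientAnnualSummary) -> Optional[float]:
    """Percent of prescribed maintenance packages actually filled, capped at 100.

    Undefined when no maintenance was prescribed.
    """
    presc = summary.prescribed_total(MAINTENANCE_CLASSES)
    if presc == 0:
        return None
    disp = summary.dispensed_total(MAINTENANCE_CLASSES)
    return min(100.0, 100.0 * disp / presc)


def combination_label(summary: PatientAnnualSummary, rule: PrtRule = "pooled") -> str:
    """Canonical label of maintenance mono-classes prescribed to a PRT patient.

    Fixed combinations are expanded to components; classes render in the
    order ICS, LTRA, LABA, LAMA joined by "+".
    """
    if not is_prt(summary, rule):
        raise ValueError(
            f"combination labels are defined for PRT patients only "
            f"(patient {summary.patient_id} is not on PRT)"
        )
    present = expand_class_set(
        c for c in MAINTENANCE_CLASSES if summary.prescribed.get(c, 0) >= 1
    )
    return "+".join(c.value for c in COMBINATION_ORDER if c in present)


def summarize_patient(
    prescriptions: pd.DataFrame, dispensings: pd.DataFrame, patient_id: str
) -> PatientAnnualSummary:
    """Aggregate one patient's records into per-class annual package totals.

    ``prescriptions`` columns: patient_id, sex, age, date, drug_class,
    packages_prescribed, prescription_id. ``dispensings`` columns:
    prescription_id, patient_id, drug_class, packages_dispensed, date.
    All records must fall within a single calendar year.
    """
    pres = prescriptions[prescriptions["patient_id"].astype(str) == str(patient_id)]
    disp = dispensings[dispensings["patient_id"].astype(str) == str(patient_id)]
    years = set(pd.to_datetime(pres["date"]).dt.year) | set(
        pd.to_datetime(disp["date"]).dt.year
    )
    if len(years) > 1:
        raise ValueError(
            f"records for patient {patient_id} span multiple years: {sorted(years)}"
        )
    prescribed: dict[DrugClass, int] = {}
    for cls, n in pres.groupby("drug_class")["packages_prescribed"].sum().items():
        prescribed[_valid_class(cls)] = int(n)
    dispensed: dict[DrugClass, int] = {}
    for cls, n in disp.groupby("drug_class")["packages_dispensed"].sum().items():
        dispensed[_valid_class(cls)] = int(n)
    if len(pres):
        age = int(pres["age"].iloc[0])
        sex = str(pres["sex"].iloc[0])
    else:
        age, sex = 15, "F"  # all-zero summary for a patient with no records
    return PatientAnnualSummary(
        patient_id=str(patient_id), age=age, sex=sex,
        prescribed=prescribed, dispensed=dispensed,
    )


def _valid_class(code: object) -> DrugClass:
    try:
        return DrugClass(str(code))
    except ValueError:
        raise UnknownDrugClassError(code) from None


def profile_patient(
    summary: PatientAnnualSummary, prt_rule: PrtRule = "pooled"
) -> ExposureProfile:
    """Derive the full exposure profile from one patient's annual summary.

    OCS measures (user flag, annual mg, band) are reported only for PRT
    patients; outside the PRT cohort they are ``None``.
    """
    prt = is_prt(summary, prt_rule)
    saba_disp = summary.dispensed.get(DrugClass.SABA, 0)
    m2t = maintenance_to_total(summary)
    adh = primary_adherence(summary)
    if prt:
        mg = ocs_annual_mg(summary)
        band = ocs_band(summary)
        user = summary.dispensed.get(DrugClass.OCS, 0) >= 1
        presc_ocs = summary.prescribed.get(DrugClass.OCS, 0) >= 1
        combo = combination_label(summary, prt_rule)
    else:
        mg, band, user, presc_ocs, combo = None, None, None, None, None
    return ExposureProfile(
        patient_id=summary.patient_id,
        age=summary.age,
        sex=summary.sex,
        age_group=age_group(summary.age),
        prt=prt,
        respiratory_rx=(
            summary.prescribed_total(MAINTENANCE_CLASSES)
            + summary.prescribed_total(RELIEVER_CLASSES)
        ) > 0,
        saba_user=saba_disp >= 1,
        saba_annual_ug=saba_annual_ug(summary),
        saba_overuse=saba_overuse(summary),
        ratio_saba_to_maintenance=ratio_saba_to_maintenance(summary),
        saba_excessive=saba_excessive(summary),
        maintenance_to_total_pct=m2t,
        m2t_ge_70=None if m2t is None else m2t >= 70.0,
        m2t_ge_50=None if m2t is None else m2t >= 50.0,
        primary_adherence_pct=adh,
        adherence_gt_50=None if adh is None else adh > 50.0,
        adherence_gt_70=None if adh is None else adh > 70.0,
        ocs_user=user,
        ocs_prescribed=presc_ocs,
        ocs_annual_mg=mg,
        ocs_band=band,
        combination_label=combo,
    )


# ---------------------------------------------------------------------------
# Vectorized cohort pipeline
# ---------------------------------------------------------------------------

_MAINT = sorted(c.value for c in MAINTENANCE_CLASSES)
_RELIEV = sorted(c.value for c in RELIEVER_CLASSES)


def _class_totals(df: pd.DataFrame, count_col: str) -> pd.DataFrame:
    """patient_id × drug_class matrix of summed package counts."""
    bad = set(df["drug_class"].unique()) - {c.value for c in DrugClass}
    if bad:
        raise UnknownDrugClassError(sorted(bad)[0])
    wide = (
        df.groupby(["patient_id", "drug_class"], sort=True)[count_col]
        .sum()
        .unstack(fill_value=0)
    )
    for c in DrugClass:
        if c.value not in wide.columns:
            wide[c.value] = 0
    return wide[[c.value for c in DrugClass]].astype(np.int64)


def _check_single_year(prescriptions: pd.DataFrame, dispensings: pd.DataFrame) -> None:
    years = set(pd.to_datetime(prescriptions["date"]).dt.year)
    years |= set(pd.to_datetime(dispensings["date"]).dt.year)
    if len(years) > 1:
        raise ValueError(f"records span multiple calendar years: {sorted(years)}")


def build_profiles(
    prescriptions: pd.DataFrame,
    dispensings: pd.DataFrame,
    prt_rule: PrtRule = "pooled",
) -> pd.DataFrame:
    """Classify every patient in the record set; one profile row per patient.

    Vectorized equivalent of ``profile_patient(summarize_patient(...))``
    applied to the whole cohort; columns mirror
    :class:`ExposureProfile` fields. Undefined values are NaN/None.
    """
    _check_single_year(prescriptions, dispensings)
    pres = _class_totals(prescriptions, "packages_prescribed")
    disp = _class_totals(dispensings, "packages_dispensed")
    disp = disp.reindex(pres.index, fill_value=0)
    extra = disp.index.difference(pres.index)
    if len(extra):
        raise ValueError(
            f"dispensing records reference unknown patients: {list(extra[:5])}"
        )

    demo = (
        prescriptions.sort_values("date")
        .groupby("patient_id")[["age", "sex"]]
        .first()
        .reindex(pres.index)
    )
    if (demo["age"] < 15).any():
        bad = demo.index[demo["age"] < 15][0]
        raise ValueError(f"age must be >= 15 (patient {bad})")

    maint_presc = pres[_MAINT].sum(axis=1)
    maint_disp = disp[_MAINT].sum(axis=1)
    reliev_presc = pres[_RELIEV].sum(axis=1)
    saba_disp = disp[DrugClass.SABA.value]
    ocs_disp = disp[DrugClass.OCS.value]
    ocs_presc = pres[DrugClass.OCS.value]

    if prt_rule == "pooled":
        prt = maint_presc > 2
    elif prt_rule == "per_class":
        prt = (pres[_MAINT] > 2).any(axis=1)
    else:
        raise ValueError(f"unknown PRT rule: {prt_rule!r}")

    total_presc = maint_presc + reliev_presc + ocs_presc
    m2t = np.where(total_presc > 0, 100.0 * maint_presc / total_presc, np.nan)
    adh = np.where(
        maint_presc > 0,
        np.minimum(100.0, 100.0 * maint_disp / maint_presc.replace(0, 1)),
        np.nan,
    )
    ratio = np.where(maint_disp > 0, saba_disp / maint_disp.replace(0, 1), np.nan)
    saba_ug = saba_disp * DEFAULT_EQUIVALENCE.saba_ug_per_canister
    overuse = saba_ug > SABA_OVERUSE_UG
    excessive = overuse | (ratio > 1) | ((maint_disp == 0) & (saba_disp >= 1))

    ocs_mg = ocs_disp * DEFAULT_EQUIVALENCE.ocs_mg_per_package
    band = np.select(
        [
            ocs_mg <= 0,
            ocs_mg <= DEFAULT_EQUIVALENCE.ocs_mg_per_package,
            ocs_mg < HIGH_OCS_MG,
        ],
        ["none", "low", "medium"],
        default="high",
    )

    # Combination labels: presence of each mono component after expansion.
    has = {
        DrugClass.ICS: (pres[DrugClass.ICS.value] + pres[DrugClass.ICS_LABA_FIXED.value]) > 0,
        DrugClass.LTRA: pres[DrugClass.LTRA.value] > 0,
        DrugClass.LABA: (
            pres[DrugClass.LABA.value]
            + pres[DrugClass.ICS_LABA_FIXED.value]
            + pres[DrugClass.LAMA_LABA_FIXED.value]
        ) > 0,
        DrugClass.LAMA: (pres[DrugClass.LAMA.value] + pres[DrugClass.LAMA_LABA_FIXED.value]) > 0,
    }
    label = pd.Series("", index=pres.index)
    for c in COMBINATION_ORDER:
        label = label.where(~has[c], label + "+" + c.value)
    label = label.str.lstrip("+")

    out = pd.DataFrame(
        {
            "patient_id": pres.index.astype(str),
            "age": demo["age"].astype(int).values,
            "sex": demo["sex"].values,
            "age_group": pd.cut(
                demo["age"],
                bins=[14, 44, 64, np.inf],
                labels=list(AGE_GROUPS),
            ).astype(str).values,
            "prt": prt.values,
            "respiratory_rx": ((maint_presc + reliev_presc) > 0).values,
            "saba_user": (saba_disp >= 1).values,
            "saba_annual_ug": saba_ug.astype(float).values,
            "saba_overuse": overuse.values,
            "ratio_saba_to_maintenance": ratio,
            "saba_excessive": excessive.values,
            "maintenance_to_total_pct": m2t,
            "m2t_ge_70": m2t >= 70.0,
            "m2t_ge_50": m2t >= 50.0,
            "primary_adherence_pct": adh,
            "adherence_gt_50": adh > 50.0,
            "adherence_gt_70": adh > 70.0,
            "ocs_user": np.where(prt, ocs_disp >= 1, None),
            "ocs_prescribed": np.where(prt, ocs_presc >= 1, None),
            "ocs_annual_mg": np.where(prt, ocs_mg.astype(float), np.nan),
            "ocs_band": np.where(prt, band, None),
            "combination_label": np.where(prt, label, None),
        }
    ).reset_index(drop=True)
    # dichotomizations are undefined where the underlying percent is
    for flag, base in [
        ("m2t_ge_70", "maintenance_to_total_pct"),
        ("m2t_ge_50", "maintenance_to_total_pct"),
        ("adherence_gt_50", "primary_adherence_pct"),
        ("adherence_gt_70", "primary_adherence_pct"),
    ]:
        out[flag] = out[flag].astype(object)
        out.loc[out[base].isna(), flag] = None
    return out


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Write profiles.csv: flags/bands as lowercase, undefined as empty."""
    df = profiles.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].map({True: "true", False: "false"})
        elif df[col].dtype == object:
            df[col] = df[col].map(
                lambda v: "true" if v is True else "false" if v is False else v
            )
    df.to_csv(path, index=False, float_format="%.6f")
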