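import numpy as np
import pandas as pd
import pytest

from rxrisk import GeneratorConfig, build_profiles, generate

MAINT = {"ICS", "ICS_LABA_FIXED", "LTRA", "LAMA", "LAMA_LABA_FIXED", "LABA"}
RELIEVERS = {"SABA", "OTHER_RELIEVER"}


@pytest.fixture(scope="session")
def mixed_cohort():
    """A mid-size synthetic cohort with every stratum well represented."""
    cfg = GeneratorConfig(
        n_patients=2000,
        seed=20160101,
        stratum_probs=(0.15, 0.25, 0.40, 0.12, 0.08),
    )
    pres, disp, gt = generate(cfg)
    return cfg, pres, disp, gt


@pytest.fixture(scope="session")
def mixed_profiles(mixed_cohort):
    _, pres, disp, _ = mixed_cohort
    return build_profiles(pres, disp)


def literal_profile(pres_rows: pd.DataFrame, disp_rows: pd.DataFrame) -> dict:
    """Brute-force oracle: apply the written exposure definitions row by row.

    Enumerates one patient's raw records and computes every measure
    directly from its textual definition, independent of the vectorized
    pipeline.
    """
    prescribed: dict[str, int] = {}
    for _, r in pres_rows.iterrows():
        prescribed[r["drug_class"]] = prescribed.get(r["drug_class"], 0) + int(
            r["packages_prescribed"]
        )
    dispensed: dict[str, int] = {}
    for _, r in disp_rows.iterrows():
        dispensed[r["drug_class"]] = dispensed.get(r["drug_class"], 0) + int(
            r["packages_dispensed"]
        )

    maint_presc = sum(v for c, v in prescribed.items() if c in MAINT)
    maint_disp = sum(v for c, v in dispensed.items() if c in MAINT)
    saba_disp = dispensed.get("SABA", 0)
    ocs_disp = dispensed.get("OCS", 0)

    # persistent respiratory treatment: more than 2 maintenance packages
    prt = maint_presc > 2

    # annual equivalents: 400 mg per OCS package, 20,000 ug per canister
    ocs_mg = ocs_disp * 400.0
    saba_ug = saba_disp * 20_000.0
    if ocs_disp == 0:
        band = "none"
    elif ocs_mg <= 400:
        band = "low"
    elif ocs_mg < 1600:
        band = "medium"
    else:
        band = "high"

    overuse = saba_ug > 240_000.0
    ratio = saba_disp / maint_disp if maint_disp > 0 else None
    excessive = overuse or (ratio is not None and ratio > 1) or (
        maint_disp == 0 and saba_disp >= 1
    )

    total_presc = maint_presc + sum(
        v for c, v in prescribed.items() if c in RELIEVERS
    ) + prescribed.get("OCS", 0)
    m2t = 100.0 * maint_presc / total_presc if total_presc > 0 else None
    adh = (
        min(100.0, 100.0 * maint_disp / maint_presc) if maint_presc > 0 else None
    )

    return {
        "prt": prt,
        "saba_user": saba_disp >= 1,
        "saba_annual_ug": saba_ug,
        "saba_overuse": overuse,
        "ratio_saba_to_maintenance": ratio,
        "saba_excessive": excessive,
        "maintenance_to_total_pct": m2t,
        "primary_adherence_pct": adh,
        "ocs_user": (ocs_disp >= 1) if prt else None,
        "ocs_annual_mg": ocs_mg if prt else None,
        "ocs_band": band if prt else None,
    }


def summary_from_counts(prescribed=None, dispensed=None, age=40, sex="F"):
    """Shorthand constructor for hand-written patient summaries."""
    from rxrisk import DrugClass, PatientAnnualSummary

    def _m(d):
        return {DrugClass(k): v for k, v in (d or {}).items()}

    return PatientAnnualSummary(
        patient_id="T", age=age, sex=sex,
        prescribed=_m(prescribed), dispensed=_m(dispensed),
    )
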