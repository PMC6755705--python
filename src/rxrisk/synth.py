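"""Synthetic one-year prescription/dispensing database generator.

Emulates the statistical structure of a national electronic
prescription-and-dispensing extract: one calendar year of records, several
prescriptions per patient, several packages and classes per prescription,
and partial dispensing (not every prescribed package is filled).

Patients are drawn from five latent strata with configurable prevalences:

* ``exacerbation_only`` — only exacerbation medication (antibiotics /
  antihistamines, possibly OCS); no maintenance or reliever classes.
* ``intermittent`` — respiratory medication but at most 2 maintenance
  packages prescribed (below the persistent-treatment threshold).
* ``prt_controlled`` — persistent respiratory treatment (≥ 3 maintenance
  packages prescribed), dispensed OCS capped below the high-dose band.
* ``prt_high_ocs`` — persistent treatment with ≥ 4 OCS packages dispensed
  (≥ 1600 mg prednisolone-equivalent).
* ``saba_overuser`` — more than 12 SABA canisters dispensed in the year;
  at most 2 maintenance packages prescribed (over-users sit largely
  outside the persistent-treatment cohort, dominated by low controller
  prescribing).

Dispensing is binomial thinning of each prescription line with a
per-patient fill probability drawn from a Beta distribution (between-patient
adherence heterogeneity spanning 0–100%). Package counts per class are
Poisson with stratum-specific means, truncated or bumped where a stratum
definition requires a minimum or maximum.

When ``assoc_log_odds`` is set, the high-OCS indicator of persistent-
treatment patients is instead drawn from a logistic model on the patient's
low maintenance-to-total indicator (< 70%), age group and sex — giving a
known ground-truth odds structure for parameter-recovery testing.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .taxonomy import DrugClass, MAINTENANCE_CLASSES

STRATA = (
    "exacerbation_only",
    "intermittent",
    "prt_controlled",
    "prt_high_ocs",
    "saba_overuser",
)

_MAINT = sorted(c.value for c in MAINTENANCE_CLASSES)

#: Mean annual prescribed packages per class, by stratum. Illustrative
#: defaults (the source database reports no per-stratum count
#: distributions); chosen to give persistent-treatment patients a
#: maintenance-to-total spread straddling the 70% cut-off.
DEFAULT_PACKAGE_MEANS: dict[str, dict[str, float]] = {
    "exacerbation_only": {"EXACERBATION_ONLY": 1.8, "OCS": 0.3},
    "intermittent": {"SABA": 1.2, "ICS": 0.5, "EXACERBATION_ONLY": 0.6},
    "prt_controlled": {
        "ICS_LABA_FIXED": 4.0, "ICS": 1.2, "LAMA": 1.0, "LTRA": 0.8,
        "SABA": 1.4, "OCS": 0.5,
    },
    "prt_high_ocs": {
        "ICS_LABA_FIXED": 4.0, "ICS": 1.2, "LAMA": 2.0, "LTRA": 1.0,
        "SABA": 2.5, "OCS": 5.0,
    },
    "saba_overuser": {"SABA": 14.0, "ICS": 0.8, "EXACERBATION_ONLY": 0.4},
}

#: Marginal stratum prevalences. Defaults follow the published cohort
#: structure: ~48% exacerbation-only, ~14.2% persistent treatment of which
#: ~2% with high OCS exposure, and SABA over-use in ~0.1% of patients.
DEFAULT_STRATUM_PROBS = (0.481, 0.376, 0.139, 0.003, 0.001)


class GeneratorConfig(BaseModel):
    """Validated configuration of the synthetic database generator."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(gt=0)
    seed: int = Field(ge=0, lt=2**31)
    year: int = 2016
    age_group_probs: tuple[float, float, float] = (0.288, 0.218, 0.494)
    female_prob: float = Field(default=0.559, ge=0.0, le=1.0)
    stratum_probs: tuple[float, float, float, float, float] = DEFAULT_STRATUM_PROBS
    adherence_beta_params: tuple[float, float] = (2.0, 1.0)
    package_count_means: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_PACKAGE_MEANS.items()}
    )
    # (intercept, low_ratio_effect, age45_64_effect, age_gt64_effect, male_effect)
    assoc_log_odds: Optional[tuple[float, float, float, float, float]] = None

    @field_validator("age_group_probs", "stratum_probs")
    @classmethod
    def _probs_sum_to_one(cls, v):
        if any(p < 0 for p in v):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(v)}")
        return v

    @field_validator("adherence_beta_params")
    @classmethod
    def _beta_positive(cls, v):
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("Beta shape parameters must be positive")
        return v

    @model_validator(mode="after")
    def _means_valid(self):
        for stratum, means in self.package_count_means.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum in package_count_means: {stratum}")
            for cls, m in means.items():
                DrugClass(cls)  # raises on unknown class
                if m < 0:
                    raise ValueError(f"mean packages must be >= 0 ({stratum}/{cls}={m})")
        return self


class DatasetValidationError(ValueError):
    """A malformed row in an on-disk dataset (carries row and field)."""

    def __init__(self, filename: str, row: int, field: str, message: str) -> None:
        super().__init__(f"{filename}, row {row}, field {field!r}: {message}")
        self.filename, self.row, self.field = filename, row, field


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (prescriptions, dispensings, ground_truth) record frames.

    Deterministic given ``config.seed``. Every dispensing row references an
    existing prescription line and never exceeds its prescribed count; all
    dates fall inside ``config.year``; all ages are ≥ 15.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    stratum_idx = rng.choice(len(STRATA), size=n, p=np.asarray(config.stratum_probs))
    strata = np.array(STRATA)[stratum_idx]
    age_grp = rng.choice(3, size=n, p=np.asarray(config.age_group_probs))
    ages = np.select(
        [age_grp == 0, age_grp == 1],
        [rng.integers(15, 45, size=n), rng.integers(45, 65, size=n)],
        default=rng.integers(65, 96, size=n),
    )
    sexes = np.where(rng.random(n) < config.female_prob, "F", "M")
    a, b = config.adherence_beta_params
    adherence = rng.beta(a, b, size=n)

    # Per-patient prescribed package counts per class (Poisson draws, then
    # stratum constraints).
    classes = [c.value for c in DrugClass]
    col = {c: i for i, c in enumerate(classes)}
    presc = np.zeros((n, len(classes)), dtype=np.int64)
    for s_i, stratum in enumerate(STRATA):
        mask = stratum_idx == s_i
        if not mask.any():
            continue
        for cls, mean in config.package_count_means.get(stratum, {}).items():
            if mean > 0:
                presc[mask, col[cls]] = rng.poisson(mean, size=mask.sum())

    maint_cols = [col[c] for c in _MAINT]
    is_prt_stratum = np.isin(strata, ("prt_controlled", "prt_high_ocs"))
    non_prt = ~is_prt_stratum

    # Persistent-treatment strata: at least 3 maintenance packages prescribed.
    deficit = 3 - presc[:, maint_cols].sum(axis=1)
    bump = is_prt_stratum & (deficit > 0)
    presc[bump, col["ICS_LABA_FIXED"]] += deficit[bump]
    # Other strata: at most 2 maintenance packages prescribed (cap greedily).
    over = non_prt & (presc[:, maint_cols].sum(axis=1) > 2)
    for i in np.where(over)[0]:
        excess = presc[i, maint_cols].sum() - 2
        for c in maint_cols:
            take = min(excess, presc[i, c])
            presc[i, c] -= take
            excess -= take
            if excess == 0:
                break
    # SABA over-users need > 12 canisters dispensable; everyone else stays
    # at or below 12 even at full adherence.
    is_over = strata == "saba_overuser"
    presc[is_over, col["SABA"]] = np.maximum(presc[is_over, col["SABA"]], 13)
    presc[~is_over, col["SABA"]] = np.minimum(presc[~is_over, col["SABA"]], 12)
    # Intermittent patients must carry at least one respiratory-class
    # prescription (zero-truncation), or they would be indistinguishable
    # from the exacerbation-only stratum.
    resp_cols = maint_cols + [col["SABA"], col["OTHER_RELIEVER"]]
    need_resp = (strata == "intermittent") & (presc[:, resp_cols].sum(axis=1) == 0)
    presc[need_resp, col["SABA"]] = 1

    # High-OCS status: stratum-driven by default, or redrawn from the
    # configured logistic model for persistent-treatment patients. In the
    # logistic mode every persistent-treatment patient is *prescribed* a
    # constant 4 OCS packages and high vs not-high is realised purely
    # through *dispensed* OCS — the maintenance-to-total covariate uses
    # prescribed counts, so the outcome assignment cannot feed back into
    # the covariate the recovery test conditions on.
    if config.assoc_log_odds is not None:
        b0, b_low, b_45, b_65, b_male = config.assoc_log_odds
        presc[is_prt_stratum, col["OCS"]] = 4
        maint = presc[:, maint_cols].sum(axis=1)
        total = (
            maint
            + presc[:, col["SABA"]]
            + presc[:, col["OTHER_RELIEVER"]]
            + presc[:, col["OCS"]]
        )
        with np.errstate(invalid="ignore"):
            m2t = np.where(total > 0, 100.0 * maint / np.maximum(total, 1), np.nan)
        low_ratio = (m2t < 70.0).astype(float)
        eta = (
            b0
            + b_low * low_ratio
            + b_45 * (age_grp == 1)
            + b_65 * (age_grp == 2)
            + b_male * (sexes == "M")
        )
        high = is_prt_stratum & (rng.random(n) < _expit(eta))
        strata = strata.copy()
        strata[is_prt_stratum & high] = "prt_high_ocs"
        strata[is_prt_stratum & ~high] = "prt_controlled"
    is_high = strata == "prt_high_ocs"
    # High-exposure patients must be able to fill >= 4 OCS packages; the
    # rest of the persistent cohort is capped below the high-dose band at
    # dispensing time (prescribed counts stay as drawn).
    presc[is_high, col["OCS"]] = np.maximum(presc[is_high, col["OCS"]], 4)

    # Guarantee >= 1 record per patient (cohort = at least one prescription).
    empty = presc.sum(axis=1) == 0
    presc[empty, col["EXACERBATION_ONLY"]] = 1

    # --- Assemble prescription lines -------------------------------------
    # Each patient's packages are split across 1-3 prescriptions on random
    # dates; each prescription can hold several classes and packages.
    year_start = np.datetime64(f"{config.year}-01-01")
    days_in_year = (
        np.datetime64(f"{config.year + 1}-01-01") - year_start
    ) // np.timedelta64(1, "D")

    p_rows: list[tuple] = []
    d_rows: list[tuple] = []
    rx_counter = 0
    for i in range(n):
        nonzero = [(classes[c], int(presc[i, c])) for c in range(len(classes)) if presc[i, c] > 0]
        total_pkgs = sum(k for _, k in nonzero)
        n_rx = int(min(1 + rng.integers(0, 3), total_pkgs)) if total_pkgs > 1 else 1
        rx_days = np.sort(rng.integers(0, days_in_year, size=n_rx))
        rx_ids = [f"RX{rx_counter + j:08d}" for j in range(n_rx)]
        rx_counter += n_rx
        pid = f"P{i:06d}"
        # multinomial split of each class's packages over the prescriptions
        line_alloc: dict[tuple[int, str], int] = {}
        for cls, k in nonzero:
            split = rng.multinomial(k, np.full(n_rx, 1.0 / n_rx))
            for j, kj in enumerate(split):
                if kj > 0:
                    line_alloc[(j, cls)] = int(kj)
        for (j, cls), kj in sorted(line_alloc.items()):
            date = str(year_start + rx_days[j])
            p_rows.append(
                (pid, sexes[i], int(ages[i]), date, cls, kj, rx_ids[j])
            )
        # binomial thinning per line with the patient's fill probability
        fills: dict[tuple[int, str], int] = {
            line: int(rng.binomial(kj, adherence[i]))
            for line, kj in sorted(line_alloc.items())
        }
        # stratum guarantees on dispensed totals
        if strata[i] == "prt_high_ocs":
            _force_min(fills, line_alloc, "OCS", 4)
        elif strata[i] == "prt_controlled":
            _force_max(fills, "OCS", 3)
        if strata[i] == "saba_overuser":
            _force_min(fills, line_alloc, "SABA", 13)
        for (j, cls), kj in sorted(fills.items()):
            if kj > 0:
                lag = int(rng.integers(0, 22))
                d_day = min(int(rx_days[j]) + lag, int(days_in_year) - 1)
                date = str(year_start + d_day)
                d_rows.append((rx_ids[j], pid, cls, kj, date))

    prescriptions = pd.DataFrame(
        p_rows,
        columns=[
            "patient_id", "sex", "age", "date", "drug_class",
            "packages_prescribed", "prescription_id",
        ],
    )
    dispensings = pd.DataFrame(
        d_rows,
        columns=["prescription_id", "patient_id", "drug_class", "packages_dispensed", "date"],
    )
    ground_truth = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "stratum": strata,
            "adherence_prob": adherence,
            "high_ocs_true": (strata == "prt_high_ocs").astype(int),
        }
    )
    return prescriptions, dispensings, ground_truth


def _force_min(
    fills: dict, alloc: dict, cls: str, minimum: int
) -> None:
    """Raise dispensed counts of ``cls`` toward prescribed until >= minimum."""
    lines = [line for line in sorted(alloc) if line[1] == cls]
    have = sum(fills.get(line, 0) for line in lines)
    for line in lines:
        if have >= minimum:
            break
        room = alloc[line] - fills.get(line, 0)
        take = min(room, minimum - have)
        fills[line] = fills.get(line, 0) + take
        have += take


def _force_max(fills: dict, cls: str, maximum: int) -> None:
    """Reduce dispensed counts of ``cls`` until the total is <= maximum."""
    lines = [line for line in sorted(fills) if line[1] == cls]
    have = sum(fills[line] for line in lines)
    for line in reversed(lines):
        if have <= maximum:
            break
        take = min(fills[line], have - maximum)
        fills[line] -= take
        have -= take


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "prescriptions.csv": {
        "patient_id": str, "sex": str, "age": int, "date": "date",
        "drug_class": "class", "packages_prescribed": int, "prescription_id": str,
    },
    "dispensings.csv": {
        "prescription_id": str, "patient_id": str, "drug_class": "class",
        "packages_dispensed": int, "date": "date",
    },
    "groundtruth.csv": {
        "patient_id": str, "stratum": "stratum", "adherence_prob": float,
        "high_ocs_true": int,
    },
}


def write_dataset(
    prescriptions: pd.DataFrame,
    dispensings: pd.DataFrame,
    ground_truth: pd.DataFrame,
    path: "str | Path",
) -> None:
    """Write the three CSV files (UTF-8, comma-delimited, ISO-8601 dates)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prescriptions.to_csv(path / "prescriptions.csv", index=False)
    dispensings.to_csv(path / "dispensings.csv", index=False)
    gt = ground_truth.copy()
    gt["adherence_prob"] = gt["adherence_prob"].map(lambda v: f"{v:.6f}")
    gt.to_csv(path / "groundtruth.csv", index=False)


def read_dataset(
    path: "str | Path",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate a dataset directory written by :func:`write_dataset`.

    Malformed rows raise :class:`DatasetValidationError` naming the row
    number (1-based, excluding the header) and the offending field.
    """
    path = Path(path)
    out = []
    for fname, schema in _SCHEMAS.items():
        df = pd.read_csv(path / fname, dtype=str, keep_default_na=False)
        missing = set(schema) - set(df.columns)
        if missing:
            raise DatasetValidationError(fname, 0, sorted(missing)[0], "missing column")
        for field_name, kind in schema.items():
            series = df[field_name]
            bad = _first_bad(series, kind)
            if bad is not None:
                raise DatasetValidationError(
                    fname, bad + 1, field_name, f"invalid value {series.iloc[bad]!r}"
                )
            if kind is int:
                df[field_name] = series.astype(np.int64)
            elif kind is float:
                df[field_name] = series.astype(float)
        out.append(df)
    return tuple(out)


def _first_bad(series: pd.Series, kind) -> Optional[int]:
    if kind is str:
        ok = series.str.len() > 0
    elif kind is int:
        ok = series.str.fullmatch(r"-?\d+").fillna(False)
        if ok.all():
            ok &= series.astype(np.int64) >= 0
    elif kind is float:
        ok = pd.to_numeric(series, errors="coerce").notna()
    elif kind == "date":
        ok = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce").notna()
    elif kind == "class":
        ok = series.isin([c.value for c in DrugClass])
    elif kind == "stratum":
        ok = series.isin(STRATA)
    else:  # pragma: no cover
        raise AssertionError(kind)
    if ok.all():
        return None
    return int(np.flatnonzero(~ok.values)[0])
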