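"""Cohort tables, per-100,000 rates and pipeline orchestration.

Renders the analysis outputs:

* stratum characteristic tables (sex, age group, maintenance-to-total and
  primary-adherence bands; counts, percents with Wilson 95% intervals, and
  per-100,000 extrapolated rates) for the cohorts *all respiratory*,
  *persistent respiratory treatment (PRT)*, *PRT with high OCS exposure*
  and *SABA over-use*;
* the one-year maintenance-combination table of the PRT cohort;
* headline cohort rates; and
* the multinomial association results at the primary (70%) and
  sensitivity (50%) maintenance-to-total cut-offs.

``run_pipeline`` chains generate → classify → tabulate → model and writes
a deterministic report bundle (CSV files plus a fixed-width text
rendering); re-running with the same configuration is byte-identical. The
run log records cohort sizes at each filter step of the analysis flowchart,
the seed and a configuration hash — no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import association as assoc_mod
from .exposure import build_profiles, round1, write_profiles
from .stats import ExtrapolationFactor, median_iqr, rate_per_100k, wilson_ci
from .synth import GeneratorConfig, generate, read_dataset, write_dataset

COHORTS = ("all_respiratory", "prt", "prt_high_ocs", "saba_overuse")

_M2T_BANDS = [
    ("no_controller_prescribed", None),  # m2t undefined or exactly 0
    (">0_to_20", lambda v: (v > 0) & (v < 20)),
    ("20_to_<50", lambda v: (v >= 20) & (v < 50)),
    ("50_to_<70", lambda v: (v >= 50) & (v < 70)),
    ("70_to_<90", lambda v: (v >= 70) & (v < 90)),
    ("90_to_100", lambda v: v >= 90),
]

_ADH_BANDS = [
    ("no_maintenance_prescribed", lambda v, ok: ~ok),
    ("0", lambda v, ok: ok & (v == 0)),
    (">0_to_20", lambda v, ok: ok & (v > 0) & (v <= 20)),
    (">20_to_50", lambda v, ok: ok & (v > 20) & (v <= 50)),
    (">50_to_70", lambda v, ok: ok & (v > 50) & (v <= 70)),
    (">70_to_90", lambda v, ok: ok & (v > 70) & (v <= 90)),
    (">90_to_100", lambda v, ok: ok & (v > 90)),
]


@dataclass
class StratumTable:
    """Characteristics of one cohort stratum (counts, %, 95% CI, rates)."""

    stratum: str
    n: int
    rate_per_100k: float
    age_median: Optional[float] = None
    age_p25: Optional[float] = None
    age_p75: Optional[float] = None
    blocks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block, tab in self.blocks.items():
            for _, r in tab.iterrows():
                rows.append({"stratum": self.stratum, "block": block, **r})
        return pd.DataFrame(rows)


def _block_table(
    labels_masks: list[tuple[str, np.ndarray]], n: int, factor: ExtrapolationFactor
) -> pd.DataFrame:
    rows = []
    for label, mask in labels_masks:
        k = int(mask.sum())
        if n > 0:
            lo, hi = wilson_ci(k, n)
            pct = 100.0 * k / n
        else:
            lo = hi = pct = np.nan
        rows.append(
            {
                "label": label,
                "count": k,
                "percent": pct,
                "percent_rounded": round1(pct) if n else np.nan,
                "ci_low": round1(lo) if n else np.nan,
                "ci_high": round1(hi) if n else np.nan,
                "rate_per_100k": round1(rate_per_100k(k, factor)),
            }
        )
    return pd.DataFrame(rows)


def stratum_table(
    profiles: pd.DataFrame, stratum: str, factor: ExtrapolationFactor
) -> StratumTable:
    """Build the Table-1-shaped characteristics table for one cohort."""
    sub = _cohort_mask(profiles, stratum)
    cohort = profiles[sub]
    n = len(cohort)
    table = StratumTable(
        stratum=stratum,
        n=n,
        rate_per_100k=round1(rate_per_100k(n, factor)) if n <= factor.sample_size else np.nan,
    )
    if n:
        table.age_median, table.age_p25, table.age_p75 = median_iqr(cohort["age"])

    sex = [("female", (cohort["sex"] == "F").to_numpy()),
           ("male", (cohort["sex"] == "M").to_numpy())]
    age = [(g, (cohort["age_group"] == g).to_numpy()) for g in ("15-44", "45-64", ">64")]

    m2t = cohort["maintenance_to_total_pct"].to_numpy(dtype=float)
    # maintenance prescribed == 0 iff m2t is 0 or undefined
    maint_zero = np.isnan(m2t) | (m2t == 0)
    m2t_blocks = []
    for lbl, f in _M2T_BANDS:
        if f is None:
            mask = maint_zero
        else:
            with np.errstate(invalid="ignore"):
                mask = f(np.nan_to_num(m2t, nan=-1.0)) & ~np.isnan(m2t)
        m2t_blocks.append((lbl, mask))

    adh = cohort["primary_adherence_pct"].to_numpy(dtype=float)
    defined = ~np.isnan(adh)
    adh_blocks = []
    for lbl, f in _ADH_BANDS:
        with np.errstate(invalid="ignore"):
            adh_blocks.append((lbl, f(np.nan_to_num(adh, nan=-1.0), defined)))

    table.blocks["sex"] = _block_table(sex, n, factor)
    table.blocks["age_group"] = _block_table(age, n, factor)
    table.blocks["maintenance_to_total"] = _block_table(m2t_blocks, n, factor)
    table.blocks["primary_adherence"] = _block_table(adh_blocks, n, factor)
    return table


def _cohort_mask(profiles: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "all_respiratory":
        return np.ones(len(profiles), dtype=bool)
    if stratum == "prt":
        return profiles["prt"].to_numpy(dtype=bool)
    if stratum == "prt_high_ocs":
        return (profiles["prt"] & (profiles["ocs_band"] == "high")).to_numpy(dtype=bool)
    if stratum == "saba_overuse":
        return profiles["saba_overuse"].to_numpy(dtype=bool)
    raise ValueError(f"unknown stratum: {stratum!r}")


def tabulate_combinations(profiles: pd.DataFrame) -> pd.DataFrame:
    """One-year maintenance-combination table for the PRT cohort.

    One row per canonical combination label: n and percent of the cohort,
    sorted by descending n (label as tie-break); percentages to 1 decimal.
    """
    prt = profiles[profiles["prt"].astype(bool)]
    n = len(prt)
    counts = prt["combination_label"].value_counts()
    df = pd.DataFrame(
        {
            "combination": counts.index,
            "n": counts.values,
            "percent": [100.0 * k / n for k in counts.values],
        }
    )
    df["percent_rounded"] = df["percent"].map(round1)
    return (
        df.sort_values(["n", "combination"], ascending=[False, True])
        .reset_index(drop=True)
    )


def headline_rates(
    profiles: pd.DataFrame, factor: ExtrapolationFactor
) -> pd.DataFrame:
    """Headline cohort sizes, percentages and per-100,000 rates."""
    prt = profiles[profiles["prt"].astype(bool)]
    saba_users = profiles[profiles["saba_user"].astype(bool)]
    rows = []

    def add(name: str, k: int, denom_name: str, denom: int) -> None:
        pct = 100.0 * k / denom if denom else np.nan
        lo, hi = wilson_ci(k, denom) if denom else (np.nan, np.nan)
        rows.append(
            {
                "quantity": name,
                "n": k,
                "denominator": denom_name,
                "denominator_n": denom,
                "percent": pct,
                "percent_rounded": round1(pct) if denom else np.nan,
                "ci_low": round1(lo) if denom else np.nan,
                "ci_high": round1(hi) if denom else np.nan,
                "rate_per_100k": round1(rate_per_100k(k, factor)),
            }
        )

    n_all = len(profiles)
    add("respiratory_any", n_all, "sample", n_all)
    add("prt", len(prt), "respiratory_any", n_all)
    add("prt_ocs_prescribed", int((prt["ocs_prescribed"] == True).sum()), "prt", len(prt))
    add("prt_ocs_dispensed", int((prt["ocs_user"] == True).sum()), "prt", len(prt))
    add("prt_high_ocs", int((prt["ocs_band"] == "high").sum()), "prt", len(prt))
    add("saba_users", len(saba_users), "respiratory_any", n_all)
    add("saba_excessive", int(saba_users["saba_excessive"].sum()), "saba_users", len(saba_users))
    add("saba_overuse", int(saba_users["saba_overuse"].sum()), "saba_users", len(saba_users))
    return pd.DataFrame(rows)


class RunConfig(BaseModel):
    """End-to-end pipeline configuration."""

    model_config = ConfigDict(frozen=True)

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    sample_size: Optional[int] = Field(default=None, gt=0)
    population_share: float = Field(default=0.45, gt=0.0, le=1.0)
    cutoff: float = Field(default=70.0, gt=0.0, lt=100.0)
    sensitivity_cutoffs: tuple[float, ...] = (50.0,)
    out_dir: str = "rxrisk_out"

    def factor(self, n_patients: int) -> ExtrapolationFactor:
        size = self.sample_size if self.sample_size is not None else max(n_patients, 1)
        return ExtrapolationFactor(sample_size=size, population_share=self.population_share)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs were removed."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class NoCohortError(RuntimeError):
    """The input contains no patients; n=0 tables were still written."""


def run_pipeline(config: RunConfig) -> dict:
    """generate/load → classify → tabulate → model; write the report bundle.

    Returns a dict with the in-memory artefacts (profiles, tables, rates,
    combination table, association results, log lines).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.6f")
        written.append(p)

    try:
        stage = "load"
        if config.generator is not None:
            prescriptions, dispensings, ground_truth = generate(config.generator)
            write_dataset(prescriptions, dispensings, ground_truth, out / "dataset")
            written += [out / "dataset" / f for f in
                        ("prescriptions.csv", "dispensings.csv", "groundtruth.csv")]
        elif config.input_dir is not None:
            prescriptions, dispensings, _ = read_dataset(config.input_dir)
        else:
            raise ValueError("RunConfig needs either a generator or an input_dir")

        stage = "classify"
        log: list[str] = []
        seed = config.generator.seed if config.generator is not None else None
        cfg_hash = hashlib.sha256(
            json.dumps(
                config.model_dump(exclude={"out_dir"}), sort_keys=True, default=str
            ).encode()
        ).hexdigest()[:16]
        log.append(f"seed: {seed}")
        log.append(f"config_hash: {cfg_hash}")
        if len(prescriptions) == 0:
            profiles = _empty_profiles()
        else:
            profiles = build_profiles(prescriptions, dispensings)
        n_all = len(profiles)
        log.append(f"patients_with_any_prescription: {n_all}")
        log.append(f"patients_age_ge_15: {n_all}")  # under-15s rejected upstream
        if n_all:
            n_resp = int((~_exacerbation_only_mask(profiles)).sum())
        else:
            n_resp = 0
        log.append(f"patients_respiratory_medication: {n_resp}")
        log.append(f"patients_exacerbation_medication_only: {n_all - n_resp}")
        n_prt = int(profiles["prt"].sum()) if n_all else 0
        log.append(f"patients_prt: {n_prt}")
        write_profiles(profiles, out / "profiles.csv")
        written.append(out / "profiles.csv")

        stage = "tabulate"
        factor = config.factor(n_all)
        tables: dict[str, StratumTable] = {}
        for stratum in COHORTS:
            t = stratum_table(profiles, stratum, factor) if n_all else _empty_table(stratum)
            tables[stratum] = t
            _write_csv(t.to_frame() if t.n or n_all else pd.DataFrame(
                columns=["stratum", "block", "label", "count", "percent",
                         "percent_rounded", "ci_low", "ci_high", "rate_per_100k"]),
                f"table_{stratum}.csv")
            log.append(f"stratum_{stratum}_n: {t.n}")
        combos = tabulate_combinations(profiles) if n_all else pd.DataFrame(
            columns=["combination", "n", "percent", "percent_rounded"])
        _write_csv(combos, "combinations.csv")
        rates = headline_rates(profiles, factor) if n_all else pd.DataFrame(
            columns=["quantity", "n", "denominator", "denominator_n", "percent",
                     "percent_rounded", "ci_low", "ci_high", "rate_per_100k"])
        _write_csv(rates, "rates.csv")

        stage = "model"
        results = {}
        if n_prt > 0 and n_all > 0:
            try:
                for cutoff in (config.cutoff, *config.sensitivity_cutoffs):
                    results[cutoff] = assoc_mod.fit_ocs_model(profiles, cutoff=cutoff)
            except assoc_mod.ModelDataError as e:
                log.append(f"model_skipped: {e}")
        if results:
            assoc_frames = []
            for cutoff, res in results.items():
                f = res.to_frame()
                f.insert(0, "cutoff", cutoff)
                assoc_frames.append(f)
            _write_csv(pd.concat(assoc_frames, ignore_index=True), "association.csv")
        else:
            log.append("model_fitted: none")

        stage = "render"
        text = _render_text(tables, combos, rates, results)
        (out / "tables.txt").write_text(text)
        written.append(out / "tables.txt")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        written.append(out / "run_log.txt")
    except Exception as e:  # noqa: BLE001 - single cleanup point
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, e) from e

    bundle = {
        "profiles": profiles,
        "tables": tables,
        "combinations": combos,
        "rates": rates,
        "association": results,
        "log": log,
    }
    if n_all == 0:
        bundle["no_cohort"] = True
    return bundle


def _exacerbation_only_mask(profiles: pd.DataFrame) -> pd.Series:
    # Exacerbation medication only: no maintenance or reliever class
    # prescribed (OCS alone does not count as respiratory medication).
    return ~profiles["respiratory_rx"].astype(bool)


def _empty_profiles() -> pd.DataFrame:
    from .exposure import ExposureProfile

    cols = list(ExposureProfile.__dataclass_fields__)
    return pd.DataFrame(columns=cols)


def _empty_table(stratum: str) -> StratumTable:
    return StratumTable(stratum=stratum, n=0, rate_per_100k=0.0)


def _render_text(tables, combos, rates, results) -> str:
    parts = []
    for stratum, t in tables.items():
        parts.append(f"== {stratum} (n={t.n}, {t.rate_per_100k} per 100,000) ==")
        if t.age_median is not None:
            parts.append(
                f"age median (P25-P75): {t.age_median:.1f} ({t.age_p25:.1f}-{t.age_p75:.1f})"
            )
        for block, tab in t.blocks.items():
            parts.append(f"-- {block} --")
            parts.append(
                tab[["label", "count", "percent_rounded", "ci_low", "ci_high",
                     "rate_per_100k"]].to_string(index=False)
            )
        parts.append("")
    parts.append("== 1-year maintenance combinations (PRT) ==")
    parts.append(
        combos[["combination", "n", "percent_rounded"]].to_string(index=False)
        if len(combos) else "(empty)"
    )
    parts.append("")
    parts.append("== headline rates ==")
    parts.append(
        rates[["quantity", "n", "percent_rounded", "ci_low", "ci_high",
               "rate_per_100k"]].to_string(index=False)
        if len(rates) else "(empty)"
    )
    parts.append("")
    for cutoff, res in results.items():
        parts.append(f"== association model (cut-off {cutoff:g}%) ==")
        parts.append(res.summary())
    return "\n".join(parts) + "\n"
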