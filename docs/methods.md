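# Methods

## The analysis

`rxrisk` operationalises a one-year, record-level risk analysis of
respiratory medication. The unit of observation is a prescription line
(one drug class, one package count, one date, one patient) and its matching
dispensing lines (pharmacy fills against that prescription). All patient
measures are annual aggregates over a single calendar year; there are no
per-patient rolling windows. Patients under 15 are excluded upstream and the
pipeline rejects them.

Two verbs matter and are tracked separately throughout: *prescribed*
(physician order) and *dispensed/filled* (pharmacy event). Exposure
measures (OCS dose band, SABA over-use, the SABA-to-maintenance ratio) use
dispensed quantities — what the patient actually obtained. The
maintenance-to-total ratio uses prescribed quantities — it measures
prescriber behaviour. Primary adherence divides one by the other, capped at
100% (dispensings can exceed prescriptions in synthetic edge cases; a
proportion of prescribed packages filled cannot meaningfully exceed 1).

### Definitions and their edge cases

* **Persistent respiratory treatment (PRT).** "More than 2 packages of any
  of the six maintenance classes prescribed" is read as *total maintenance
  packages pooled across classes > 2* — the most inclusive consistent
  reading, and the one coherent with the ratio definitions, which likewise
  pool maintenance classes. The stricter per-single-class reading is
  available as `prt_rule="per_class"` and covered by tests.
* **OCS dose bands** partition users exactly: low (0, 400] mg, medium
  (400, 1600) mg, high [1600, ∞) mg prednisolone-equivalent; "none" for
  zero packages dispensed. Band boundaries are exercised in tests at 400,
  1599.99 (3 packages = 1200 mg is medium) and 1600 mg. The 5 mg
  prednisolone dose is the equivalence *unit* for standardizing
  heterogeneous products; banding arithmetic uses the 400 mg standard
  package (20 × 20 mg). `EquivalenceConstants` accepts per-product
  (doses_per_package, mg_per_dose) overrides; mapping real product codes to
  classes is the caller's responsibility (records carry class codes
  directly; no ATC dictionary is bundled).
* **SABA over-use** is strict: > 12 canisters/year (> 240,000 µg). Twelve
  canisters is not over-use; thirteen (260,000 µg) is.
* **Excessive use** = over-use OR SABA-to-maintenance ratio > 1. A SABA
  user with zero maintenance fills has an undefined ratio and is classified
  excessive — the "no controller" over-users must fall inside the
  excessive-use population.
* **OCS scope.** OCS measures are reported only within the PRT cohort
  (outside it the profile fields are null), limiting confounding by
  non-respiratory OCS indications. SABA measures cover every patient with
  respiratory prescriptions.
* **Fixed combinations** (ICS+LABA, LAMA+LABA) count as one package in all
  package-count arithmetic and expand to their mono components only for
  combination labelling, rendered in the canonical order
  ICS, LTRA, LABA, LAMA.
* **Exacerbation-only medication** (antibiotics, H1-antihistamines) never
  enters maintenance, reliever or total package counts. A patient with only
  such records has undefined maintenance-to-total and adherence.

### Statistics

* **Extrapolation**: rate per 100,000 = count × 100,000 ×
  population_share / sample_size; defaults 0.45 / 82,714 (the design of the
  motivating national sample). `invert_rate` is the exact inverse on
  integer counts and is used to recover cohort counts from published rates.
* **Proportion intervals**: Wilson score (via
  `statsmodels.stats.proportion.proportion_confint`). Chosen because it is
  well-behaved at small n and extreme proportions and reproduces the
  motivating study's printed bounds exactly (e.g. 13/44 → 18.2–44.2);
  the complement symmetry ci(k, n) = 100 − reversed ci(n−k, n) is property
  tested, and empirical coverage ≥ 93% is checked by simulation at
  p = 0.3, n = 44 (Wilson's slight under/over-coverage is tolerated).
* **Medians** with P25–P75 use linear-interpolation quantiles.
* **Crude odds ratios**: ad/bc with Woolf (log) intervals; a 0.5 continuity
  correction on every cell iff any cell is zero; a zero row or column makes
  the OR undefined and flags the result rather than emitting a number.
* **The association model** is multinomial logistic regression of the OCS
  exposure band (none/low/medium/high; reference none — "multinomial"
  implies more than two levels, and the dose bands are the natural ordered
  categories) on: maintenance-to-total < cutoff (70% primary, 50%
  sensitivity), age 45–64, age > 64, male. Fitting is maximum likelihood by
  Newton iterations (statsmodels `MNLogit`), log-likelihood tolerance 1e-8,
  and Wald 95% intervals on exp(coef). The high-vs-none contrast is the
  headline; low and medium contrasts are emitted alongside. Non-convergence
  (typically separation when high-exposure counts are tiny) sets
  `converged=False`, raises a warning, and exits the CLI with code 3 —
  never a silent number. All percentages in reports are rounded to one
  decimal, half away from zero.

## The synthetic generator

The generator emulates the structure of a national
prescription/dispensing extract, not any particular population's values:
one calendar year; 1–3 prescriptions per patient, each holding several
classes and package counts (multinomial split of annual class totals);
dispensing as **binomial thinning** of each prescription line with a
per-patient fill probability drawn from Beta(α, β) (defaults (2, 1),
median ≈ 0.71, matching the wide spread of primary adherence — including
0% and 100% — that claims data show). Package counts per class are Poisson
with stratum-specific means; truncation/bumping enforces each stratum's
defining minimum or maximum:

| stratum | guarantees |
|---|---|
| exacerbation_only | no maintenance or reliever classes |
| intermittent | ≥ 1 respiratory-class prescription, ≤ 2 maintenance packages |
| prt_controlled | ≥ 3 maintenance packages prescribed; dispensed OCS ≤ 3 packages |
| prt_high_ocs | PRT plus dispensed OCS ≥ 4 packages |
| saba_overuser | dispensed SABA ≥ 13 canisters; ≤ 2 maintenance packages |

These guarantees make the five strata exactly identifiable downstream,
which is what the parameter-recovery tests exercise (prevalences within 3
binomial standard errors at n = 10,000). Default stratum prevalences
(0.481, 0.376, 0.139, 0.003, 0.001) follow the cohort structure of the
motivating study: roughly half exacerbation-only, ~14% persistent
treatment, ~2% of the persistent cohort with high OCS exposure, ~0.1%
over-users. Default demographics (28.8/21.8/49.4% across age groups, 55.9%
female) mirror its persistent-treatment cohort. Per-stratum package-count
means are illustrative, not calibrated — the source reports no per-stratum
count distributions — and are chosen so persistent-treatment patients
straddle the 70% maintenance-to-total cut-off.

Two generation modes govern high OCS exposure. In the default
**stratum-driven** mode the marginal prevalence is fixed by
`stratum_probs`; the association between low maintenance-to-total and high
exposure is then mechanical (OCS prescriptions depress the ratio's
numerator share) and strong. In the **conditional** mode
(`assoc_log_odds = (intercept, low_ratio, age45_64, age_gt64, male)`), the
persistent-treatment patients' high/not-high split is redrawn from a
logistic model on those covariates, and ground truth is relabelled
accordingly (the configured controlled/high split of `stratum_probs` is
overridden; their sum still fixes the PRT share). To keep the generating
coefficient identified as the fitted high-vs-none log-odds, every
persistent-treatment patient is prescribed a constant 4 OCS packages and
exposure is realised purely through *dispensed* OCS: the
maintenance-to-total covariate uses prescribed counts, so outcome
assignment cannot feed back into the covariate, and the not-high band
(none/low/medium) depends only on the patient's fill probability, which is
independent of the covariates. Under these conditions the multinomial
high-vs-none contrast equals the generating coefficient exactly up to an
intercept shift, and the recovery test (OR 4 on the low-ratio term, 50
replicates of 2,500 patients) requires the fitted CI to cover 4 in ≥ 90%
of replicates.

A single seeded `numpy` Generator drives everything; the same seed yields
byte-identical CSV output. Not emulated: multi-year carryover, seasonality
beyond uniform dates, prescriber and geography effects, dose strengths
within a class, or correlation between adherence and demographics. Passing
tests therefore demonstrate that the pipeline measures what it defines and
recovers known structure — not that any particular real population looks
like the defaults.

## Pipeline and numerical choices

* `run_pipeline` chains generate/load → classify → tabulate → model; any
  stage failure removes partial outputs and raises an error naming the
  stage. An empty cohort still writes n = 0 tables and is signalled
  distinctly (CLI exit 2, "no cohort"). Exit codes: 0 success,
  2 validation, 3 non-convergence.
* Stratum tables put every patient of the stratum in exactly one row of
  each categorical block, so block counts sum to the stratum n; patients
  with undefined values get explicit rows ("no controller prescribed",
  "no maintenance prescribed"). Percent denominators are the stratum n.
* Run logs carry the seed and a configuration hash (output directory
  excluded), never timestamps, so re-runs are byte-comparable.
* Problem sizes in the test-suite simulations — 2,000-patient fixture
  cohorts, 10,000 patients for prevalence recovery, 50 × 2,500 for
  odds-ratio coverage, 2,000 draws for interval coverage — were chosen as
  the smallest sizes at which the checked statistical properties are
  stable, keeping the full suite around a minute.

## Known limitations

* Dispensings are matched to prescriptions by identifier; fills of
  elsewhere-prescribed medication are out of scope, and the
  dispensed ≤ prescribed constraint is enforced per prescription line,
  not per patient-year.
* Whether a fixed-combination package should count once or per component in
  the ratio denominators is not settled usage; it counts once here.
* "Prescribed and dispensed" cohort membership (e.g. for SABA users)
  requires both at least one prescription and at least one fill.
* The multinomial model reports all non-reference contrasts, but with rare
  outcomes the low/medium contrasts can be unstable even when the headline
  contrast is well determined; check `converged` and the interval widths.
* No multiple-testing adjustment and no survey weighting are applied.
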