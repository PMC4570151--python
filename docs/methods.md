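# Methods

This note documents the models, rules and numerical choices implemented in
`sirsfluids`, the defaults behind them, and what the synthetic-data tests
do and do not establish.

## Data model and missingness

The pipeline consumes nine linked CSV tables (patients, encounters, vitals,
labs, IV-fluid orders, medication orders, ICD-9 diagnoses with
present-on-admission flags, ICD-9 procedures, positive microbiology
cultures) with ISO-8601 datetimes. Analysis inclusion requires patient
identifier, age, race and gender; rows failing this are dropped and
counted. Lab values are converted once, at load, to a fixed canonical unit
per analyte (e.g. hemoglobin g/L, potassium mmol/L, creatinine mg/dL) with
fixed multiplicative factors; thresholds downstream are always applied on
the canonical scale.

Missing data are assumed normal throughout: an absent lab can never satisfy
an abnormality rule, contributes 0 severity points, and yields KDIGO stage
0. When an analyte has repeated readings, the most abnormal reading in the
rule's direction decides. Cultures are recorded only when positive; absence
means not detected.

All temporal rules use **calendar days** derived from timestamps ("same
day", "day prior", "within N days"), because the source rules are phrased
in days and the matching logic of day-granular EHRs makes sub-day windows
spurious precision. The two deliberate exceptions are the hemoglobin-drop
rule (> 20 g/L between readings ≤ 24 h apart, sliding) and the KDIGO
0.3 mg/dL rise (≤ 48 h between readings), which are explicitly per-hour
definitions.

## SIRS qualification

An encounter qualifies on its earliest calendar day with heart rate
> 90 bpm (strict) **and** at least one of: temperature > 38 °C or < 36 °C
(strict); respiratory rate ≥ 20/min or PaCO₂ ≤ 32 mmHg (inclusive);
WBC ≥ 12 or ≤ 4 ×10⁹/L (inclusive). Tachycardia is mandatory — it anchors
the definition — so tachycardia alone, or secondary criteria without it,
never qualify. Only the first qualification is used; encounters are not
re-screened on later days if the fluid rules fail.

## Severity and comorbidity

**APS (APACHE-II Acute Physiology Score).** The twelve acute-physiology
variables are scored against the standard APACHE-II point bands,
transcribed into `phenotype.APS_BANDS`. The qualification day and the
prior day are scored separately — each using that day's most abnormal
value per variable — and the larger daily total is kept. Missing variables
score 0. Three documented simplifications: Glasgow Coma Scale is absent
from the data model and assumed 15 (0 points); oxygenation combines the
day's worst PaO₂, highest FiO₂ and lowest PaCO₂ (readings are not
co-timed; FiO₂ absent → room air 0.21), using the A–a gradient band only
when FiO₂ ≥ 0.5; creatinine points are not doubled for acute renal
failure, since ARF is itself an adjudicated outcome here. Chronic-health
and age points are intentionally out of scope — only the physiology score
is used for adjustment.

**Elixhauser comorbidities.** ICD-9 prefix matching per category
(Quan 2005 ICD-9-CM adaptation, shipped as editable vocabulary data), with
three modifications enforced in code regardless of configuration: code 586
removed from renal failure, 557.9 removed from peripheral vascular
disease, and the fluid/electrolyte category dropped — keeping comorbidity
flags disjoint from measured outcomes.

**SOFA subscores** (coagulation/platelets, liver/bilirubin,
respiratory/PaO₂:FiO₂, cardiovascular) use the standard thresholds over
days 0–3 after qualification. Order-level medication data carry no doses,
so any vasopressor order scores cardiovascular 3; MAP < 70 mmHg scores 1.

**KDIGO staging** is creatinine-only: baseline = lowest value in days −7…
−1; peak searched in days 0…+3 (configurable). Stage 1 at ≥ 1.5× baseline
or a ≥ 0.3 mg/dL rise within 48 h; stage 2 at ≥ 2×; stage 3 at ≥ 3× or
peak ≥ 4.0 mg/dL with a qualifying rise. Encounters with no
pre-qualification baseline are reported as not-AKI (the missing-assumed-
normal analogue) rather than excluded.

## Cohorts and fluid accounting

The qualifying window is days 0–2 relative to qualification ("within 48
hours"); the total window is days 0–3 ("the following 72 hours"); both are
arguments. Only the four monitored non-dextrose crystalloids enter volume
sums and chloride loads; bags ≤ 250 mL never count (drug-admixture
carriers — removing one is an exact no-op, asserted in tests). Chloride
concentrations (mmol/L): balanced 98, saline 154, lactated Ringer's 109,
half-saline 77 — formulary values, vocabulary-editable. Both the total
chloride load (mmol) and the volume-weighted mean delivered concentration
(mmol/L) are emitted, since either may be wanted as "chloride load".

Balanced membership (≥ 0.5 L balanced in days 0–2) is evaluated before
saline membership (≥ 0.5 L saline in days 0–2 AND zero balanced volume in
days 0–3), so a patient qualifying for both is balanced; either cohort may
receive other crystalloids. The no-balanced rule for the saline cohort is
scoped to the total window, not the whole stay, matching the 72-hour fluid
accounting. Exclusions — age < 18, stay < 24 h, > 1 L (strict) on day −1,
any colloid or hypertonic saline, ESRD (diagnosis set), cardiac surgery
(procedure set) — are all evaluated and all violated reasons reported,
not short-circuited. One record per patient (first qualifying encounter).

## Outcome adjudication

Administrative outcomes count ICD-9 diagnosis codes **not** flagged
present-on-admission; an "unknown" POA flag counts as an outcome
(conservative toward detecting complications; configurable). Procedures
have no POA flag and count when dated in the stay. Clinical definitions
follow the operational rules: IV antiarrhythmic (days 0–3) → dysrhythmia;
troponin > 0.04 ng/mL → cardiac stress; (echo order or BNP > 600 pg/mL)
with same-day diuretic → CHF; vasopressor (days 0–3) → cardiac failure;
hemoglobin drop > 20 g/L/24 h; transfusion procedure codes; coagulopathy =
INR > 1.5 without warfarin, or platelets < 150 ×10⁹/L, or D-dimer
> 500 ng/mL; culture-anchored infections require a positive culture plus
WBC > 12 ×10⁹/L within ±1 day of culture and an antibiotic within culture
day…+3, mapped to pneumonia / sepsis / UTI / line infection by specimen.
Electrolyte flags use the stated ranges (Mg 0.70–1.0, K 3.5–5.0,
Na 136–145, ionized Ca 1.1–1.4 mmol/L) on the most abnormal reading;
replacement flags require the low flag plus a matching replacement order.
Acidosis: hyperchloremic = arterial pH < 7.35 and chloride > 110 mmol/L;
metabolic = arterial pH < 7.35 and bicarbonate < 22 mmol/L; lactic =
venous or arterial lactate > 2.0 mmol/L; a lactate-ordered flag records
testing intensity. Where a definition states a window it is honored
(cardiac: days 0–3); where it does not, the full index stay is used. The
troponin/D-dimer/INR limits are common reference values and
vocabulary-configurable; the WBC unit in the infection rule is read as
cells/mm³ (≡ 12 ×10⁹/L), reconciling an inconsistent printed unit.
Endpoints: death from discharge status; LOS = (discharge − admit)/24 h;
readmission at N days = any later admission of the same patient starting
within N days of index discharge (30 ⊆ 60 ⊆ 90 asserted).

## Propensity model, matching, balance

The propensity model regresses the balanced-fluid indicator on
demographics, hospital attributes and comorbidity flags. Categorical
covariates are dummy-coded against their modal level; terms are
backward-eliminated while the largest Wald P exceeds 0.20 (the elimination
criterion is unstated in the source; 0.20 is the package default and an
argument). Binary terms that quasi-separate the arms (an empty
treatment-by-term cell) are screened out before fitting — elimination
would discard them with P ≈ 1, but they stall the likelihood — while a
term that perfectly predicts the arm raises an estimation error, as does
non-convergence. Exact duplicate design columns are dropped.

Matching is the classic case–control digit-greedy procedure: tiers d = 8
down to 1; at each tier, cases (the smaller arm) in seeded-random order
pair with the lowest-indexed unmatched control whose score rounds to the
same d-digit value, without replacement. No caliper beyond the 1-digit
tier. Pair count is seed-invariant; pairings within tiers are
reproducible under the seed. A brute-force reimplementation of the same
rule serves as the test oracle.

Balance diagnostics report pre/post-match P values (pooled t test for
continuous, Pearson χ² without continuity correction for categorical) and
pooled-SD standardized differences (max over levels for categoricals).
Covariates with post-match P < 0.1 are the residual-imbalance set and
enter the adjusted outcome models alongside the APS.

## Effect estimation

Unadjusted ORs come from the matched 2×2 with Wald (log-normal) intervals
and no continuity correction — this convention reproduces the reference
table's printed CIs exactly from their counts. A zero cell yields
`defined=False`, never an imputed estimate. Adjusted ORs are unconditional
logistic fits (outcome ~ cohort + APS + residual covariates); the matched-
pair structure is deliberately ignored, matching the reported use of χ²,
Student's t and plain logistic models rather than paired analogues. No
multiple-testing correction is applied, mirroring the source analysis.
Display rounding: ORs/CIs to 3 decimals, percentages to 2.

## Synthetic-EHR generator

The generator is first-class, tested code defining the study conditions.
Each patient receives demographics and hospital attributes with marginals
resembling the reference cohort's baseline characteristics, comorbidity flags (written as POA diagnoses), a latent
gamma severity (shape 2.0, scale 2.4; mean ≈ 4.8, matching the reported
post-match APS scale) that drives tachycardia magnitude, creatinine and
the outcome models, SIRS physiology (prevalence 0.5; tachycardia plus one
secondary criterion on the qualification day), and fluid orders from a
logistic assignment model whose default intercept plants the observed
~98:2 saline:balanced split. Outcomes are drawn from logistic models with
explicit treatment log-ORs — defaults: mortality ln 0.38, low-potassium-
with-replacement ln 0.50, hyperchloremic acidosis ln 0.35, 90-day
readmission ln 0.73, a cardiac administrative code ln 0.49 — plus
log-normal LOS and geometric readmission gaps. Deliberate boundary cases
(499 mL-only totals, 250 mL bags, > 1 L and exactly-1 L prior-day fluid,
colloid, under-age, short-stay, ESRD, cardiac surgery) are injected at low
configurable rates. `inject_confounding` adds a covariate to both the
assignment and an outcome model; the crude-OR bias it induces is verified
against exact 2×2×2 enumeration. A fixed config and seed reproduce the
bundle byte-for-byte; the stored true propensity is exactly the assignment
model evaluated on the generated covariates.

What the generator does **not** emulate: real marginal/joint distributions
of any hospital system, realistic pharmacy formularies, measurement error
in phenotype inputs, informative missingness, or care processes that react
to severity. Passing recovery tests therefore demonstrate correctness of
the pipeline's logic and estimators under the assumed data-generating
structure, not robustness to real-world EHR pathologies.

## Problem sizes and numerical choices

Effect-recovery experiments run the full pipeline at n = 20,000 patients
per replicate with a 50:50 arm split, null confounding and ~15% baseline
mortality, so matched 2×2 cells are well populated; 210 replicates
(70 per planted OR of 0.3, 0.5, 1.0) give a Monte-Carlo binomial band of
±0.039 around nominal 95% coverage. Structural tests use n = 2,000–8,000.
Propensity scores are clipped to (ε, 1−ε), ε = 10⁻¹²; logistic fits use
Newton with a BFGS fallback and flag |β| > 30 or non-convergence as
estimation errors. APS day ties prefer day 0; identical-score matching
ties resolve to the lowest-indexed control.

## Known limitations

ICD-9 outcome/exclusion code sets are editorial defaults (the validated
source lists were never published) and must be reviewed before any use on
real data. GCS, vasopressor doses and mechanical-ventilation status are
absent from the data model, truncating the achievable APS and SOFA ranges.
The reference coagulopathy row cannot be recomputed from its printed
counts because its denominators exclude warfarin recipients and are
unpublished. Multi-encounter patients contribute only their first
qualifying encounter.
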