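# Methods

## Scope and model

`rtcost` prices the planning and delivery of adjuvant breast radiotherapy
for a fixed cohort under a baseline protocol and under a sequence of six
guideline changes. The model is deterministic activity-based costing: no
uncertainty intervals, no outcome or cost-effectiveness modelling, no
scheduling/queueing simulation, no per-patient variation in task duration,
and no costs for heating/lighting, VMAT/IMRT planning, implementation-phase
work, or on-treatment physician/nursing review.

A patient is a record of rule-relevant covariates plus a baseline regimen.
A regimen is a fractionation schedule: primary dose and fractions, nodal
target class (`none`, `scax` = supraclavicular + undissected axilla,
`scax_imn` = the same plus the internal mammary chain), a DIBH flag, and an
optional 5-fraction tumour-bed boost. All rule rewrites resolve against a
regimen registry, so a rewrite that would produce an unregistered schedule
fails loudly rather than inventing one.

## Resource pricing

**Machine time.** Each fraction books a standard appointment slot:

| nodal class | free breathing | DIBH |
|---|---|---|
| none | 15 min | 20 min |
| sc/ax | 15 min | 25 min |
| sc/ax + IMN | 20 min | 35 min |

Boost fractions book the `none` slot for the patient's breathing technique.
This table was reconstructed as the unique simple slot assignment that
reproduces every audited per-regimen linac-minutes total (e.g. 3,675 min
across 7 IMN-DIBH patients = 525 min each = 15 × 35; 3,750 across 6 boosted
IMN-DIBH patients = 625 = 15 × 35 + 5 × 20). The reconstruction is enforced
exactly by tests over all audited cells.

**Staff time and cost.** Care paths price tasks as minutes × staff count ×
occurrences × hourly rate, with occurrences per course, per fraction, or
per treatment week (weeks = ⌈total fractions / 5⌉, matching the single
weekly chart check in the one-week pathway). Staff linac time counts every
attending staff member (two radiation therapists per fraction); machine
time counts the slot once. Hourly rates are annual salary / annual worked
hours. Defaults: 1,956 h/year (39-hour week net of typical leave) and
mid-scale 2023 Irish public-sector salaries (radiation therapist €58,812,
physicist €85,000, physician €172,000, other €45,000). These are
configuration knobs: the packaged pipeline takes staff euros from the
calibration fixture below, and no reported quantity depends on the salary
table; the care-path route exists as a cross-check and for sensitivity
work.

**Infrastructure.** Cost per gray follows a capital-throughput model: a
€2.5M linac with a 10 % annual service charge over a 12-year lifetime
treating 2.7 patients per hour gives €37.72/Gy. The derivation needs the
machine's annual operating hours, which is a departmental metric, so the
rate itself is the operative configuration parameter;
`derive_rate_per_gy`/`implied_operating_hours` document the algebra (the
configured rate implies ≈ 1,686 operating hours/year at 2.67 Gy per
attendance). Billable dose is primary dose + 2.67 Gy per boost fraction
(a 5-fraction boost bills 13.35 Gy). This uniquely reconciles all audited
boosted-regimen infrastructure cells within €1 (e.g. 58 × 53.35 Gy ×
€37.72 = €116,717).

## Calibration fixture

The operative per-patient profiles are audited 2019 per-regimen totals
divided by patient counts, kept at full precision
(`rtcost/data/calibration.csv`, provenance per row). Infrastructure euros
are always recomputed from the billable-gray model rather than read from
the fixture, which keeps cohort infrastructure totals an independent
conservation check (Σ billable Gy × rate).

The two one-week schedules were not in use in the audit year and are
calibrated at per-patient level:

- machine minutes follow the slot model exactly: 75 (free breathing), 100
  (DIBH);
- the non-linac pair (327, 361 min) is the integer solution of
  47x + 21y = 22,950, the constraint imposed by the audited post-change
  cohort non-linac total (119,025 − 1,315) given the final counts of 47
  free-breathing and 21 DIBH one-week patients, restricted to plausible
  values (DIBH adds planning/QA time; both must exceed the fixed-task floor
  of the documented pathway);
- staff cost €291.02/patient (both techniques) reproduces the audited
  post-change cohort saving of €62,477.

The documented one-week care path sums to 360 non-linac minutes, 33 more
than the calibrated 327; similarly the three-week template generalises to
400 min where the audited table implies 410. The audited values take
precedence; no phantom task is invented to close the gap.

The "50/24" schedule in the audit table is treated as 50 Gy in 25
fractions — a suspected typo, since its linac minutes (1,250 across 2
patients = 625 = 25 × 25) and infrastructure euros (3,772 = 2 × 50 ×
37.72) only fit 25 fractions.

## The rule engine

Changes apply strictly in order 1→6; each sees the previous rewrites; no
change ever edits patient covariates. Conventions adopted where the rules
leave freedom, all following the principle that the more resource-intensive
option is chosen:

1. **40/15 replaces 50 Gy conventional fractionation** — keyed on the
   regimen (primary dose 50 Gy); in the packaged cohort all such patients
   are reconstruction patients, so the regimen-based and indication-based
   readings coincide.
2. **Individualised boost** (invasive, breast-conserving only): boost :=
   indicated, where indicated means age < 50, or ≥ 50 with grade 3, LVI,
   extensive intraductal component, or a positive margin. Mastectomy and
   in-situ assignments are untouched.
3. **One-week schedule** for invasive disease on a breast/chest-wall-only,
   non-boosted schedule, preserving the breathing technique. In-situ
   disease is excluded.
4. **High-risk DCIS boost** (breast-conserving): boost := indicated, where
   high risk is any of age < 50, symptomatic presentation, size > 15 mm,
   multifocality, intermediate/high nuclear grade, comedonecrosis, radial
   margin < 10 mm.
5. **IMN irradiation** where indicated (N2-3, or N1 plus grade 3, LVI,
   triple-negative subtype, age < 40, or central/medial tumour), applied to
   patients already receiving nodal radiotherapy; a patient with frank N2-3
   disease on a breast-only schedule is additionally escalated to full
   locoregional coverage. This is how the single whole-breast patient who
   gains nodes + IMN is encoded — via staging, not a bespoke flag.
6. **DIBH** for age < 60 with left-sided treatment, age < 60 with
   right-sided IMN treatment, or ≥ 60 when the free-breathing plan is
   unsatisfactory (an explicit input flag, since the model cannot see
   dosimetry). DIBH is a ratchet: it is added when indicated and never
   withdrawn from a patient already planned in breath hold.

Each change is idempotent, and per-change deltas telescope exactly to the
baseline-to-final difference (both are property-tested).

## Reporting conventions

Money is kept at full precision internally; rendered tables round half-up
to whole euros. Reported "staff time" in delta tables is machine slot
minutes plus non-linac staff minutes (the linac staffing multiplier is
excluded); this is the convention under which the IMN change's
+11,345 min follows exactly from the audited per-patient values.
Percentages truncate toward zero at one decimal (9,700 / 74,850 renders
"12.9", where arithmetic rounding would give 13.0); the infrastructure
percentage is rendered at two decimals (13.38). Full-precision values are
always emitted alongside rendered strings in the JSON run summary.

## Synthetic cohort generator

The generator is constructive, not sampling-based. The packaged spec
(`rtcost/data/cohort_spec.yaml`) fixes, per baseline regimen, how many
patients follow each named transition role (keep/lose a boost, move to the
one-week schedule, gain IMN, convert to DIBH, ...). Phase one forces the
covariates each role requires — e.g. a boost loser is ≥ 50 with no risk
factor; an IMN gainer is N2-3 or N1 with exactly the adverse factors the
rule needs; a DIBH convert is under 60 with left-sided disease; a patient
who must stay free-breathing is right-sided or ≥ 60 with a satisfactory
plan. Phase two distributes the remaining free covariates to the marginal
targets (greedy quota assignment over eligible patients, deterministic
order, failing loudly with the binding constraint when a quota cannot be
met). Phase three draws ages uniformly within each patient's band and
shuffles record order; these are the only uses of the seeded stream, so a
seed fixes the cohort file byte for byte, and every transition count holds
for *any* seed.

Hard constraints (generation fails if violated): record invariants,
baseline assignment counts, all internally consistent marginal targets, and
the rule-engine transition counts recomputed by brute force (34 boost
removals, 68 one-week patients, 5 DCIS boost additions, 42 IMN additions
reaching 71, and the full final assignment-count column). Soft,
report-only targets are the ones the source table prints inconsistently:
LVI "no" (144 printed, but yes = 76 of 224 implies 148), luminal-A count
(subtype column sums to 205 over 208 invasive patients; the three
unallocated patients are assigned luminal A), three DCIS feature "no" rows
(the DCIS sub-table covers 15 of 16 patients), and mean age (58.61 target;
the generated value, ≈ 59.3 at the default seed, is reported).

What the generator emulates: the printed marginal distributions, the
baseline regimen mix, and the exact transition structure. What it does not
emulate: realistic covariate correlations beyond those constraints (e.g.
grade and subtype are allocated by quota, not by joint distribution), true
age distribution shape within bands, or any outcome-related structure.
Passing tests therefore demonstrate that the costing and rule machinery
reproduce the published resource arithmetic on a cohort with the published
structure — not that the generator mimics an institutional case mix in any
finer sense.

## Known source inconsistencies

- The published narrative reports treatment changes for 164 (73 %)
  patients, but under the published trajectory table and transition counts
  the number of patients whose final regimen can differ from baseline is at
  most ≈ 137; the packaged plan yields 133, reported as a soft note.
- The narrative's "5 additional patients treated in DIBH" conflicts with
  the trajectory table's net +16; the table is followed (it reproduces the
  65,150-minute final linac total).
- The published per-change delta grid (and the one-week change's headline
  figures of €47,489 / 13,820 min) cannot be reconciled exactly with the
  verified baseline and final totals under any single per-patient
  parameterisation; the package reports its own per-change deltas, which
  telescope exactly to the verified overall deltas (the one-week step
  computes to −€47,381 / −16,492 staff-time minutes at the packaged
  calibration).

## Numerical and degenerate-input conventions

Totals are plain float sums over ≤ a few hundred patients of values ≥ 1,
so floating error is far below the €1 reporting tolerance. Percentage
deltas against a zero baseline are reported as undefined (None/empty
cell). Zero-task care paths and empty cohorts yield zero totals; a
fractionated regimen must contain a per-fraction linac task; aggregate
calibration requires n > 0; slot tables must price DIBH at or above free
breathing for the same nodal class. Problem sizes everywhere are the
224-patient cohort; the full pipeline, test suite and acceptance script
run in seconds on one CPU.
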