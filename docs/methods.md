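# Methods

## Claims model

The unit of analysis is a reimbursement dispensing record: an anonymised
patient, a dispensing date, the prescribed and dispensed
(substance, strength) pair, a quantity of dose units, and channel
metadata (paper/electronic form, brand/INN prescribing, pharmacy and
physician identifiers). The default cohort is ICD-10 I48.0–I48.4 and
I48.9 (atrial fibrillation and flutter) dispensed between 2012-01-01
and 2022-12-31; both the code set and the window are configuration.
Diagnosis matching is exact against the configured set — no prefix
expansion — and substance names are lowercased INN with a small alias
table (e.g. the clopidogrel/aspirin combination). Strengths are carried
as decimal milligrams and compared for exact equality (2.5 mg apixaban
is representable exactly; all marketed strengths here are multiples of
0.5 mg). Row-level validation rejects, rather than aborts on, bad rows;
a strict mode promotes rejections to failures.

## PDC with carryover

Let a patient's fills of one agent be `(t_i, s_i)` with days of supply
`s_i = floor(quantity / doses_per_day)` capped at 90 days (the 3-month
prescription course limit). Same-day fills of the same agent are merged
by summing supply and re-capping. Coverage is accumulated
chronologically with unlimited stockpiling: the exhaustion date after
fill `i` is `max(exhaustion, t_i) + s_i`. The observation window is the
half-open interval `[t_1, t_k)`; the numerator is the number of covered
days inside it and the denominator is `t_k − t_1`.

Design choices that were genuinely open:

* **"Omitting the last prescription."** Read as: the window ends at the
  last dispensing date and the last fill's supply opens no covered days
  (with half-open clipping this falls out automatically). The
  alternative reading — drop the final fill entirely and end the window
  at the new last fill — is available as
  `denominator_mode="drop_last"` for sensitivity analysis. The default
  matches the standard refill-interval PDC and makes a gapless refiller
  score exactly 100%.
* **Half-open day convention.** The first fill date is a covered day,
  the last is outside the window; gapless refills score exactly 100%.
* **Group boundaries.** PDC exactly 80 or exactly 90 falls in the
  middle group (`<80`, `[80, 90]`, `>90`).
* **Pooled DOAC scope.** Stock ledgers are kept per agent and a day is
  covered when any ledger covers it (set union). Stocks are never mixed
  across agents, so a switch day cannot be counted twice. With one
  agent this reduces exactly to the single-agent metric.
* **Strength changes within an agent** are treated as one supply
  stream; the record does not reveal whether the prescriber intended a
  regimen reset.
* **Carryover-off variant** (each fill covers only its own interval) is
  a config switch used for sensitivity; it is provably never larger
  than the carryover metric.

Patients with fewer than two merged fills, or with all fills on one
date, are excluded with a reason rather than scored. Cohort summaries
report both mean and median PDC, since a single "total adherence level"
can reasonably be either aggregate.

The implementation is interval arithmetic (segment union); its
correctness oracle is a deliberately naive day-by-day simulation
(`synth.truth_pdc`) that materialises a per-day coverage array with
per-agent stock counters. The two are required to agree exactly — not
approximately — on random fill sequences and on every generated
patient.

## Dispensing errors

The conformity cross-tab counts prescriptions by prescribed key (rows)
and dispensed key (columns), restricted to a configured substance set
(default: the four DOACs). A mismatch is any off-diagonal cell —
substance or strength differing — with direction labels
`dispensed_higher`, `dispensed_lower`, `other_substance`; no clinical
severity grading is attempted. The headline rate supports two
denominators because the published conformity table's cell sum
(704,327) differs slightly from the stated sub-cohort size (704,521)
without explanation; the package takes neither as "correct" and exposes
both (they round to the same 1.1%). Off-list prescribing (a substance
outside the approved reimbursement list for the diagnosis group) is
flagged separately at the record level.

## Utilisation trends

Yearly tables key on the dispensing year (the database rows are
dispensed prescriptions). Switchers are patients with ≥2 distinct
anticoagulant molecules *prescribed* over their full history —
prescribing, not dispensing, defines a therapy change, which also makes
the classification robust to one-off dispensing substitutions.
Categories `warfarin_to_doac` (a DOAC after the first warfarin) and
`among_doacs` (≥2 distinct DOACs) may both hold for one patient; the
distinct-molecule distribution is reported as exclusive counts.
Pharmacy spread is reported both as exclusive (exactly k pharmacies)
and cumulative (≤k) shares, because "visited one or two pharmacies" is
a cumulative statement.

## Group statistics

Welch's heteroscedastic ANOVA (weighted means, Welch–Satterthwaite
denominator df) tests age differences across adherence groups; it is
implemented directly from the textbook formulation and cross-checked in
the test suite against an independent implementation. The chi-square
goodness-of-fit test compares observed category counts (females per
adherence group; switchers per group) against expected counts
**proportional to the adherence-group sizes** — the "no deviation from
a random distribution among the groups" null. That expected
construction is a config surface (`gof_expected`), since other
constructions are defensible. p-values are reported rounded to three
decimals alongside the exact value; no multiple-testing correction is
applied.

## Synthetic cohort generator

The generator emulates the study conditions of a national AF/flutter
reimbursement extract: age ~ N(75, 9.6) years, 59.6% female, therapy
onset uniform over the window (leaving ≥180 days of history),
warfarin-only initiation before 2018, DOAC-era initiation weighted
toward rivaroxaban with market-entry years 2018 (rivaroxaban,
dabigatran), 2019 (edoxaban) and 2020 (apixaban), switch probability
0.418, per-row dispensing-error rate 0.011 (90% adjacent-strength,
10% cross-substance — mirroring the near-diagonal published conformity
structure), off-list rate 0.0005, electronic-prescription adoption
jumping from ~1.5% (2017) to 80.6% (2018) and 98.7% (2022), INN
adoption jumping to 61.2% in 2020, and a distinct-pharmacy count per
patient with P(1) = 0.167 and P(≤2) = 0.277. These mirror the published
regime shifts and cohort margins; where no value was reported
(antiarrhythmic co-medication 40%, supply mix 30/60/90 days weighted
0.60/0.15/0.25, diagnosis-code and speciality mixes) a single realistic
choice was fixed.

Refill behaviour is one-parameter: each patient draws a gap-inflation
factor `g` from a lognormal (median 1.35, σ = 0.35, clipped to
[0.8, 3]) and refills `round(g·supply)` days (±2-day jitter) after the
previous fill, so true PDC ≈ min(100, 100/g) and mean cohort PDC under
the defaults lands in the low-70s with roughly 40% of patients above
80% — the adherence character of real oral-anticoagulant cohorts. The
median 1.35 was chosen once for that character, not fitted to any
reported aggregate.

All randomness flows from `default_rng([seed, sha256(patient_id)])`, so
cohorts are byte-reproducible and extensible: growing `n_patients`
leaves existing patients' histories unchanged. Ground truth (true PDC
per patient and per agent via the day-by-day oracle, switcher
structure, per-row error and off-list flags, pharmacy counts) is
recorded at emission time.

What the generator does **not** emulate: persistence/discontinuation
(therapy runs to the window end), dose titration within an agent,
mid-study ageing, seasonal dispensing, hospitalisation gaps, pharmacy
market structure, or any correlation between adherence and
demographics. Passing recovery tests therefore demonstrates that the
pipeline measures what the generator encodes — not that real cohorts
satisfy the generator's assumptions.

## Verification set-up and problem sizes

Property tests (hypothesis, derandomised) and a seeded 1,000-sequence
sweep require exact interval-vs-oracle agreement, translation
invariance, the [0, 100] range, monotonicity under an added interior
fill, and carryover dominance. Parameter recovery runs at 5,000
patients (~230k rows) and asserts every generator dial — female
fraction, error rate, switch probability, per-year channel adoption,
off-list rate, pharmacy distribution — within three binomial standard
errors; the gap-inflation sweep checks mean PDC decreases monotonically
in `g`. Type-I error of both tests is simulated at 500 null replicates
(α = 0.05, accepted within three Monte-Carlo standard errors).
Published-table quantities are recomputed deterministically from the
packaged fixtures and must match the printed values at printed
precision. `scripts/acceptance.py` re-runs all of this from scratch in
well under a minute.

## Known limitations

* The PDC denominator requires an observed refill history; recently
  initiated patients (one fill) are excluded, which in short windows
  biases the scored population toward established users.
* Dispensing errors are detected as key mismatches only; quantity
  mismatches and legitimate pharmacist substitutions are
  indistinguishable from errors in claims data.
* The goodness-of-fit expected vector is a modelling choice; with
  group-size-proportional expectations the test is asymptotically
  calibrated only when the flagged subset's group membership is
  i.i.d. across patients.
* Calendar arithmetic is whole-day; time-of-day and partial supplies
  are out of scope.
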