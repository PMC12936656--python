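# Methods

## Data model

A prescription record carries: patient and prescription identifiers,
issue and dispense dates (whole calendar days — the resolution the whole
pipeline operates at), the ATC code, up to three active-substance
components with strengths (mass, volume, unit-count or international
units), the free-text drug form, the optional daily-dose fields (times
per day/week, amount per administration with its unit, free text), the
optional prescriber-entered course length ("provided DS", days), and the
dispensed-package quantities (package count, units per package for
countable forms, item size for measured forms). Since no public schema
exists for e-prescription exports, readers accept a column-mapping
dialect; files are delimited UTF-8 text with ISO-8601 dates.

Validation distinguishes errors (violations that make DS resolution
impossible: zero packages, no components, dispense before issue) from
warnings (everything else, e.g. a dose frequency without its period);
the pipeline's purpose is to salvage incomplete records, so it rejects
as little as possible.

## Cleaning

*Substance correction.* The dispensed package is authoritative for the
active-substance composition: wherever the package registry disagrees
with the record, the registry components are substituted and a
provenance note appended. Correction is applied wherever a disagreement
exists (no attempt is made to date-scope it), and is idempotent.

*Refill-series artifact.* A recurring entry error stamps each member of
a same-day refill series with the *combined* course length (typically
180 days for 3 × 60). Series of two or more same-patient,
same-substance, same-issue-date prescriptions whose provided DS all
equal the configured artifact value are flagged; with the fix enabled
their provided DS is suppressed (treated as absent) — never rewritten to
a guessed share, since only the error, not the correction formula, is
well established. The fix is off by default.

## Daily-dose normalisation

The daily dose is `dose_times` (per day, or per week divided by 7) times
the amount per administration. Amounts come in several notations:

- **unit-count** ("2 tablets"): used directly;
- **substance amount** ("10 mg"): divided by candidate component
  strengths. For combination products the candidate order matters: a
  5 + 10 mg product prescribed as "5 mg", "10 mg" or "15 mg" always
  means *one unit*. Parsing therefore first accepts any candidate whose
  quotient is exactly 1 (summed strength first, then singles), then
  falls back to the summed strength and each single strength largest
  first, gated by a plausibility range (default 0.25–20 units/dose) and
  a dosing granularity grid (default 0.25 units — quarter-tablet steps).
  The gate rejects unit-confusion artifacts such as a milligram figure
  entered as a unit count; implausible amounts raise a parse error and
  the record falls through to imputation;
- **volume**: as above against volume strengths;
- **drops**: converted to millilitres with a per-substance
  drops-per-mL table (drop size varies with formulation; default 20
  drops/mL, overridable per substance).

## Drug-form stratification

Records are stratified into 14 groups (single-dose, semisolid, nail
polish, ear/eye/oral drops, inhalation, nasal spray, syrup, transdermal
patch, intravaginal contraceptive, implant/vaccine, insulin injection,
other) by an ordered keyword match on the drug-form text, with ATC-prefix
fallbacks for uninformative texts ("solution for injection" → insulin for
A10A, vaccine for J07). Subgroups with distinct imputation rules are
assigned by ATC prefix: anti-infective/anti-inflammatory eye drops
(S01A/S01B/S01C), antifungal nasal spray (R01AX), antibiotic syrup (J01),
hormonal (G03) and analgesic (N02) patches; single-dose-container eye
drops are recognised from the form text. The mapping is configuration
(YAML-swappable), not ground truth: the group definitions name
therapeutic classes, and the shipped prefixes are one defensible
encoding. Classification is total and deterministic; unmatched records
land in `other`.

## Days'-supply resolution

*Calculation.* `DS = floor(total dispensed units / units per day)`, with
a minimum of one day. Floor encodes "full days of coverage"; rounding is
configurable (floor/round/ceil). Countable forms use
packages × units-per-package; measured forms (volume/drops doses) use
packages × item-size. For single-dose-container eye drops the countable
unit is the container, one container per administration.

*Reconciliation.* When both a calculated and a provided DS exist, the
smaller wins: pharmacies may dispense a larger package than the course
needs, so the smaller figure better estimates the course length. The
comparison applies in every rule chain that both calculates and consults
the provided value (disable with `reconcile_in_chains=False`). Provided
DS values above a plausibility cap (default 365 days) are used but
flagged in the trace — warn-only, never rewritten.

*Mode imputation* (single-dose forms only). The mode table maps
(sorted substance names, sorted strength signature) to the strictly most
frequent observed daily dose. Ties at the top frequency exclude the key
— tie-breaking by any rule would fabricate a mode — as does support
below `min_support` (default 1; the statistically cautious can raise
it). Exclusion operates at the substance × strength key, not the whole
substance, because dosing is strength-specific. Excluded or absent keys
leave the prescription unimputed. Mode counting is order-invariant.

*Form rule chains.* Each non-single-dose group runs an ordered strategy
chain; shipped defaults:

| group | chain |
|---|---|
| semisolid | provided → 30 d × packages |
| nail polish | provided → 210 d (package ≥ 3 mL) / 180 d |
| ear drops | provided → 7 d |
| eye drops (multi-dose) | provided → 30 d × packages |
| eye drops (anti-infective) | provided → 14 d × packages |
| eye drops (single-dose containers) | calculate → provided → 30 d |
| oral drops | calculate → provided → 30 d |
| inhalation | calculate → provided → 60 d |
| nasal spray | calculate → provided → 30 d |
| nasal spray (antifungal) | calculate → provided → 7 d |
| syrup | calculate → provided → 30 d × packages |
| syrup (antibiotic) | provided → 14 d |
| patch | provided → 7 d × patches |
| patch (hormonal) | provided → 7 d × patches + 7 d |
| patch (analgesic) | provided → 3 d × patches |
| intravaginal | provided → 30 d × items |
| implant/vaccine | 1 d (provided DS deliberately ignored: no entry standard exists) |
| insulin | provided → 60 d |
| other | provided → unresolved |

Constants derive from product-characteristics summaries and prescribing
conventions: short anti-infective courses, 30-day shelf lives of opened
multi-dose containers, the 2-month chronic-prescription convention
(inhalation, insulin), patch wear times. The whole rule set is a YAML
config; every constant is overridable. Which of the two nail-polish
package types maps to 210 vs 180 days is not documented anywhere
authoritative; the larger package → 210 d, with the size threshold
configurable.

*Small-group policy.* Form groups with fewer than 1000 prescriptions in
the batch (configurable) are restricted to the provided-DS strategy:
imputation rules tuned on a handful of records are not trustworthy.

*Baseline comparator.* Calculate from the daily dose where possible
(single-dose forms); otherwise impute a flat 30 days. The provided DS is
not consulted. This is the cheap comparator the full pipeline's value is
measured against.

Resolution is total: every record yields a result with a method tag
(`calculated`, `provided`, `min_of_calculated_and_provided`,
`mode_imputed`, `form_imputed`, `baseline_imputed`, `unresolved`) and a
human-readable trace; the run report aggregates counts and per-group
percentages.

## Adherence (CMA5)

For one patient-medication stream, the observation window is
`[first dispensing, last dispensing)` — half-open, so the final fill
closes the window and its supply is discarded along with any other stock
outstanding at the window end. Stock accumulates at each fill and is
drawn down one day of supply per covered day (carryover: a refill
dispensed early is stored). CMA5 = covered days / window days ∈ [0, 1].
The interval implementation (per inter-fill gap, `min(stock, gap)` days
covered) is exactly equal to a literal day-by-day simulation, which the
package also ships as the test oracle; equality is asserted exhaustively
on small windows and on seeded random streams.

Yearly adherence uses each calendar year's fills as an independent
window (no cross-year stock carry-in — the conservative reading of
"yearly basis"), requires at least two fills in the year, keys streams
by full ATC code, and reports at the 3-character therapeutic-subgroup
level. Records with unresolved DS are excluded from adherence input
rather than defaulted.

Two-period QC (defaults 2012–2015 vs 2017–2019, the transition year 2016
excluded): per subgroup, mean DS with a normal-approximation 95% CI
(mean ± 1.96 sd/√n), banded green/yellow/red by the absolute
between-period mean difference with closed boundaries at 7 (green
includes 7) and 30 (yellow includes 30) days; and mean CMA5 per period
with its change, comparable side by side between the baseline and
corrected resolutions.

## Synthetic cohorts

The generator emulates the structure of a national dispensing extract
under the documented study conditions, with per-record ground truth.

- **Catalog**: ~30 synthetic substances spanning all 14 form groups —
  ten chronic tablet products (60-unit packages, daily-dose
  distributions putting 0.7 on the modal dose, including one 5 + 10 mg
  combination), acute tablets, and one or more representatives of every
  other group. Weights make tablets ≈ 55% of prescriptions.
- **Streams**: chronic substances refill continuously across 2012–2019
  with inter-fill gaps uniform in [0.9, 1.2] × the fill's true DS
  (occasional gaps and stockpiling); acute substances produce 1–3 fills.
  The daily dose is redrawn per dispensing (dose titration between
  refills), which makes the per-record modal share of every
  substance-strength key equal the configured modal probability — the
  property mode-recovery checks rely on.
- **Notation**: unit-count / single-component-mass / summed-component-mass
  in a 0.50/0.25/0.25 mix, with a 10% chance an integer daily frequency
  is written per week; volume and drop doses for liquid forms;
  qualitative-only dosing for semisolid-like forms.
- **Missingness**: era of the *dispensing date* against the mid-2016
  cutoff — before: daily dose missing with p = 0.674, provided DS
  present with p = 0.152; after: 0.004 and 0.361. The provided DS, when
  present, equals the true DS.
- **Error injection** (separate, off by default): same-day refill-triple
  stamping with the combined 180-day course, and substance falsification
  recoverable from the registry.

What the generator does *not* emulate: real substance prevalence,
prescriber idiosyncrasies beyond the stated rates, dose-change-without-
renotation errors, partially-wrong provided DS values, or OTC/inpatient
gaps. Passing tests therefore demonstrate the pipeline's correctness
under the stated missingness and error regimes, not its accuracy on any
particular national dataset.

## Problem sizes and numerics

The shipped tests use a 300-patient cohort (~24,000 prescriptions,
≥ 10,000 of them pre-cutoff quantitative-dose records), large enough
that every chronic substance-strength key has mode-table support in the
hundreds while the whole suite runs in seconds. Missingness realism is
asserted against the 99% binomial CI at the realised n. CMA5 equality is
checked exactly (integer day arithmetic; both implementations divide the
same integers). Daily doses are keyed after rounding to 6 decimals to
absorb representation noise from weekly frequencies (4/7 per day).

## Known limitations

- Free-text dosing instructions are not mined beyond the structured
  fields; qualitative instructions ("once daily") carry no quantity and
  are treated as absent.
- The mode table assumes the observed dose distribution of a key is
  stationary; where regimens vary with disease severity the modal dose
  can systematically over- or under-shoot (visible as implausibly high
  adherence for some groups).
- Machine-learning dose imputation is out of scope.
- Cross-year stock carry-in for yearly CMA5 is available via
  `yearly_adherence(..., carry_in=True)` but is not the default; with
  carry-in disabled, December stockpiles are forfeited at the year
  boundary.
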