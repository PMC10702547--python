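# Methods

## Data model and ingestion

FAERS-style quarterly extracts are `$`-delimited ASCII tables with a header
line and no quoting mechanism. `faerspv.io` parses six table kinds (DEMO,
DRUG, REAC, OUTC, THER, INDI) plus a deleted-case list into string-typed
pandas frames, matching header names case-insensitively against a synonym
map (extensible in the run config; the shipped map covers the recent layout
plus the legacy `ISR`/`GNDR_COD` aliases). Because the format cannot escape
its delimiter, a `$` inside a value is a hard error on write and a skipped,
counted line on read. Child-table rows whose `primaryid` is absent from DEMO
are dropped with a logged count rather than treated as fatal — spontaneous
report data is dirty by nature.

Dates are partial (`yyyymmdd`, `yyyymm`, `yyyy`) and are preserved as
strings; each stage applies its own resolution rule. Comparisons use the
monotone key (year, month-or-0, day-or-0), so a missing component compares
as earliest. `parse_partial_date` validates calendar bounds (leap days
included) and never raises.

## Deduplication

One case accumulates versions; per `caseid` the version with the latest
`fda_dt` survives, ties broken by the numerically larger `primaryid`, and
cases on the deleted list are removed entirely. Deduplication is applied
globally across all pooled quarters, not per quarter, since a case's
versions may span periods. The rule is idempotent and order-independent
(both property-tested), and the audit report satisfies
`kept + removed_duplicates + removed_deleted = total_in` by construction.

## Cohort definition and characterisation

A report enters the cohort when any drug mention matches a query name by
case-insensitive, whitespace-normalised substring containment on the
verbatim drug name and/or active-ingredient field, *and* the mention's role
code is accepted (default: `PS` only — primary suspect — trading recall for
specificity). No spelling correction or ingredient-dictionary mapping is
attempted.

The demographic summary forces one outcome category per report by a
most-serious-outcome precedence, DE > LT > DS > HO with everything else
(CA, RI, OT, or no outcome record) as "other"; the precedence is a
configurable argument since reporting conventions differ. Age bins are
<18, 18–65 (inclusive at both ends), >65; ages convert to years via
YR=1, DEC=10, MON=1/12, WK=1/52.18, DY=1/365.25, HR=1/8766. Reporting year
is the year of the surviving version's receipt date (`fda_dt`), chosen over
the event date because the latter is frequently missing. Country is the
occurrence country with reporter country as fallback. Every tally group
keeps unknowns as explicit categories so each group sums exactly to the
cohort size; percentages are half-up at 2 decimals (banker's rounding would
misprint tied values).

## Contingency tables

Counting is report-level at both PT and SOC level: a report listing a term
twice, or two terms of one organ class, contributes one count. This makes
`a+b = |cohort|` and `c+d = |background|` for every label — the invariant
the tests enforce — and matches the only reading under which published
SOC-level case counts (subsets of the cohort size) are coherent. Cohort and
background cells are disjoint: the background is "all other drugs". Labels
with `a = 0` are omitted. PT strings are matched case-insensitively with
whitespace collapsed, preserving a representative verbatim spelling for
output. SOC aggregation uses a user-supplied two-column CSV (MedDRA is
licensed and not shipped); unmapped terms are grouped under `UNMAPPED` and
logged.

## Estimators and criteria

Formulas as in the README. Numerical notes:

* **Zero cells.** No continuity correction by default — the printed-formula
  convention of the screens this package reproduces; statistics that would
  divide by zero become NaN, are flagged undefined, and never satisfy a
  criterion. `continuity=0.5` (Haldane–Anscombe, added to all four cells)
  is available for robustness studies; the criterion threshold `N ≥ 3`
  always uses the raw `a`.
* **IC variance.** Two modes. `standard` (default) is the closed-form
  posterior-variance approximation of the BCPNN with Beta priors
  (γ₁₁ = α₁ = β₁ = 1, α = β = 2), delta-propagated to log2. `fixed_offset`
  sets IC025 = IC − 1.67, a fixed half-width observed in some published
  screens whose variance convention is not stated; it exists to reproduce
  such tables side by side.
* **PRR boundary.** PRR ≥ 2 is inclusive.
* **Identities.** Because EBGM here is the unshrunk relative reporting
  ratio, IC = log2(EBGM) exactly, and both log-normal intervals have the
  point estimate as the geometric mean of their bounds; both identities are
  property-tested and serve as consistency checks on any published table.
  Note EBGM/IC are *not* monotone in `a` with the margins free (`a` appears
  in both), unlike ROR and PRR.
* **Output.** Full precision in CSVs; an optional paper-style export adds
  2-decimal columns. Results sort by descending `n`, then label.

## Time to onset

Onset is event date minus the earliest day-resolved therapy start among
THER rows referencing a matched drug mention (first exposure). Only fully
day-resolved dates qualify; exclusions are tallied by reason (missing or
partial event date, missing or partial start date, negative interval) so
that retained + excluded equals the cohort size. Day 0 is valid. The
summary uses half-open 30-day bins [30(k−1), 30k), k = 1..12, with a
terminal ">360" bin, and quartiles by linear interpolation between order
statistics (numpy's default) — chosen as the common convention; nearest-
order-statistic quartile definitions will disagree on tiny samples.

## Synthetic-report generator

`simulate()` draws, per case: exposure to the study drug as primary suspect
(probability 0.02 by default), a truncated-geometric number of preferred
terms (p = 0.45, max 8, mean ≈ 2.1), and the terms themselves from a
60-term, 10-SOC vocabulary with Zipf-like baseline probabilities. Injected
associations multiply an exposed case's term probabilities by λ and
renormalise — the multinomial tilt under which "the estimator recovers λ"
is well posed. The generator then adds the messiness the pipeline must
survive: duplicate versions (probability 0.1; same caseid, higher
primaryid, later receipt date, occasionally a blanked demographic field),
deleted cases (0.02), concomitant role-C drug mentions (Poisson, mean 0.7,
including rare non-exposed mentions of the study drug that the role filter
must exclude), repeated terms within a report, and a day/month/missing
date-quality mix (0.6/0.1/0.3). Demographic category mixes follow the
published characteristics of a real oncology-drug cohort; onset times are
log-normal with median 54 days and σ = 1.4 (back-solved from a published
17–112 day interquartile range). All randomness flows from a single seed
through one generator; equal seeds give byte-identical files.

`expected_table()` returns the closed-form expected 2×2 cells — exposure ×
deletion survival × the containment probability
`Σₖ P(K=k)(1−(1−q)ᵏ)` under the tilted or baseline term distribution — so
recovery tests compare estimates against model-implied values rather than
against λ itself (the two differ once containment is non-rare; likewise the
model-implied ROR, an odds ratio, exceeds the implied relative reporting
ratio).

What the generator does **not** emulate: drug co-reporting structure and
masking/competition bias, reporting-trend drift over calendar time, real
term vocabularies, or free-text name noise beyond simple brand/strength
variants. Passing recovery tests therefore demonstrates estimator and
plumbing correctness under the stated generative model, not robustness to
those real-data phenomena.

## Validation experiment and problem sizes

The recovery experiment (`faerspv.validation`) runs the full pipeline on
100 seeded replicates of 10,000 cases with injections λ = 5, 20, 50 placed
on terms whose expected `a` exceeds 20 for at least two of them. Judged
quantities: the median EBGM across replicates per injected term against its
model-implied value (the per-replicate sampling s.d. of ln EBGM is ≈ √(1/a),
so an aggregate-over-seeds comparison is the statistically meaningful one at
these counts); ROR interval coverage of the model-implied odds ratio; and
the all-four-criteria false-positive rate over the λ = 1 terms (< 1%). The
10⁴-case, 100-replicate size keeps the whole suite in tens of seconds on a
single CPU while leaving expected counts large enough for the stated
checks; Monte-Carlo agreement of the generator with its closed form is
additionally checked once at 10⁵ cases within 4 standard deviations.

## Known limitations

* EBGM is the unshrunk relative reporting ratio; true gamma-Poisson
  shrinkage (and Monte-Carlo IC credible intervals) are out of scope, so
  small-count estimates are noisier than a shrunk screen would give.
* No multiple-comparison adjustment is applied, matching common screening
  practice; interpret single flagged labels accordingly.
* Indications (INDI) are parsed and carried but not analysed.
* Matching is substring-based; verbatim names that misspell the drug are
  missed.
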