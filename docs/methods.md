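# Methods

## Problem and scope

`faerspv` implements a spontaneous-report pharmacovigilance analysis of the
kind run against the FDA Adverse Event Reporting System (FAERS): ingest the
quarterly report tables, reduce them to one report per case, extract a drug
cohort by name lexicon at the primary-suspect role, characterize the case
series for one system organ class (SOC), measure time to onset, and detect
drug–event reporting associations with the reporting odds ratio (ROR).  The
reference configuration is the GLP-1 receptor agonist (GLP-1 RA) class —
exenatide, liraglutide, lixisenatide, dulaglutide, semaglutide, tirzepatide —
scanned against the psychiatric disorders SOC (MedDRA code 10037175).

Disproportionality analysis measures *reporting* association only.  Nothing
in this package estimates incidence or causality; a "signal" is a statistical
flag for prioritizing clinical review, not an effect estimate.

## Ingestion and dates

Quarterly extracts are dollar-delimited tables with one header line (DEMO,
DRUG, REAC, OUTC, THER, INDI); the delimiter is configurable so fixtures can
use friendlier dialects.  DEMO, DRUG and REAC are mandatory.  Rows with an
unusable `primaryid` are quarantined with their row number and counted,
never silently dropped; child rows without a DEMO parent are counted as
orphans.  Reaction preferred terms (PTs) are de-duplicated case-insensitively
within a report because all downstream counting is at report level.

FAERS dates are frequently partial.  `parse_date` keeps partial dates and
attaches a precision flag (`day`/`month`/`year`/`none`) rather than nulling
them; each stage applies its own usability rule.  De-duplication compares
receipt dates by their known prefix, treating a day-precision date as more
recent than a month-precision date in the same month (more information =
more recent knowledge).  Time-to-onset requires day precision on both sides.

## De-duplication

FAERS publishes every version of a case.  One report per case is retained by
two criteria: the most recent FDA receipt date wins; receipt-date ties are
broken by the numerically larger `primaryid` (lexicographic fallback for
non-numeric ids).  The procedure is order-independent, idempotent, and emits
an audit file naming the rule used per case.  Cases without a `caseid` are
quarantined and reported.

## Cohort extraction and SOC tagging

A report enters the cohort when a DRUG row with role code PS (primary
suspect) matches the lexicon.  Matching is case-insensitive on
punctuation-normalized tokens by exact equality or whole-word containment
(`"ozempic 0.5 mg pen"` matches semaglutide; no stemming, no edit distance).
Both `drugname` and `prod_ai` are matched by default since reporters use
either; the field set is configurable.  PT→SOC assignment uses a supplied
single-primary-SOC table; the MedDRA dictionary is licensed and is not
shipped — tests and the synthetic generator use a fixture catalog.  Unmapped
PTs are tagged and counted, never dropped.  A report naming two regimens as
primary suspect counts once overall and once per regimen, which is why
per-regimen rows can sum to slightly more than the overall row.

## Descriptives

Categorical blocks (sex, age known/unknown, reporting region, reporting
year, reporter occupation, indication group, outcome) always carry an
explicit Unknown row, so each block's counts sum to the stratum size.
Percentages are computed against the stratum case count and rounded half-up
to two decimals.  Outcomes are collapsed to one slot per report — the most
serious listed code under the conventional severity order (death >
life-threatening > hospitalization > disability > congenital anomaly >
required intervention > other) — so the outcome block also conserves counts;
reports listing no outcome are Unknown.  Ages are converted to years from
FAERS unit codes (decades ×10, months /12, weeks /52, days /365.25).
Quantiles use linear interpolation between order statistics (numpy's default
rule), which is what yields fractional IQR bounds such as 145.4 days from
integer data; the rule is configurable.

## Time to onset

Onset is the interval in days from the earliest day-precision therapy start
among THER rows linked to a matched primary-suspect drug (first exposure =
initiation) to the report's single DEMO event date.  Only strictly positive
onsets are usable; every report receives exactly one status: `included`,
`excluded_missing` (either side absent or not day-precise),
`excluded_invalid_order` (dosing after the event), or `excluded_nonpositive`
(0 days).  Bin edges are half-open (lo, hi] on integer days, so the 0–30 bin
covers days 1–30 and 360+ is unbounded; bin counts conserve the included
total by construction.  A regimen with fewer than 5 usable onsets (default)
is summarized as *insufficient* and excluded from between-regimen
comparison, with the exclusion logged.

No canonical test exists for comparing onset distributions in this setting.
Because the quantity is a heavily skewed duration summarized by median/IQR,
the primary comparison is a global Kruskal–Wallis test with pairwise
two-sided Mann–Whitney tests, Holm-adjusted; a log-rank variant over the
cumulative curves is available because onsets are durations (all events
observed, no censoring model).  Pairwise p-values are validated against a
brute-force permutation test on the same U statistic.

## Disproportionality

For a drug set D and event set E over the full de-duplicated universe, each
report lands in exactly one cell of the 2×2 table (a = D-report with an E
event, b = D-report without, c/d the same for the comparator), so a+b is the
total D report count and the four cells sum to the universe.  Then

    ROR = (a·d)/(b·c),
    95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) ).

A pair is a signal when a ≥ 5 and the lower CI bound (ROR05) exceeds 1.  The
count floor — 5 rather than the conventional 3 — is the only false-positive
control; no multiple-testing adjustment is applied, which is standard in
this analysis style and a known limitation.  Any zero cell yields a
not-computable result; a Haldane +0.5 correction exists behind a flag, off
by default, since the count floor already guards sparse tables.  The
comparator is "all other drugs": reports whose PS drugs include no member of
the analyzed set — so when one regimen is analyzed, sibling-regimen reports
fall in the comparator.  A class-exclusive comparator (sibling reports
removed) is available for sensitivity analysis.  Grouped-category RORs treat
a PT set as one event with the same report-level counting, so co-reported
PTs never double-count.

Event-level counting is report-level everywhere: two matching PTs on one
report contribute one count.  This is required for the a+b margin to equal
the drug's total report count.

## Synthetic universe

The generator emits a parseable quarterly bundle plus exact ground truth:
the surviving version per case, cohort and target-SOC membership, the exact
2×2 cells of every planted association (computed from the emitted case-level
facts, so recovery checks are deterministic), and every cohort case's true
onset before date corruption.  Identical configs give byte-identical files.

Defaults emulate the GLP-1 RA psychiatric case series wherever the published
margins state a value: the six-regimen mix follows the published all-AE
report shares; sex (65.9/31.0/3.1), region (≈93% North America), occupation
(≈80% consumer), indication and outcome margins follow the published
case-series distributions; the usable-onset fraction is 18.3% with small
invalid-order and same-day corruption rates; partial dates appear as month-
or year-precision strings.  Onsets are log-normal per regimen with the
published medians (45/16/7/12/10 days; 31 for the regimen lacking published
onset data) and sigmas derived from the published IQRs via
q75/q25 = exp(2·0.6745·σ); draws are clipped at 6,000 days so therapy dates
stay on the calendar.  Planted associations carry the eight published signal
RORs (1.28–3.77) as true odds ratios via an exact odds transform of the
comparator-arm rate; the fallback that guarantees every report at least one
reaction draws only from non-target-SOC null PTs, so analyzed event rates
stay exactly Bernoulli in each arm.

Two quantities are deliberately *not* at the published scale.  The universe
is desk-sized (default 20,000 cases versus 16.5 million), and the
target-drug share and planted-event background rates (0.001–0.005) are
raised so that planted associations can reach the a ≥ 5 count floor at that
size; at the published per-report rarities every planted signal would be
invisible in a desk-scale universe.  A consequence is that the synthetic
target-SOC share runs a few points above the published 4.55%.  What passing
tests show, therefore, is that the machinery recovers exactly what was
planted under realistic dirty-data mechanics — not that the generator
reproduces FAERS's marginal distributions, which it does not attempt beyond
the stated margins (no drug-drug correlation structure, one event date per
report, no secular reporting trends, single-regimen reports by default).

## Numerical and design choices

- Percentages: decimal half-up rounding to 2 places (not banker's rounding),
  matching how such tables are conventionally printed.
- Quantiles: linear interpolation; configurable via any numpy rule.
- ROR z-quantile: 1.96 by default (the printed convention); any quantile can
  be passed, e.g. Φ⁻¹(0.975) for agreement with statsmodels to 9 decimals.
- Scan ordering: signals first, descending ROR.
- Degenerate inputs: empty quantile input returns absent (not 0); empty
  report universes raise; all-tie onset comparisons are skipped with a
  reason; zero-cell tables are not-computable results, not exceptions.
- Problem sizes in tests and the acceptance script (universes of 2,000 to
  20,000 cases, 1,000-replicate coverage simulations, 10,000-resample
  permutation oracles) are chosen so the whole suite runs in minutes on one
  CPU while keeping every statistical check adequately powered.

## Known limitations

Signal detection inherits every spontaneous-reporting caveat: no exposure
denominator, reporting bias, duplicate reports beyond the two-criterion
rule, and confounding by indication.  The pipeline neither adjusts for
multiplicity (by design, matching the method it implements) nor models
within-case correlation of events.  The onset comparison assumes the usable-
onset subset is representative, which underreporting may violate.
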