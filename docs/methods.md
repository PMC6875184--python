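# Methods

## The phenotype and its screens

A member is algorithm-positive when, inside the study window (default
2010-01-01 through 2014-08-31, both ends inclusive), she has at least one
**inpatient** claim carrying an ICD-9-CM category-182 diagnosis, or
outpatient claims with such a diagnosis on at least two **distinct**
service dates. Two outpatient diagnoses on the same day never qualify: a
same-day pair is more likely a single encounter billed twice than
corroborating evidence. Any inter-diagnosis duration is allowed as long as
both dates fall in the window. Codes in category 179 (malignant neoplasm
of uterus, part unspecified) are deliberately excluded from qualification —
a specificity-over-sensitivity trade appropriate when downstream studies
need a high PPV.

Rule constants live in `AlgorithmConfig` and are all overridable: target
prefixes (`{"182"}`), excluded prefixes (`{"179"}`), washout category range
(140–209, the ICD-9 malignant-neoplasm chapter), study window, baseline
length (365 days), enrollment gap tolerance (0 days), and the two
qualification thresholds.

Decisions the phenotype definition leaves open, and how this package
resolves them:

- **Index date** — the earliest diagnosis date among met criteria (for the
  two-outpatient route, the first of the two). Earliest evidence is the
  natural anchor for an *incident* case.
- **Route assignment** — a member can meet both criteria; strata need a
  partition. The member is `inpatient` when her first inpatient target
  diagnosis falls on or before the day the second distinct outpatient
  diagnosis occurs (same-day ties go to inpatient), else `outpatient`.
- **Baseline windows are half-open**: `[index − 365 d, index)`. The
  index-date claim itself is not baseline history — otherwise every case
  would self-exclude via its own 182.xx code. Both the continuous-enrollment
  screen and the cancer washout use this window; "12 months" is implemented
  as 365 days.
- **Exclusion cascade order is fixed** — not-female, then insufficient
  enrollment, then baseline cancer — so attrition reports are comparable
  across runs. Excluded qualifiers stay in the cohort table with a reason
  rather than disappearing.
- **Age at index** is index year minus birth year (the schema carries no
  birth month); strata are 30–44, 45–64, 65+, with an explicit `other`
  stratum rather than silent dropping.
- **Inpatient diagnoses count in any code position** for qualification;
  the per-claim principal-diagnosis flag (first-listed code) is used only
  by record-source ranking, where tier 1 demands a *principal* target
  diagnosis. Inpatient claims lacking the flag are conservatively
  ineligible for tier 1.
- **Tier-2 ranking counts visits, not claim lines**: distinct service
  dates at a provider with a target code; an office needs at least two
  such dates to be listed. Ties break lexicographically on provider id so
  output is order-invariant.

## Validation statistics

Chart adjudication yields a three-level label per reviewer: confirmed /
not-endometrial / non-evaluable. Two-reviewer consensus defaults to the
*conservative* policy (non-evaluable if either reviewer says so; confirmed
only if both confirm); *either-confirms* and *adjudicator-tiebreak*
policies are available because published validations rarely state how
disagreements were reconciled into final counts.

PPV is the exact rational `confirmed / (confirmed + not)`; non-evaluable
charts never enter the denominator. Display rounding is half-up to one
decimal percent, applied only at output. The default confidence interval
is the Wald normal approximation truncated to [0, 1] — recomputation shows
it reproduces every published stratum interval of the motivating
validation study at printed precision — with Wilson and Clopper–Pearson
offered because Wald is poorly behaved near the boundaries (it degenerates
to zero width at p̂ ∈ {0, 1}; an upper bound that truncates at 100% is
printed as 100.0). One caveat found during recomputation: the study's
*overall* printed interval (86.9–93.6 for 286/315) does not match the Wald
formula (which gives 87.6–94.0), while every stratum interval does; the
overall interval is therefore documented as non-reproducible and excluded
from checks.

Cohen's kappa is `(p_o − p_e)/(1 − p_e)` on the 3×3 reviewer cross-tab,
with `p_e` the marginal-product expected agreement; kappa is flagged
undefined (NaN) when both raters are constant and identical. The
outpatient gap statistic is the day count between the first two distinct
outpatient target dates per outpatient-route member; SD uses n−1, the
median the midpoint convention.

## What the synthetic generator emulates

Each member is one of: **true case** (planted 182.xx pattern, adjudicated
confirmed), **mimic** (another condition miscoded 182.xx — hyperplasia,
stromal sarcoma, ovarian cancer, etc. — adjudicated not-endometrial), or
**background** (non-cancer noise codes only: hypertension, diabetes, URI,
…, drawn Poisson at ~2 claims/member-year). A configurable fraction of
planted charts is non-evaluable, overriding the label. Defaults plant
286 true cases and 29 mimics per 2,000 members with 15/330 non-evaluable —
the evaluable confirmed:not ratio of the motivating validation sample —
with 4.3% of true cases truncated to a single outpatient claim (the
algorithm's known sensitivity leak) and 44/330 of planted routes
inpatient.

The outpatient inter-diagnosis gap is `1 + LogNormal(log(9.5), 1.8)` days,
rounded: median ≈ 10.5 d, distribution mean ≈ 50 d, a heavy right tail.
Note that *realized* cohort gaps have a smaller mean (~35 d at the default
window) because both claims must land inside the study window, which
right-truncates the tail; the median is nearly unaffected. Age at index is
truncated normal (63.4, 10.3) on [30, 94].

Enrollment spans cover the full baseline year of every planted case by
construction; when a member draws an enrollment gap (10% of members), the
gap is placed strictly *before* the baseline window for planted cases and
anywhere for background members. Consequently every clean planted
inpatient/outpatient case is captured by the engine and every
single-outpatient or background member is not — a designed invariant that
recovery tests assert exactly. Baseline cancer contamination (a washout
code planted pre-index) is a separate opt-in fraction, default 0, used to
exercise the washout screen.

Each member draws from `default_rng([seed, member_index])`, so per-member
output is invariant to population size and identical configs give
byte-identical CSVs.

What the generator does **not** model — and hence what passing recovery
tests do not show about real claims: billing dynamics (reversals,
transfers, revenue codes), correlated utilization, miscoded *dates*,
chart-retrieval failure (every planted case has an adjudication record),
per-mimic claim-pattern differences (mimics reuse the true-case route
mix), and ICD-10-era coding. Recovery of the planted PPV demonstrates the
pipeline's internal consistency, not the algorithm's accuracy on any real
population.

## Numerical and testing notes

- All qualification logic works on dot-stripped, uppercased codes; prefix
  matching is category-aware for 3-digit numeric prefixes.
- Interval merging of enrollment spans happens at load; the engine merges
  again defensively for hand-built datasets. Abutting spans (end + 1 day =
  next start) merge; a 1-day gap keeps spans apart.
- The engine is cross-checked against a deliberately literal brute-force
  reimplementation (explicit day sets, claim subsets) on hundreds of random
  micro-datasets, and Wald/Clopper–Pearson coverage claims are checked by
  exact binomial enumeration rather than simulation alone.
- Problem sizes in the test-suite Monte-Carlo checks: 200 seeds × 400
  members for estimator unbiasedness, 50 seeds × 2,000 members for
  pipeline recovery at the study's planted ratio, 10,000 draws for the gap
  distribution; chosen so each check's Monte-Carlo error is well inside
  its assertion tolerance.

## Known limitations

- No sensitivity, specificity, or NPV: like the chart-review design it
  mirrors, the toolkit only ever examines algorithm-positive members.
- Calendar-month baseline arithmetic is not implemented (365 days only).
- The canonical CSV schema is a minimal reconstruction sufficient for the
  algorithm; real source formats (X12 837, OMOP CDM) need external ETL.
- Cohen's kappa is computed but has no external benchmark fixture beyond
  closed-form arithmetic, since reviewer-level cross-tabs are rarely
  published.
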