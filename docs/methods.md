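# Methods

## The problem

In-hospital drug regimens change daily. Point-in-time indicators — whether a
patient is polymedicated at admission or discharge, how many interacting
pairs are on board the day they leave — ignore everything that happens in
between, which in high-intensity settings (stem-cell transplantation,
intensive care) is where most of the drug burden accumulates. This package
computes two cumulative metrics that integrate the daily state over the
whole stay and the machinery needed to compare them against the conventional
point-in-time metrics.

## Determinants, assessed daily

For every calendar day of the index stay (day 1 = admission day, the unit of
analysis is the calendar day; administration timestamps are truncated on
read) the pipeline derives:

* **Polypharmacy (PP)** — ≥ 5 distinct drugs administered that day;
  **hyperpolypharmacy (HPP)** — ≥ 10. "Distinct drugs" means distinct
  normalized ATC codes as recorded (typically level-5 substances); repeated
  administrations of the same code count once. A `count_level` option rolls
  codes up to a coarser ATC level before counting, for sensitivity analyses
  — the appropriate counting level is a genuine modelling choice and the
  as-given default is the least aggregated one.
* **Pre-transplant L01 exclusion** — on days strictly before the transplant
  date, ATC class L01 (antineoplastics) is excluded from the distinct-drug
  count, so conditioning chemotherapy does not inflate the polypharmacy
  signal. The exclusion is scoped to the PP/HPP count only: DDI and PIM
  screening always sees the full day's administrations, because an
  interaction involving a cytotoxic agent is still an interaction. The
  transplant day itself is not excluded. Without a transplant date the rule
  is inert.
* **Drug-drug interactions (DDI)** — a knowledge-table pair fires when two
  *distinct* administered codes match its two terms on the same day (a
  single drug matching both terms of an entry does not interact with
  itself). Terms match by ATC prefix at any hierarchy level. Events are
  deduplicated per day by canonical sorted pair; when several knowledge rows
  reduce to the same pair the worst severity wins. The four source severity
  levels collapse to two analysis groups: major = {contraindicated, should
  be avoided}, moderate = {precaution of use, to take into account};
  "minor" is accepted on input as a synonym of moderate.
* **Potentially inappropriate medications (PIM)** — administered codes are
  prefix-matched daily against a reference term list, only for patients aged
  ≥ 65 at admission (age is held constant across the stay). For younger
  patients the determinant is *not applicable*, propagated as missing rather
  than zero, so cohort summaries use the aged subgroup as denominator.

## Cumulative metrics

* **CDE** — for PP/HPP, the number of stay days with the flag set; for
  DDIs/PIMs, occurrence-days: the sum over days of the number of distinct
  same-day events, so four distinct interactions on one day contribute four.
  CDE is an integer by construction.
* **CDED** — CDE divided by the length of stay. LOS is counted inclusively,
  `(discharge − admission) + 1`, so a patient exposed every day has
  CDED = 1 exactly and the daily matrix has exactly LOS rows. For DDIs/PIMs
  CDED is the mean number of daily events and can exceed 1.

Conventional metrics are evaluated on the whole first and last calendar day:
presence (flag set / any event) and count (distinct drugs for PP/HPP, events
for DDIs, matched terms for PIMs). The trajectory label combines presence at
admission and discharge (0→0, 0→1, 1→0, 1→1). CDED is rendered at 6 decimal
places in CSV output; reruns are byte-identical.

## Comparison statistics

Distributions are screened with Shapiro-Wilk at α = 0.05 (samples with n
outside [3, 5000] or zero variance are reported not-testable); exposure
counts essentially never pass, so the comparisons are nonparametric.
Spearman's r_s is computed as the Pearson correlation of mid-ranks (average
ranks on ties), with the two-sided P value from the t approximation
`t = r_s √((n−2)/(1−r_s²))` on n−2 df; |r_s| = 1 maps to P = 0. An exact
permutation P value is available for n ≤ 10 (full enumeration; intended for
very small subgroups). |r_s| < 0.3 is flagged *weak* — the conventional
cut-off below which a single time-point count is judged uninformative about
whole-stay exposure. Trajectory groups are described by mean, median,
quartiles (linear interpolation between order statistics — the default of
mainstream statistical software; nothing here depends strongly on the
convention) and range; empty groups are omitted. Exposed/unexposed contrasts
are summarized descriptively by the difference of medians *d*; no inferential
test and no multiplicity adjustment are applied, matching the descriptive
intent, and raw P values are reported.

## Factorial analysis of mixed data

Implemented from first principles. Quantitative columns are centered and
scaled with the population divisor *n* (the convention of the principal
FAMD implementations; it makes eigenvalues invariant under row
duplication). Each qualitative column is expanded to indicators; category k
is divided by √p_k and centered. The combined matrix, divided by √n, is
decomposed by SVD; eigenvalues are the squared singular values, and the
total inertia equals `p_quant + (Σ categories − p_qual)` — an identity the
tests verify to 1e−8. A column's contribution to a dimension is its squared
right-singular-vector entry × 100 (per dimension these sum to 100);
variables aggregate their categories. Representation quality cos² is the
squared correlation with the component for a quantitative variable and the
correlation ratio η² divided by (levels − 1) for a qualitative one; either
sums to 1 over the full decomposition. Component signs are arbitrary in an
SVD, so they are fixed deterministically: the column with the largest
|loading| on each dimension loads positively. Three components are reported
by default. Rank-deficient inputs return the available components with a
warning.

The default variable list contrasts conventional metrics (drug and DDI
counts at admission/discharge; presence of PP, HPP, DDI at both time
points) with the cumulative metric of one mode (CDE or CDED) for PP, HPP
and DDI. Whether severity-restricted DDI counts should enter separately is
an open modelling choice; the default keeps the pooled DDI variables, and
the column lists are overridable. PIM variables are always excluded: they
exist only for the aged subgroup and would introduce structural
missingness. Single-level qualitative columns (e.g. nobody hyperpolymedicated
at admission) and zero-variance quantitative columns are dropped with a
warning; rows with missing values are dropped with a logged count.

## Synthetic cohorts

The generator emulates a transplant-ward cohort so every stage is testable
without external data. Per patient: stay length uniform on 14–52 days and
age uniform on 21–70 (the ranges reported for this population; roughly a
third of patients reach the PIM age threshold); the expected distinct-drug
count follows a piecewise-linear admission→peak→discharge profile (defaults
3 → 12 → 5 drugs/day, peak at 45% of the stay) with Poisson realization —
the simplest count-noise model consistent with day-to-day regimen
fluctuation; the transplant is placed at ⌊0.2 × LOS⌋ with daily L01
conditioning chemotherapy before it, exercising the exclusion path; near
the peak, a known interacting pair from the packaged toy knowledge table is
co-prescribed with probability 0.6 per day; and 90% of patients aged ≥ 65
carry one chronic PIM administered every day. These defaults reproduce the
qualitative cohort pattern the metrics were designed around — near-universal
polypharmacy at some point during the stay, hyperpolypharmacy common
mid-stay but rare at admission and discharge, interactions frequent, chronic
PIMs in the old — not any particular cohort's point values, which depend on
unavailable patient data.

Randomness comes from per-patient substreams keyed by (seed, patient
index), so cohorts are reproducible and stable under reordering. Alongside
the records the generator emits ground truth recomputed from the emitted
records by a separate plain-loop code path, so the detection pipeline can be
checked for exact agreement (planted-truth recovery).

The packaged toy knowledge tables (12 interaction entries across all four
severity levels and ATC term levels 2–5; 9 PIM terms mixing substance codes
and class prefixes) and the ~46-code ATC palette are syntactically valid and
structurally representative but not pharmacologically authoritative — they
exist to exercise prefix matching, severity mapping and the L01 path.

A deterministic one-patient fixture encodes the worked example of the
cumulative metrics: a 34-day stay with exactly 5 drugs on day 1, ≥ 5 on days
1–6, 10–25 and 27–28, ≥ 10 on days 15–21 only, and 1 drug on day 34 — giving
CDE(PP) = 24, CDE(HPP) = 7 and a 1→0 polypharmacy trajectory.

## What the tests do and do not show

The suite verifies: exact arithmetic on the deterministic fixture; oracle
equivalence of interaction detection (brute-force pair × rule scan),
tied-rank correlation (hand-enumerated mid-ranks, cross-checked against
scipy) and order statistics; the FAMD spectral identities and agreement
with an independently coded eigendecomposition reference; exact
planted-truth recovery on a 200-patient synthetic cohort; structural
invariants (CDED ∈ [0,1] for PP/HPP, CDE(HPP) ≤ CDE(PP), severity groups
partition DDI exposure, byte-identical reruns); and a Shapiro-Wilk type-I
simulation (2000 replicates, tolerance two binomial standard errors).
Problem sizes — 200 synthetic patients, 500-instance oracle sweeps, 2000
normality replicates — were chosen as the smallest that make the stochastic
checks stable.

Passing on synthetic data shows the computations are correct under the
generator's assumptions. It does not validate the metrics clinically, and
real administration data differ in ways the generator does not model:
irregular multi-phase regimens, missing or miscoded records, transfers and
interrupted stays, correlated drug choices beyond the planted pairs, and
knowledge tables orders of magnitude larger.

## Known limitations

* Exposure is binary per drug-day; doses, routes and pharmacokinetic
  exposure are out of scope, as are recency-weighted cumulative models.
* Each patient contributes a single index stay; multi-stay and outpatient
  continuity are not modelled.
* The DDI screen is per-day co-administration; it ignores pharmacological
  latency (an interaction whose members are given on adjacent days is not
  counted).
* Cohort-level point estimates depend on the knowledge tables supplied;
  with the packaged toy tables they are structurally, not clinically,
  meaningful.
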