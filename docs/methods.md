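# Methods

## The exposure model

The unit of analysis is the *exposure window*: a non-overlapping span of
`window_days` (default 30) days of patient age, anchored at age 0, so day
*d* falls in window `d // window_days`. A dispensed prescription exposes
the patient for the closed day interval

```
[fill_age_days, fill_age_days + days_supply - 1]
```

and the patient is counted as exposed to the drug in every window that
interval touches. The closed-interval convention makes a 30-day supply
filled on a window boundary occupy exactly one 30-day window, which is
why 30 days — the most common days-of-supply — is the natural default.
Windows are a deliberate approximation: two scripts a few days apart may
land in different windows (missed concomitance), and two scripts weeks
apart may share a window (spurious concomitance). Fixed anchoring also
creates *partial windows* at the start and end of each enrollment period;
with uniformly random enrollment offsets their mean observed duration is
`window_days / 2` (≈15 days for the default), and with median enrollment
around 29 months they are a few percent of all windows.

Claims with missing or non-positive days-of-supply are rejected and
tallied, never silently coerced: silent coercion would bias counts in an
unauditable way.

Drug codes resolve to one or more active ingredients before windowing;
a combination product exposes the patient to each constituent. Classes
are the level-2 ("therapeutic main group") tier of the ATC hierarchy —
the first three characters (letter-digit-digit) of an ingredient's single
pre-resolved *primary* ATC code. Which of an ingredient's several ATC
codes is primary is an input contract of the mapping table, not a rule of
this package. A class is counted once per window regardless of how many
member drugs are present.

## Counting

Two counts are kept per combination *S* of ingredients (or classes):

* `exact(S)` — windows whose complete drug set equals *S*. Every exposed
  window contributes to exactly one exact key, so
  `Σ_S exact(S) = W_exposed`; this conservation identity is asserted on
  every pipeline run.
* `at_least(S) = Σ_{E ⊇ S} exact(E)` — windows containing *S*, possibly
  with more drugs.

At-least queries run against the summarized exact table (orders of
magnitude fewer keys than raw windows) via a per-drug inverted index:
posting lists of exact keys are intersected, then their counts summed.
The result is checked against the naive superset sum exhaustively in the
tests.

At-least counts are anti-monotone (`S ⊆ S' ⇒ at_least(S) ≥
at_least(S')`), so candidate combinations of size N are generated
Apriori-style: an N-set is a candidate iff **all** of its (N−1)-subsets
reach the support threshold. The all-subsets reading is the one with a
provable no-false-negative guarantee: any N-combo whose own count reaches
the threshold has every subset at or above it, hence is always generated.
With threshold 0 the generator degenerates to full enumeration, which is
what the brute-force comparisons in the tests use. The default threshold
of 1,000 windows presumes a population-scale run; the analysis drivers
scale it to 20 for desk-size cohorts.

## Derived statistics

For a combination *S* of size N over a universe of `W` exposed windows
(windows with at least one prescription of any drug):

* `fraction_exact = exact(S) / at_least(S)`
* `fraction_all_windows = at_least(S) / W`
* `observe_per_expect_1s` (N>1): observed over expected-under-independence
  from single-drug marginals, `at_least(S) / (W · Π_d at_least({d})/W)`.
* `observe_per_expect_N1` (N>2): the minimum over the N splits of *S*
  into an (N−1)-subset plus one drug of
  `at_least(S) / (at_least(S∖{d}) · at_least({d}) / W)` — the
  overrepresentation beyond what the subsets already explain. For N=2
  both definitions coincide algebraically, so the subset variant is only
  reported for N>2. The identity
  `overrep_subsets(S) = overrep_singles(S) / max_d overrep_singles(S∖{d})`
  holds exactly and is asserted on every computed record. Note the
  subset-based ratio is *not* always larger than the single-drug ratio:
  that holds only when every proper subset has ratio ≤ 1, so the package
  computes both faithfully and enforces nothing.
* `estimate_drug_combo_cost_per_day`: the sum over member ingredients of
  the per-ingredient median payment-per-days-supply. Additivity is the
  minimal assumption for a quantity the source data defines only per
  drug; it is labeled an estimate. Costs are undefined at class level.

One universe `W = W_exposed` is used for every denominator — both the
published incidence fraction and the expected-incidence computation —
for internal consistency.

Undefined ratios (zero marginals) are NaN in memory and empty fields on
disk, never 0 or infinity. Medians over an even number of claims use
midpoint interpolation. Combination keys are canonically sorted
(lexicographic by ingredient name / ATC code), making equal sets compare
equal and output files diff-stable; record rows sort by descending
at-least count with the canonical key breaking ties.

### Two calibration subtleties of the exposed-window universe

Both matter when interpreting observed/expected ratios near 1, and both
are exercised by dedicated tests:

1. **Deflation.** Conditioning the universe on "any prescription"
   couples otherwise independent drugs: for scripts arriving as
   independent Poisson streams, the pairwise ratio tends to
   `P(window exposed)` (closed form `1 − e^−λ`), not 1. Sparse cohorts
   therefore show ratios below 1 for independent drugs.
2. **Inflation.** Heterogeneous observation time per window — partial
   windows at enrollment boundaries, or edge effects from supplies
   spilling across windows — is shared between drugs and biases ratios
   upward (a few percent under realistic settings).

A clean independence null must therefore saturate the universe (a
ubiquitous background maintenance drug), align enrollment to window
boundaries, and use within-window scripts; `independence_null_config`
constructs exactly that, and the pipeline's pairwise ratio on it is
statistically indistinguishable from 1. The same two effects explain why
the outcome relative-risk of events scheduled independently of
prescriptions centers somewhat below 1 (between the exposed-window
fraction and 1) rather than exactly at 1.

## The synthetic cohort generator

No public claims source exists at the relevant scale, so the package
ships a generator whose **planted structure is the ground truth** the
pipeline is tested against. It emulates, per patient:

* one contiguous eligibility period; months drawn from a discretized
  lognormal (scale 32 months, σ=0.8, support 1–96) giving a median of
  ~29 months and a 10–90% range of ~11–67; start age uniform over 18–80
  years, so enrollment offsets relative to window boundaries are uniform;
* latent chronic conditions (default five clusters: metabolic syndrome,
  hypertension, cardiac, anxiety/depression, reflux; prevalences
  0.06–0.15): an affected patient fills all of a condition's drugs
  together from enrollment start, refilling back-to-back every
  `days_supply` (30) days while a monthly persistence Bernoulli draw
  (0.90–0.95) succeeds — this induces the correlated multi-drug refills
  that drive real co-prescription;
* independent acute prescriptions at 4.75 per patient-year with duration
  mix {5: .15, 7: .15, 10: .10, 14: .25, 21: .15, 60: .10, 90: .10},
  calibrated jointly with the chronic refills so the overall claim mix
  lands near 50% 30-day supplies and 20% supplies of ≤10 days;
* combination products (single code, several ingredients) in the acute
  pool; payments of `days_supply × Σ ingredient rates × lognormal noise`
  (median multiplier 1, so median payment-per-day recovers the configured
  rate).

All parameters are free configuration, documented as such — they are
**not** estimates of any proprietary database. Fixing the seed fixes the
output tables bitwise. Claims always respect eligibility bounds.

What the generator deliberately does **not** emulate: demographic strata
(age/sex/coverage composition), calendar-time trends in prescribing,
adherence gaps and stockpiling (exposure equals dispensed supply),
seasonality, and drug-specific duration profiles. Passing tests
therefore show the *pipeline arithmetic* is correct and calibrated under
known structure; they say nothing about how closely any real cohort's
numbers would be reproduced.

The Monte-Carlo enrichment oracle (`planted_enrichment`) estimates a
pair's expected observed/expected ratio by simulating replicate cohorts
and pushing them through a brute-force **day-level** reference pipeline
(one row per exposed day, grouped by `day // window_days`) that shares no
code with the production scanner or index. Parameter-recovery tests
require the production path to agree with this oracle within Monte-Carlo
error.

## Record files

The publication layout is two families of five tab-delimited files
(`db_drugs_{1..5}s.tsv`, `db_atc_classes_{1..5}s.tsv`): N name columns
(code+name pairs for classes), then at-least count, exact count, cost
(drugs only), `fraction_exact`, `fraction_all_windows`, and the two
ratio columns where applicable (N>1 / N>2). All combinations are emitted
for N≤2; N=3..5 require 10,000 at-least windows by default. Counts below
100 windows are rendered as the privacy token `"<100"`; by default the
mask applies to both count columns (the conservative reading — whether
the published files mask the at-least column too cannot be determined
from their description, so it is configurable via
`RecordEmissionPolicy.mask_both_counts`). Reading a record file parses
the token into an explicit censored representation (flag + exclusive
upper bound), never a number, and censored cells survive a
write→read→write cycle byte-identically.

## Sensitivity procedures

* **Window duration** — recounting at {10, 20, 30, 40, 50, 60, 90} days
  on a fixed claims table. Longer windows can only merge exposures, so
  the mean distinct-drug count per exposed window is non-decreasing;
  rankings shift in favour of short-duration drugs as windows lengthen.
* **Cohort size** — patient-level subsampling without replacement at a
  fixed seed. Reports the fraction of exposed windows carrying a
  once-observed exact combination (the windows denominator is the
  measure that is monotone in cohort size) and the stability of the
  top-K (default 100) at-least ranking: overlap plus Spearman rank
  correlation on shared keys.
* **Outcome relative risk** — per combination above a minimum at-least
  count, the fraction of patients whose 30-day *day-level* lookback
  (ending the day before their first event; later events discarded)
  contains the combination, divided by `fraction_all_windows`. The
  day-level lookback avoids truncation at window boundaries; it is a
  deliberate reading of "the 30 days prior", and the discrete-window
  alternative would systematically shorten lookbacks. These ratios are
  descriptive associations only; no confounder adjustment of any kind is
  attempted.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which each property is sharply testable: oracle
equivalence on ~1,500 random claims × 3 window lengths; exhaustive
subset-lattice checks on cohorts restricted to ≤12 ingredients;
calibration on 10 replicates of 2,000 patients against a 50-replicate
day-level oracle (3-standard-error agreement); the partial-window mean
on 10,000 patients (±1 day). Determinism is exercised as bitwise
equality of serialized outputs. Nothing at these sizes is claimed to
reproduce population-scale magnitudes — scale-dependent quantities
(counts of unique combinations, once-observed fractions) are asserted
only as directions and identities, never as printed values.

## Known limitations

* Exposure equals dispensed supply; non-adherence inflates apparent
  concomitance.
* The windowing approximation miscounts concomitance near window
  boundaries in both directions (see above); the partial-window error is
  bounded and quantified but not corrected.
* Combination-product payments are attached in full to each constituent
  ingredient's cost sample — a documented upward bias for those
  ingredients.
* Exposure is only defined inside eligibility: the window-universe
  accounting treats an exposed (patient, window) pair outside the
  patient's eligibility period as an input-integrity error rather than
  guessing how to count it (the generator never produces such claims).
* The subset-based overrepresentation is reported as defined even where
  it is smaller than the single-drug ratio.
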