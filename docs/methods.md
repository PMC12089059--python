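# Methods

## Data model and curation

A spontaneous report is a case with demographics (sex, age, weight, country,
reporter qualification), a set of drug mentions with role codes (PS primary
suspect, SS secondary suspect, C concomitant, I interacting) and a non-empty
set of adverse-event preferred terms.  Curation applies, in order:

1. **Version deduplication** — among rows sharing a case id, only the highest
   version survives.
2. **Cross-case deduplication** — distinct case ids identical on the key
   tuple (sorted event-term set, event date, sex, age, weight, country,
   primary-suspect substance) collapse to one; the lexicographically smallest
   case id is kept.  The full sorted term set (not any single term) enters the
   key.  Both choices are deterministic tie-breaks; dedup is idempotent and
   order of the two stages matters (version first), which is why it is fixed.
3. **Drug-name normalization** — exact lookup of the
   whitespace/punctuation-collapsed, case-folded verbatim name in a synonym
   table; if that fails, one retry on the name stem (tokens before the first
   dose-like token, e.g. "NORVASC 5MG" → "norvasc").  No fuzzy matching:
   near-miss spellings stay uncanonicalized rather than risk capturing
   relatives such as nimodipine.
4. **Inclusion filters** — reporter qualification in {MD, PH, OT, RN} when
   `hcp_only` (unknown/consumer/lawyer excluded, the conservative reading of a
   professional-reporters-only design); exposure requires the drug of
   interest with role PS when `ps_only`.  Non-exposed reports are retained:
   they are the comparator background ("all other drugs") of every 2×2 table.
   Age units YR/DEC/MON/WK/DY/HR are converted to years; an unrecognized unit
   leaves age unknown.  Every stage logs its report count.

## Contingency tables and subgroups

Counting is report-level: a report contributes once per distinct term, so one
report feeds many events' `a` cells and tables are dependent across events;
no correction is applied, criteria are evaluated per pair.  Candidate events
are all terms with `a ≥ 1` (the criteria themselves require `a ≥ 3`).

Five standard cohorts: entire, male, female, elderly (age ≥ 65), younger
(age < 65, age known).  Unknown sex/age is excluded from the sex/age
subgroups but kept in "entire"; with the published amlodipine cohort counts
this reproduces the subgroup denominators exactly (7,846 / 9,182 / 7,954 /
7,865 of 18,886), which is also what fixes the elderly cut at 65.

## Disproportionality statistics

Implemented exactly as printed in the pharmacovigilance literature (see the
README table).  Numerical choices:

* **Zero cells** leave ROR/PRR/EBGM undefined (NaN); an undefined statistic
  never yields a positive flag.  No Haldane 0.5 correction is applied by
  default (none is part of the reference criteria).
* **CI direction**: the log-Wald intervals are two-sided (±1.96); every
  criterion consumes the lower limit.
* **BCPNN**: the point IC is the raw log₂ observed/expected.  The interval
  uses the closed-form posterior moment approximation (Bate 1998 /
  Gustafsson) with canonical priors α₁ = β₁ = γ₁₁ = 1, α = β = 2:
  IC025 = E(IC) − 2·√V(IC).  Tests validate it against a Monte-Carlo draw
  from the same posterior (independent Beta factors): agreement is within
  0.02 bits at moderate counts (a ≈ 50) but the normal approximation carries
  up to ~0.1 bit of skew error at a ≈ 5; the criterion IC025 > 0 is applied
  to the closed form, as is standard.
* **EBGM** is the plain observed/expected reporting ratio with a log-normal
  interval — the printed form, and the default throughout.  A true
  multi-item gamma-Poisson shrinker (`mgps_ebgm`: two-component gamma mixture
  prior fit by marginal negative-binomial maximum likelihood, posterior
  geometric mean and 5th percentile per pair) is available for users who want
  shrinkage; it is deliberately not wired into the consensus criteria.
* The PRR case-count gate is `a ≥ 3` (the Evans criterion); reading it as a
  bound on the table total would be vacuous.
* Consensus = conjunction of the four flags; ranking is by descending ROR
  with lexicographic term tie-break.

## Logistic validation

Each candidate event is a binary outcome in a maximum-likelihood logistic
regression (IRLS, tolerance 1e-8, 100-iteration cap) on exposure with sex
(male indicator; unknown dropped) and age band (<18, 18–64 reference, 65–85,
≥86; unknown dropped) as covariates.  Wald CI and p-value for the exposure
coefficient; no multiple-testing adjustment (recorded in the run manifest).
Separation is detected by a diverging coefficient norm or non-finite standard
errors and reported as a flagged row, never as silent estimates.  With no
covariates the fitted exposure OR equals the ROR of the collapsed 2×2 exactly
(saturated-model identity; asserted in tests).

## Synthetic-report generator

The generator emulates what the analysis assumes: per-case demographics from
configured marginals, one PS drug per case (background cases draw from a pool
of 50 dummy names), events conditionally independent given exposure and
subgroup, with per-event background rates drawn once from a configured range.
Signals are planted on the **odds** scale, p' = m·p/(1 − p + m·p), so the
multiplier m is the exact estimand of the ROR.  Duplicates are exact
key-tuple copies under fresh case ids (exercising cross-case, not version,
dedup); variant spellings replace the exposed drug's verbatim name at a
configured rate; non-HCP reports are injected by switching the reporter code.
Cases that draw no event receive a filler term ("drug ineffective") so every
report is valid; the filler is excluded from calibration summaries.  A
ground-truth ledger records planted multipliers with realized a/b/c/d (among
HCP-reported unique cases), duplicate pairs and variant spellings, and
reconciles exactly with the emitted tables.

`table2_like_config` sets the demographic marginals to the published
amlodipine-cohort proportions (female 48.6%, male 41.5%, unknown 9.8%; age
bands 3.7/38.0/35.7/6.4/16.2%; weight and reporter likewise);
`table2_fixture_cohort` builds the 18,886-report cohort with those counts
*exactly* (deterministically, no sampling) for descriptive-arithmetic tests —
only the marginals are published, so the joint distribution across blocks is
arbitrary there.

What the generator does **not** model: secular reporting trends, stimulated
reporting, indication channeling, correlated event co-reporting, partial
(non-exact) duplicates, or MedDRA hierarchy structure (the toy PT→SOC map is
round-robin).  Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated sampling model, not robustness to
those real-data phenomena.

## Study conditions used by tests and the acceptance script

* Formula correctness: 10,000 random all-positive tables against an
  independently coded oracle at 1e-9 relative, with spot checks against
  scipy's Pearson χ² and statsmodels' 2×2 odds-ratio CI.
* Null calibration: 200 replicates of n = 20,000 with 40 events at 1%
  background rate and 5% exposure, all multipliers 1: consensus
  false-positive rate per pair must not exceed the strictest single method
  and must stay under 1%.
* Recovery: 100 replicates with one planted multiplier of 8: consensus
  detection in ≥ 90, adjusted-logistic 95% CI coverage at its nominal rate.

These sizes keep the whole suite at a few minutes on one CPU while leaving
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The comparator is the full retained background ("all other drugs"); no
  active-comparator or restricted-background designs.
* MedDRA itself is license-bound: preferred terms are opaque normalized
  strings and the PT→SOC mapping is a user-supplied table.
* No time-stratified disproportionality, propensity scores, Firth
  correction, or duplicate-aware variance correction.
* The closed-form BCPNN bound is anti-conservative by up to ~0.1 bit at very
  small counts (see above); users needing exact posterior quantiles can use
  the Monte-Carlo construction shown in the tests.
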