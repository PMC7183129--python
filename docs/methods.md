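# Methods

## Scope and code handling

ICD-10 codes are parsed to WHO four-character granularity: a category
(letter + two digits), an optional fourth digit, with national
extension characters beyond the fourth significant one silently
discarded and the dot treated purely as rendering.  Chapter membership
is a deterministic lookup in the hard-coded WHO chapter boundary
ranges (A00–B99 = I, …, Q00–Q99 = XVII, …, U00–U99 = XXII); categories
in unallocated gaps (D49, E91–E99, H96–H99, K94–K99, P97–P99, T99,
V00, Y99) are rejected.  Only chapters I–XVII enter mining: the
remaining chapters code symptoms, injury mechanisms, external causes,
and health-service contact, which co-occur for administrative rather
than clinical reasons.  Any non-I–XVII chapter is treated uniformly as
out of scope.  The full tabular list (including dagger/asterisk
designations) is licensed and not shipped; asterisk codes and
dagger–asterisk pairings come from a user-supplied registry file, and
the synthetic data marks its own registry.

## Mining

Records are stratified by age (0–4, 5–19, 20–44, 45–64, 65+; the 5–19
stratum is carried but never mined) and reduced to transactions: the
set of in-scope codes truncated to level 3 or 4, set semantics,
records emptied by scoping dropped with a count.  Frequent itemsets
come from a bitmask-counting Apriori (candidate join on sorted
prefixes, downward-closure pruning); rules have a single-code
consequent.  Defaults: confidence ≥ 0.05 **and** joint support count
≥ 20 (both enforced explicitly — a confidence floor bounds support
from *above*, not below, so the count floor is not implied), maximum
itemset size 3 (LHS up to two codes), output ordered by
(age group, level, RHS, LHS) with deterministic rule ids.
`brute_force_mine` recomputes everything by exhaustive enumeration
over the code universe (≤ 16 distinct codes) directly against the
transaction list and is the oracle the Apriori path is tested against.

## Cleaning cascade

Order: nested pruning → significance → stability → dagger–asterisk,
each stage reporting exactly which rules it removed and why.

* **Nested pruning** (delta 0.1): two rules are nested if they share
  the RHS and one LHS strictly contains the other.  A rule is removed
  iff a *surviving* simpler rule has confidence within delta;
  survivorship is resolved bottom-up by LHS size, which makes the
  fixpoint unique and input-order independent (a removed rule can
  neither remove nor shield another).
* **Significance** (alpha 0.05): each rule's 2×2 table over the
  training transactions is tested with Pearson chi-squared without
  continuity correction when every expected cell count is ≥ 5,
  otherwise Fisher's exact two-sided test (the conventional switch; a
  zero-margin table yields p = 1 with a warning).  P-values are
  Benjamini–Hochberg adjusted within one (age group, digit level)
  mining run — the natural testing family here — and rules with
  adjusted p ≥ alpha are removed.
* **Stability** (0.05): confidence is recomputed on the held-out 30%
  validation split; the threshold is an *absolute* confidence
  difference, consistent with the other confidence-scale thresholds.
  Rules whose LHS never occurs in validation are removed as
  uncheckable.
* **Dagger–asterisk**: a rule pairing an asterisk code on one side
  with a paired dagger code (matched at category or subcategory level)
  on the other encodes a coding convention and is removed; a strict
  mode removes any rule containing an asterisk code.

The 70/30 record-level split uses `floor(n·0.7)` training records and
is deterministic under its seed.

## Quality metrics

Hospitals qualify with volume strictly greater than 1000 records.  Per
(rule, hospital), the LHS count `n` and joint count `k` are taken over
that hospital's transactions in the rule's stratum and level; stats
with `n < 5` are flagged insufficient and excluded from sums rather
than imputed.  The Wilson score interval (95%) supplies the weight
`1 − width` for **bias** = Σ_hospitals (1 − width)·|confidence −
reference|; the reference confidence defaults to the one stored in
the rule set at mining time and can be overridden per rule.
**Variance** sums (2 − width)·|confidence difference| over all
within-group hospital pairs, where the pairwise interval is
`diff ± q(0.95, k, ∞)/√2 · SE` with `k` the number of usable hospitals
in the group and SE the pooled score standard error
`sqrt(p̄(1−p̄)(1/n_i + 1/n_j))`.  The exact construction behind
"studentized range with a score statistic" admits more than one
reading; this pooled-SE form is isolated in a single function
(`pairwise_diff_interval`) so it can be swapped, and at `k = 2` it
provably collapses to the unadjusted two-proportion score interval
(`q(0.95, 2, ∞) = √2·z₀.₉₇₅`).  At `k = n` the Wilson upper bound is
exactly 1 and the lower bound interior; at `k = 0` the lower bound is
exactly 0.  Rules rank descending per hospital group with rule-id
tie-break; both raw sums (the metric proper) and per-hospital /
per-pair means (for cross-group comparability) are reported.

## Synthetic data

The generator emulates the *shape* of re-abstracted inpatient data,
not real epidemiology.  Per record: hospital ∝ volume weight; age
group from {0–4: 14%, 5–19: 6%, 20–44: 26%, 45–64: 24%, 65+: 30%},
age uniform within group (65+ capped at 99); baseline codes by
independent Bernoulli inclusion from the age group's pool; planted
rules applied in rule-id order (single pass, no fixpoint, so chained
rules are reproducible): if the LHS is present, the RHS is added with
probability θ; per-hospital error model (drop each present code with
its under-coding probability, add over-coding candidates
unconditionally); cap at 25 codes by random removal of baseline codes;
empty records redrawn.  Everything is deterministic under the seed.

Independent inclusion plus single-pass rule firing yields the
closed-form confidence used as the test oracle:

    s = θ + (1 − θ)·π_RHS,   p = s·(1 − u_RHS),
    confidence = p + (1 − p)·o_RHS

neglecting the vanishing perturbations of the 25-code cap and the
empty-record redraw.  `inject_undercoding` drops one code at one
hospital with a given rate; a record reduced to zero codes is removed
entirely (abstracts carry at least one diagnosis), so a drop rate of 1
leaves exactly zero occurrences.

The default configuration plants, per mined stratum, ten single-code
LHS ("anchor") rules with θ ∈ {0.2, 0.35, 0.5, 0.65, 0.8} (two sweeps),
anchor inclusion π = 0.18, consequent baseline π = 0.02, all planted
codes in distinct categories so three-digit truncation maps each rule
to a unique category-level rule.  Pools are age-appropriate (perinatal
P-codes for 0–4, obstetric O-codes for 20–44, circulatory / endocrine
/ genitourinary / respiratory codes for 45+), sprinkled with
out-of-scope Z/R codes that exercise the chapter filter, plus one
dagger–asterisk pair (A17.0 → G01, θ = 0.95) in the 65+ stratum whose
rule exists only by coding convention.  Twelve hospitals in three
groups (teaching 12k–18k, large community 5k–8k, small community
0.8k–1.5k volume weights) put the >1000 volume filter on both sides.
The inclusion probabilities were calibrated once, by scripted sweep,
to the target shape of median 3 codes per record with quartiles in
[2, 4] over 10,000 records; the anchor/consequent values above are
the frozen result.  No per-hospital volume distribution is claimed to
be realistic — groups and weights are chosen for coverage of the
eligibility and grouping logic.

What passing tests on this generator do **not** show: robustness to
real comorbidity correlation structure, real code frequency
distributions (hundreds of rare categories), coder-level effects, or
administrative fields; the generator has none of these by design.

## Statistical power of the stability stage

At the default study size (20,000 records), a planted rule's LHS
occurs roughly 500–1,100 times per stratum, so the train-minus-
validation confidence difference has standard error
`sqrt(p(1−p)(1/0.7 + 1/0.3)/n_LHS)` ≈ 0.03–0.045, and the 0.05
stability threshold sits at only 1.1–1.8 standard errors.  Each
genuine rule therefore carries a 7–27% chance (by θ and stratum) of
being removed by sampling noise alone, and a typical run loses about
four of the forty planted rules at the three-digit level.  This is a
property of the 5% absolute threshold at these supports, not an
implementation artifact; making all forty survive reliably would
require LHS supports incompatible with the median-3 code-count shape.
The validation suite therefore distinguishes the idealised
all-rules-survive check (kept, and expected to fail, as a statement of
that limit) from the supported property: ≥ 90% recovery with survivor
confidences tracking the closed form at binomial-noise level.

## Validation experiments

* Miner exactness: 100 random databases (≤ 10 codes, ≤ 300
  transactions, random thresholds), Apriori vs brute force, exact
  set equality.
* Wilson empirical coverage at (n = 100, p = 0.3) over 10,000 draws;
  note the exact coverage there is 93.7% (Wilson coverage oscillates
  with n and p), near the lower edge of the nominal band.
* BH adjustment against the literal step-up definition on random
  p-vectors, and against statsmodels.
* Under-coding detection: drop one rule's RHS at one teaching hospital
  at rates 0/0.2/0.4 (20 seeds × 20,000 records), reference
  confidences at their closed forms; mean bias and mean variance of
  the affected rule must rise strictly with the rate and the rule must
  top the group's bias ranking at rate 0.4.
* Determinism: the full 30,000-record pipeline (4 strata × 2 levels,
  cascade, assessment, reports) is byte-identical across reruns with
  the same seed; run manifests carry the seed, thresholds, stage
  counts, and config hash, and never wall-clock time.

Problem sizes in tests (10,000–30,000 records, 20-seed detection runs)
were chosen so each experiment's sampling error is far below the
effect it checks while the whole suite stays interactive.

## Known limitations

* The chapter table encodes boundaries only; it cannot reject codes
  that are syntactically valid and inside a chapter range but
  unallocated in the tabular list (e.g. a nonexistent fourth digit).
* Bias and variance are aggregate screens: a single hospital deviating
  on a single rule is not evidence of error, and no pass/fail
  acceptability thresholds are provided deliberately.
* The pairwise-interval construction is one faithful reading of a
  simultaneous score interval; alternatives (e.g. unpooled SE) would
  change variance weights slightly.
* Multi-code consequents are not generated; LHS size is capped (default
  2) for review tractability.
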