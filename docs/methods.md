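# Methods

## Problem and data model

A hospital prescription table (DS1) holds one row per prescription:
`MEDICATION` (free text or a catalog pick), `YEAR`, `STRUCTURE` (true iff
the entry was picked from the catalog) and `ATC_L5` (present exactly when
structured). The drug product catalog (DS2) pairs product names and
ingredient names with ATC level-5 codes; one catalog row is the unit — no
attempt is made to split multi-ingredient strings, and combination products
legitimately reuse an ingredient name under a different ATC code. Grouping
the unstructured texts by exact string yields DS3 (`MEDICATION, FREQUENCY,
Step1..Step3`); the most frequent DS3 rows plus reviewer fields form the
validation workbook DS4.

ATC codes are validated structurally: lengths {1, 3, 4, 5, 7} map to
levels 1–5; position 1 must be one of the 14 anatomical group letters
(A B C D G H J L M N P R S V), positions 2–3 and 6–7 digits, positions 4–5
letters. Codes at coarser levels are string prefixes of their descendants,
so truncation is prefix-taking and is idempotent and monotone. No WHO index
lookup is performed — the package checks well-formedness, not existence,
since institutional catalogs are the source of truth for which codes occur.

## Similarity stack

"Levenshtein similarity" is realized as the **indel** distance
(insertions/deletions only; a substitution costs 2):
`indel(a,b) = |a| + |b| − 2·LCS(a,b)`. This is the only reading consistent
with the published worked-example ratio of 54 for the pair
"stada paracetamol" / "paracetamol stada 400 mg" (the classic 3-operation
distance gives a different value). The implementation is a bit-parallel
LCS (one integer register per 64 characters of the shorter string); the
test suite proves it equal to a brute-force DP oracle exhaustively on small
alphabets and on random pairs.

Scores are `round(100·(|a|+|b|−indel)/(|a|+|b|))` with half-away-from-zero
rounding (needed to turn 53.66 into 54). Conventions for degenerate input:
two empty strings score 100, one empty string scores 0 (falls out of the
formula). Normalization lower-cases, maps every character that is not a
Unicode letter or digit (including underscore) to a space, collapses
whitespace and tokenizes; it is idempotent.

- **partial ratio**: best simple ratio of the shorter string against
  equal-length windows of the longer, windows anchored at the start
  positions implied by longest-matching-block alignments
  (`difflib.SequenceMatcher`, `autojunk=False`), clamped to the valid
  range; ties break to the leftmost window. Anchoring at matching blocks
  rather than scanning all O(n) windows is deterministic, fast, and
  reproduces the worked-example value 65.
- **token-sort ratio**: simple ratio of the strings rebuilt as sorted
  normalized tokens.
- **token-set ratio**: with `t0` the sorted intersection of the two token
  *sets* and `t1`/`t2` the intersection plus each side's sorted remainder,
  the maximum of the three pairwise simple ratios. Set semantics (duplicate
  tokens collapse) follow the intersection/remainder construction. A
  consequence worth knowing: `token_set ≥ token_sort` holds whenever both
  token lists are duplicate-free, but duplicate collapse can break it
  (e.g. "00" vs "0.0" scores 67 vs 80) — the property test is scoped
  accordingly and the counterexample is frozen as a regression test.

## Matching algorithms

Algorithms 1 (ingredient) and 2 (product) use **whole-token contiguous
phrase containment** after normalization, not raw substring search: a
substring hit inside a longer word ("ASS" in "WASSER") would destroy the
near-perfect precision exact matching is used for. The longest matching
name wins (token count, then character length); if equally long matches map
to more than one distinct ATC code the algorithm returns nothing —
precision first, ambiguity is not guessed away. This deliberately makes
combination products (same ingredient name, different ATC) unresolvable by
algorithm 1.

Algorithm 3 computes the token-set ratio of the query against every
ingredient and product name, keeps each ATC code's best-scoring name,
and returns the top-k (default 3) by score, tie-broken by longer matched
name then lexicographic ATC for determinism. It answers for every query
with at least one normalized token; a query that normalizes to nothing
returns an empty result (every token-set score would degenerate to 100
against everything, which is meaningless).

## Exclusion rules and confidence tiers

The rule engine ships with the three documented examples (`BGA`, `BE`,
`BB` as whole-leading-token prefixes on normalized text) and loads
institution-specific rules from YAML; first match wins, in file order.
Prefix and exact rules act on normalized text; regex rules on the raw
string, case-insensitively, since regex authors control their own classes.

Reliability tiers, ordered: `consensus_exact` (algorithms 1+2 agree, or all
three) > `consensus_high` (an exact algorithm agrees with the similarity
top-1) > `score_based` (similarity-only answer with top score strictly
above the threshold) > `needs_review`; rule-excluded entries sit below as
`excluded_nomed`. The default score threshold of **84.28** is the mean
similarity score of validated-correct matches in the motivating validation
data — an empirical indication, exposed as a parameter, not a law. The
score-separation test is Welch's two-sided two-sample *t*-test (the groups'
variances are not assumed equal) plus a descriptive panel (count, mean,
sample SD, min/quartiles/max) per group.

Concordance compares algorithm results at ATC level 5 only; truncated
codes never silently stand in.

## Pipeline and reporting conventions

- Grouping key: the exact raw string, case-sensitive ("NaCl 0.9%" and
  "NaCL 0.9%" stay separate rows, as they do in real review data).
- Top-N coverage: the N most frequent texts' frequency sum over a caller-
  chosen denominator; passing the pre-exclusion unstructured count measures
  coverage against the full unstructured corpus.
- Workbook FINAL resolution precedence: reviewer-entered CORRECT code >
  first algorithm result marked correct (Eval1, Eval2, Eval3 order) > a
  label or code entered in FINAL directly > `no_eval`. CORRECT/FINAL accept
  codes truncated to level 3 or 4 (reviewers often can pin the therapeutic
  class but not the substance, e.g. insulins); truncated codes aggregate
  upward into the level-1 group report but are never imputed to level 5 and
  so never appear in the ingredient report.
- Bucket accounting: every record lands in exactly one of structured /
  resolved-to-ATC / nomed (rule-excluded plus reviewer-flagged) / unspec /
  not-validated; the sum equals the input size and is asserted on every
  run. Percentages print at 2 decimals, half away from zero. In the group
  report, ATC rows' share-of-total uses the ATC-classified total as
  denominator while label rows use the full record count, mirroring the
  reporting convention of structuredness tables in the field.
- Matching cost is quadratic in (texts × catalog names), so the pipeline
  runs the cascade on the top-N grouped texts (default N=1000, the scale at
  which manual validation is realistic); the long tail stays `no_eval`.
  Conservation and the initial assessment never depend on N.

## Synthetic data generator

`FixtureSpec` defaults encode the study conditions the package is built
around: structured fraction 0.4773, non-medication fraction 0.091, 100,000
prescriptions. Values without an external anchor were chosen once as
field-realistic: a 300-entry catalog, a 2,000-text unique free-text pool,
Zipf exponent 1.5 (at which the top 1,000 texts cover ≈99% of the
unstructured mass — real corpora are less extreme, around two-thirds at
that cut, but the skew phenomenon is what matters for top-N validation),
10% combination products, and a corruption mix of verbatim product texts
(0.25), ingredient-plus-dose (0.30), token shuffles (0.15), truncations
(0.10), typos at indel distance k=2 (0.10) and texts unrelated to their
source row (0.10).

Names are built from syllable templates, never from a licensed drug list;
German decorations (dose/form words, "| (ingredient)" drop-down rendering,
umlauts) are structural only. Non-medication texts come from an order-text
vocabulary, most starting with rule-catchable tokens, a few (e.g. "RR
messen") only identifiable in review. Every non-nomed text's true ATC
exists in the generated catalog; per-text truth and corruption class are
recorded. A single seed drives all draws; generated file sets include a
JSON sidecar recording the generating spec (kept out of the CSVs
themselves so the files stay plainly parseable).

`evaluate_against_truth` is a **synthetic reviewer**: it marks each
algorithm result right or wrong against ground truth, enters the truth in
CORRECT when no algorithm found it, flags unrelated-text renderings
`unspec` (a real reviewer could not recover those either) and order texts
`nomed`.

What passing fixture-based tests shows — and what it does not: the
generator exercises token reordering, fragments, dose suffixes, duplicate
ingredient names and frequency skew, so it validates the mechanics and the
accounting end to end. It does not reproduce German morphology,
misspellings beyond controlled indels, multi-drug texts in one field, or
the real error taxonomy of similarity matching (dosage-form ambiguity,
combination-product confusions are present only in stylized form), so
fixture accuracy numbers say nothing quantitative about accuracy on real
hospital data.

## Numerical and degenerate-input choices

- Rounding: half away from zero everywhere a value is printed or an
  integer score is formed.
- Readers quarantine, never drop: accepted + rejected = input rows; exact
  duplicate catalog rows are dropped with a logged count.
- Encoding: UTF-8 first, Latin-1 fallback, recorded on the result.
- Score threshold comparison is strict (`>`).
- Welch test requires ≥2 values per group; identical groups give t=0, p=1.
- `truncate` to a finer level than the code has is an error, not padding.

## Known limitations

- Whole-token containment misses inflected or concatenated forms
  ("Ibuprofensaft") by design; those fall through to algorithm 3.
- One free text is assumed to name one medication; multi-drug orders in a
  single field are out of scope.
- The level-1 group report trusts FINAL codes; no plausibility check
  against the catalog is applied to reviewer-entered codes beyond
  structural validation.
- Year information is carried through I/O but not analyzed.
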