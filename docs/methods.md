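# Methods

## Problem and scope

Free-text medication entries and reasons-for-use from epidemiological
abstraction forms are high-cardinality, misspelling-ridden, and mix drugs
with self-reported supplements.  `medtext` condenses them into two
interpretable feature sets: ATC therapeutic classes (levels 1–3) for
medications and organ-system disease categories for reasons, with an
explicit manual-review queue and curator-override path for the residue the
automation cannot resolve.  All knowledge sources are file-backed lexicons;
there is no network dependency anywhere in the core.

## Edit-distance core

`lev(a, b)` is the unit-cost Levenshtein distance, computed by two-row
dynamic programming over the standard recursion (base case `max(i, j)` when
`min(i, j) = 0`; substitution cost `1` when the compared characters differ,
`0` when equal).  The test suite checks this implementation exhaustively
against a direct memoized recursion of the defining equation (all ~132k
string pairs of length ≤ 5 over a 3-letter alphabet) and verifies the metric
axioms on random pairs.

The normalized ratio is

    ratio(a, b) = (|a| + |b| − lev(a, b)) / (|a| + |b|),

with `ratio("", "") := 1.0` (identical strings; avoids 0/0 while preserving
"ratio = 1 iff equal").  This is *not* the substitution-cost-2 ratio used by
python-Levenshtein/rapidfuzz `ratio()`: a single substitution here costs 1,
so our ratio is higher on substitution-heavy pairs.  Anyone recalibrating
thresholds against values from those libraries must account for this.

### Match policies

A `MatchPolicy` holds `ratio_threshold` (default 0.85, strict `>`),
`distance_threshold` (default 2, strict `<`, i.e. distance ≤ 1) and a
combinator:

- **drug rule** (`ANY`): ratio clause OR distance clause;
- **reason rule** (`ALL`): both clauses;
- **supplement check / word spell-check**: ratio clause only.

The defaults are deliberately a common, generic operating point rather than
a corpus-tuned one; both thresholds and combinators are parameters precisely
so they can be recalibrated per study against a held-out sample.

`best_match` scores every candidate and returns the accepted candidate with
maximal ratio, ties broken by minimal distance, then lexicographic order.
The tie-break is a package design choice (nothing in the problem dictates a
winner among equally good candidates); it makes results deterministic and
independent of candidate-list order, which the suite asserts.

## Medication branch

1. **Preprocessing**: case-fold; replace punctuation with spaces; collapse
   whitespace; drop tokens that are pure numbers, number+unit or bare units
   (`mg`, `mcg`, `ml`, `g`), or members of the configurable dose-form
   stoplist (`er`, `xr`, `sr`, `cr`, `la`, `succ`, `tart`, `tab(s)`,
   `cap(s)`, `generic`, `extra`, `strength`, `inhaler`, `nebulizer`).  If
   every token would drop, the case-folded original is kept, so matching
   always has input.
2. **Supplement exclusion** precedes drug matching; a hit ends processing
   for that record.  Abbreviations such as `vit b12` must be stored as
   explicit supplement entries: `ratio("vit b12", "vitamin b12") ≈ 0.78`
   sits below any sensible ratio threshold, so fuzzy matching cannot bridge
   abbreviation gaps.
3. **Normalization** matches against canonical names and synonyms jointly; a
   synonym hit resolves to the entry's canonical generic name.
4. **Class mapping** resolves the concept id through the ontology adapter
   and truncates ATC codes to the requested level (default 3), deduplicating
   after truncation (keeping the lexicographically smallest label per
   truncated code).  One drug may carry several classes; outputs serialize
   them pipe-separated in a single row so record counts stay invariant.

The adapter is a two-method contract (`resolve_concept`, `atc_codes`).  The
shipped implementation answers from the loaded lexicon bundle; a remote
adapter backed by a terminology REST service can implement the same contract
but is intentionally out of the tested core (offline reproducibility, no
terms-of-service exposure).  `requests`-based code is therefore absent.

## Reason branch

Reasons are normalized (case-fold, punctuation → space but `/` kept for
shorthand like `b/p`), spell-corrected word-by-word (dictionary members and
non-alphabetic tokens pass through; otherwise the highest-ratio dictionary
word above threshold replaces the token), stemmed, and the whole space-joined
stem string is looked up in the stem→category map — exact hit first, then
fuzzy under the ALL rule.  Multi-word stems are matched as whole strings,
not word-by-word, matching the key format of the curated map.

### Stemmer

The Lancaster stemmer is implemented as a Paice/Husk rule engine with the
standard published 115-rule table pinned in `medtext/stemmer.py`.  Each rule
(keyed by final letter) matches a suffix, optionally only on still-unmodified
words ("intact"), removes N characters, appends a replacement, and either
stops or continues.  A rewrite is applied only if the result is acceptable:
vowel-initial stems keep ≥ 2 letters; consonant-initial stems keep ≥ 3 and
must show a vowel (with `y` counted) in the leading positions.  The table is
version-pinned data: editing it silently re-keys every stem map built
against it.

Known divergences, golden-tested:

- `arthritis → arthrit` (not the shorter `arthr` sometimes quoted).  No
  single rule table can produce both `gastritis → gastrit` and
  `arthritis → arthr`, since both words end in `-ritis`; the engine treats
  them alike.  The packaged stem map keys `arthrit` and keeps `arthr` as an
  alias of the same category, so both forms map identically.
- `diarrhe` (the stem of `diarrhea`) is not a fixed point: re-stemming
  yields `diarrh` via the final-`e` rule.  Stem-map keys are otherwise fixed
  points under the pinned table.

### Overrides

Curator overrides are keyed on case-folded raw text and always win,
regardless of prior status (manual curation is the final authority).
Application is idempotent and order-independent.

## Synthetic data generator

The generator emulates the *structure* of restricted survey data: a drug and
supplement lexicon of pronounceable consonant–vowel names with every pair of
distinct names at Levenshtein distance ≥ `min_separation`; corpus entries
drawn per a stated composition (default 60% drugs / 30% supplements / 10%
garbage, reflecting that roughly half of raw survey records are supplements
or unmappable residue); each drug/supplement entry corrupted by exactly
`n_edits` seeded random insert/delete/substitute operations (default 1);
garbage strings resampled until > 3 edits from every lexicon name; and each
record paired with a reason word whose stem keys the stem map.  Composition
counts use largest-remainder rounding, so they are exact, and everything is
reproducible from (parameters, seed).

It does **not** emulate: realistic medication frequency distributions, brand
synonym usage, dosage strings beyond the stoplist's coverage, multi-drug
entries, or natural-language reason phrasing.  A green synthetic test
establishes that the matching machinery recovers truth under the stated
noise model — not that real survey text maps at any particular rate.

The separation/corruption defaults are chosen to make recovery *provable*:
with pairwise separation ≥ 2d + 1 and corruption < d edits (d = the
distance threshold 2), the true name is the unique lexicon name whose
acceptance ball contains the corrupted string, so precision = recall = 1 and
supplement confusions = 0 — asserted over multiple seeds.

### Evaluation metrics

`evaluate` reports precision and recall of canonical-name recovery over
records, supplement confusions (true supplements mapped as drugs plus true
drugs excluded as supplements), and the auto-mapped fraction over *distinct*
non-supplement raw terms — the convention used when quoting manual-mapping
workload, since curation effort scales with distinct terms, not records.
Note the distinct-term fraction is **not** monotone in corruption strength:
corrupting names inflates the number of distinct auto-mapped variants and
hence the denominator, so an uncorrupted corpus (few distinct clean terms
against the same garbage terms) can show a *lower* fraction than a corrupted
one.  Degradation with noise is therefore asserted on the record-level
correct-recovery rate, which is monotone and is the quantity the claim
meaningfully constrains.

## Reporting

`summarize` counts: total records, records surviving supplement removal,
distinct raw terms (case-folded, whitespace-collapsed; empty fields
ignored), category counts over mapped outputs, and manual percentages over
distinct terms (a distinct medication term counts as manual only if none of
its records mapped; supplement-excluded terms are outside the denominator).
`n_medication_categories` may exceed the distinct-term count on small inputs
because one drug can carry several ATC classes; each reason term yields at
most one category, so there `categories ≤ distinct terms` is enforced as an
invariant.

Threshold monotonicity (raising the ratio threshold never increases matches;
equivalently lowering it never decreases them) holds exactly at each
matching stage and is asserted there.  It does *not* hold end-to-end: a
looser ratio threshold also loosens the upstream supplement check, which can
swallow records before drug matching (at 0.5, `aspirin` fuzzy-matches the
supplement `iron`), and makes word-level spell correction aggressive enough
to corrupt stems (`htn` → `high` at 0.5).  This interplay is a real property
of threshold-coupled pipelines and worth knowing before recalibrating.

## Determinism and I/O

All outputs (`medications.tsv`, `reasons.tsv`, `manual_queue.tsv`,
`report.json`) are byte-identical across repeated identical invocations: no
timestamps in data files, fixed `\n` line endings, sorted serialization of
sets, ratios printed at fixed 6-decimal precision.  Lexicon files are read
with exact line-number error reporting; loading validates ATC syntax
(level 1–3 patterns), canonical-name uniqueness, and the absence of
drug/supplement name collisions.  `load_bundle ∘ save_bundle` is the
identity on validated bundles in both TSV and JSON formats.

## Limitations

- No dose/frequency/route extraction; multi-drug strings
  ("aspirin + dipyridamole") are not split.
- No Damerau transpositions, keyboard-aware costs, or phonetic matching;
  abbreviations must be lexicon entries.
- No negation/context handling on reasons; no SNOMED/UMLS linking.
- ATC levels 4–5 and alternative hierarchies are out of scope (the adapter
  contract permits them; nothing implements them).
- Packaged fixtures are tiny and synthetic; real deployments must supply
  their own licensed vocabularies via the documented file formats.
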