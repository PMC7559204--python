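# medtext

Epidemiological studies often record medications and the reasons for taking
them as free text on abstraction forms.  The same drug surfaces as
"ibuprofen", "Advil", "Extra Strength Advil" or "ibuprofen 200 mg"; reasons
arrive as "high blood pressure", "HTN" or "b/p"; self-reported entries mix in
supplements that must be excluded before analysis.  `medtext` condenses this
raw text into interpretable features: medication entries become WHO ATC
therapeutic classes (level 1–3), and reasons-for-use become organ-system
disease categories — with everything the automation cannot resolve routed to
an explicit manual-review queue and a curator override path.

It is a library for epidemiologists and research software engineers who need
reproducible, offline feature extraction from survey text; the public face is
the importable API plus the narrative scripts in `examples/`.

## Method

The core similarity measure is the unit-cost Levenshtein distance
`lev(a, b)` with the normalized ratio

```
ratio(a, b) = (|a| + |b| − lev(a, b)) / (|a| + |b|)
```

(note: plain unit-cost distance in the numerator, unlike the
substitution-cost-2 ratio of some fuzzy-matching libraries).  A fuzzy match
is accepted by a `MatchPolicy`: drug matching accepts when
`ratio > 0.85` **or** `lev < 2`; reason matching requires **both** clauses;
the supplement check uses the ratio clause alone.  All thresholds and
combinators are configurable.

**Medication branch** — preprocess (case-fold, strip punctuation, dosages
and dose-form tokens) → exclude supplements by fuzzy lookup in a supplement
lexicon → best fuzzy match over canonical drug names and brand/abbreviation
synonyms → resolve the concept id and truncate its ATC codes to the
requested level (one drug may carry several classes).

**Reason branch** — spell-correct each word against a general dictionary
(highest ratio above threshold) → reduce words to stems with a pinned
Lancaster (Paice/Husk) suffix-rule engine → look up the space-joined stem
string in a curated stem→category map (exact, then fuzzy) → apply curator
overrides, which always win.

**Synthetic data** — because real survey datasets of this kind are
restricted, `medtext.synthetic` generates lexicons with controlled pairwise
name separation, corrupts entries with a seeded edit-operation model, and
scores pipeline output against ground truth.  With pairwise separation
≥ 2d + 1 and fewer than d corruption edits, recovery of every canonical name
is provable — and the test suite asserts it.

## Worked example

```python
from medtext import RawRecord, fixture_dir, load_bundle, process_medications

bundle = load_bundle(fixture_dir())
records = [RawRecord("S1", "Fexafenedine", ""), RawRecord("S5", "Vit B12", "")]
for r in process_medications(records, bundle):
    print(r.raw, "->", r.status.value, r.canonical_name,
          sorted(c.label for c in r.atc_classes))
```

Running `python examples/02_medications.py` prints:

```
Fexafenedine         -> mapped               fexofenadine         [antihistamines]
Hydrochlorothazide   -> mapped               hydrochlorothiazide  [diuretics]
Metoprolol Succ ER   -> mapped               metoprolol           [beta-adrenergic blocking agents]
Quinipril            -> mapped               quinapril            [angiotensin converting enzyme inhibitors]
Vit B12              -> supplement_excluded  -                    [-]
ibuprofen 200 mg     -> mapped               ibuprofen            [antiinflammatory and antirheumatic products, non-steroids]
xanthozep            -> manual_queue         -                    [-]
```

Each line is one record's single outcome: a misspelling resolved to its
canonical generic drug and therapeutic class(es), a supplement excluded
before drug matching, or an unmappable string queued for human review.  The
other examples cover fuzzy-match scoring (`01`), the reason branch with
overrides (`03`), the synthetic recovery benchmark (`04`) and the end-to-end
run that writes `medications.tsv`, `reasons.tsv`, `manual_queue.tsv` and
`report.json` (`05`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch: the deterministic
fixture pipeline run (record counts, class counts, manual percentages) and a
seeded synthetic benchmark (lexicon generation, single-edit corruption,
precision/recall/auto-mapped fraction against ground truth), then writes the
results JSON to `--out`.

See `docs/methods.md` for the model details, parameter defaults, numerical
choices and known limitations.
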