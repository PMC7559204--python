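# Packaged lexicon fixtures

Small, fully synthetic knowledge-source files used by the tests and examples.
They contain no licensed vocabulary content: concept ids (`RXSYN000xx`) are
made up, and ATC class labels are plain-English therapeutic class names
attached explicitly per code.

- `drugs.tsv` — seven drugs chosen to exercise the worked examples shipped
  with the package: fexofenadine, hydrochlorothiazide, metoprolol, quinapril
  (single-class drugs), aspirin (a multi-class drug carrying both an
  analgesic and an antithrombotic code), albuterol and ibuprofen.  Synonyms
  are common US brand names/abbreviations.
- `supplements.tsv` — common supplement names; includes the abbreviation
  `vit b12` as its own entry because abbreviations are too far from their
  expansions for fuzzy matching (ratio("vit b12", "vitamin b12") ≈ 0.78).
- `stem_map.tsv` — stem → organ-system category map.  Keys are the pinned
  Lancaster-engine stems of the example reasons (e.g. `ulc colit`,
  `diabet`, `high blood press`); `arthr` is kept as an alias of `arthrit`
  (same category).  One source row collapsing "mood" and "anxiety disorders"
  is ambiguous; only `anxy → anxiety disorders` is included and "mood" is
  deliberately left unmapped.
- `wordlist.txt` — a minimal general-language dictionary for reason
  spell correction.
- `records.tsv` — a synthetic input batch: misspelled drug names, dose-form
  suffixes, two supplement entries, one garbage name (`xanthozep`,
  synthetic), and reasons ranging from exact stem-map hits to entries that
  legitimately end in the manual queue (`allergies`, `headache`).
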