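"""Reason branch: free-text reasons for use to organ-system disease categories.

Each reason is spell-corrected word by word, reduced to Lancaster stems, and
the stem string is looked up in the curated stem->category map; a curator
override rescues one entry from the manual queue.
"""

from medtext import RawRecord, fixture_dir, load_bundle, process_reasons

bundle = load_bundle(fixture_dir())
records = [
    RawRecord("S1", "", "ulcerative collitis"),  # misspelled, then corrected
    RawRecord("S2", "", "high blood pressure"),
    RawRecord("S3", "", "HTN"),
    RawRecord("S4", "", "b/p"),
    RawRecord("S5", "", "diabetes"),
    RawRecord("S6", "", "sore everywhere"),  # nothing in the stem map
]
overrides = {"sore everywhere": "pain"}

for result in process_reasons(records, bundle, overrides=overrides):
    print(
        f"{result.raw:22s} corrected={result.corrected:20s} "
        f"stems={result.stem_string:18s} {result.status.value:12s} "
        f"-> {result.category or '-'}"
    )
# The three hypertension spellings converge on one category; the override
# turns the manual-queue record into an 'overridden' mapping.
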