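"""Medication branch: raw free-text entries to ATC therapeutic classes.

Runs the packaged fixture lexicon over a handful of misspelled, dose-form
laden entries.  Each line shows the record's single status: mapped to a
canonical drug with its therapeutic classes, excluded as a supplement, or
queued for manual review.
"""

from medtext import RawRecord, fixture_dir, load_bundle, process_medications

bundle = load_bundle(fixture_dir())
records = [
    RawRecord("S1", "Fexafenedine", ""),
    RawRecord("S2", "Hydrochlorothazide", ""),
    RawRecord("S3", "Metoprolol Succ ER", ""),
    RawRecord("S4", "Quinipril", ""),
    RawRecord("S5", "Vit B12", ""),
    RawRecord("S6", "ibuprofen 200 mg", ""),
    RawRecord("S7", "xanthozep", ""),  # synthetic garbage name
]

for result in process_medications(records, bundle):
    classes = ", ".join(sorted(c.label for c in result.atc_classes)) or "-"
    print(
        f"{result.raw:20s} -> {result.status.value:20s} "
        f"{result.canonical_name or '-':20s} [{classes}]"
    )
# 'Vit B12' is excluded before drug matching; 'xanthozep' matches nothing
# within the thresholds and lands in the manual queue.
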