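"""End-to-end run: records TSV in, four artifacts out, plus the summary report.

Processes the packaged fixture batch and writes medications.tsv, reasons.tsv,
manual_queue.tsv and report.json to ./scratch_out.  Outputs are byte-stable:
re-running produces identical files.
"""

import json
from pathlib import Path

from medtext import PipelineConfig, fixture_dir, run_pipeline

out_dir = Path("scratch_out")
result = run_pipeline(
    fixture_dir() / "records.tsv",
    fixture_dir(),
    config=PipelineConfig(),  # 0.85 / <2 thresholds, ATC level 3
    overrides={"headache": "pain"},
    out_dir=out_dir,
)

report = result.report
print(f"records processed:            {report.n_records}")
print(f"after supplement removal:     {report.n_after_supplement_removal}")
print(f"distinct raw medications:     {report.n_distinct_raw_medications}")
print(f"medication classes:           {report.n_medication_categories}")
print(f"distinct raw reasons:         {report.n_distinct_raw_reasons}")
print(f"reason categories:            {report.n_reason_categories}")
print(f"% distinct medications manual: {report.pct_medications_manual:.1f}")
print(f"% distinct reasons manual:     {report.pct_reasons_manual:.1f}")
print(f"\nartifacts: {sorted(p.name for p in out_dir.iterdir())}")
print(json.loads((out_dir / 'report.json').read_text()))
# The manual percentages are over distinct terms: each distinct unmappable
# term counts once no matter how many records repeat it.
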