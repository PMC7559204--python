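"""Summary reporting and the end-to-end pipeline runner.

`summarize` condenses a pipeline run into feature-set sizes: raw record
counts, counts after supplement removal, distinct raw terms, category counts
after mapping, and the share of distinct terms still requiring manual
curation (the convention is to count distinct terms, not records, when
quoting manual workload).

`run_pipeline` wires everything together — load lexicons, medication branch,
reason branch, overrides, summary — and optionally writes four artifacts to
an output directory: ``medications.tsv``, ``reasons.tsv``,
``manual_queue.tsv`` and ``report.json``.  Outputs carry no timestamps and
are byte-identical across repeated identical invocations.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .lexicon import BundleAdapter, LexiconBundle, OntologyAdapter, load_bundle
from .match import Combinator, MatchPolicy
from .meds import DEFAULT_FORM_STOPLIST, MedMatch, MedStatus, process_medications
from .reasons import ReasonMatch, ReasonStatus, process_reasons
from .records import RawRecord, read_records_tsv

__all__ = [
    "SummaryReport",
    "PipelineConfig",
    "PipelineResult",
    "summarize",
    "run_pipeline",
    "read_overrides_tsv",
]

logger = logging.getLogger("medtext")


@dataclass(frozen=True)
class SummaryReport:
    """Feature-set sizes for one pipeline run."""

    n_records: int
    n_after_supplement_removal: int
    n_distinct_raw_medications: int
    n_medication_categories: int
    n_distinct_raw_reasons: int
    n_reason_categories: int
    pct_medications_manual: float
    pct_reasons_manual: float

    def __post_init__(self) -> None:
        if self.n_after_supplement_removal > self.n_records:
            raise ValueError("records after supplement removal exceed total records")
        # NOTE: n_medication_categories may legitimately exceed the distinct
        # raw term count because one drug can map to multiple ATC classes;
        # each reason term maps to at most one category, so there the bound
        # is a real invariant.
        if self.n_reason_categories > self.n_distinct_raw_reasons:
            raise ValueError("reason categories exceed distinct raw terms")
        for name in ("pct_medications_manual", "pct_reasons_manual"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {value}")


def _fold_term(text: str) -> str:
    return " ".join(text.casefold().split())


def summarize(
    med_results: Sequence[MedMatch],
    reason_results: Sequence[ReasonMatch],
) -> SummaryReport:
    """Compute feature-set sizes from completed pipeline runs.

    Distinct raw terms are counted after case folding and whitespace
    collapsing; empty raw fields are not counted as terms.  Manual
    percentages are over distinct terms — for medications, over distinct
    non-supplement terms (a distinct term counts as manual only if none of
    its records mapped).
    """
    med_terms: Dict[str, bool] = {}
    supplement_terms = set()
    categories = set()
    for result in med_results:
        term = _fold_term(result.raw)
        if not term:
            continue
        if result.status is MedStatus.SUPPLEMENT_EXCLUDED:
            supplement_terms.add(term)
            continue
        mapped = result.status is MedStatus.MAPPED
        med_terms[term] = med_terms.get(term, False) or mapped
        if mapped:
            categories.update(code.code for code in result.atc_classes)

    reason_terms: Dict[str, bool] = {}
    reason_categories = set()
    for result in reason_results:
        term = _fold_term(result.raw)
        if not term:
            continue
        auto = result.status is not ReasonStatus.MANUAL_QUEUE
        reason_terms[term] = reason_terms.get(term, False) or auto
        if result.category is not None:
            reason_categories.add(result.category)

    n_records = len(med_results)
    n_after = sum(1 for r in med_results if r.status is not MedStatus.SUPPLEMENT_EXCLUDED)
    n_distinct_meds = len(med_terms) + len(supplement_terms - set(med_terms))
    pct_med_manual = (
        100.0 * sum(1 for auto in med_terms.values() if not auto) / len(med_terms)
        if med_terms
        else 0.0
    )
    pct_reason_manual = (
        100.0 * sum(1 for auto in reason_terms.values() if not auto) / len(reason_terms)
        if reason_terms
        else 0.0
    )
    return SummaryReport(
        n_records=n_records,
        n_after_supplement_removal=n_after,
        n_distinct_raw_medications=n_distinct_meds,
        n_medication_categories=len(categories),
        n_distinct_raw_reasons=len(reason_terms),
        n_reason_categories=len(reason_categories),
        pct_medications_manual=pct_med_manual,
        pct_reasons_manual=pct_reason_manual,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; defaults are the package's standard thresholds.

    Precedence when building a config: explicit keyword arguments beat values
    from a JSON config file, which beat these defaults (mirroring the usual
    flags > file > defaults behavior of batch tools).
    """

    ratio_threshold: float = 0.85
    distance_threshold: int = 2
    med_combinator: Combinator = Combinator.ANY
    reason_combinator: Combinator = Combinator.ALL
    atc_level: int = 3
    form_stoplist: frozenset = DEFAULT_FORM_STOPLIST

    def __post_init__(self) -> None:
        if self.atc_level not in (1, 2, 3):
            raise ValueError(f"atc_level must be 1..3, got {self.atc_level}")

    @property
    def med_policy(self) -> MatchPolicy:
        return MatchPolicy(self.ratio_threshold, self.distance_threshold, self.med_combinator)

    @property
    def reason_policy(self) -> MatchPolicy:
        return MatchPolicy(self.ratio_threshold, self.distance_threshold, self.reason_combinator)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file, with keyword arguments taking precedence."""
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**payload, **overrides}
        if "form_stoplist" in merged:
            merged["form_stoplist"] = frozenset(merged["form_stoplist"])
        for key in ("med_combinator", "reason_combinator"):
            if key in merged:
                merged[key] = Combinator(merged[key])
        return cls(**merged)


@dataclass(frozen=True)
class PipelineResult:
    med_results: List[MedMatch]
    reason_results: List[ReasonMatch]
    report: SummaryReport


def read_overrides_tsv(path: str | Path) -> Dict[str, str]:
    """Read a curator override table (columns reason_raw, category)."""
    overrides: Dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != ["reason_raw", "category"]:
            raise ValueError(f"expected header ['reason_raw', 'category'], got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2 or not row[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed override row {row}")
            overrides[row[0]] = row[1].strip()
    return overrides


def _write_medications_tsv(results: Sequence[MedMatch], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "subject_id", "medication_raw", "status", "canonical_name",
                "concept_id", "atc_codes", "match_distance", "match_ratio",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.subject_id,
                    r.raw,
                    r.status.value,
                    r.canonical_name or "",
                    r.concept_id or "",
                    "|".join(
                        f"{c.code}:{c.label}"
                        for c in sorted(r.atc_classes, key=lambda c: c.code)
                    ),
                    "" if r.match_distance is None else r.match_distance,
                    "" if r.match_ratio is None else f"{r.match_ratio:.6f}",
                ]
            )


def _write_reasons_tsv(results: Sequence[ReasonMatch], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "subject_id", "reason_raw", "corrected", "stem_string",
                "status", "category", "match_distance", "match_ratio",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.subject_id,
                    r.raw,
                    r.corrected,
                    r.stem_string,
                    r.status.value,
                    r.category or "",
                    "" if r.match_distance is None else r.match_distance,
                    "" if r.match_ratio is None else f"{r.match_ratio:.6f}",
                ]
            )


def _write_manual_queue_tsv(
    med_results: Sequence[MedMatch],
    reason_results: Sequence[ReasonMatch],
    path: Path,
) -> None:
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["branch", "subject_id", "raw"])
        for m in med_results:
            if m.status is MedStatus.MANUAL_QUEUE:
                writer.writerow(["medication", m.subject_id, m.raw])
        for r in reason_results:
            if r.status is ReasonStatus.MANUAL_QUEUE:
                writer.writerow(["reason", r.subject_id, r.raw])


def run_pipeline(
    records: Sequence[RawRecord] | str | Path,
    bundle: LexiconBundle | str | Path,
    config: PipelineConfig = PipelineConfig(),
    overrides: Optional[Mapping[str, str]] = None,
    adapter: Optional[OntologyAdapter] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Execute load -> medication branch -> reason branch -> overrides -> summary.

    *records* and *bundle* may be in-memory objects or paths (a records TSV
    and a lexicon directory).  When *out_dir* is given, writes
    ``medications.tsv``, ``reasons.tsv``, ``manual_queue.tsv`` and
    ``report.json`` there; outputs are deterministic byte-for-byte.
    """
    if isinstance(records, (str, Path)):
        records = read_records_tsv(records)
    if isinstance(bundle, (str, Path)):
        bundle = load_bundle(bundle)
    if adapter is None:
        adapter = BundleAdapter(bundle)

    logger.info("processing %d records", len(records))
    med_results = process_medications(
        records,
        bundle,
        policy=config.med_policy,
        adapter=adapter,
        atc_level=config.atc_level,
        form_stoplist=config.form_stoplist,
    )
    logger.info(
        "medication branch: %d mapped, %d supplements, %d manual",
        sum(r.status is MedStatus.MAPPED for r in med_results),
        sum(r.status is MedStatus.SUPPLEMENT_EXCLUDED for r in med_results),
        sum(r.status is MedStatus.MANUAL_QUEUE for r in med_results),
    )
    reason_results = process_reasons(
        records, bundle, policy=config.reason_policy, overrides=overrides
    )
    logger.info(
        "reason branch: %d auto, %d overridden, %d manual",
        sum(r.status is ReasonStatus.AUTO for r in reason_results),
        sum(r.status is ReasonStatus.OVERRIDDEN for r in reason_results),
        sum(r.status is ReasonStatus.MANUAL_QUEUE for r in reason_results),
    )
    report = summarize(med_results, reason_results)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_medications_tsv(med_results, out_dir / "medications.tsv")
        _write_reasons_tsv(reason_results, out_dir / "reasons.tsv")
        _write_manual_queue_tsv(med_results, reason_results, out_dir / "manual_queue.tsv")
        (out_dir / "report.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return PipelineResult(list(med_results), list(reason_results), report)
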